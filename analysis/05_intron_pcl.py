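#!/usr/bin/env python
"""Intron position classes: site extraction, reference projection, census."""

import argparse
import json
from pathlib import Path

from mitocomp.genbank_io import extract_cds, get_gene, read_genbank_dir
from mitocomp.intron_pcl import classify_pcls, extract_intron_sites, map_to_reference, pcl_matrix


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--panel", type=Path, default=Path("results/panel"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    records = read_genbank_dir(args.panel)
    panel = json.loads((args.panel / "panel.json").read_text())
    ref = panel["reference_cox1"]

    assignments = {}
    hit = total = 0
    for rec in records:
        man = json.loads((args.panel / f"{rec.id}.manifest.json").read_text())
        sites = extract_intron_sites(rec, "cox1")
        cds = extract_cds(rec, get_gene(rec, "cox1"))
        labelled = map_to_reference(cds, ref, sites)
        assignments[rec.id] = {l for _, l, _ in labelled}
        planted = set(man["intron_sites"].get("cox1", []))
        total += len(planted)
        hit += len({int(l[1:]) for _, l, _ in labelled} & planted)

    summary = classify_pcls(assignments)
    summary.to_csv(args.outdir / "pcl_summary.tsv", sep="\t", index=False)
    pcl_matrix(assignments).to_csv(args.outdir / "pcl_matrix.tsv", sep="\t")
    n_common = int((summary["status"] == "common").sum())
    print(f"planted-site recovery: {hit}/{total}")
    print(f"{len(summary)} Pcls across the panel "
          f"({n_common} common, {len(summary) - n_common} rare)")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
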