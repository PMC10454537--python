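#!/usr/bin/env python
"""Repeats: interspersed self-hits, tandem tracts, genome coverage."""

import argparse
import json
from pathlib import Path

import pandas as pd

from mitocomp.genbank_io import read_genbank_dir
from mitocomp.repeats import find_interspersed, find_tandem, hits_table, repeat_proportion


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--panel", type=Path, default=Path("results/panel"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    records = read_genbank_dir(args.panel)

    rows, all_hits = [], []
    for rec in records:
        man = json.loads((args.panel / f"{rec.id}.manifest.json").read_text())
        hits = find_interspersed(rec.sequence)
        tandems = find_tandem(rec.sequence)
        prop = repeat_proportion(hits, tandems, rec.length)
        planted = [r for r in man["repeats"] if r["kind"] == "interspersed"]
        recovered = sum(
            any(h.length >= 0.8 * r["length"] for h in hits) for r in planted
        )
        rows.append({
            "genome": rec.id, "n_interspersed": len(hits), "n_tandem": len(tandems),
            "interspersed_pct": 100 * prop["interspersed_frac"],
            "tandem_pct": 100 * prop["tandem_frac"],
            "planted_recovered": f"{recovered}/{len(planted)}",
        })
        ht = hits_table(hits)
        ht.insert(0, "genome", rec.id)
        all_hits.append(ht)

    df = pd.DataFrame(rows)
    df.to_csv(args.outdir / "repeats.tsv", sep="\t", index=False)
    pd.concat(all_hits).to_csv(args.outdir / "repeat_hits.tsv", sep="\t", index=False)
    print("wrote repeats.tsv and repeat_hits.tsv")
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
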