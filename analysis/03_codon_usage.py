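#!/usr/bin/env python
"""Codon usage: RSCU matrix, start/stop audit, AT-rich vs GC-rich usage."""

import argparse
from pathlib import Path

from mitocomp.codon_usage import (
    genome_codon_table,
    modal_codons,
    rich_codon_usage,
    rscu_matrix,
    start_stop_audit,
)
from mitocomp.genbank_io import read_genbank_dir


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--panel", type=Path, default=Path("results/panel"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    records = read_genbank_dir(args.panel)

    mat = rscu_matrix(records, genes="core")
    mat.round(4).to_csv(args.outdir / "rscu_core.tsv", sep="\t")
    audit = start_stop_audit(records)
    audit.to_csv(args.outdir / "start_stop.tsv", sep="\t", index=False)
    modal = modal_codons(audit)
    modal.to_csv(args.outdir / "modal_codons.tsv", sep="\t", index=False)

    total = None
    for rec in records:
        t = genome_codon_table(rec, genes="core")
        total = t if total is None else total + t
    rich = rich_codon_usage(total)
    top = max(total.counts, key=lambda c: total.counts[c])
    print(f"wrote rscu_core.tsv ({mat.shape[0]} x {mat.shape[1]}), start_stop.tsv")
    print(f"modal stop codon across genes: {set(modal['modal_stop'])}")
    print(f"top codon {top.replace('T', 'U')}; "
          f"AT-rich codon usage {rich['at_rich_frac'] * 100:.1f}% "
          f"of {rich['total_codons']:,} codons")


if __name__ == "__main__":
    main()
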