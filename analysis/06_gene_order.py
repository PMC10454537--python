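#!/usr/bin/env python
"""Gene order: 17-marker arrangements and breakpoint distances."""

import argparse
from pathlib import Path

from mitocomp.gene_order import distance_matrix, extract_order, order_table
from mitocomp.genbank_io import read_genbank_dir


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--panel", type=Path, default=Path("results/panel"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    records = read_genbank_dir(args.panel)

    orders = [extract_order(r) for r in records]
    order_table(orders).to_csv(args.outdir / "gene_orders.tsv", sep="\t", index=False)
    dm = distance_matrix(orders)
    dm.to_csv(args.outdir / "breakpoint_matrix.tsv", sep="\t")
    print("wrote gene_orders.tsv and breakpoint_matrix.tsv")
    for o in orders:
        print(f"  {o.species}: {' '.join(o.markers)}")
    print("breakpoint distances:")
    print(dm.to_string())


if __name__ == "__main__":
    main()
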