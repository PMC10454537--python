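"""Circular gene-order extraction and rearrangement comparison.

The order of the 17 conserved markers (15 core PCGs + rns + rnl) around the
circle is a rearrangement signature: orders are normalised to start at cox1
with cox1 in forward orientation, and two genomes are compared by their
shared circular adjacencies.  The breakpoint distance is the number of
adjacencies of one order absent from the other; it is 0 exactly when the
orders coincide up to rotation (and, in unsigned mode, reflection of the
strand labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genbank_io import CORE_PCGS, MitogenomeRecord

__all__ = ["GeneOrder", "OrderComparison", "MARKERS", "extract_order", "compare_orders"]

#: The 17 markers used for gene-order comparison (tRNAs excluded).
MARKERS = frozenset(CORE_PCGS | {"rns", "rnl"})


@dataclass
class GeneOrder:
    markers: list[str]  # signed names: "cox1" (forward) or "-cox1" (reverse)
    species: str
    circular: bool = True
    missing: list[str] = field(default_factory=list)

    def names(self) -> list[str]:
        return [m.lstrip("-") for m in self.markers]


@dataclass(frozen=True)
class OrderComparison:
    identical: bool
    shared_adjacencies: int
    breakpoint_distance: int


def _signed(name: str, strand: str) -> str:
    return name if strand == "+" else f"-{name}"


def _flip(marker: str) -> str:
    return marker.lstrip("-") if marker.startswith("-") else f"-{marker}"


def extract_order(record: MitogenomeRecord) -> GeneOrder:
    """Marker order around the circle, rotated to cox1, oriented cox1-forward.

    Markers are sorted by start coordinate; if cox1 lies on the minus strand
    the whole order is reverse-complemented (list reversed, signs flipped)
    before rotation, so the result is invariant to which strand the genome
    was deposited on.
    """
    found: dict[str, tuple[int, str]] = {}
    duplicates = []
    for feat in record.features:
        if feat.kind in {"intron", "exon_segment"}:
            continue
        if feat.name in MARKERS:
            if feat.name in found:
                duplicates.append(feat.name)
                continue
            found[feat.name] = (feat.start, feat.strand)
    if duplicates:
        raise ValueError(f"{record.id}: duplicated markers {sorted(set(duplicates))}")
    if "cox1" not in found:
        raise ValueError(f"{record.id}: cox1 not annotated; cannot normalise order")
    ordered = sorted(found.items(), key=lambda kv: kv[1][0])
    markers = [_signed(name, strand) for name, (_, strand) in ordered]
    if found["cox1"][1] == "-":
        markers = [_flip(m) for m in reversed(markers)]
    idx = markers.index("cox1")
    markers = markers[idx:] + markers[:idx]
    missing = sorted(MARKERS - set(found))
    return GeneOrder(markers=markers, species=record.id, missing=missing)


def _adjacencies_unsigned(markers: list[str], circular: bool) -> set[frozenset[str]]:
    names = [m.lstrip("-") for m in markers]
    pairs = list(zip(names, names[1:]))
    if circular and len(names) > 1:
        pairs.append((names[-1], names[0]))
    return {frozenset(p) for p in pairs}


def _adjacencies_signed(markers: list[str], circular: bool) -> set[tuple[str, str]]:
    pairs = list(zip(markers, markers[1:]))
    if circular and len(markers) > 1:
        pairs.append((markers[-1], markers[0]))
    # an adjacency a->b reads as -b->-a on the other strand
    out = set()
    for a, b in pairs:
        out.add((a, b))
        out.add((_flip(b), _flip(a)))
    return out


def compare_orders(a: GeneOrder, b: GeneOrder, signed: bool = False) -> OrderComparison:
    """Breakpoint comparison of two circular gene orders.

    Markers missing from either order are dropped pairwise before comparing.
    In unsigned mode (default) an adjacency is an unordered marker pair; in
    signed mode orientation matters (an adjacency matches its reverse
    complement).
    """
    names_a, names_b = set(a.names()), set(b.names())
    common = names_a & names_b
    if not common:
        raise ValueError("compare_orders: disjoint marker sets")
    ma = [m for m in a.markers if m.lstrip("-") in common]
    mb = [m for m in b.markers if m.lstrip("-") in common]
    if signed:
        adj_a = _adjacencies_signed(ma, a.circular)
        adj_b = _adjacencies_signed(mb, b.circular)
        shared = len(adj_a & adj_b) // 2
        distance = len([x for x in _pairs_signed(ma, a.circular) if x not in adj_b])
    else:
        adj_a = _adjacencies_unsigned(ma, a.circular)
        adj_b = _adjacencies_unsigned(mb, b.circular)
        shared = len(adj_a & adj_b)
        distance = len(adj_a - adj_b)
    return OrderComparison(
        identical=(distance == 0), shared_adjacencies=shared, breakpoint_distance=distance
    )


def _pairs_signed(markers: list[str], circular: bool) -> list[tuple[str, str]]:
    pairs = list(zip(markers, markers[1:]))
    if circular and len(markers) > 1:
        pairs.append((markers[-1], markers[0]))
    return pairs


def order_table(orders: list[GeneOrder]) -> pd.DataFrame:
    rows = [
        {
            "species": o.species,
            "order": " ".join(o.markers),
            "missing": ",".join(o.missing),
        }
        for o in orders
    ]
    return pd.DataFrame(rows)


def distance_matrix(orders: list[GeneOrder], signed: bool = False) -> pd.DataFrame:
    n = len(orders)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = compare_orders(orders[i], orders[j], signed=signed).breakpoint_distance
            mat[i, j] = mat[j, i] = d
    labels = [o.species for o in orders]
    return pd.DataFrame(mat, index=labels, columns=labels)
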