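"""Repeat detection: genome self-comparison and tandem periodicity scan.

Interspersed repeats are found by comparing the genome against itself (and
its reverse complement) with exact 15-mer seeds, chaining seeds on a common
diagonal and extending them ungapped under an x-drop rule; hits are kept when
they reach ``min_len`` bases at ``min_identity`` percent identity.  These
explicit thresholds replace database-dependent e-value cutoffs, making the
scan reproducible; the defaults (30 bp, 80%) sit at the identity floor
reported for Cyathus mitogenome repeats.

Tandem repeats are found by a periodicity scan: for each period p, maximal
runs of positions with seq[i] == seq[i+p] are extended and reported when the
repeat tract exceeds 10 bp; runs already explained by a smaller period that
divides p are suppressed.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genbank_io import reverse_complement

__all__ = [
    "RepeatHit",
    "TandemRepeat",
    "find_interspersed",
    "find_tandem",
    "repeat_proportion",
]

_SEED_K = 15
_XDROP = 20
_MATCH, _MISMATCH = 1, -2


@dataclass(frozen=True)
class RepeatHit:
    interval_a: tuple[int, int]  # 1-based inclusive
    interval_b: tuple[int, int]
    length: int
    identity: float  # percent
    strand: str  # '+' direct repeat, '-' inverted repeat


@dataclass(frozen=True)
class TandemRepeat:
    start: int  # 1-based
    period: int
    copies: float
    total_len: int
    consensus: str


def _seed_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return index


def _extend(seq_a: str, seq_b: str, ia: int, ib: int, k: int) -> tuple[int, int, int, int]:
    """Ungapped x-drop extension of a seed; returns (start_a, start_b, length, matches)."""
    best_left = 0
    score = best = 0
    off = 0
    while ia - off - 1 >= 0 and ib - off - 1 >= 0:
        off += 1
        score += _MATCH if seq_a[ia - off] == seq_b[ib - off] else _MISMATCH
        if score > best:
            best, best_left = score, off
        if best - score > _XDROP:
            break
    best_right = k
    score = best = 0
    off = k - 1
    while ia + off + 1 < len(seq_a) and ib + off + 1 < len(seq_b):
        off += 1
        score += _MATCH if seq_a[ia + off] == seq_b[ib + off] else _MISMATCH
        if score > best:
            best, best_right = score, off + 1
        if best - score > _XDROP:
            break
    start_a, start_b = ia - best_left, ib - best_left
    length = best_left + best_right
    matches = sum(
        seq_a[start_a + i] == seq_b[start_b + i] for i in range(length)
    )
    return start_a, start_b, length, matches


def _collect_hits(
    seq_a: str, seq_b: str, min_len: int, min_identity: float, same: bool
) -> list[tuple[int, int, int, float]]:
    """Seed/extend between two sequences; coordinates are 0-based starts.

    ``same=True`` marks self-comparison: the main diagonal is excluded and
    only pairs with a < b kept (mirror duplicates removed).
    """
    k = _SEED_K
    index = _seed_positions(seq_b, k)
    claimed: dict[int, list[tuple[int, int]]] = defaultdict(list)  # diagonal -> intervals
    hits = []
    for ia in range(len(seq_a) - k + 1):
        kmer = seq_a[ia : ia + k]
        for ib in index.get(kmer, ()):
            if same and ia >= ib:
                continue
            diag = ia - ib
            covered = any(s <= ia < e for s, e in claimed[diag])
            if covered:
                continue
            sa, sb, length, matches = _extend(seq_a, seq_b, ia, ib, k)
            claimed[diag].append((sa, sa + length))
            if length >= min_len:
                identity = 100.0 * matches / length
                if identity >= min_identity:
                    hits.append((sa, sb, length, identity))
    return hits


def _merge_hits(hits: list[tuple[int, int, int, float]]) -> list[tuple[int, int, int, float]]:
    """Merge overlapping hits on the same diagonal, keeping the longest span."""
    by_diag: dict[int, list[tuple[int, int, int, float]]] = defaultdict(list)
    for h in hits:
        by_diag[h[0] - h[1]].append(h)
    merged = []
    for diag, group in by_diag.items():
        group.sort()
        cur = list(group[0])
        for h in group[1:]:
            if h[0] <= cur[0] + cur[2]:  # overlap on diagonal
                new_end = max(cur[0] + cur[2], h[0] + h[2])
                # weighted identity over union
                cur_matches = cur[3] / 100.0 * cur[2]
                h_matches = h[3] / 100.0 * h[2]
                cur[2] = new_end - cur[0]
                cur[3] = min(100.0, 100.0 * (cur_matches + h_matches) / cur[2])
            else:
                merged.append(tuple(cur))
                cur = list(h)
        merged.append(tuple(cur))
    return merged


def find_interspersed(
    seq: str, min_len: int = 30, min_identity: float = 80.0
) -> list[RepeatHit]:
    """Interspersed (direct and inverted) repeats by self-comparison."""
    s = seq.upper()
    if len(s) < min_len:
        raise ValueError(f"sequence shorter than min_len={min_len}")
    out = []
    for sa, sb, length, identity in _merge_hits(
        _collect_hits(s, s, min_len, min_identity, same=True)
    ):
        out.append(
            RepeatHit(
                interval_a=(sa + 1, sa + length),
                interval_b=(sb + 1, sb + length),
                length=length,
                identity=round(identity, 2),
                strand="+",
            )
        )
    rc = reverse_complement(s)
    n = len(s)
    seen = set()
    for sa, sb_rc, length, identity in _merge_hits(
        _collect_hits(s, rc, min_len, min_identity, same=False)
    ):
        # map reverse-complement coordinates back to the forward strand
        sb = n - (sb_rc + length)
        ia = (sa + 1, sa + length)
        ib = (sb + 1, sb + length)
        if ia == ib:
            continue  # a palindrome aligned onto itself
        key = tuple(sorted([ia, ib]))
        if key in seen:
            continue
        seen.add(key)
        lo, hi = sorted([ia, ib])
        out.append(
            RepeatHit(
                interval_a=lo, interval_b=hi, length=length,
                identity=round(identity, 2), strand="-",
            )
        )
    out.sort(key=lambda h: (h.interval_a, h.interval_b))
    return out


def find_tandem(
    seq: str, max_period: int = 500, min_total: int = 11, min_copies: float = 2.0
) -> list[TandemRepeat]:
    """Tandem repeats via periodicity scan (vectorised over positions)."""
    s = seq.upper()
    if not s:
        raise ValueError("find_tandem: empty sequence")
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    n = len(arr)
    reported: list[TandemRepeat] = []
    for p in range(1, min(max_period, n - 1) + 1):
        eq = arr[: n - p] == arr[p:]
        if not eq.any():
            continue
        # maximal runs of True
        padded = np.concatenate(([False], eq, [False]))
        diffs = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diffs == 1)
        ends = np.flatnonzero(diffs == -1)  # exclusive
        runs = ends - starts
        keep = (runs + p >= min_total) & (runs >= p * (min_copies - 1.0))
        for st, en in zip(starts[keep], ends[keep]):
            run = en - st
            total = run + p
            copies = total / p
            if _explained_by_smaller(reported, st, total, p):
                continue
            consensus = s[st : st + p]
            reported.append(
                TandemRepeat(
                    start=int(st) + 1,
                    period=p,
                    copies=round(copies, 2),
                    total_len=int(total),
                    consensus=consensus,
                )
            )
    reported.sort(key=lambda t: (t.start, t.period))
    return reported


def _explained_by_smaller(
    reported: list[TandemRepeat], start: int, total: int, period: int
) -> bool:
    end = start + total
    for t in reported:
        if t.period >= period or period % t.period:
            continue
        t_start, t_end = t.start - 1, t.start - 1 + t.total_len
        overlap = min(end, t_end) - max(start, t_start)
        if overlap >= 0.9 * total:
            return True
    return False


def _interval_union(intervals: list[tuple[int, int]]) -> int:
    """Total bases covered by a union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return sum(e - s + 1 for s, e in merged)


def repeat_proportion(
    hits: list[RepeatHit], tandems: list[TandemRepeat], genome_bp: int
) -> dict[str, float]:
    """Fraction of the genome covered by each repeat class (interval union)."""
    inter = [h.interval_a for h in hits] + [h.interval_b for h in hits]
    tand = [(t.start, t.start + t.total_len - 1) for t in tandems]
    return {
        "interspersed_frac": _interval_union(inter) / genome_bp,
        "tandem_frac": _interval_union(tand) / genome_bp,
    }


def hits_table(hits: list[RepeatHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_a": h.interval_a[0], "end_a": h.interval_a[1],
                "start_b": h.interval_b[0], "end_b": h.interval_b[1],
                "length": h.length, "identity": h.identity, "strand": h.strand,
            }
            for h in hits
        ]
    )


def tandem_table(tandems: list[TandemRepeat]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start": t.start, "period": t.period, "copies": t.copies,
                "total_len": t.total_len, "consensus": t.consensus,
            }
            for t in tandems
        ]
    )
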