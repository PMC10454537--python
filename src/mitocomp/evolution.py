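"""Pairwise molecular-evolution metrics: K2P distance, NG86 Ka/Ks, NJ tree.

The Kimura 2-parameter distance separates transition (P) and transversion
(Q) proportions over ungapped alignment columns:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Ka/Ks follows Nei & Gojobori (1986): per-codon synonymous site fractions
under genetic code 4, pathway-averaged substitution counts for codons
differing at more than one position, and Jukes-Cantor correction
d = -3/4 * ln(1 - 4/3 * p) of the per-site proportions.  Mutational paths to
stop codons are excluded from the site fractions (normalising over non-stop
changes keeps Sa + Ss = 3 x codons) and pathways through stop codons are
dropped from the average unless every pathway hits one.

Gap handling is pairwise deletion: gapped columns (K2P) or gapped/ambiguous
codons (Ka/Ks) are removed per pair before counting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .codon_usage import codon_families, stop_codons

__all__ = [
    "AlignedPair",
    "K2PResult",
    "KaKsResult",
    "SaturationError",
    "k2p",
    "nei_gojobori",
    "gene_summary",
    "nj_tree",
    "global_align",
]

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class SaturationError(ValueError):
    """Distance undefined: substitution proportions outside the model's domain."""


@dataclass(frozen=True)
class AlignedPair:
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")


@dataclass(frozen=True)
class K2PResult:
    P: float
    Q: float
    d: float
    n: int


@dataclass(frozen=True)
class KaKsResult:
    Ka: float
    Ks: float
    ratio: float | None
    Na: float
    Ns: float
    Sa: float
    Ss: float
    codons: int


def is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def k2p(pair: AlignedPair) -> K2PResult:
    """Kimura 2-parameter distance with pairwise deletion of gapped columns."""
    ts = tv = n = 0
    for a, b in zip(pair.seq_a.upper(), pair.seq_b.upper()):
        if a not in "ACGT" or b not in "ACGT":
            continue
        n += 1
        if a == b:
            continue
        if is_transition(a, b):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("k2p: no comparable (ungapped ACGT) columns")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P saturated: P={P:.4f}, Q={Q:.4f}")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P=P, Q=Q, d=d, n=n)


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986


@lru_cache(maxsize=8)
def _code_maps(code_id: int):
    return codon_families(code_id), stop_codons(code_id)


@lru_cache(maxsize=None)
def _syn_sites(codon: str, code_id: int) -> float:
    """Synonymous site count of one codon (0..3).

    Per position, the synonymous fraction is computed over the non-stop
    single-base changes at that position.
    """
    fam, stops = _code_maps(code_id)
    aa = fam[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in stops:
                continue
            valid += 1
            if fam[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str, code_id: int) -> tuple[float, float]:
    """(Ns, Na) between two codons, averaged over minimal pathways.

    Pathways passing through a stop codon are excluded; if all pathways do,
    the average falls back to all pathways.
    """
    fam, stops = _code_maps(code_id)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = c1
        ns = na = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stops or cur in stops:
                through_stop = True
                step_syn = False
            else:
                step_syn = fam[cur] == fam[nxt]
            if step_syn:
                ns += 1
            else:
                na += 1
            cur = nxt
        all_paths.append((ns, na))
        if not through_stop:
            valid.append((ns, na))
    paths = valid if valid else all_paths
    ns_avg = sum(p[0] for p in paths) / len(paths)
    na_avg = sum(p[1] for p in paths) / len(paths)
    return ns_avg, na_avg


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differing sites."""
    if p >= 0.75:
        raise SaturationError(f"Jukes-Cantor saturated: p={p:.4f}")
    if p == 0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori(pair: AlignedPair, code_id: int = 4) -> KaKsResult:
    """NG86 Ka/Ks for a codon-aligned pair of coding sequences.

    Codons containing gaps or ambiguity codes are dropped pairwise; codons
    where either sequence has a premature stop are excluded (flag semantics:
    they simply do not contribute).  ``ratio`` is None when Ks == 0.
    """
    a, b = pair.seq_a.upper(), pair.seq_b.upper()
    if len(a) % 3:
        raise ValueError("nei_gojobori: aligned length must be a multiple of 3")
    _, stops = _code_maps(code_id)
    Ss = Na = Ns = 0.0
    ncod = 0
    sa = sb = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if set(ca + cb) - set("ACGT"):
            continue
        is_last = i == len(a) - 3
        if ca in stops or cb in stops:
            if not is_last:
                pass  # premature stop: excluded
            continue
        ncod += 1
        sa += _syn_sites(ca, code_id)
        sb += _syn_sites(cb, code_id)
        ns, na = _pathway_counts(ca, cb, code_id)
        Ns += ns
        Na += na
    if ncod == 0:
        raise ValueError("nei_gojobori: no comparable codons")
    Ss = (sa + sb) / 2.0
    Sa = 3.0 * ncod - Ss
    ps = Ns / Ss if Ss > 0 else 0.0
    pa = Na / Sa if Sa > 0 else 0.0
    Ks = jukes_cantor(ps)
    Ka = jukes_cantor(pa)
    ratio = (Ka / Ks) if Ks > 0 else None
    return KaKsResult(Ka=Ka, Ks=Ks, ratio=ratio, Na=Na, Ns=Ns, Sa=Sa, Ss=Ss, codons=ncod)


# ---------------------------------------------------------------------------
# Alignment helper (desk-scale fixtures; externally aligned FASTA is the
# primary input path)


def global_align(seq_a: str, seq_b: str) -> AlignedPair:
    """Global affine-gap alignment (match 1, mismatch -1, open -5, extend -1).

    The first traceback of Biopython's PairwiseAligner is used, giving a
    deterministic alignment.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    return AlignedPair(seq_a=str(aln[0]), seq_b=str(aln[1]))


# ---------------------------------------------------------------------------
# Per-gene aggregation


def _codon_alignable(seqs: dict[str, str]) -> bool:
    lens = {len(s) for s in seqs.values()}
    return len(lens) == 1 and next(iter(lens)) % 3 == 0


def gene_summary(gene: str, sequences: dict[str, str], code_id: int = 4) -> dict:
    """Aggregate pairwise K2P / Ka / Ks over a per-species CDS set.

    Sequences of equal length are treated as already (codon-)aligned;
    unequal lengths are globally aligned per pair first.  Saturated pairs are
    excluded from the summaries and counted in ``excluded_pairs``.  Both the
    mean and median of each metric across pairs are reported.
    """
    species = sorted(sequences)
    if len(species) < 2:
        raise ValueError(f"gene_summary({gene}): need >= 2 species")
    k2ps, kas, kss, ratios = [], [], [], []
    excluded = 0
    for sp1, sp2 in itertools.combinations(species, 2):
        s1, s2 = sequences[sp1], sequences[sp2]
        if len(s1) != len(s2):
            pair = global_align(s1, s2)
        else:
            pair = AlignedPair(s1, s2)
        try:
            k2ps.append(k2p(pair).d)
        except (SaturationError, ValueError):
            excluded += 1
            continue
        if len(pair.seq_a) % 3 == 0:
            try:
                res = nei_gojobori(pair, code_id)
            except (SaturationError, ValueError):
                excluded += 1
                continue
            kas.append(res.Ka)
            kss.append(res.Ks)
            if res.ratio is not None:
                ratios.append(res.ratio)
    return {
        "gene": gene,
        "n_species": len(species),
        "n_pairs": len(k2ps),
        "excluded_pairs": excluded,
        "k2p_median": float(np.median(k2ps)) if k2ps else None,
        "k2p_mean": float(np.mean(k2ps)) if k2ps else None,
        "ka_mean": float(np.mean(kas)) if kas else None,
        "ks_mean": float(np.mean(kss)) if kss else None,
        "kaks_mean": float(np.mean(ratios)) if ratios else None,
        "kaks_of_means": (float(np.mean(kas) / np.mean(kss)) if kas and kss and np.mean(kss) > 0 else None),
    }


def gene_summary_table(per_gene: dict[str, dict[str, str]], code_id: int = 4) -> pd.DataFrame:
    rows = [gene_summary(g, seqs, code_id) for g, seqs in sorted(per_gene.items()) if len(seqs) >= 2]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Neighbor joining (plumbing: desk-scale topology sanity check)


def nj_tree(distances: np.ndarray, labels: list[str]) -> tuple[object, str]:
    """Neighbor-joining tree from a symmetric distance matrix.

    Returns (skbio TreeNode, newick string); negative branch lengths are
    clamped to 0.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    mat = np.asarray(distances, dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("nj_tree: distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0):
        raise ValueError("nj_tree: diagonal must be zero")
    dm = DistanceMatrix(mat, ids=list(labels))
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    from io import StringIO

    buf = StringIO()
    tree.write(buf)
    return tree, buf.getvalue().strip()


def k2p_distance_matrix(sequences: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """Pairwise K2P distance matrix over a set of equal-length sequences."""
    labels = sorted(sequences)
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pair = AlignedPair(sequences[labels[i]], sequences[labels[j]])
        d = k2p(pair).d
        mat[i, j] = mat[j, i] = d
    return mat, labels
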