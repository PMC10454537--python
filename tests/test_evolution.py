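"""K2P, NG86 Ka/Ks (vs exhaustive pathway oracle), gene summaries, NJ tree."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from mitocomp.codon_usage import ALL_CODONS, codon_families, stop_codons
from mitocomp.evolution import (
    AlignedPair,
    SaturationError,
    _pathway_counts,
    _syn_sites,
    gene_summary,
    k2p,
    k2p_distance_matrix,
    nei_gojobori,
    nj_tree,
)
from mitocomp.synthetic_data import CodonEvolSpec, simulate_codon_pair

# ---------------------------------------------------------------------------
# independent oracle: recursive pathway enumeration, written separately from
# the implementation's permutation loop

_FAM = codon_families(4)
_STOPS = stop_codons(4)


def oracle_syn_sites(codon: str) -> float:
    total = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1 :] for b in "ACGT" if b != codon[pos]]
        alts = [a for a in alts if a not in _STOPS]
        if alts:
            total += sum(_FAM[a] == _FAM[codon] for a in alts) / len(alts)
    return total


def oracle_pathways(c1: str, c2: str):
    """All minimal substitution pathways as lists of (syn?, intermediate)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []

    def walk(cur, remaining, steps):
        if not remaining:
            paths.append(steps)
            return
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            syn = (
                cur not in _STOPS and nxt not in _STOPS and _FAM[cur] == _FAM[nxt]
            )
            walk(nxt, [p for p in remaining if p != pos],
                 steps + [(syn, nxt)])

    walk(c1, diff, [])
    return paths


def oracle_counts(c1: str, c2: str) -> tuple[float, float]:
    paths = oracle_pathways(c1, c2)
    ok = [p for p in paths if not any(i in _STOPS for _, i in p)]
    use = ok if ok else paths
    ns = sum(sum(s for s, _ in p) for p in use) / len(use)
    na = sum(sum(not s for s, _ in p) for p in use) / len(use)
    return ns, na


class TestK2P:
    def test_identical_sequences(self):
        res = k2p(AlignedPair("ACGTACGT", "ACGTACGT"))
        assert res.P == res.Q == 0.0
        assert res.d == 0.0

    def test_closed_form_example(self):
        # 20 sites: 2 transitions, 1 transversion -> P=0.1, Q=0.05
        a = "A" * 20
        b = "G" * 2 + "C" * 1 + "A" * 17
        res = k2p(AlignedPair(a, b))
        assert res.P == pytest.approx(0.1)
        assert res.Q == pytest.approx(0.05)
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.90)
        assert res.d == pytest.approx(expected)
        assert res.d == pytest.approx(0.1702, abs=5e-5)

    def test_saturation_all_transversions(self):
        with pytest.raises(SaturationError):
            k2p(AlignedPair("AAAA", "CCCC"))

    def test_gapped_columns_pairwise_deleted(self):
        res = k2p(AlignedPair("AC-GT", "ACAGT"))
        assert res.n == 4 and res.d == 0.0

    def test_monotonic_in_p_and_q(self):
        def d(p, q):
            return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)

        for p, q in [(0.05, 0.05), (0.1, 0.1), (0.2, 0.05)]:
            assert d(p + 0.01, q) > d(p, q)
            assert d(p, q + 0.01) > d(p, q)

    def test_matches_jukes_cantor_under_jc_pattern(self):
        # JC expects transitions:transversions = 1:2; with P = Q/2 exactly
        # satisfied at p_total = P + Q, K2P reduces to the JC value
        n = 12000
        nts, ntv = 400, 800
        a = "A" * n
        b = "G" * nts + "C" * (ntv // 2) + "T" * (ntv // 2) + "A" * (n - nts - ntv)
        res = k2p(AlignedPair(a, b))
        p = (nts + ntv) / n
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert res.d == pytest.approx(jc, abs=1e-4)


class TestNeiGojobori:
    def test_identical_pair(self):
        res = nei_gojobori(AlignedPair("ATGAAATTA", "ATGAAATTA"))
        assert res.Ka == res.Ks == 0.0
        assert res.ratio is None

    def test_single_synonymous_difference(self):
        # Gly -> Gly: the single pathway is synonymous
        ns, na = _pathway_counts("GGA", "GGG", 4)
        assert (ns, na) == (1.0, 0.0)
        # embedded in a longer CDS the counts surface in the result
        res = nei_gojobori(
            AlignedPair("ATGAAATTACCTGGA", "ATGAAATTACCTGGG")
        )
        assert res.Ns == 1.0 and res.Na == 0.0

    def test_two_difference_pathway_average(self):
        ns, na = _pathway_counts("AAA", "AGC", 4)
        ons, ona = oracle_counts("AAA", "AGC")
        assert (ns, na) == pytest.approx((ons, ona))
        assert ns + na == pytest.approx(2.0)

    def test_site_counts_partition_three_sites(self):
        for codon in ("ATG", "TTA", "GGG", "TGA"):
            s = _syn_sites(codon, 4)
            assert 0.0 <= s <= 3.0
            assert s == pytest.approx(oracle_syn_sites(codon))

    def test_oracle_equivalence_all_codon_pairs(self):
        """Pathway counts match exhaustive enumeration on all 64x64 pairs."""
        sense = [c for c in ALL_CODONS if c not in _STOPS]
        for c1, c2 in itertools.product(sense, repeat=2):
            ns, na = _pathway_counts(c1, c2, 4)
            ons, ona = oracle_counts(c1, c2)
            assert ns == pytest.approx(ons), (c1, c2)
            assert na == pytest.approx(ona), (c1, c2)
            ndiff = sum(a != b for a, b in zip(c1, c2))
            assert ns + na == pytest.approx(ndiff)

    def test_sites_sum_rule(self):
        a = "ATGAAATTAGGGCCTACTGTTCAT"
        b = "ATGAAGTTAGGGCCAACTGTTCAT"
        res = nei_gojobori(AlignedPair(a, b))
        assert res.Sa + res.Ss == pytest.approx(3 * res.codons)

    def test_frame_violation_raises(self):
        with pytest.raises(ValueError):
            nei_gojobori(AlignedPair("ATGA", "ATGA"))

    def test_gapped_codons_dropped(self):
        res = nei_gojobori(AlignedPair("ATG---TTA", "ATGAAATTA"))
        assert res.codons == 2

    @pytest.mark.parametrize("omega", [0.1, 0.5, 1.0])
    def test_omega_recovery(self, omega):
        """NG86 recovers the simulated Ka/Ks within +-0.1 at 10,000 codons."""
        anc, der, _ = simulate_codon_pair(
            CodonEvolSpec(omega=omega, n_codons=10_000, seed=17)
        )
        res = nei_gojobori(AlignedPair(anc, der))
        assert res.ratio == pytest.approx(omega, abs=0.1)
        if omega < 1:
            assert res.ratio < 1


class TestGeneSummary:
    def test_identical_species_zero_distance(self):
        cds = "ATGAAATTAGGGTAA"
        out = gene_summary("toy", {"s1": cds, "s2": cds})
        assert out["k2p_median"] == 0.0

    def test_planted_divergence_ordering(self):
        rng = np.random.default_rng(5)
        base = "ATG" + "".join(rng.choice(["GCT", "AAA", "TTA", "GGT"], size=400)) + "TAA"

        def mutate(seq, n):
            s = list(seq)
            pos = rng.choice(len(s) - 6, size=n, replace=False) + 3
            for p in pos:
                s[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[s[p]]
            return "".join(s)

        fast = {"a": base, "b": mutate(base, 90), "c": mutate(base, 120)}
        slow = {"a": base, "b": mutate(base, 30), "c": mutate(base, 40)}
        assert (
            gene_summary("fast", fast)["k2p_median"]
            > gene_summary("slow", slow)["k2p_median"]
        )

    def test_purifying_selection_panel(self, panel):
        """Genes evolved at omega<1 show mean Ka/Ks below 1."""
        from mitocomp.genbank_io import classify_features, extract_cds

        records, _, _ = panel
        seqs = {}
        for rec in records:
            classes = classify_features(rec)
            for i, cls in classes.items():
                if cls == "core_pcg" and rec.features[i].name == "cox1":
                    seqs[rec.id] = extract_cds(rec, rec.features[i])
        out = gene_summary("cox1", seqs)
        assert out["kaks_mean"] is not None and out["kaks_mean"] < 1

    def test_single_species_raises(self):
        with pytest.raises(ValueError):
            gene_summary("x", {"only": "ATGTAA"})


class TestNJ:
    def test_three_taxon_closed_form(self):
        # d(a,b)=0.3, d(a,c)=0.4, d(b,c)=0.5 -> branch lengths
        # a=(0.3+0.4-0.5)/2=0.1, b=(0.3+0.5-0.4)/2=0.2, c=(0.4+0.5-0.3)/2=0.3
        mat = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
        tree, _ = nj_tree(mat, ["a", "b", "c"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.3)

    def test_additive_four_taxon_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        mat = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree, newick = nj_tree(mat, ["a", "b", "c", "d"])
        # the split {a,b} | {c,d} must be present
        names = lambda node: {t.name for t in node.tips()}
        splits = {frozenset(names(n)) for n in tree.non_tips()}
        assert frozenset({"a", "b"}) in splits or frozenset({"c", "d"}) in splits
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["d"] == pytest.approx(4.0)

    def test_asymmetric_matrix_raises(self):
        mat = np.array([[0, 1.0, 2], [1, 0, 3], [2, 3.1, 0]])
        with pytest.raises(ValueError):
            nj_tree(mat, list("abc"))

    def test_planted_panel_topology_recovered(self, panel):
        from io import StringIO

        from skbio import TreeNode

        from mitocomp.genbank_io import classify_features, extract_cds
        from mitocomp.synthetic_data import PANEL_NEWICK

        records, _, _ = panel
        concat = {}
        for rec in records:
            classes = classify_features(rec)
            seqs = {
                rec.features[i].name: extract_cds(rec, rec.features[i])
                for i, cls in classes.items()
                if cls == "core_pcg"
            }
            concat[rec.id] = "".join(seqs[g] for g in sorted(seqs))
        mat, labels = k2p_distance_matrix(concat)
        tree, _ = nj_tree(mat, labels)
        planted = TreeNode.read(StringIO(PANEL_NEWICK))
        rf = tree.compare_rfd(planted)
        assert rf == 0
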