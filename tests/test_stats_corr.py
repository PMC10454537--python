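"""Pearson and Wilcoxon statistics against enumeration/arithmetic oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from mitocomp.stats_corr import (
    component_correlations,
    pearson_test,
    wilcoxon_rank_sum,
)


def oracle_wilcoxon_two_sided(x, y) -> float:
    """Exact two-sided p by enumerating all rank assignments."""
    pooled = sorted(list(x) + list(y))
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # tie-free inputs only
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    all_ranks = list(range(1, len(pooled) + 1))
    for combo in itertools.combinations(all_ranks, n1):
        us.append(sum(combo) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(1, 8, dtype=float)
        res = pearson_test(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(1, 8, dtype=float)
        assert pearson_test(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        # covariance/variance arithmetic: sum(dx*dy)=10, sum(dx^2)=10,
        # sum(dy^2)=14.8 -> r = 10/sqrt(148)
        r_hand = 10 / math.sqrt(148)
        t_hand = r_hand * math.sqrt(3 / (1 - r_hand**2))
        p_hand = 2 * sps.t.sf(abs(t_hand), df=3)
        res = pearson_test(x, y)
        assert res.r == pytest.approx(r_hand)
        assert res.t_stat == pytest.approx(t_hand)
        assert res.p == pytest.approx(p_hand, rel=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        base = pearson_test(x, y)
        scaled = pearson_test(3 * x + 7, y)
        assert scaled.r == pytest.approx(base.r)
        assert scaled.p == pytest.approx(base.p)
        flipped = pearson_test(-2 * x, y)
        assert flipped.r == pytest.approx(-base.r)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            pearson_test([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            pearson_test([1, 2], [3, 4])

    def test_type_one_error_calibration(self):
        """Under the null, rejection at alpha=0.05 happens 5% +- 1% of the time."""
        rng = np.random.default_rng(2024)
        n, reps = 20, 10_000
        rejections = 0
        xs = rng.normal(size=(reps, n))
        ys = rng.normal(size=(reps, n))
        # closed-form p from r (identical to the scipy path, but vectorised so
        # the calibration finishes quickly); spot-check agreement first
        spot = pearson_test(xs[0], ys[0])
        r = (
            ((xs - xs.mean(1, keepdims=True)) * (ys - ys.mean(1, keepdims=True))).sum(1)
            / np.sqrt(((xs - xs.mean(1, keepdims=True)) ** 2).sum(1))
            / np.sqrt(((ys - ys.mean(1, keepdims=True)) ** 2).sum(1))
        )
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * sps.t.sf(np.abs(t), df=n - 2)
        assert p[0] == pytest.approx(spot.p, rel=1e-9)
        rate = float(np.mean(p < 0.05))
        assert rate == pytest.approx(0.05, abs=0.01)


class TestWilcoxon:
    def test_complete_separation_three_vs_three(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p == pytest.approx(0.1)  # 2 * 1/20

    def test_identical_samples_near_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.1, 2.1, 2.9])
        assert res.p >= 0.6

    def test_exact_matches_enumeration_all_small_sizes(self):
        """Exact p equals full enumeration for every n_x, n_y <= 6."""
        rng = np.random.default_rng(11)
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2) + rng.normal() * 0.5
                res = wilcoxon_rank_sum(x, y)
                assert res.method == "exact"
                assert res.p == pytest.approx(oracle_wilcoxon_two_sided(x, y))

    def test_ties_use_normal_approximation(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [2.0, 4.0, 5.0, 5.0]
        res = wilcoxon_rank_sum(x, y)
        assert res.method == "normal-approx"
        assert 0 < res.p <= 1

    def test_tied_p_close_to_permutation_oracle(self):
        rng = np.random.default_rng(12)
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 3.0, 4.0, 4.0, 6.0])
        res = wilcoxon_rank_sum(x, y)
        # permutation oracle on the tied data (rank-sum statistic)
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        w_obs = ranks[: len(x)].sum()
        ws = []
        for combo in itertools.combinations(range(10), 5):
            ws.append(ranks[list(combo)].sum())
        ws = np.array(ws)
        mean_w = ws.mean()
        p_perm = min(1.0, 2 * min(
            np.mean(ws <= w_obs), np.mean(ws >= w_obs)
        ))
        assert res.p == pytest.approx(p_perm, abs=0.1)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestComponentCorrelations:
    def test_planted_linear_relationship(self):
        """A component tracking genome size is flagged with r ~ 1."""
        import pandas as pd

        rng = np.random.default_rng(13)
        n = 20
        size = rng.integers(40_000, 260_000, size=n).astype(float)
        rows = []
        for i in range(n):
            un_orf = 0.2 * size[i] + rng.normal(0, 2_000)
            rna = rng.normal(8_000, 300)  # size-independent
            rows.append(
                {
                    "genome": f"g{i}", "genome_bp": size[i],
                    "core_pcg_bp": rng.normal(15_000, 500),
                    "rna_bp": rna, "heg_bp": 0.05 * size[i] + rng.normal(0, 1_000),
                    "un_orf_bp": un_orf,
                    "intron_bp": 0.1 * size[i] + rng.normal(0, 1_500),
                    "intergenic_bp": 0.4 * size[i] + rng.normal(0, 3_000),
                }
            )
        df = pd.DataFrame(rows)
        corr = component_correlations(df).set_index("component")
        assert corr.loc["un_orf", "r"] > 0.9
        assert corr.loc["un_orf", "p"] < 1e-6
        assert abs(corr.loc["rna", "r"]) < 0.5

    def test_needs_three_genomes(self):
        import pandas as pd

        with pytest.raises(ValueError):
            component_correlations(pd.DataFrame({"genome": ["a"], "genome_bp": [1]}))
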