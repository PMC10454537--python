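"""Summary statistics: size-component correlations and CDS-vs-intron GC test.

Two procedures cover the package's statistical needs:

* Pearson correlation with the t-based significance test
  (t = r * sqrt((n-2) / (1-r^2)) against Student's t with n-2 df, two-sided),
  used to relate mitogenome length to the length of each composition class.
* The Wilcoxon rank-sum (Mann-Whitney) test, exact by null enumeration for
  small tie-free samples and a tie-corrected continuity-corrected normal
  approximation otherwise, used to compare GC content of CDS vs intronic
  regions across a panel.

Both report two-sided p-values, matching R's cor.test/wilcox.test defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .composition import CLASS_NAMES

__all__ = [
    "CorrelationResult",
    "RankTestResult",
    "pearson_test",
    "wilcoxon_rank_sum",
    "component_correlations",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    t_stat: float
    p: float
    n: int


@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # rank-sum W of the first sample
    p: float
    method: str  # "exact" or "normal-approx"


def pearson_test(x, y) -> CorrelationResult:
    """Pearson r with a two-sided t-test of H0: rho = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("pearson_test: vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("pearson_test: need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_test: zero variance in input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return CorrelationResult(r=r, t_stat=t, p=float(res.pvalue), n=n)


def wilcoxon_rank_sum(x, y) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact null enumeration when n_x + n_y <= 20 and the pooled sample is
    tie-free; otherwise the normal approximation with continuity and tie
    correction.  The reported statistic is the rank sum of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum: both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (x.size + y.size <= 20) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank sum
    return RankTestResult(
        statistic=w,
        p=float(min(1.0, res.pvalue)),
        method="exact" if exact else "normal-approx",
    )


def component_correlations(components: pd.DataFrame) -> pd.DataFrame:
    """Genome size vs component length correlations across a panel.

    ``components`` is the per-genome table from
    :func:`mitocomp.composition.component_table` (the "mean" row, if present,
    is dropped).  One row per composition class.
    """
    df = components[components["genome"] != "mean"]
    if len(df) < 3:
        raise ValueError("component_correlations: need >= 3 genomes")
    size = df["genome_bp"].astype(float).to_numpy()
    rows = []
    for name in CLASS_NAMES:
        col = df[f"{name}_bp"].astype(float).to_numpy()
        try:
            res = pearson_test(size, col)
            rows.append(
                {"component": name, "r": res.r, "t": res.t_stat, "p": res.p, "n": res.n}
            )
        except ValueError:
            rows.append(
                {"component": name, "r": np.nan, "t": np.nan, "p": np.nan, "n": len(df)}
            )
    return pd.DataFrame(rows)


def cds_vs_intron_gc(records) -> RankTestResult:
    """Wilcoxon comparison of per-genome CDS GC vs intronic GC."""
    from .composition import nucleotide_stats
    from .genbank_io import classify_features, extract_cds, segment_sequence

    cds_gc, intron_gc = [], []
    for rec in records:
        classes = classify_features(rec)
        cds_seq = "".join(
            extract_cds(rec, rec.features[i])
            for i, cls in classes.items()
            if cls == "core_pcg"
        )
        intron_seq = "".join(
            segment_sequence(rec, s, e)
            for feat in rec.features
            if feat.kind == "intron"
            for s, e in feat.segments
        )
        if cds_seq:
            cds_gc.append(nucleotide_stats(cds_seq).gc_content)
        if intron_seq:
            intron_gc.append(nucleotide_stats(intron_seq).gc_content)
    if not cds_gc or not intron_gc:
        raise ValueError("cds_vs_intron_gc: need both CDS and intron sequence")
    return wilcoxon_rank_sum(np.array(cds_gc), np.array(intron_gc))
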