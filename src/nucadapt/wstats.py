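"""Weighted group statistics, OGT correlations and significance tiers.

Group summaries are meta-genome averages: weighted means over member
genomes with weights proportional to genome size.  Group comparisons use a
two-sample t-test with Welch's correction to the degrees of freedom, built
on weighted means and variances; with unit weights every statistic reduces
exactly to its textbook unweighted counterpart.

Weighted variance follows the frequency-weight convention: weights are
normalized to sum to N and s2 = sum w_i (x_i - xbar_w)^2 / (N - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class WeightedSample:
    values: np.ndarray
    weights: np.ndarray

    def __init__(self, values: Sequence[float], weights: Sequence[float] | None = None):
        self.values = np.asarray(values, dtype=float)
        if weights is None:
            weights = np.ones_like(self.values)
        self.weights = np.asarray(weights, dtype=float)
        if self.values.shape != self.weights.shape or self.values.ndim != 1:
            raise ValueError("values and weights must be equal-length 1-d")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class WeightedTestResult:
    t: float
    df: float
    p: float
    tier: str
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    tier: str


def significance_tier(p: float) -> str:
    """Tier marks: '+' p<0.05, '*' p<0.01, '**' p<0.0001, else ''."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.0001:
        return "**"
    if p < 0.01:
        return "*"
    if p < 0.05:
        return "+"
    return ""


def weighted_mean_var(sample: WeightedSample) -> tuple[float, float]:
    """Weighted mean and frequency-weight sample variance."""
    w = sample.weights * (sample.n / sample.weights.sum())
    mean = float(np.sum(w * sample.values) / sample.n)
    if sample.n < 2:
        raise ValueError("variance undefined for n < 2")
    var = float(np.sum(w * (sample.values - mean) ** 2) / (sample.n - 1))
    return mean, var


def weighted_welch_ttest(a: WeightedSample, b: WeightedSample) -> WeightedTestResult:
    """Two-sample weighted t-test with Welch-corrected degrees of freedom.

    t = (xbar_a - xbar_b) / sqrt(s2_a/N_a + s2_b/N_b), with N_i the genome
    counts and s2_i the weighted sample variances; df by Welch-Satterthwaite.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("both samples need n >= 2")
    ma, va = weighted_mean_var(a)
    mb, vb = weighted_mean_var(b)
    qa, qb = va / a.n, vb / b.n
    se2 = qa + qb
    if se2 == 0:
        if ma == mb:
            return WeightedTestResult(t=0.0, df=float(a.n + b.n - 2), p=1.0, tier="")
        log.warning("zero variance with unequal means: degenerate test")
        return WeightedTestResult(
            t=np.inf if ma > mb else -np.inf,
            df=float(a.n + b.n - 2), p=0.0, tier="**", degenerate=True,
        )
    t = (ma - mb) / np.sqrt(se2)
    df = se2**2 / (qa**2 / (a.n - 1) + qb**2 / (b.n - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return WeightedTestResult(t=float(t), df=float(df), p=p, tier=significance_tier(p))


def one_sample_weighted_ttest(sample: WeightedSample, mu0: float) -> WeightedTestResult:
    """One-sample weighted t-test of H0: weighted mean equals mu0."""
    if sample.n < 2:
        raise ValueError("need n >= 2")
    mean, var = weighted_mean_var(sample)
    df = float(sample.n - 1)
    if var == 0:
        if mean == mu0:
            return WeightedTestResult(t=0.0, df=df, p=1.0, tier="")
        return WeightedTestResult(
            t=np.inf if mean > mu0 else -np.inf, df=df, p=0.0, tier="**",
            degenerate=True,
        )
    t = (mean - mu0) / np.sqrt(var / sample.n)
    p = float(2 * stats.t.sf(abs(t), df))
    return WeightedTestResult(t=float(t), df=df, p=p, tier=significance_tier(p))


def ogt_correlation(values: Sequence[float], ogts: Sequence[float]) -> CorrelationResult:
    """Unweighted Pearson correlation of a per-genome statistic with OGT.

    p from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom, two-sided.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(ogts, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and ogts must be equal-length 1-d")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, n=n, p=p, tier=significance_tier(p))


def metagenome_average(
    values: Mapping[str, float],
    sizes: Mapping[str, float],
    groups: Mapping[str, str],
) -> dict[str, float]:
    """Genome-size-weighted mean of a per-genome statistic within each group.

    ``values``/``sizes``/``groups`` are keyed by genome id; every genome must
    belong to exactly one group.
    """
    sums: dict[str, float] = {}
    wsums: dict[str, float] = {}
    for gid, v in values.items():
        grp = groups[gid]
        w = float(sizes[gid])
        if w <= 0:
            raise ValueError(f"genome {gid} has nonpositive size")
        sums[grp] = sums.get(grp, 0.0) + w * v
        wsums[grp] = wsums.get(grp, 0.0) + w
    return {grp: sums[grp] / wsums[grp] for grp in sums}


def loop_stem_wilcoxon(
    loop_values: Sequence[float], stem_values: Sequence[float]
) -> float:
    """Two-sided paired Wilcoxon signed-rank p (Pratt zero handling).

    All-zero differences (loop identical to stem in every genome) return
    p = 1 with a log flag; scipy treats that case as an error.
    """
    x = np.asarray(loop_values, dtype=float)
    y = np.asarray(stem_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if len(x) < 6:
        raise ValueError("need n >= 6 pairs")
    if np.all(x == y):
        log.warning("all paired differences are zero; p = 1 by convention")
        return 1.0
    res = stats.wilcoxon(x, y, zero_method="pratt", alternative="two-sided")
    return float(res.pvalue)
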