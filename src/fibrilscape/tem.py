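"""Fibril width morphometrics from negative-stain TEM measurements.

Width lists are measured transverse to the fibril axis and, for the
polyglutamine fibrils studied here, read out the impenetrable polyQ
core (the stain penetrates the flexible flanking domains).  This module
summarizes per-condition width distributions and compares conditions
with a rank-based test: the observed histograms are skewed, so a
Mann-Whitney U test is preferred over a t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["WidthSample", "WidthStats", "ConditionComparison",
           "width_stats", "compare_conditions", "per_fibril_means"]


@dataclass
class WidthSample:
    """Fibril width measurements for one preparation condition."""

    condition: str
    widths: np.ndarray
    fibril_ids: np.ndarray | None = None  # optional, for per-fibril averaging

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size < 1:
            raise ValueError("widths must be a non-empty 1D array")
        if np.any(self.widths <= 0):
            raise ValueError("all widths must be positive")
        if self.fibril_ids is not None:
            self.fibril_ids = np.asarray(self.fibril_ids)
            if self.fibril_ids.shape != self.widths.shape:
                raise ValueError("fibril_ids must match widths in length")

    @property
    def n(self) -> int:
        return self.widths.size


@dataclass(frozen=True)
class WidthStats:
    condition: str
    n: int
    mean: float
    sd: float
    median: float
    sem: float
    bin_edges: np.ndarray
    counts: np.ndarray
    reference_nm: float | None = None  # e.g. mean width without inhibitor


@dataclass(frozen=True)
class ConditionComparison:
    condition_a: str
    condition_b: str
    mean_difference: float  # a - b, nm
    ci_low: float
    ci_high: float
    effect_size: float  # Cohen's d (pooled sd)
    p_value: float  # two-sided Mann-Whitney U


def per_fibril_means(s: WidthSample) -> WidthSample:
    """Collapse repeated measurements per fibril to one mean each.

    The measurement protocol takes several width readings along each
    fibril; statistics can be run on the pooled measurements or on
    per-fibril means.  Requires ``fibril_ids``.
    """
    if s.fibril_ids is None:
        raise ValueError("sample has no fibril_ids to group by")
    df = pd.DataFrame({"id": s.fibril_ids, "w": s.widths})
    means = df.groupby("id", sort=True)["w"].mean()
    return WidthSample(condition=s.condition, widths=means.to_numpy())


def width_stats(s: WidthSample, bin_width: float = 1.0,
                reference_nm: float | None = None) -> WidthStats:
    """Summary statistics and a fixed-origin histogram of one sample.

    Bins are half-open [lo, hi) starting at 0 nm so no measurement is
    double-counted; ``reference_nm`` is passed through for plotting a
    reference line (e.g. the no-inhibitor mean width).
    """
    if s.n < 3:
        raise ValueError("need at least 3 measurements for statistics")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    top = np.ceil(s.widths.max() / bin_width) * bin_width + bin_width
    edges = np.arange(0.0, top + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(s.widths, bins=edges)
    return WidthStats(
        condition=s.condition, n=s.n,
        mean=float(s.widths.mean()), sd=float(s.widths.std(ddof=1)),
        median=float(np.median(s.widths)),
        sem=float(s.widths.std(ddof=1) / np.sqrt(s.n)),
        bin_edges=edges, counts=counts, reference_nm=reference_nm)


def compare_conditions(a: WidthSample, b: WidthSample,
                       n_boot: int = 1000, seed: int = 0) -> ConditionComparison:
    """Two-sample width comparison: mean difference with bootstrap CI,
    Cohen's d, and a two-sided Mann-Whitney U p-value."""
    if a.n < 3 or b.n < 3:
        raise ValueError("both samples need at least 3 measurements")
    diff = float(a.widths.mean() - b.widths.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for k in range(n_boot):
        boots[k] = (rng.choice(a.widths, a.n).mean()
                    - rng.choice(b.widths, b.n).mean())
    lo, hi = np.percentile(boots, [2.5, 97.5])
    pooled = np.sqrt(((a.n - 1) * a.widths.var(ddof=1)
                      + (b.n - 1) * b.widths.var(ddof=1)) / (a.n + b.n - 2))
    d = diff / pooled if pooled > 0 else 0.0
    if np.array_equal(a.widths, b.widths):
        p = 1.0  # identical data: no evidence of difference
    else:
        p = float(stats.mannwhitneyu(a.widths, b.widths,
                                     alternative="two-sided").pvalue)
    return ConditionComparison(
        condition_a=a.condition, condition_b=b.condition,
        mean_difference=diff, ci_low=float(lo), ci_high=float(hi),
        effect_size=float(d), p_value=p)
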