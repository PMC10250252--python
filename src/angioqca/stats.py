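"""Paired and grouped statistics for original-vs-segmented measurements.

The study compares, case by case, measurements taken on the reference
("original") arm against the same measurements on the segmented arm:

* normality of the paired differences is checked with Shapiro–Wilk at
  alpha = 0.05;
* normal differences -> paired-samples t-test, non-normal -> Wilcoxon
  signed-rank (the documented fallback for the non-normal paired case);
* independent groups -> Mann–Whitney U (2 groups) or Kruskal–Wallis (>2);
* significance threshold p < 0.05; no multiple-testing correction.

Difference summaries are reported as the median (25th–75th percentile) of
the per-case |original − segmented| — absolute differences, which is why
the reported interquartile ranges start at or near zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, EmptyInputError

ALPHA = 0.05


@dataclass
class PairedSample:
    """Per-case (original, segmented) value pairs for one parameter."""

    parameter: str
    original: np.ndarray
    segmented: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.original = np.asarray(self.original, float)
        self.segmented = np.asarray(self.segmented, float)
        if self.original.shape != self.segmented.shape:
            raise InsufficientDataError("paired arrays must have equal length")

    @property
    def n(self) -> int:
        return len(self.original)

    @property
    def differences(self) -> np.ndarray:
        return self.original - self.segmented


@dataclass
class ComparisonResult:
    parameter: str
    test_name: str
    p_value: float
    original_mean: float | None = None
    original_sd: float | None = None
    segmented_mean: float | None = None
    segmented_sd: float | None = None
    diff_median: float | None = None
    diff_q25: float | None = None
    diff_q75: float | None = None
    n: int = 0
    significant: bool = False
    degenerate: bool = False
    normal_differences: bool | None = None
    group_summaries: dict = field(default_factory=dict)


def check_normality(values, alpha: float = ALPHA) -> tuple[bool, float]:
    """Shapiro–Wilk verdict: (looks_normal, p).  A constant vector is
    degenerate and reported non-normal with p = NaN, without crashing."""
    values = np.asarray(values, float)
    if len(values) < 3:
        raise InsufficientDataError("normality check needs n >= 3")
    if np.ptp(values) == 0:
        return False, float("nan")
    stat = sps.shapiro(values)
    return bool(stat.pvalue >= alpha), float(stat.pvalue)


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q25, q75) with linear interpolation between order statistics."""
    values = np.asarray(values, float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise EmptyInputError("median_iqr of an empty sample")
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return float(med), float(q25), float(q75)


def paired_compare(sample: PairedSample, alpha: float = ALPHA) -> ComparisonResult:
    """Compare the two arms of a paired sample.

    Paired t-test when the differences look normal, Wilcoxon signed-rank
    otherwise.  All-zero differences are a degenerate identity case,
    reported as p = 1 with a flag.  The difference summary is the median
    (IQR) of the absolute per-case differences.
    """
    if sample.n < 3:
        raise InsufficientDataError("paired comparison needs >= 3 complete pairs")
    diffs = sample.differences
    abs_med, abs_q25, abs_q75 = median_iqr(np.abs(diffs))
    base = dict(
        parameter=sample.parameter,
        original_mean=float(sample.original.mean()),
        original_sd=float(sample.original.std(ddof=1)),
        segmented_mean=float(sample.segmented.mean()),
        segmented_sd=float(sample.segmented.std(ddof=1)),
        diff_median=abs_med,
        diff_q25=abs_q25,
        diff_q75=abs_q75,
        n=sample.n,
    )
    if np.all(diffs == 0):
        return ComparisonResult(
            test_name="degenerate (all differences zero)",
            p_value=1.0,
            significant=False,
            degenerate=True,
            normal_differences=None,
            **base,
        )
    normal, _ = check_normality(diffs, alpha)
    if normal:
        res = sps.ttest_rel(sample.original, sample.segmented)
        name = "paired t-test"
    else:
        res = sps.wilcoxon(sample.original, sample.segmented)
        name = "Wilcoxon signed-rank"
    p = float(res.pvalue)
    return ComparisonResult(
        test_name=name,
        p_value=p,
        significant=bool(p < alpha),
        normal_differences=normal,
        **base,
    )


def group_compare(values, groups, parameter: str = "", alpha: float = ALPHA) -> ComparisonResult:
    """Mann–Whitney U for two independent groups, Kruskal–Wallis for more."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labels = [g for g in dict.fromkeys(groups.tolist())]  # stable order
    pools = [values[groups == g] for g in labels]
    if len(pools) < 2:
        raise InsufficientDataError("group comparison needs >= 2 groups")
    if any(len(p) < 2 for p in pools):
        raise InsufficientDataError("every group needs n >= 2")
    if len(pools) == 2:
        res = sps.mannwhitneyu(pools[0], pools[1], alternative="two-sided")
        name = "Mann-Whitney U"
    else:
        res = sps.kruskal(*pools)
        name = "Kruskal-Wallis"
    p = float(res.pvalue)
    summaries = {}
    for g, pool in zip(labels, pools):
        med, q25, q75 = median_iqr(pool)
        summaries[g] = {"n": int(len(pool)), "median": med, "q25": q25, "q75": q75}
    return ComparisonResult(
        parameter=parameter,
        test_name=name,
        p_value=p,
        n=int(len(values)),
        significant=bool(p < alpha),
        group_summaries=summaries,
    )
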