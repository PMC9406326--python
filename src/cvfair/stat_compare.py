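"""Normality-gated statistical comparison and ROC-space summaries.

For each metric the two 10-fold samples (complex vs real structure) are
first checked for normality with the Shapiro-Wilk test. If both samples
are compatible with normality at the significance level alpha (default
0.05), the means are compared with the two-tailed pooled-variance
Student's t-test; otherwise with the two-tailed Mann-Whitney U test
(normal approximation with tie and continuity corrections — at n = 10
with heavy ties the exact distribution is convention-dependent).

Each structure's operating point in ROC space is the (false-positive
rate, sensitivity) pair built from its mean Recall/Sensitivity and mean
Specificity across folds; classifier quality is summarized by the
Euclidean distance from that point to the ideal corner (0, 1), and the
relative superiority of the closer structure is
``100 * (d_worse - d_better) / d_worse`` percent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError
from .training_eval import FoldMetricTable, METRIC_COLUMNS

__all__ = [
    "MetricSample",
    "ComparisonResult",
    "RocPoint",
    "ComparisonReport",
    "shapiro_wilk",
    "students_t",
    "mann_whitney_u",
    "select_and_compare",
    "roc_distance",
    "relative_superiority",
    "build_report",
]


@dataclass(frozen=True)
class MetricSample:
    """One metric's per-fold values for one dataset/structure."""

    values: np.ndarray
    metric: str = ""
    dataset_id: str = ""
    structure_id: str = ""

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("metric samples must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size


def _values(sample) -> np.ndarray:
    return sample.values if isinstance(sample, MetricSample) else np.asarray(sample, float)


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (Royston's algorithm via scipy)."""
    vals = _values(sample)
    if not 3 <= vals.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(vals) == 0:
        raise DegenerateInputError("constant sample has no normality test")
    res = stats.shapiro(vals)
    return float(res.statistic), float(res.pvalue)


def students_t(a, b) -> tuple[float, float]:
    """Two-sample pooled-variance (classical Student's) t-test, two-tailed."""
    va, vb = _values(a), _values(b)
    if va.size < 2 or vb.size < 2:
        raise ValueError("t-test requires at least 2 values per sample")
    if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
        return 0.0, 1.0
    if va.std(ddof=1) == 0 and vb.std(ddof=1) == 0:
        raise DegenerateInputError("both samples are constant")
    res = stats.ttest_ind(va, vb, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def welch_t(a, b) -> tuple[float, float]:
    """Welch's unequal-variance variant (configuration alternative)."""
    res = stats.ttest_ind(_values(a), _values(b), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U with tie-corrected normal approximation."""
    va, vb = _values(a), _values(b)
    if va.size == 0 or vb.size == 0:
        raise ValueError("samples must be non-empty")
    if np.ptp(np.concatenate([va, vb])) == 0:
        # every observation tied: no evidence of a shift
        return float(va.size * vb.size / 2), 1.0
    res = stats.mannwhitneyu(va, vb, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonResult:
    """Outcome of the gated mean comparison for one metric."""

    metric: str
    mean_a: float
    mean_b: float
    normality_p_a: float
    normality_p_b: float
    chosen_test: str  # "t" | "U"
    statistic: float
    p_value: float
    alpha: float
    decision: str = field(init=False)  # "H0 rejected" | "H0 retained"

    def __post_init__(self):
        self.decision = "H0 rejected" if self.p_value < self.alpha else "H0 retained"


def select_and_compare(a: MetricSample, b: MetricSample, alpha: float = 0.05) -> ComparisonResult:
    """Shapiro-gated mean comparison: t if both samples pass normality, else U."""
    if isinstance(a, MetricSample) and isinstance(b, MetricSample) and a.metric != b.metric:
        raise ValueError(f"metric mismatch: {a.metric!r} vs {b.metric!r}")
    va, vb = _values(a), _values(b)

    def _normality_p(v):
        # a constant sample cannot come from a (non-degenerate) normal
        # distribution; treat it as failing the gate outright
        try:
            return shapiro_wilk(v)[1]
        except DegenerateInputError:
            return 0.0

    pa, pb = _normality_p(va), _normality_p(vb)
    if pa >= alpha and pb >= alpha:
        chosen, (stat, p) = "t", students_t(va, vb)
    else:
        chosen, (stat, p) = "U", mann_whitney_u(va, vb)
    return ComparisonResult(
        metric=getattr(a, "metric", ""), mean_a=float(va.mean()), mean_b=float(vb.mean()),
        normality_p_a=pa, normality_p_b=pb, chosen_test=chosen,
        statistic=stat, p_value=p, alpha=alpha,
    )


def roc_distance(sensitivity: float, specificity: float) -> float:
    """Euclidean distance in ROC space from (1 - specificity, sensitivity)
    to the ideal classifier corner (0, 1)."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return float(np.hypot(1.0 - specificity, 1.0 - sensitivity))


def relative_superiority(d_better: float, d_worse: float) -> float:
    """Percent reduction in ROC distance of the better classifier:
    ``100 * (d_worse - d_better) / d_worse``."""
    if d_worse <= 0:
        raise DegenerateInputError("reference distance must be positive")
    return 100.0 * (d_worse - d_better) / d_worse


@dataclass(frozen=True)
class RocPoint:
    """One structure's ROC-space operating point."""

    sensitivity: float
    specificity: float

    @property
    def false_positive_rate(self) -> float:
        return 1.0 - self.specificity

    @property
    def distance_to_ideal(self) -> float:
        return roc_distance(self.sensitivity, self.specificity)


@dataclass
class DatasetComparison:
    dataset_id: str
    results: list[ComparisonResult]
    roc_complex: RocPoint
    roc_real: RocPoint
    distance_complex: float
    distance_real: float
    better_structure: str
    superiority_percent: float
    notes: list[str]


@dataclass
class ComparisonReport:
    """Full per-dataset comparison: gated tests, ROC points, superiority."""

    alpha: float
    datasets: list[DatasetComparison]

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent)

    def to_text(self) -> str:
        lines = [f"Comparison report (alpha = {self.alpha})"]
        for d in self.datasets:
            lines.append(f"\n== {d.dataset_id} ==")
            for r in d.results:
                lines.append(
                    f"  {r.metric:12s} mean {r.mean_a:.5f} vs {r.mean_b:.5f}  "
                    f"normality p ({r.normality_p_a:.5f}, {r.normality_p_b:.5f})  "
                    f"{r.chosen_test}-test p {r.p_value:.3g}  {r.decision}"
                )
            lines.append(
                f"  ROC distance complex {d.distance_complex:.5f} "
                f"real {d.distance_real:.5f} -> {d.better_structure} better "
                f"by {d.superiority_percent:.2f}%"
            )
            for note in d.notes:
                lines.append(f"  note: {note}")
        return "\n".join(lines)


def compare_tables(ctab: FoldMetricTable, rtab: FoldMetricTable,
                   alpha: float = 0.05) -> DatasetComparison:
    """Gated comparison of one complex/real fold-table pair."""
    results, notes = [], []
    for metric in METRIC_COLUMNS:
        a = MetricSample(ctab.column(metric), metric, ctab.dataset_id, "complex")
        b = MetricSample(rtab.column(metric), metric, rtab.dataset_id, "real")
        res = select_and_compare(a, b, alpha=alpha)
        results.append(res)
        if res.chosen_test == "U" and metric != "Accuracy":
            notes.append(
                f"{metric}: normality rejected for at least one sample "
                f"(p = {res.normality_p_a:.4g}, {res.normality_p_b:.4g}); "
                "U test used instead of t"
            )
    cmeans, rmeans = ctab.means(), rtab.means()
    roc_c = RocPoint(cmeans["Recall"], cmeans["Specificity"])
    roc_r = RocPoint(rmeans["Recall"], rmeans["Specificity"])
    d_c, d_r = roc_c.distance_to_ideal, roc_r.distance_to_ideal
    if d_c == d_r:
        better, sup = "tie", 0.0
    elif d_c < d_r:
        better, sup = "complex", relative_superiority(d_c, d_r)
    else:
        better, sup = "real", relative_superiority(d_r, d_c)
    return DatasetComparison(
        dataset_id=ctab.dataset_id or rtab.dataset_id, results=results,
        roc_complex=roc_c, roc_real=roc_r, distance_complex=d_c,
        distance_real=d_r, better_structure=better, superiority_percent=sup,
        notes=notes,
    )


def build_report(tables, alpha: float = 0.05) -> ComparisonReport:
    """Build the full report from ``{dataset_id: (complex_table, real_table)}``
    (or an iterable of such pairs)."""
    if isinstance(tables, dict):
        pairs = list(tables.values())
    else:
        pairs = list(tables)
    datasets = [compare_tables(c, r, alpha=alpha) for c, r in pairs]
    return ComparisonReport(alpha=alpha, datasets=datasets)
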