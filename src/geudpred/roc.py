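"""ROC/AUC scoring, Youden operating points, and the comparison statistics.

The AUC is computed as the tie-corrected pair probability (the Mann-Whitney
statistic): concordant positive-negative pairs plus half of the tied pairs,
over all such pairs.  Its 95% confidence interval uses DeLong's
variance estimate from the per-observation structural components.  The
operating point maximizes the Youden index J = sensitivity + specificity - 1
over candidate cutoffs placed at midpoints between adjacent distinct
scores, with the rule "score >= cutoff predicts injury"; ties in J resolve
to the lower cutoff (higher sensitivity).

``select_optimal_a`` implements the volume-effect-parameter selection rule:
the argmax of AUC over the ``a`` grid, with exact ties (common, since an
AUC on n observations is a rational with a small denominator) resolved to
the median of the tied set.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import NamedTuple, Sequence

import numpy as np
import scipy.stats

__all__ = [
    "DegenerateInputWarning",
    "UndefinedStatisticError",
    "RocSummary",
    "SweepResult",
    "roc_auc",
    "youden_cutoff",
    "youden_index",
    "auc_matrix",
    "select_optimal_a",
    "pearson_r",
    "paired_t",
    "independent_t",
    "TTestResult",
    "CorrelationResult",
    "scan_point_parameters",
]


class DegenerateInputWarning(UserWarning):
    """Scores carry no information (constant) or the CI is degenerate."""


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for this input (e.g. a constant
    vector in a Pearson correlation)."""


@dataclasses.dataclass(frozen=True)
class RocSummary:
    """AUC with DeLong 95% CI and the Youden-optimal operating point."""

    auc: float
    ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int
    degenerate: bool = False

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J statistic, sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def _validate_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.ndim != 1 or y.ndim != 1 or s.shape != y.shape:
        raise ValueError("scores and labels must be 1-D of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if not np.all(np.isin(y, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    y = y.astype(bool)
    if y.all() or not y.any():
        raise UndefinedStatisticError(
            "both outcome classes must be present to build a ROC curve"
        )
    return s, y


def _mann_whitney_auc(scores: np.ndarray, pos: np.ndarray) -> float:
    ranks = scipy.stats.rankdata(scores)
    m = int(pos.sum())
    n = pos.size - m
    return (float(ranks[pos].sum()) - m * (m + 1) / 2.0) / (m * n)


def _delong_ci(scores: np.ndarray, pos: np.ndarray, auc: float) -> tuple[tuple[float, float], bool]:
    """DeLong 95% CI via midrank structural components."""
    x = scores[pos]
    y = scores[~pos]
    m, n = x.size, y.size
    tz = scipy.stats.rankdata(np.concatenate([x, y]))
    tx = scipy.stats.rankdata(x)
    ty = scipy.stats.rankdata(y)
    v01 = (tz[:m] - tx) / n  # components over positives
    v10 = 1.0 - (tz[m:] - ty) / m  # components over negatives
    s01 = float(np.var(v01, ddof=1)) if m > 1 else 0.0
    s10 = float(np.var(v10, ddof=1)) if n > 1 else 0.0
    var = s01 / m + s10 / n
    if var <= 0:
        return (auc, auc), True
    half = scipy.stats.norm.ppf(0.975) * math.sqrt(var)
    return (max(0.0, auc - half), min(1.0, auc + half)), False


def _best_youden(scores: np.ndarray, pos: np.ndarray) -> tuple[float, float, float]:
    """Scan candidate cutoffs; return (cutoff, sensitivity, specificity)."""
    u = np.unique(scores)
    # Lowest candidate classifies everything positive; midpoints cover the rest.
    candidates = np.concatenate(([u[0]], 0.5 * (u[:-1] + u[1:])))
    best = (-np.inf, math.nan, math.nan, math.nan)
    m = int(pos.sum())
    n = pos.size - m
    for c in candidates:
        pred = scores >= c
        sens = float((pred & pos).sum()) / m
        spec = float((~pred & ~pos).sum()) / n
        j = sens + spec - 1.0
        if j > best[0] + 1e-12:  # strict improvement keeps the lower cutoff
            best = (j, float(c), sens, spec)
    return best[1], best[2], best[3]


def roc_auc(scores, labels) -> RocSummary:
    """Tie-corrected AUC with DeLong 95% CI and Youden operating point.

    Orientation is fixed: a higher score predicts injury.  Constant scores
    yield AUC 0.5 with a :class:`DegenerateInputWarning`.
    """
    s, y = _validate_scores_labels(scores, labels)
    m = int(y.sum())
    n = y.size - m
    if np.ptp(s) == 0:
        warnings.warn(
            "constant scores carry no information; AUC set to 0.5",
            DegenerateInputWarning,
            stacklevel=2,
        )
        return RocSummary(0.5, (0.5, 0.5), float(s[0]), 1.0, 0.0, m, n, True)
    auc = _mann_whitney_auc(s, y)
    ci, degenerate = _delong_ci(s, y, auc)
    cutoff, sens, spec = _best_youden(s, y)
    return RocSummary(auc, ci, cutoff, sens, spec, m, n, degenerate)


def youden_cutoff(scores, labels) -> RocSummary:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Same summary as :func:`roc_auc`; provided under the name of the
    selection rule it implements.
    """
    return roc_auc(scores, labels)


def auc_matrix(scores: np.ndarray, labels) -> np.ndarray:
    """Tie-corrected AUC of each column of ``scores`` against ``labels``.

    Columns with constant scores are returned as NaN (flagged, not
    fabricated); callers decide how to report them.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    y = np.asarray(labels).astype(bool)
    m = int(y.sum())
    n = y.size - m
    if m == 0 or n == 0:
        raise UndefinedStatisticError("both outcome classes must be present")
    ranks = scipy.stats.rankdata(s, axis=0)
    auc = (ranks[y].sum(axis=0) - m * (m + 1) / 2.0) / (m * n)
    constant = np.ptp(s, axis=0) == 0
    auc[constant] = np.nan
    return auc


def select_optimal_a(
    a_values: Sequence[float], aucs: Sequence[float], tie_tol: float = 1e-12
) -> float:
    """Optimal volume-effect parameter: argmax of AUC over the grid.

    AUC values within ``tie_tol`` of the maximum form the argmax set; a
    unique argmax is returned as-is, multiple argmaxes resolve to the
    median of the set (for an even-sized set, the midpoint of the two
    central values).  NaN cells (degenerate scores) are ignored.
    """
    a = np.asarray(a_values, dtype=float)
    u = np.asarray(aucs, dtype=float)
    if a.size == 0 or a.shape != u.shape:
        raise ValueError("a_values and aucs must be non-empty and aligned")
    valid = np.isfinite(u)
    if not valid.any():
        return math.nan
    top = float(np.nanmax(u))
    tied = valid & (u >= top - tie_tol)
    return float(np.median(a[tied]))


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float
    note: str | None = None


class CorrelationResult(NamedTuple):
    r: float
    pvalue: float


def pearson_r(x, y) -> CorrelationResult:
    """Product-moment correlation with the two-tailed t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson_r needs two aligned vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            "correlation undefined for a constant vector"
        )
    res = scipy.stats.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue))


def paired_t(x, y) -> TTestResult:
    """Paired-samples t-test: a one-sample t on the differences x - y.

    Degenerate cases are signalled rather than hidden: zero-variance
    differences with nonzero mean give an infinite t (p = 0); identically
    zero differences give t = 0, p = 1, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired_t needs two aligned vectors of length >= 2")
    d = x - y
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(0.0, 1.0, "all differences are zero")
        return TTestResult(
            math.copysign(math.inf, mean), 0.0, "zero-variance differences"
        )
    res = scipy.stats.ttest_rel(x, y)
    return TTestResult(float(res.statistic), float(res.pvalue))


def independent_t(x, y, equal_var: bool = True) -> TTestResult:
    """Two-sample t-test (pooled-variance form by default; Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size < 2 or y.size < 2:
        raise ValueError("independent_t needs two vectors of length >= 2")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if float(x[0]) == float(y[0]):
            return TTestResult(0.0, 1.0, "both samples constant and equal")
        return TTestResult(
            math.copysign(math.inf, float(np.mean(x) - np.mean(y))),
            0.0,
            "zero pooled variance",
        )
    res = scipy.stats.ttest_ind(x, y, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.pvalue))


def scan_point_parameters(matrix, labels) -> list[tuple[object, RocSummary]]:
    """Rank the simple dose/volume point predictors (D_V, V_D) by AUC.

    Returns (column metadata, ROC summary) pairs sorted by descending AUC;
    ties resolve toward the smaller index parameter (smaller V for D_V,
    smaller D for V_D).  Constant columns score 0.5 (degenerate, flagged).
    """
    y = np.asarray(labels)
    ranked: list[tuple[object, RocSummary]] = []
    for meta in matrix.columns:
        if meta.family not in ("d_v", "v_d"):
            continue
        col = matrix.values[meta.name].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateInputWarning)
            summary = roc_auc(col, y)
        ranked.append((meta, summary))
    ranked.sort(
        key=lambda item: (
            -item[1].auc,
            item[0].family,
            item[0].volume_cc if item[0].volume_cc is not None else item[0].threshold_gy,
        )
    )
    return ranked


@dataclasses.dataclass
class SweepResult:
    """AUC surface of EUD_V_D over the (threshold D, exponent a) grid.

    ``auc`` has shape (len(threshold_doses), len(a_values)); NaN marks
    degenerate cells (constant scores cohort-wide).  ``m_auc`` is the
    per-threshold maximum over ``a``; ``a_opt`` the median-resolved argmax.
    """

    structure_class: str
    threshold_doses: np.ndarray
    a_values: np.ndarray
    auc: np.ndarray
    m_auc: np.ndarray = dataclasses.field(init=False)
    a_opt: np.ndarray = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        nd, na = self.auc.shape
        if nd != self.threshold_doses.size or na != self.a_values.size:
            raise ValueError("auc surface shape does not match the grid")
        m = np.full(nd, np.nan)
        aopt = np.full(nd, np.nan)
        for i in range(nd):
            row = self.auc[i]
            if np.isfinite(row).any():
                m[i] = np.nanmax(row)
                aopt[i] = select_optimal_a(self.a_values, row)
        self.m_auc = m
        self.a_opt = aopt

    def auc_at(self, threshold: float, a: float) -> float:
        i = int(np.argmin(np.abs(self.threshold_doses - threshold)))
        j = int(np.argmin(np.abs(self.a_values - a)))
        return float(self.auc[i, j])
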