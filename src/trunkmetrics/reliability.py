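"""Observer-reliability statistics for rater studies.

The machinery of a photographic test-retest study: n subjects
(photographs) are each measured by k raters on one or two occasions.
For every measure, a complete subject-by-rater grid feeds a two-way
crossed ANOVA without replication:

    MSR  between-subject mean square   (df n-1)
    MSC  between-rater mean square     (df k-1)
    MSE  residual mean square          (df (n-1)(k-1))

from which the four classical two-way intraclass correlation forms are
derived (single/average measures crossed with consistency/absolute
agreement):

    ICC(C,1) = (MSR-MSE) / (MSR + (k-1) MSE)
    ICC(A,1) = (MSR-MSE) / (MSR + (k-1) MSE + (k/n)(MSC-MSE))
    ICC(C,k) = (MSR-MSE) / MSR
    ICC(A,k) = (MSR-MSE) / (MSR + (MSC-MSE)/n)

95% confidence intervals use the exact F-based intervals for the
consistency forms and the Satterthwaite-degrees construction for the
agreement forms.  The F test of subject discrimination is MSR/MSE with
(n-1, (n-1)(k-1)) degrees of freedom; note ICC(C,k) = 1 - 1/F exactly.

Measurement error on the scale of the measure itself is the standard
error of measurement, SEM = SD * sqrt(1 - ICC).

Defaults follow common practice for this study design: inter-observer
reliability (reproducibility) uses AVERAGE-measures absolute agreement
across the k raters of round 1; intra-observer repeatability uses
SINGLE-measures consistency on each rater's subject-by-occasion grid
(k = 2 occasions).  Both are overridable everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IncompleteGridError, TrunkMetricsError
from .geometry import MEASURES

__all__ = [
    "IccForm",
    "RatingsTable",
    "AnovaMeanSquares",
    "IccResult",
    "SemResult",
    "DescriptiveStats",
    "TTestResult",
    "NormalityResult",
    "InterObserverResult",
    "IntraObserverResult",
    "descriptive_stats",
    "anova_mean_squares",
    "icc",
    "icc_confidence_interval",
    "sem",
    "classify_icc",
    "interobserver_study",
    "intraobserver_study",
    "aggregate_icc_matrix",
    "descriptives_with_sem",
    "group_compare",
    "normality_check",
]


class IccForm(str, Enum):
    """The four two-way ICC forms (single/average x consistency/agreement)."""

    SINGLE_CONSISTENCY = "single_consistency"    # ICC(C,1), a.k.a. ICC(3,1)
    SINGLE_AGREEMENT = "single_agreement"        # ICC(A,1), a.k.a. ICC(2,1)
    AVERAGE_CONSISTENCY = "average_consistency"  # ICC(C,k), a.k.a. ICC(3,k)
    AVERAGE_AGREEMENT = "average_agreement"      # ICC(A,k), a.k.a. ICC(2,k)

    @property
    def is_average(self) -> bool:
        return self in (IccForm.AVERAGE_CONSISTENCY, IccForm.AVERAGE_AGREEMENT)

    @property
    def is_agreement(self) -> bool:
        return self in (IccForm.SINGLE_AGREEMENT, IccForm.AVERAGE_AGREEMENT)


# ---------------------------------------------------------------------------
# Ratings container
# ---------------------------------------------------------------------------

_RATINGS_COLUMNS = ("subject_id", "rater_id", "occasion", "measure", "value")


@dataclass
class RatingsTable:
    """Long-format ratings: one row per (subject, rater, occasion, measure)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _RATINGS_COLUMNS if c not in self.data.columns]
        if missing:
            raise TrunkMetricsError(f"ratings table missing columns: {missing}")
        self.data = self.data.loc[:, list(_RATINGS_COLUMNS)].copy()
        self.data["occasion"] = self.data["occasion"].astype(int)
        self.data["value"] = self.data["value"].astype(float)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RatingsTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def measures(self) -> list[str]:
        present = list(dict.fromkeys(self.data["measure"]))
        ordered = [m for m in MEASURES if m in present]
        return ordered + [m for m in present if m not in ordered]

    def raters(self) -> list[str]:
        return sorted(map(str, set(self.data["rater_id"])))

    def subjects(self) -> list[str]:
        return sorted(map(str, set(self.data["subject_id"])))

    def grid(self, measure: str, occasion: int = 1) -> pd.DataFrame:
        """Complete subject x rater matrix for one measure and occasion."""
        sl = self.data[(self.data["measure"] == measure) & (self.data["occasion"] == occasion)]
        grid = sl.pivot_table(
            index="subject_id", columns="rater_id", values="value", aggfunc="mean"
        ).sort_index(axis=0).sort_index(axis=1)
        _require_complete(grid, f"measure {measure!r}, occasion {occasion}")
        return grid

    def rater_grid(self, rater_id: str, measure: str) -> pd.DataFrame:
        """Complete subject x occasion matrix for one rater and measure."""
        sl = self.data[
            (self.data["measure"] == measure)
            & (self.data["rater_id"].astype(str) == str(rater_id))
        ]
        grid = sl.pivot_table(
            index="subject_id", columns="occasion", values="value", aggfunc="mean"
        ).sort_index(axis=0).sort_index(axis=1)
        _require_complete(grid, f"rater {rater_id!r}, measure {measure!r}")
        return grid


def _require_complete(grid: pd.DataFrame, what: str) -> None:
    if grid.size == 0:
        raise IncompleteGridError(f"{what}: no ratings found")
    if grid.isna().any().any():
        named = [
            f"(subject {grid.index[i]!r}, column {grid.columns[j]!r})"
            for i, j in zip(*np.where(grid.isna().to_numpy()))
        ]
        raise IncompleteGridError(f"{what}: missing cells {named}")


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DescriptiveStats:
    n: int
    min: float
    max: float
    mean: float
    sd: float
    median: float
    iqr: float


def descriptive_stats(values: Sequence[float]) -> DescriptiveStats:
    """n, min, max, mean, SD (n-1 denominator), median and IQR.

    Quartiles use linear interpolation between order statistics (the
    default 'linear' quantile rule); IQR = Q3 - Q1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise TrunkMetricsError("descriptive_stats: empty input")
    if arr.size < 2:
        raise TrunkMetricsError("descriptive_stats: need n >= 2 for the SD")
    q1, q3 = np.percentile(arr, [25, 75])
    return DescriptiveStats(
        n=int(arr.size),
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        median=float(np.median(arr)),
        iqr=float(q3 - q1),
    )


# ---------------------------------------------------------------------------
# Two-way ANOVA decomposition and ICC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaMeanSquares:
    """Mean squares of the two-way crossed ANOVA without replication."""

    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_raters: int

    @property
    def df_rows(self) -> int:
        return self.n_subjects - 1

    @property
    def df_cols(self) -> int:
        return self.k_raters - 1

    @property
    def df_error(self) -> int:
        return (self.n_subjects - 1) * (self.k_raters - 1)


def anova_mean_squares(grid: pd.DataFrame | np.ndarray) -> AnovaMeanSquares:
    """Decompose a complete subject x rater grid into MSR, MSC, MSE."""
    if isinstance(grid, pd.DataFrame):
        _require_complete(grid, "anova grid")
        arr = grid.to_numpy(dtype=float)
    else:
        arr = np.asarray(grid, dtype=float)
        if np.isnan(arr).any():
            i, j = map(int, next(zip(*np.where(np.isnan(arr)))))
            raise IncompleteGridError(f"anova grid: missing cell (subject {i}, rater {j})")
    n, k = arr.shape
    if n < 2 or k < 2:
        raise TrunkMetricsError(f"anova grid needs n>=2 subjects and k>=2 raters, got {n}x{k}")
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((arr - grand) ** 2).sum())
    ss_error = ss_total - ss_rows - ss_cols
    # snap floating-point residue to an exact zero (e.g. identical columns)
    if ss_error <= 1e-12 * max(ss_total, 1.0):
        ss_error = 0.0
    return AnovaMeanSquares(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=max(ss_error, 0.0) / ((n - 1) * (k - 1)),
        n_subjects=n,
        k_raters=k,
    )


@dataclass(frozen=True)
class IccResult:
    form: IccForm
    value: float
    ci_low: float
    ci_high: float
    f_value: float
    p_value: float
    n_subjects: int
    k_raters: int
    level: float = 0.95


def _icc_point(ms: AnovaMeanSquares, form: IccForm) -> float:
    msr, msc, mse = ms.ms_rows, ms.ms_cols, ms.ms_error
    n, k = ms.n_subjects, ms.k_raters
    if form is IccForm.SINGLE_CONSISTENCY:
        denom = msr + (k - 1) * mse
    elif form is IccForm.SINGLE_AGREEMENT:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif form is IccForm.AVERAGE_CONSISTENCY:
        denom = msr
    else:
        denom = msr + (msc - mse) / n
    if denom == 0.0:
        raise TrunkMetricsError("ICC undefined: zero denominator (no variance at all)")
    return (msr - mse) / denom


def icc(ms: AnovaMeanSquares, form: IccForm = IccForm.AVERAGE_AGREEMENT,
        level: float = 0.95) -> IccResult:
    """ICC point estimate, confidence interval and subject F test."""
    n, k = ms.n_subjects, ms.k_raters
    if n < 2 or k < 2:
        raise TrunkMetricsError("ICC needs n>=2 and k>=2")
    value = _icc_point(ms, form)
    if ms.ms_error == 0.0:
        f_value = math.inf
        p_value = 0.0
    else:
        f_value = ms.ms_rows / ms.ms_error
        p_value = float(stats.f.sf(f_value, n - 1, (n - 1) * (k - 1)))
    ci_low, ci_high = icc_confidence_interval(ms, form, level)
    return IccResult(
        form=form, value=value, ci_low=ci_low, ci_high=ci_high,
        f_value=f_value, p_value=p_value, n_subjects=n, k_raters=k, level=level,
    )


def icc_confidence_interval(
    ms: AnovaMeanSquares, form: IccForm, level: float = 0.95
) -> tuple[float, float]:
    """F-based confidence interval for the chosen ICC form.

    Consistency forms use the exact interval built from
    F_obs = MSR/MSE; agreement forms use the Satterthwaite
    approximation to the denominator degrees of freedom.  A zero MSE
    collapses the interval onto the point estimate.
    """
    n, k = ms.n_subjects, ms.k_raters
    value = _icc_point(ms, form)
    if ms.ms_error == 0.0:
        return value, value
    alpha = 1.0 - level
    if not form.is_agreement:
        f_obs = ms.ms_rows / ms.ms_error
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        if form.is_average:
            return 1 - 1 / fl, 1 - 1 / fu
        return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)

    # Agreement forms: Satterthwaite degrees for the linear combination
    # of MSC and MSE in the denominator.
    msr, msc, mse = ms.ms_rows, ms.ms_cols, ms.ms_error
    r1 = _icc_point(ms, IccForm.SINGLE_AGREEMENT)
    if r1 >= 1.0:
        return value, value
    a = (k * r1) / (n * (1 - r1))
    b = 1 + (k * r1 * (n - 1)) / (n * (1 - r1))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    low1 = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    high1 = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    if form.is_average:
        # Spearman-Brown step-up of the single-measures bounds.
        def step_up(r: float) -> float:
            return k * r / (1 + (k - 1) * r)

        return step_up(low1), step_up(high1)
    return low1, high1


# ---------------------------------------------------------------------------
# SEM and interpretation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SemResult:
    sem: float
    sd_used: float
    icc_used: float


def sem(sd: float, icc_value: float) -> SemResult:
    """Standard error of measurement, SEM = SD * sqrt(1 - ICC)."""
    if sd < 0:
        raise TrunkMetricsError("sem: sd must be >= 0")
    if icc_value > 1:
        raise TrunkMetricsError("sem: ICC cannot exceed 1")
    return SemResult(sem=sd * math.sqrt(1.0 - icc_value), sd_used=sd, icc_used=icc_value)


#: Interpretation bands; each band is closed on the left.
_ICC_BANDS = ((0.9, "excellent"), (0.75, "good"), (0.5, "moderate"))


def classify_icc(value: float) -> str:
    """Interpretation band: <0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, >=0.9 excellent."""
    if value > 1:
        raise TrunkMetricsError("ICC cannot exceed 1")
    for threshold, label in _ICC_BANDS:
        if value >= threshold:
            return label
    return "poor"


# ---------------------------------------------------------------------------
# Study runners
# ---------------------------------------------------------------------------


@dataclass
class InterObserverResult:
    """Per-measure inter-observer ICCs and the unweighted total-mean row."""

    form: IccForm
    occasion: int
    per_measure: dict[str, IccResult]
    total_mean_icc: float = field(init=False)
    total_mean_ci_low: float = field(init=False)
    total_mean_ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        vals = list(self.per_measure.values())
        self.total_mean_icc = float(np.mean([r.value for r in vals]))
        self.total_mean_ci_low = float(np.mean([r.ci_low for r in vals]))
        self.total_mean_ci_high = float(np.mean([r.ci_high for r in vals]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "measure": m,
                "icc": r.value,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "f_value": r.f_value,
                "p_value": r.p_value,
            }
            for m, r in self.per_measure.items()
        ]
        rows.append(
            {
                "measure": "Total Mean",
                "icc": self.total_mean_icc,
                "ci_low": self.total_mean_ci_low,
                "ci_high": self.total_mean_ci_high,
                "f_value": np.nan,
                "p_value": np.nan,
            }
        )
        return pd.DataFrame(rows)


def interobserver_study(
    table: RatingsTable,
    occasion: int = 1,
    form: IccForm = IccForm.AVERAGE_AGREEMENT,
    level: float = 0.95,
) -> InterObserverResult:
    """Reproducibility: one ICC per measure across raters at one occasion.

    The summary row is the unweighted mean of the per-measure ICC values
    and of the CI bounds.
    """
    per_measure = {
        m: icc(anova_mean_squares(table.grid(m, occasion)), form, level)
        for m in table.measures()
    }
    return InterObserverResult(form=form, occasion=occasion, per_measure=per_measure)


@dataclass
class IntraObserverResult:
    """Per-rater test-retest ICCs, per-measure aggregation, total-mean row."""

    form: IccForm
    matrix: pd.DataFrame      # raters x measures, ICC values
    aggregate: pd.DataFrame   # measures x (mean, sd, min, max)
    total_mean: pd.Series     # column-wise mean of aggregate over measures


def aggregate_icc_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Aggregate a raters x measures ICC matrix per measure.

    Returns the measures x (mean, sd, min, max) table and its unweighted
    column-wise mean over measures (the total-mean row, including the
    mean of the per-measure minima and maxima).
    """
    agg = pd.DataFrame(
        {
            "mean": matrix.mean(axis=0),
            "sd": matrix.std(axis=0, ddof=1),
            "min": matrix.min(axis=0),
            "max": matrix.max(axis=0),
        }
    )
    agg.index.name = "measure"
    return agg, agg.mean(axis=0)


def intraobserver_study(
    table: RatingsTable,
    form: IccForm = IccForm.SINGLE_CONSISTENCY,
    level: float = 0.95,
) -> IntraObserverResult:
    """Repeatability: per rater and measure, ICC on the subject x occasion grid."""
    raters = table.raters()
    measures = table.measures()
    matrix = pd.DataFrame(index=raters, columns=measures, dtype=float)
    for r in raters:
        for m in measures:
            grid = table.rater_grid(r, m)
            if grid.shape[1] < 2:
                raise IncompleteGridError(
                    f"rater {r!r}, measure {m!r}: needs both occasions"
                )
            matrix.loc[r, m] = icc(anova_mean_squares(grid), form, level).value
    matrix.index.name = "rater_id"
    aggregate, total_mean = aggregate_icc_matrix(matrix)
    return IntraObserverResult(form=form, matrix=matrix, aggregate=aggregate,
                               total_mean=total_mean)


def descriptives_with_sem(
    table: RatingsTable,
    inter: InterObserverResult | None = None,
    occasion: int = 1,
) -> pd.DataFrame:
    """Per-measure descriptives of the per-photo mean ratings, with SEM.

    For each measure, the n subject values are the means over raters at
    the given occasion; SEM pairs their SD with the inter-observer ICC
    of the same measure (computed here if not supplied).
    """
    if inter is None:
        inter = interobserver_study(table, occasion=occasion)
    rows = []
    for m in table.measures():
        grid = table.grid(m, occasion)
        per_photo = grid.mean(axis=1).to_numpy()
        d = descriptive_stats(per_photo)
        s = sem(d.sd, inter.per_measure[m].value)
        rows.append(
            {
                "measure": m, "n": d.n, "min": d.min, "max": d.max,
                "mean": d.mean, "sd": d.sd, "median": d.median, "iqr": d.iqr,
                "sem": s.sem,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparison and normality
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    significant: bool
    alpha: float = 0.05


def group_compare(
    group_a: Sequence[float], group_b: Sequence[float], alpha: float = 0.05
) -> TTestResult:
    """Two-sample, two-sided, pooled-variance Student's t test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise TrunkMetricsError("group_compare: each group needs n >= 2")
    df = int(a.size + b.size - 2)
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0, significant=False, alpha=alpha)
        raise TrunkMetricsError(
            "group_compare: zero pooled variance with unequal means; t undefined"
        )
    res = stats.ttest_ind(a, b, equal_var=True)
    p = float(res.pvalue)
    return TTestResult(t=float(res.statistic), df=df, p=p,
                       significant=p < alpha, alpha=alpha)


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p: float
    flag: str  # "normal", "non-normal" or "non-testable"


def normality_check(values: Sequence[float], alpha: float = 0.05) -> NormalityResult:
    """One-sample Kolmogorov-Smirnov test against N(sample mean, sample sd).

    Advisory only — the flag never blocks downstream analysis.  Because
    the normal parameters are estimated from the same sample, the
    nominal KS p-value is conservative (the Lilliefors correction is
    not applied); treat the flag as a screen, not a formal test.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 5:
        raise TrunkMetricsError("normality_check: need n >= 5")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        return NormalityResult(statistic=math.nan, p=math.nan, flag="non-testable")
    stat, p = stats.kstest(arr, "norm", args=(arr.mean(), sd))
    flag = "normal" if p > alpha else "non-normal"
    return NormalityResult(statistic=float(stat), p=float(p), flag=flag)
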