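import math

import numpy as np
import pandas as pd
import pytest

from trunkmetrics import (
    IccForm,
    IncompleteGridError,
    RatingsTable,
    TrunkMetricsError,
    anova_mean_squares,
    classify_icc,
    descriptive_stats,
    group_compare,
    icc,
    icc_confidence_interval,
    interobserver_study,
    intraobserver_study,
    normality_check,
    sem,
)

GRID_A = np.array([[1, 2], [3, 4], [5, 6]], float)       # MSE exactly 0
GRID_B = np.array([[1, 2], [2, 2], [4, 5]], float)


def _independent_ss_icc(grid: np.ndarray, form: IccForm) -> float:
    """Direct elementwise sums-of-squares oracle, no shared code paths."""
    n, k = grid.shape
    grand = sum(sum(row) for row in grid) / (n * k)
    row_means = [sum(row) / k for row in grid]
    col_means = [sum(grid[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((m - grand) ** 2 for m in row_means) / (n - 1)
    msc = n * sum((m - grand) ** 2 for m in col_means) / (k - 1)
    sse = sum(
        (grid[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    if form is IccForm.SINGLE_CONSISTENCY:
        return (msr - mse) / (msr + (k - 1) * mse)
    if form is IccForm.SINGLE_AGREEMENT:
        return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if form is IccForm.AVERAGE_CONSISTENCY:
        return (msr - mse) / msr
    return (msr - mse) / (msr + (msc - mse) / n)


# ---------------------------------------------------------- descriptives


def test_descriptive_stats_hand_example():
    d = descriptive_stats([1, 2, 3, 4, 5])
    assert (d.n, d.min, d.max, d.mean, d.median) == (5, 1, 5, 3, 3)
    assert d.sd == pytest.approx(math.sqrt(2.5))  # 1.5811
    assert d.iqr == pytest.approx(2.0)  # linear-interpolation quartiles 2 and 4


def test_descriptive_stats_constant_and_small_inputs():
    d = descriptive_stats([4, 4, 4])
    assert d.sd == 0.0 and d.iqr == 0.0
    with pytest.raises(TrunkMetricsError):
        descriptive_stats([4])
    with pytest.raises(TrunkMetricsError):
        descriptive_stats([])


# ----------------------------------------------------------------- ANOVA


@pytest.mark.parametrize(
    "grid, expected",
    [
        (GRID_A, (8.0, 1.5, 0.0)),
        (GRID_B, (31 / 6, 2 / 3, 1 / 6)),
    ],
)
def test_anova_mean_squares_hand_examples(grid, expected):
    ms = anova_mean_squares(grid)
    assert ms.ms_rows == pytest.approx(expected[0], abs=1e-12)
    assert ms.ms_cols == pytest.approx(expected[1], abs=1e-12)
    assert ms.ms_error == pytest.approx(expected[2], abs=1e-12)
    assert (ms.df_rows, ms.df_cols, ms.df_error) == (2, 1, 2)


def test_rater_column_shift_moves_only_ms_cols():
    shifted = GRID_B.copy()
    shifted[:, 1] += 7.0
    base = anova_mean_squares(GRID_B)
    moved = anova_mean_squares(shifted)
    assert moved.ms_rows == pytest.approx(base.ms_rows)
    assert moved.ms_error == pytest.approx(base.ms_error)
    assert moved.ms_cols != pytest.approx(base.ms_cols)


def test_missing_cell_is_named():
    grid = GRID_B.copy()
    grid[1, 0] = np.nan
    with pytest.raises(IncompleteGridError, match="subject 1"):
        anova_mean_squares(grid)


# ------------------------------------------------------------------- ICC


def test_icc_hand_examples():
    ms_a = anova_mean_squares(GRID_A)
    assert icc(ms_a, IccForm.SINGLE_CONSISTENCY).value == pytest.approx(1.0)
    assert icc(ms_a, IccForm.SINGLE_AGREEMENT).value == pytest.approx(8 / 9)
    ms_b = anova_mean_squares(GRID_B)
    assert icc(ms_b, IccForm.SINGLE_CONSISTENCY).value == pytest.approx(0.9375)
    assert icc(ms_b, IccForm.SINGLE_AGREEMENT).value == pytest.approx(15 / 17)  # 0.88235


def test_zero_mse_gives_exact_one_and_infinite_f():
    res = icc(anova_mean_squares(GRID_A), IccForm.SINGLE_CONSISTENCY)
    assert res.value == 1.0
    assert math.isinf(res.f_value) and res.p_value == 0.0
    assert (res.ci_low, res.ci_high) == (1.0, 1.0)


def test_icc_matches_independent_ss_oracle():
    rng = np.random.default_rng(31)
    for _ in range(30):
        n = rng.integers(2, 9)
        k = rng.integers(2, 6)
        grid = rng.normal(0, 1, (n, k)) + rng.normal(0, 1.5, (n, 1)) + rng.normal(0, 0.7, (1, k))
        ms = anova_mean_squares(grid)
        for form in IccForm:
            assert icc(ms, form).value == pytest.approx(
                _independent_ss_icc(grid, form), abs=1e-10
            ), form


def test_icc_matches_pingouin_cross_package():
    import pingouin as pg

    rng = np.random.default_rng(8)
    grid = rng.normal(0, 1, (10, 4)) + rng.normal(0, 2, (10, 1)) + rng.normal(0, 0.5, (1, 4))
    df = pd.DataFrame(grid).reset_index().melt("index", var_name="rater", value_name="val")
    ref = pg.intraclass_corr(df, targets="index", raters="rater", ratings="val").set_index("Type")
    ms = anova_mean_squares(grid)
    mapping = {
        "ICC(A,1)": IccForm.SINGLE_AGREEMENT,
        "ICC(C,1)": IccForm.SINGLE_CONSISTENCY,
        "ICC(A,k)": IccForm.AVERAGE_AGREEMENT,
        "ICC(C,k)": IccForm.AVERAGE_CONSISTENCY,
    }
    for typ, form in mapping.items():
        mine = icc(ms, form)
        assert mine.value == pytest.approx(ref.loc[typ, "ICC"], abs=1e-10)
        lo, hi = ref.loc[typ, "CI95"]
        # pingouin prints its interval rounded to 2 decimals
        assert mine.ci_low == pytest.approx(lo, abs=0.005)
        assert mine.ci_high == pytest.approx(hi, abs=0.005)


def test_icc_form_orderings():
    rng = np.random.default_rng(12)
    for _ in range(10):
        grid = rng.normal(0, 1, (8, 4)) + rng.normal(0, 1.5, (8, 1)) + rng.normal(0, 1.0, (1, 4))
        ms = anova_mean_squares(grid)
        single_c = icc(ms, IccForm.SINGLE_CONSISTENCY).value
        avg_c = icc(ms, IccForm.AVERAGE_CONSISTENCY).value
        single_a = icc(ms, IccForm.SINGLE_AGREEMENT).value
        avg_a = icc(ms, IccForm.AVERAGE_AGREEMENT).value
        if single_c > 0:
            assert single_c <= avg_c
        if single_a > 0:
            assert single_a <= avg_a
        if ms.ms_cols >= ms.ms_error:
            assert single_a <= single_c + 1e-12
            assert avg_a <= avg_c + 1e-12


def test_consistency_invariant_under_rater_shifts_agreement_not():
    grid = np.array([[1.0, 2.0, 1.5], [3.0, 3.5, 2.8], [5.0, 6.1, 5.5], [7.0, 7.4, 7.2]])
    shifted = grid + np.array([[0.0, 3.0, -2.0]])
    ms, ms_s = anova_mean_squares(grid), anova_mean_squares(shifted)
    assert icc(ms, IccForm.SINGLE_CONSISTENCY).value == pytest.approx(
        icc(ms_s, IccForm.SINGLE_CONSISTENCY).value, abs=1e-12
    )
    assert icc(ms, IccForm.SINGLE_AGREEMENT).value != pytest.approx(
        icc(ms_s, IccForm.SINGLE_AGREEMENT).value, abs=1e-6
    )


def test_average_consistency_equals_one_minus_inverse_f():
    rng = np.random.default_rng(4)
    grid = rng.normal(0, 1, (15, 12)) + rng.normal(0, 3, (15, 1))
    ms = anova_mean_squares(grid)
    res = icc(ms, IccForm.AVERAGE_CONSISTENCY)
    assert res.value == pytest.approx(1 - 1 / res.f_value, abs=1e-12)


# ----------------------------------------------------- confidence interval


def test_ci_contains_point_estimate_and_nests():
    rng = np.random.default_rng(9)
    for _ in range(10):
        grid = rng.normal(0, 1, (7, 5)) + rng.normal(0, 1.2, (7, 1))
        ms = anova_mean_squares(grid)
        for form in IccForm:
            value = icc(ms, form).value
            lo95, hi95 = icc_confidence_interval(ms, form, 0.95)
            lo99, hi99 = icc_confidence_interval(ms, form, 0.99)
            assert lo95 <= value <= hi95
            assert lo99 <= lo95 and hi99 >= hi95


def test_ci_coverage_under_known_population_icc():
    """95% interval covers a true single-consistency ICC of 0.8 at the
    reference design (n=15, k=12) in roughly 95% of replicates."""
    rho, n, k = 0.8, 15, 12
    rng = np.random.default_rng(123)
    covered = 0
    reps = 500
    for _ in range(reps):
        grid = rng.normal(0, math.sqrt(rho), (n, 1)) + rng.normal(0, math.sqrt(1 - rho), (n, k))
        lo, hi = icc_confidence_interval(anova_mean_squares(grid), IccForm.SINGLE_CONSISTENCY)
        covered += lo <= rho <= hi
    assert 0.91 <= covered / reps <= 0.99


# ---------------------------------------------------- SEM and classification


def test_sem_reproduces_reference_cells():
    assert sem(9.5, 0.990).sem == pytest.approx(0.95, abs=1e-12)
    assert sem(14.9, 0.994).sem == pytest.approx(1.1541, abs=5e-4)
    assert sem(3.3, 1.0).sem == 0.0


def test_sem_rejects_icc_above_one_and_is_monotone():
    with pytest.raises(TrunkMetricsError):
        sem(1.0, 1.01)
    sems = [sem(2.0, r).sem for r in (0.5, 0.7, 0.9, 0.99)]
    assert sems == sorted(sems, reverse=True)
    assert sem(4.0, 0.75).sem == pytest.approx(2 * sem(2.0, 0.75).sem)


@pytest.mark.parametrize(
    "value, band",
    [
        (0.981, "excellent"), (0.9, "excellent"), (0.8999, "good"), (0.75, "good"),
        (0.6, "moderate"), (0.5, "moderate"), (0.49, "poor"), (-0.2, "poor"),
    ],
)
def test_classify_icc_bands(value, band):
    assert classify_icc(value) == band


# ----------------------------------------------------------- study runners


def _long_table(grids_by_measure, occasion=1):
    rows = []
    for measure, grid in grids_by_measure.items():
        for i, row in enumerate(np.atleast_2d(grid)):
            for j, v in enumerate(row):
                rows.append(
                    dict(subject_id=f"S{i}", rater_id=f"R{j}", occasion=occasion,
                         measure=measure, value=float(v))
                )
    return pd.DataFrame(rows)


def test_interobserver_study_is_compositional():
    table = RatingsTable(_long_table({"SHA": GRID_B, "WAD": GRID_A * 1.7}))
    res = interobserver_study(table, form=IccForm.SINGLE_CONSISTENCY)
    assert res.per_measure["SHA"].value == pytest.approx(
        icc(anova_mean_squares(GRID_B), IccForm.SINGLE_CONSISTENCY).value
    )
    assert res.total_mean_icc == pytest.approx(
        (res.per_measure["SHA"].value + res.per_measure["WAD"].value) / 2
    )


def test_identical_raters_give_unit_icc():
    col = np.array([[1.0], [4.0], [9.0], [2.5]])
    grid = np.repeat(col, 3, axis=1)
    table = RatingsTable(_long_table({"SHA": grid}))
    res = interobserver_study(table, form=IccForm.AVERAGE_AGREEMENT)
    assert res.per_measure["SHA"].value == 1.0


def test_intraobserver_perfect_repeatability():
    rows = []
    for r in range(3):
        for occ in (1, 2):
            for i, v in enumerate([1.0, 5.0, 2.0, 8.0]):
                rows.append(dict(subject_id=f"S{i}", rater_id=f"R{r}", occasion=occ,
                                 measure="WAD", value=v + 0.1 * r))
    res = intraobserver_study(RatingsTable(pd.DataFrame(rows)))
    assert (res.matrix["WAD"] == 1.0).all()
    assert res.aggregate.loc["WAD", "sd"] == 0.0


def test_intraobserver_missing_occasion_is_an_error():
    rows = _long_table({"WAD": GRID_B}, occasion=1)
    with pytest.raises(IncompleteGridError):
        intraobserver_study(RatingsTable(rows))


def test_incomplete_inter_grid_names_cell():
    df = _long_table({"SHA": GRID_B})
    df = df.drop(df[(df.subject_id == "S1") & (df.rater_id == "R0")].index)
    with pytest.raises(IncompleteGridError, match="S1"):
        interobserver_study(RatingsTable(df))


# --------------------------------------------------- group test, normality


def test_group_compare_hand_example():
    res = group_compare([1, 2, 3], [2, 3, 4])
    assert res.t == pytest.approx(-math.sqrt(1.5), abs=1e-10)  # -1.2247
    assert res.df == 4
    assert res.p == pytest.approx(0.2879, abs=5e-4)
    assert not res.significant


def test_group_compare_degenerate_cases():
    res = group_compare([2.0, 2.0], [2.0, 2.0])
    assert (res.t, res.p) == (0.0, 1.0)
    with pytest.raises(TrunkMetricsError):
        group_compare([2.0, 2.0], [3.0, 3.0])
    with pytest.raises(TrunkMetricsError):
        group_compare([1.0], [1.0, 2.0])


def test_normality_check_flags():
    rng = np.random.default_rng(0)
    normal_flags = [
        normality_check(rng.normal(0, 1, 1000)).flag == "normal" for _ in range(20)
    ]
    assert sum(normal_flags) >= 18
    uniform = rng.uniform(0, 1, 1000) * 100
    assert normality_check(uniform).flag == "non-normal"
    assert normality_check([3.0] * 10).flag == "non-testable"
    with pytest.raises(TrunkMetricsError):
        normality_check([1, 2, 3])
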