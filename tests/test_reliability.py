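"""Two-way absolute-agreement ICC, classification, and the report schema."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffmkit import (
    DataError,
    NumericalError,
    RatingTable,
    classify_icc,
    generate_rating_table,
    icc_agreement,
    reliability_report,
)

# small two-way table, independently hand-computable
FIXTURE_5x3 = np.array(
    [
        [9.0, 10.0, 8.0],
        [6.0, 6.0, 5.0],
        [8.0, 9.0, 7.0],
        [7.0, 8.0, 6.0],
        [10.0, 12.0, 9.0],
    ]
)


def _anova_oracle(X):
    """Textbook two-way ANOVA mean squares computed from first principles."""
    n, k = X.shape
    grand = X.mean()
    msr = k * ((X.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((X.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    resid = X - X.mean(axis=1, keepdims=True) - X.mean(axis=0, keepdims=True) + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    return msr, msc, mse


def test_icc_matches_mean_squares_oracle():
    res = icc_agreement(FIXTURE_5x3)
    msr, msc, mse = _anova_oracle(FIXTURE_5x3)
    n, k = FIXTURE_5x3.shape
    expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    assert res.estimate == pytest.approx(expected, abs=1e-10)
    assert res.mean_squares["rows"] == pytest.approx(msr, abs=1e-10)
    assert res.mean_squares["columns"] == pytest.approx(msc, abs=1e-10)
    assert res.mean_squares["error"] == pytest.approx(mse, abs=1e-10)
    assert res.ci_low <= res.estimate <= res.ci_high


def test_icc_matches_pingouin_cross_check():
    """Independent implementation check: pingouin's ICC2 (two-way random,
    absolute agreement, single rater)."""
    import pingouin as pg

    n, k = FIXTURE_5x3.shape
    df = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "ratings": FIXTURE_5x3.ravel(),
        }
    )
    icc = pg.intraclass_corr(data=df, targets="targets", raters="raters", ratings="ratings")
    ref = icc[icc["Type"] == "ICC(A,1)"].iloc[0] if (icc["Type"] == "ICC(A,1)").any() else icc[icc["Type"] == "ICC2"].iloc[0]
    res = icc_agreement(FIXTURE_5x3)
    assert res.estimate == pytest.approx(float(ref["ICC"]), abs=1e-9)
    lo, hi = ref["CI95"] if "CI95" in ref.index else ref["CI95%"]
    assert res.ci_low == pytest.approx(float(lo), abs=0.01)
    assert res.ci_high == pytest.approx(float(hi), abs=0.01)


def test_identical_columns_give_one():
    col = np.array([1.0, 4.0, 2.5, 7.0])
    res = icc_agreement(np.column_stack([col, col, col]))
    assert res.estimate == pytest.approx(1.0, abs=1e-12)


def test_zero_variance_is_error():
    with pytest.raises(NumericalError):
        icc_agreement(np.full((5, 3), 2.0))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
def test_icc_affine_invariant(a, b):
    base = icc_agreement(FIXTURE_5x3).estimate
    scaled = icc_agreement(a * FIXTURE_5x3 + b).estimate
    assert scaled == pytest.approx(base, abs=1e-12)


@pytest.mark.parametrize(
    "value,label",
    [
        (0.92, "excellent"),
        (0.76, "excellent"),
        (0.75, "good"),  # strict '>' for excellent
        (0.65, "good"),
        (0.6, "good"),
        (0.5, "fair"),
        (0.4, "fair"),
        (0.3, "poor"),
        (-0.2, "poor"),  # negative estimates reported as computed
    ],
)
def test_classification_thresholds(value, label):
    assert classify_icc(value) == label


def test_report_design_size_and_schema():
    table = generate_rating_table(15, 3, 2, 3.0, 0.3, 1.0, seed=11)
    assert table.design_size == 17 * 15 * 3 * 2 == 1530
    report = reliability_report(table)
    assert report.attrs["design_size"] == 1530
    # Table-3 layout: 3 intraobserver + 2 interobserver rows per motion
    assert len(report) == 17 * (3 + 2)
    per_motion = report.groupby("motion")["analysis"].value_counts()
    assert set(per_motion.values) == {3, 2}
    assert report["icc"].le(1).all()


def test_perfect_agreement_report_all_ones():
    rows = []
    for m in ["a", "b"]:
        for s in range(6):
            for r in range(3):
                for e in range(2):
                    rows.append((s, r, e, m, 1.0 + 2.0 * s))
    table = RatingTable(pd.DataFrame(rows, columns=["subject", "rater", "session", "motion", "value"]))
    report = reliability_report(table)
    assert np.allclose(report["icc"], 1.0)


def test_incomplete_design_lists_missing_cells():
    table = generate_rating_table(4, 2, 2, 1.0, 0.1, 0.5, seed=0, motions=["m"])
    df = table.df.drop(index=table.df.index[3])
    with pytest.raises(DataError, match="missing"):
        RatingTable(df)


def test_noisier_raters_rank_lower():
    """Per-rater intraobserver ICCs order inversely to rater error SDs."""
    sds = np.array([0.5, 1.0, 2.0])
    per_rater = {j: [] for j in range(3)}
    for seed in range(200):
        table = generate_rating_table(
            12, 3, 2, subject_sd=3.0, rater_sd=0.2, error_sd=1.0,
            seed=seed, motions=["m"], rater_error_sd=sds,
        )
        for j in range(3):
            m = table.matrix("m", columns="session", fixed={"rater": j})
            per_rater[j].append(icc_agreement(m).estimate)
    medians = [np.median(per_rater[j]) for j in range(3)]
    assert medians[0] > medians[1] > medians[2]
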