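"""Intra/inter-observer reliability statistics for repeated FFM measurements.

The estimator is the two-way random-effects, absolute-agreement,
single-measurement intraclass correlation — ICC(A,1) in the McGraw & Wong
nomenclature, ICC(2,1) in Shrout & Fleiss — computed from the two-way ANOVA
mean squares with the F-distribution 95% confidence interval.  The paper's
qualitative thresholds are applied verbatim: > 0.75 excellent, 0.6-0.75
good, 0.4-0.6 fair, < 0.4 poor (boundaries 0.75 and 0.6 classify as good,
0.4 as fair, matching the strict ">" printed for excellent).

A :class:`RatingTable` is a complete crossed design of measurements indexed
by (subject, rater, session, motion).  The per-motion report follows the
published layout: one intraobserver ICC per rater (that rater's sessions as
columns) and one interobserver ICC per session (raters as columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .errors import DataError, NumericalError

REQUIRED_COLUMNS = ["subject", "rater", "session", "motion", "value"]


def classify_icc(value: float) -> str:
    """Qualitative label for an ICC estimate (negative estimates allowed)."""
    if value > 1:
        raise DataError(f"ICC cannot exceed 1 (got {value})")
    if value > 0.75:
        return "excellent"
    if value >= 0.6:
        return "good"
    if value >= 0.4:
        return "fair"
    return "poor"


@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str
    classification: str
    n_subjects: int
    n_measurements: int
    mean_squares: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci95_low": self.ci_low,
            "ci95_high": self.ci_high,
            "model": self.model,
            "classification": self.classification,
            "n_subjects": self.n_subjects,
            "n_measurements": self.n_measurements,
            **{f"ms_{k}": v for k, v in self.mean_squares.items()},
        }


def icc_agreement(matrix: np.ndarray, confidence: float = 0.95) -> ICCResult:
    """ICC(A,1) with its F-based confidence interval for a subjects x
    measurements matrix (complete, >= 2 subjects and >= 2 columns).

    Mean squares: MSR (rows/subjects), MSC (columns/measurements), MSE
    (residual).  Point estimate::

        (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The interval uses the Satterthwaite degrees of freedom of McGraw & Wong.
    A zero-variance matrix has no defined ICC and raises (never NaN).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise DataError(f"need a subjects x measurements matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite measurement values")
    n, k = X.shape
    grand = X.mean()
    if np.allclose(X, grand):
        raise NumericalError("zero total variance: ICC undefined")
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((X - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-300:
        raise NumericalError("degenerate mean squares: ICC undefined")
    icc = (msr - mse) / denom

    # F-based CI (McGraw & Wong, ICC(A,1))
    alpha = 1.0 - confidence
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_u = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:  # perfect agreement: interval collapses
        lower = upper = 1.0
    lower = min(lower, icc)
    upper = max(upper, icc)
    return ICCResult(
        estimate=float(icc),
        ci_low=float(lower),
        ci_high=float(upper),
        model="ICC(A,1) two-way random, absolute agreement",
        classification=classify_icc(float(icc)),
        n_subjects=n,
        n_measurements=k,
        mean_squares={"rows": float(msr), "columns": float(msc), "error": float(mse)},
    )


class RatingTable:
    """Complete crossed table of repeated measurements.

    Wraps a long-format DataFrame with columns subject, rater, session,
    motion, value.  Completeness (every cell exactly once) is validated for
    the default estimator.
    """

    def __init__(self, df: pd.DataFrame):
        missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing_cols:
            raise DataError(f"rating table is missing column(s): {missing_cols}")
        df = df[REQUIRED_COLUMNS].copy()
        if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
            raise DataError("rating table contains non-finite values")
        self.df = df
        self.subjects = sorted(df["subject"].unique().tolist())
        self.raters = sorted(df["rater"].unique().tolist())
        self.sessions = sorted(df["session"].unique().tolist())
        self.motions = list(dict.fromkeys(df["motion"]))
        self._validate_complete()

    def _validate_complete(self) -> None:
        counts = self.df.groupby(["motion", "subject", "rater", "session"]).size()
        dup = counts[counts > 1]
        if len(dup):
            raise DataError(f"duplicate cells in rating table: {dup.index.tolist()[:5]} ...")
        expected = len(self.motions) * len(self.subjects) * len(self.raters) * len(self.sessions)
        if len(self.df) != expected:
            have = set(map(tuple, self.df[["motion", "subject", "rater", "session"]].itertuples(index=False)))
            missing = [
                (m, s, r, e)
                for m in self.motions
                for s in self.subjects
                for r in self.raters
                for e in self.sessions
                if (m, s, r, e) not in have
            ]
            raise DataError(
                f"incomplete crossed design: {len(missing)} missing cell(s), "
                f"first few {missing[:5]}"
            )

    @property
    def design_size(self) -> int:
        """Total measurement count n_motions x n_subjects x n_raters x n_sessions."""
        return len(self.df)

    def matrix(self, motion, columns: str, fixed: dict) -> np.ndarray:
        """Subjects x columns matrix for one motion; ``columns`` is 'rater'
        or 'session' and ``fixed`` pins the other factor."""
        sub = self.df[self.df["motion"] == motion]
        for key, val in fixed.items():
            sub = sub[sub[key] == val]
        pivot = sub.pivot(index="subject", columns=columns, values="value")
        return pivot.loc[self.subjects].to_numpy()

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def reliability_report(table: RatingTable, confidence: float = 0.95) -> pd.DataFrame:
    """Per-motion intraobserver (per rater, across sessions) and
    interobserver (per session, across raters) ICCs with CIs and labels.

    Returns a tidy DataFrame with one row per (motion, analysis, unit);
    ``df.attrs['design_size']`` carries the total measurement count.
    """
    if len(table.sessions) < 2:
        raise DataError("intraobserver analysis needs >= 2 sessions")
    if len(table.raters) < 2:
        raise DataError("interobserver analysis needs >= 2 raters")
    rows = []
    for motion in table.motions:
        for rater in table.raters:
            m = table.matrix(motion, columns="session", fixed={"rater": rater})
            res = icc_agreement(m, confidence)
            rows.append((motion, "intraobserver", f"rater={rater}", res))
        for session in table.sessions:
            m = table.matrix(motion, columns="rater", fixed={"session": session})
            res = icc_agreement(m, confidence)
            rows.append((motion, "interobserver", f"session={session}", res))
    report = pd.DataFrame(
        [
            {
                "motion": motion,
                "analysis": analysis,
                "unit": unit,
                "icc": r.estimate,
                "ci95_low": r.ci_low,
                "ci95_high": r.ci_high,
                "classification": r.classification,
            }
            for motion, analysis, unit, r in rows
        ]
    )
    report.attrs["design_size"] = table.design_size
    report.attrs["model"] = "ICC(A,1) two-way random, absolute agreement"
    return report
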