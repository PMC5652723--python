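"""Survival stratification by inferred regulatory activity.

Patients are split by the sign of an iRAS column (high: > 0, low: < 0), or
into four quadrants by the signs of two columns. Group survival is compared
with Kaplan-Meier curves and the log-rank test; a multivariate Cox
proportional-hazards model assesses whether activity remains prognostic
after adjusting for clinical covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from statsmodels.duration.hazard_regression import PHReg

from cistrome_compare.formats import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class StratifiedCohort:
    labels: pd.Series  # sample_id -> group label
    scheme: str  # 'sign2' or 'quadrant4'
    group_sizes: dict[str, int] = field(default_factory=dict)
    er_positive_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group_sizes = self.labels.value_counts().to_dict()


def _er_fractions(labels: pd.Series, er_status: pd.Series | None) -> dict[str, float]:
    if er_status is None:
        return {}
    er = er_status.reindex(labels.index) == "+"
    return {g: float(er[labels == g].mean()) for g in labels.unique()}


def stratify_sign(
    iras_column: pd.Series, er_status: pd.Series | None = None
) -> StratifiedCohort:
    """Two groups by activity sign: high (iRAS > 0) vs low (iRAS < 0).

    Exact zeros go to the low group with a logged count. An empty group is
    an error (the comparison would be vacuous).
    """
    vals = iras_column.astype(float)
    if not np.isfinite(vals).all():
        raise ValidationError("non-finite activity scores")
    n_zero = int((vals == 0).sum())
    if n_zero:
        logger.info("stratify_sign: %d exact-zero scores assigned to 'low'", n_zero)
    labels = pd.Series(np.where(vals > 0, "high", "low"), index=vals.index)
    for group in ("high", "low"):
        if (labels == group).sum() == 0:
            raise ValidationError(f"group {group!r} is empty")
    cohort = StratifiedCohort(labels, "sign2")
    cohort.er_positive_fraction = _er_fractions(labels, er_status)
    return cohort


def stratify_quadrant(
    iras_a: pd.Series,
    iras_b: pd.Series,
    er_status: pd.Series | None = None,
) -> StratifiedCohort:
    """Four groups by the signs of two activity columns.

    Group 1: a > 0, b <= 0; group 2: a > 0, b > 0; group 3: a <= 0, b <= 0;
    group 4: a <= 0, b > 0. Empty groups warn but do not error.
    """
    if not iras_a.index.equals(iras_b.index):
        raise ValidationError("activity columns are not sample-aligned")
    a = iras_a.astype(float) > 0
    b = iras_b.astype(float) > 0
    group = np.select(
        [a & ~b, a & b, ~a & ~b, ~a & b], ["1", "2", "3", "4"], default="?"
    )
    labels = pd.Series(group, index=iras_a.index)
    for g in "1234":
        if (labels == g).sum() == 0:
            warnings.warn(f"quadrant group {g} is empty")
    cohort = StratifiedCohort(labels, "quadrant4")
    cohort.er_positive_fraction = _er_fractions(labels, er_status)
    return cohort


@dataclass
class SurvivalTestResult:
    statistic: float
    df: int
    p: float
    km_curves: dict[str, pd.DataFrame]  # group -> columns time, survival


def logrank(
    labels: pd.Series, times: pd.Series, events: pd.Series
) -> SurvivalTestResult:
    """k-group log-rank test plus product-limit Kaplan-Meier curves."""
    idx = labels.index
    times = times.reindex(idx).astype(float)
    events = events.reindex(idx).astype(int)
    if (times <= 0).any():
        raise ValidationError("survival times must be positive")
    if events.sum() == 0:
        raise ValidationError("no events in the cohort")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValidationError("log-rank needs >= 2 groups")
    res = multivariate_logrank_test(times, labels, events)
    curves: dict[str, pd.DataFrame] = {}
    for g in groups:
        mask = labels == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return SurvivalTestResult(
        float(res.test_statistic), len(groups) - 1, float(res.p_value), curves
    )


@dataclass
class CoxFit:
    coefficients: pd.Series  # log hazard ratios
    standard_errors: pd.Series
    p_values: pd.Series

    def hazard_ratio(self, covariate: str) -> float:
        return float(np.exp(self.coefficients[covariate]))


def cox_multivariate(
    covariates: pd.DataFrame,
    times: pd.Series,
    events: pd.Series,
    ties: str = "breslow",
) -> CoxFit:
    """Multivariate Cox proportional-hazards fit (Breslow ties by default).

    Rows with missing values are dropped listwise (logged); constant or
    duplicated covariates raise an error before fitting.
    """
    df = covariates.copy()
    df["__time"] = times.reindex(df.index).astype(float)
    df["__event"] = events.reindex(df.index).astype(int)
    n_before = len(df)
    df = df.dropna()
    if len(df) < n_before:
        logger.info("cox_multivariate: dropped %d incomplete rows", n_before - len(df))
    X = df.drop(columns=["__time", "__event"])
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValidationError(f"covariate {col!r} is constant")
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValidationError("covariates are collinear (singular information)")
    if len(df) <= X.shape[1]:
        raise ValidationError("more covariates than observations")
    model = PHReg(
        df["__time"].to_numpy(),
        X.to_numpy(dtype=float),
        status=df["__event"].to_numpy(),
        ties=ties,
    )
    try:
        fit = model.fit(disp=False, maxiter=100)
    except Exception as exc:  # pragma: no cover - numerical pathologies
        raise ValidationError(f"Cox fit failed to converge: {exc}") from exc
    params = np.asarray(fit.params, dtype=float)
    if not np.isfinite(params).all():
        raise ValidationError("Cox fit produced non-finite coefficients")
    names = list(X.columns)
    return CoxFit(
        pd.Series(params, index=names),
        pd.Series(np.asarray(fit.bse, dtype=float), index=names),
        pd.Series(np.asarray(fit.pvalues, dtype=float), index=names),
    )


def encode_binary(series: pd.Series, positive: str = "+") -> pd.Series:
    """0/1 encoding of a categorical clinical column ('+' -> 1)."""
    return (series == positive).astype(float)
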