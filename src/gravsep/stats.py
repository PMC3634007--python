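"""Cohort statistics: shared variance between metrics and PAEE models.

Two questions are answered here.  First, how interchangeable are two
metrics in free-living data, split into a between-individual component
(do they rank people the same way?) and a within-individual component
(do they track the same minute-to-minute pattern?).  The estimator is a
correlation decomposition: between = squared correlation of participant
means, within = squared correlation of participant-mean-centred epoch
values.  It is symmetric in the pair and invariant to linear rescaling
of either metric.

Second, how much of daily physical-activity energy expenditure
(PAEE, MJ/day) does a metric explain alongside body weight, via
ordinary least squares ``PAEE ~ intercept + BW + metric``, and does a
second metric add anything on top (nested-model F-test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "VarianceDecomposition",
    "PaeeModel",
    "within_between_r2",
    "paee_regression",
    "additive_value",
]


@dataclass(frozen=True)
class VarianceDecomposition:
    """Shared variance (r^2) of a metric pair, within and between people."""

    metric_pair: Tuple[str, str]
    r2_within: float
    r2_between: float
    n_participants: int
    n_epochs: int


@dataclass(frozen=True)
class PaeeModel:
    """OLS fit of PAEE on body weight and one metric summary."""

    metric: str
    intercept: float
    bw_coef: float
    metric_coef: float
    residual_se: float
    r2: float
    n: int


def _corr2(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def within_between_r2(
    epochs_a: np.ndarray,
    epochs_b: np.ndarray,
    participant_ids: Sequence,
    metric_pair: Tuple[str, str] = ("A", "B"),
) -> VarianceDecomposition:
    """Within- and between-individual shared variance of paired epochs.

    ``epochs_a`` and ``epochs_b`` are paired per-epoch values (non-wear
    epochs already excluded) with a participant label per epoch.
    Participants contributing fewer than two epochs are dropped with a
    warning: they carry no within-person information and would make the
    centring degenerate.
    """
    df = pd.DataFrame(
        {
            "a": np.asarray(epochs_a, dtype=float),
            "b": np.asarray(epochs_b, dtype=float),
            "pid": np.asarray(participant_ids),
        }
    )
    sizes = df.groupby("pid").size()
    small = sizes[sizes < 2].index
    if len(small):
        warnings.warn(
            f"dropping {len(small)} participant(s) with fewer than 2 epochs",
            stacklevel=2,
        )
        df = df[~df["pid"].isin(small)]
    if df["pid"].nunique() < 2:
        raise ValueError("need at least two participants with >= 2 epochs")

    means = df.groupby("pid")[["a", "b"]].mean()
    r2_between = _corr2(means["a"].to_numpy(), means["b"].to_numpy())
    centred = df[["a", "b"]] - df.groupby("pid")[["a", "b"]].transform("mean")
    r2_within = _corr2(centred["a"].to_numpy(), centred["b"].to_numpy())
    return VarianceDecomposition(
        metric_pair=metric_pair,
        r2_within=r2_within,
        r2_between=r2_between,
        n_participants=int(df["pid"].nunique()),
        n_epochs=int(len(df)),
    )


def _design(body_weight: np.ndarray, *metrics: np.ndarray) -> np.ndarray:
    return sm.add_constant(np.column_stack([body_weight, *metrics]))


def paee_regression(
    paee_mj_day: Sequence[float],
    body_weight_kg: Sequence[float],
    metric_summary: Sequence[float],
    metric_name: str = "metric",
) -> PaeeModel:
    """OLS of PAEE on body weight and one per-person metric summary.

    Metric summaries are conventionally in mg so the fitted coefficient
    reads as MJ/day per mg.  Raises on a constant metric column (the
    design matrix would be rank-deficient).
    """
    y = np.asarray(paee_mj_day, dtype=float)
    bw = np.asarray(body_weight_kg, dtype=float)
    m = np.asarray(metric_summary, dtype=float)
    if m.std() == 0:
        raise ValueError(f"metric {metric_name!r} is constant; model is rank-deficient")
    fit = sm.OLS(y, _design(bw, m)).fit()
    return PaeeModel(
        metric=metric_name,
        intercept=float(fit.params[0]),
        bw_coef=float(fit.params[1]),
        metric_coef=float(fit.params[2]),
        residual_se=float(np.sqrt(fit.mse_resid)),
        r2=float(fit.rsquared),
        n=int(fit.nobs),
    )


def additive_value(
    paee_mj_day: Sequence[float],
    body_weight_kg: Sequence[float],
    metric_a: Sequence[float],
    metric_b: Sequence[float],
) -> Tuple[float, float]:
    """Does metric B add to a model already holding BW and metric A?

    Returns ``(delta_r2, p_value)`` from the F-test of
    ``PAEE ~ BW + A`` nested in ``PAEE ~ BW + A + B``.  A metric B that
    is (numerically) collinear with the smaller model contributes
    nothing: ``(0.0, 1.0)``.
    """
    y = np.asarray(paee_mj_day, dtype=float)
    bw = np.asarray(body_weight_kg, dtype=float)
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    small = sm.OLS(y, _design(bw, a)).fit()
    big_design = _design(bw, a, b)
    if np.linalg.matrix_rank(big_design) < big_design.shape[1]:
        return 0.0, 1.0
    big = sm.OLS(y, big_design).fit()
    delta_r2 = float(big.rsquared - small.rsquared)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on near-singular F
        _, p_value, _ = big.compare_f_test(small)
    if np.isnan(p_value):
        return delta_r2, 1.0
    return delta_r2, float(p_value)
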