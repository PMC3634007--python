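"""Bench-analysis pipeline: period-consistent averaging and error tables.

Each simulated condition is summarised by averaging metric output and
reference acceleration over an integer number of oscillation periods in
the middle two minutes of the recording (the first and last 30 s absorb
filter transients and rig settling).  Errors are reported in mg
(1 mg = 0.001 g) and, where the reference is non-zero, as relative
percentages; band summaries group conditions by frequency band, angular
range and radius band, averaging relative errors per condition first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .errors import TooShortError
from .metrics import compute_metric
from .robot_sim import (
    OscillationCondition,
    condition_grid,
    generate_trajectory,
    reference_acceleration,
    simulate_sensor,
    static_trajectory,
)

__all__ = [
    "ConditionResult",
    "BandSummary",
    "period_average",
    "compute_errors",
    "evaluate_grid",
    "summarize_bands",
    "grid_mean_absolute_error",
    "FREQ_BANDS",
    "RADIUS_BANDS",
]

#: frequency bands of the summary table (Hz); static conditions form their own rows
FREQ_BANDS: Tuple[Tuple[float, float], ...] = (
    (0.05, 0.2),
    (0.25, 0.55),
    (0.6, 0.8),
    (0.9, 1.1),
    (1.2, 1.3),
    (1.4, 2.0),
    (2.1, 3.0),
    (3.2, 4.0),
)

#: radius bands of the summary table (m)
RADIUS_BANDS: Tuple[Tuple[float, float], ...] = ((0.1, 0.3), (0.3, 0.6), (0.6, 0.8))

DEFAULT_WINDOW = (30.0, 150.0)


@dataclass(frozen=True)
class ConditionResult:
    """Period-averaged estimate vs reference for one (condition, radius, metric)."""

    frequency_hz: float
    angle_min_deg: float
    angle_max_deg: float
    radius_m: float
    metric: str
    estimate_mg: float
    reference_mg: float
    error_mg: float
    rel_error_pct: float  # NaN when the reference is zero (static rows)


@dataclass(frozen=True)
class BandSummary:
    """One summary-table cell: a metric within a frequency x radius band."""

    freq_band: Tuple[float, float]
    angle_range: Tuple[float, float]
    radius_band: Tuple[float, float]
    metric: str
    n: int
    mean_reference_mg: float
    mean_error_mg: float
    mean_abs_error_mg: float
    mean_rel_error_pct: float  # NaN for static rows


def _window_slice(
    fs: float, frequency_hz: float, window: Tuple[float, float], n_samples: int
) -> slice:
    w0, w1 = window
    if frequency_hz > 0:
        n_periods = math.floor((w1 - w0) * frequency_hz)
        if n_periods < 1:
            raise TooShortError(
                f"window of {w1 - w0} s holds no full period at {frequency_hz} Hz"
            )
        end = w0 + n_periods / frequency_hz
    else:
        end = w1
    i0 = int(math.ceil(w0 * fs - 1e-9))
    i1 = int(math.ceil(end * fs - 1e-9))  # end-exclusive
    if i1 > n_samples:
        raise TooShortError(
            f"recording of {n_samples / fs:.1f} s does not cover the averaging "
            f"window ending at {end:.1f} s"
        )
    return slice(i0, i1)


def period_average(
    values: np.ndarray,
    fs: float,
    frequency_hz: float,
    window: Tuple[float, float] = DEFAULT_WINDOW,
) -> float:
    """Mean of ``values`` over whole oscillation periods inside ``window``.

    The averaging interval starts at ``window[0]`` and spans the largest
    whole number of periods that fit before ``window[1]``; sample ``i``
    is taken at time ``i / fs``.  For a static series (``frequency_hz ==
    0``) the plain mean over the window is returned.
    """
    values = np.asarray(values, dtype=float)
    sl = _window_slice(fs, frequency_hz, window, values.shape[0])
    return float(values[sl].mean())


def compute_errors(
    estimate_mean_g: float, reference_mean_g: float
) -> Tuple[float, float]:
    """(absolute error in mg, relative error in %).

    Relative error is (estimate - reference) / reference; it is NaN when
    the reference is zero (static conditions report only mg).
    """
    abs_mg = 1000.0 * (estimate_mean_g - reference_mean_g)
    if reference_mean_g == 0:
        return abs_mg, float("nan")
    return abs_mg, 100.0 * (estimate_mean_g - reference_mean_g) / reference_mean_g


def evaluate_condition(
    cond: OscillationCondition,
    metric_names: Sequence[str] = ("ENMO", "HFEN", "HFEN+"),
    noise_sd_g: float = 0.0,
    seed: Optional[int] = None,
    cutoff_hz: float = 0.2,
    band_high_hz: float = 15.0,
    order: int = 4,
    truncate: bool = False,
    zero_phase: bool = False,
    window: Tuple[float, float] = DEFAULT_WINDOW,
    condition_index: int = 0,
) -> list[ConditionResult]:
    """Evaluate all radii and metrics of one condition.

    Negative metric output is kept by default (``truncate=False``): the
    bench exists to expose when and how metrics fail, and clamping would
    mask the ENMO collapse during vertical-plane rotation.
    """
    if cond.is_static:
        traj = static_trajectory(cond.angle_min_deg, cond.duration_s, cond.fs)
    else:
        traj = generate_trajectory(cond)
    results = []
    for ri, radius in enumerate(cond.radii_m):
        child_seed = None
        if noise_sd_g > 0:
            if seed is None:
                raise ValueError("a seed is required for noisy evaluation")
            child_seed = np.random.SeedSequence(
                entropy=seed, spawn_key=(condition_index, ri)
            )
        sensor = simulate_sensor(traj, radius, noise_sd_g=noise_sd_g, seed=child_seed)
        ref_mean = period_average(
            reference_acceleration(traj, radius), cond.fs, cond.frequency_hz, window
        )
        for name in metric_names:
            series = compute_metric(
                sensor.recording,
                name,
                cutoff_hz=cutoff_hz,
                band_high_hz=band_high_hz,
                order=order,
                truncate=truncate,
                zero_phase=zero_phase,
            )
            est_mean = period_average(series.values, cond.fs, cond.frequency_hz, window)
            abs_mg, rel_pct = compute_errors(est_mean, ref_mean)
            results.append(
                ConditionResult(
                    frequency_hz=cond.frequency_hz,
                    angle_min_deg=cond.angle_min_deg,
                    angle_max_deg=cond.angle_max_deg,
                    radius_m=radius,
                    metric=name,
                    estimate_mg=est_mean * 1000.0,
                    reference_mg=ref_mean * 1000.0,
                    error_mg=abs_mg,
                    rel_error_pct=rel_pct,
                )
            )
    return results


def evaluate_grid(
    conditions: Optional[Iterable[OscillationCondition]] = None,
    metric_names: Sequence[str] = ("ENMO", "HFEN", "HFEN+"),
    noise_sd_g: float = 0.0,
    seed: Optional[int] = None,
    window: Tuple[float, float] = DEFAULT_WINDOW,
    **metric_kwargs,
) -> list[ConditionResult]:
    """Run the bench over ``conditions`` (default: the full grid)."""
    if conditions is None:
        conditions = condition_grid()
    results: list[ConditionResult] = []
    for ci, cond in enumerate(conditions):
        results.extend(
            evaluate_condition(
                cond,
                metric_names=metric_names,
                noise_sd_g=noise_sd_g,
                seed=seed,
                window=window,
                condition_index=ci,
                **metric_kwargs,
            )
        )
    return results


def _freq_band(f: float) -> Optional[Tuple[float, float]]:
    if f == 0:
        return (0.0, 0.0)
    for band in FREQ_BANDS:
        if band[0] <= f <= band[1] + 1e-9:
            return band
    return None


def _radius_band(r: float) -> Optional[Tuple[float, float]]:
    for band in RADIUS_BANDS:
        if band[0] <= r <= band[1] + 1e-9:
            return band
    return None


def summarize_bands(results: Sequence[ConditionResult]) -> list[BandSummary]:
    """Aggregate condition results into summary-table cells.

    The signed mean error in mg is the printed headline of each cell;
    relative errors are averaged across conditions within the cell
    (each condition-radius pair already carries its own relative error).
    Static rows keep NaN relative error.
    """
    groups: dict[tuple, list[ConditionResult]] = {}
    for res in results:
        fb = _freq_band(res.frequency_hz)
        rb = _radius_band(res.radius_m)
        if fb is None or rb is None:
            continue
        key = (fb, (res.angle_min_deg, res.angle_max_deg), rb, res.metric)
        groups.setdefault(key, []).append(res)

    summaries = []
    for (fb, angles, rb, metric), cell in sorted(groups.items()):
        errors = np.array([c.error_mg for c in cell])
        rels = np.array([c.rel_error_pct for c in cell])
        summaries.append(
            BandSummary(
                freq_band=fb,
                angle_range=angles,
                radius_band=rb,
                metric=metric,
                n=len(cell),
                mean_reference_mg=float(np.mean([c.reference_mg for c in cell])),
                mean_error_mg=float(errors.mean()),
                mean_abs_error_mg=float(np.abs(errors).mean()),
                mean_rel_error_pct=(
                    float(np.nanmean(rels)) if not np.all(np.isnan(rels)) else float("nan")
                ),
            )
        )
    return summaries


def grid_mean_absolute_error(
    results: Sequence[ConditionResult], metric: str, moving_only: bool = True
) -> float:
    """Mean |error| in mg for one metric across condition-radius pairs."""
    errs = [
        abs(r.error_mg)
        for r in results
        if r.metric == metric and (not moving_only or r.frequency_hz > 0)
    ]
    if not errs:
        raise ValueError(f"no results for metric {metric!r}")
    return float(np.mean(errs))
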