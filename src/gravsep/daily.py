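"""Free-living processing chain.

Turns multi-day wrist/hip recordings into per-person summaries:

1. static calibration check (per-axis offset and gain against the 1 g
   identity of motionless recordings);
2. per-15-min-block classification into wear / non-wear / clipping,
   with blocks snapped to clock quarter-hours;
3. metric computation and 1-min epoch averaging;
4. same-clock-time imputation of flagged blocks across days;
5. per-person mean and the wear-time inclusion rule.

The non-wear rule (long near-static window, per-axis SD threshold) is a
configurable stand-in in the style of the established raw-accelerometry
pipelines; every threshold is a keyword so an alternative rule can be
dropped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .errors import CalibrationError
from .metrics import MetricSeries
from .recording import TriaxialRecording

__all__ = [
    "WEAR",
    "NONWEAR",
    "CLIPPING",
    "BlockFlagSeries",
    "EpochSeries",
    "CalibrationModel",
    "calibrate_static",
    "detect_clipping",
    "detect_nonwear",
    "combine_flags",
    "epoch_average",
    "impute_blocks",
    "participant_summary",
    "ParticipantSummary",
]

WEAR = "wear"
NONWEAR = "nonwear"
CLIPPING = "clipping"

BLOCK_LENGTH_MIN = 15
EPOCH_LENGTH_S = 60


@dataclass(frozen=True)
class BlockFlagSeries:
    """Per-block wear/non-wear/clipping flags aligned to clock quarter-hours.

    ``first_block`` is the index of the first block counted from local
    midnight (block ``k`` covers ``[k*15, (k+1)*15)`` minutes of day),
    so two recordings starting at different offsets within a
    quarter-hour share identical block boundaries.
    """

    flags: np.ndarray  # array of str
    first_block: int
    block_length_min: int = BLOCK_LENGTH_MIN

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", np.asarray(self.flags, dtype=object))

    @property
    def n_blocks(self) -> int:
        return self.flags.shape[0]


@dataclass(frozen=True)
class EpochSeries:
    """Per-epoch mean metric values in g, with imputation bookkeeping."""

    values: np.ndarray
    epoch_length_s: int = EPOCH_LENGTH_S
    imputed: Optional[np.ndarray] = None
    start_time: float = 0.0
    metric: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        imputed = (
            np.zeros(values.shape[0], dtype=bool)
            if self.imputed is None
            else np.asarray(self.imputed, dtype=bool)
        )
        if imputed.shape != values.shape:
            raise ValueError("imputed mask must match values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "imputed", imputed)

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CalibrationModel:
    """Per-axis offset (g) and gain: calibrated = raw * gain + offset."""

    offset: np.ndarray  # (3,)
    gain: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        offset = np.asarray(self.offset, dtype=float)
        gain = np.asarray(self.gain, dtype=float)
        if offset.shape != (3,) or gain.shape != (3,):
            raise ValueError("offset and gain must each have shape (3,)")
        object.__setattr__(self, "offset", offset)
        object.__setattr__(self, "gain", gain)

    def apply(self, rec: TriaxialRecording) -> TriaxialRecording:
        return rec.with_data(rec.data * self.gain + self.offset)

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(offset=np.zeros(3), gain=np.ones(3))


def calibrate_static(
    static_recordings: Sequence[TriaxialRecording],
    tolerance_g: float = 0.003,
    min_component_g: float = 0.25,
) -> CalibrationModel:
    """Fit per-axis offset and gain from motionless recordings.

    Each recording is reduced to its mean vector (a static point on the
    unit gravity sphere); offsets and gains are chosen by least squares
    so calibrated static magnitudes are 1 g.  Requires at least six
    points whose dominant components span both signs of every axis,
    otherwise the six parameters are not identifiable.  The fit is
    rejected if any calibrated point deviates from 1 g by more than
    ``tolerance_g``.
    """
    if len(static_recordings) < 6:
        raise CalibrationError(
            f"need at least 6 static orientations, got {len(static_recordings)}"
        )
    points = np.array([rec.data.mean(axis=0) for rec in static_recordings])
    for axis in range(3):
        comp = points[:, axis]
        if comp.max() < min_component_g or comp.min() > -min_component_g:
            raise CalibrationError(
                f"static orientations do not span both signs of axis {axis}; "
                "offset and gain are under-determined"
            )

    def residuals(params: np.ndarray) -> np.ndarray:
        offset, gain = params[:3], params[3:]
        return np.linalg.norm(points * gain + offset, axis=1) - 1.0

    fit = optimize.least_squares(residuals, x0=np.r_[np.zeros(3), np.ones(3)])
    model = CalibrationModel(offset=fit.x[:3], gain=fit.x[3:])
    worst = np.max(np.abs(residuals(fit.x)))
    if worst > tolerance_g:
        raise CalibrationError(
            f"calibration rejected: worst static magnitude deviates from 1 g "
            f"by {worst:.4f} g (> {tolerance_g} g)"
        )
    if np.any(np.abs(model.gain - 1) > 0.1) or np.any(np.abs(model.offset) > 0.1):
        raise CalibrationError("fitted calibration is implausibly far from identity")
    return model


def _block_layout(rec: TriaxialRecording, block_length_min: int) -> Tuple[int, np.ndarray]:
    """(first clock block index, per-sample block index within recording)."""
    block_s = block_length_min * 60
    times = rec.start_time + rec.t
    abs_block = np.floor(times / block_s).astype(int)
    first = int(abs_block[0])
    return first, abs_block - first


def detect_clipping(
    rec: TriaxialRecording,
    range_g: float = 6.0,
    frac_threshold: float = 0.01,
    block_length_min: int = BLOCK_LENGTH_MIN,
) -> BlockFlagSeries:
    """Flag blocks where the signal saturates the sensor's dynamic range.

    A block is flagged when more than ``frac_threshold`` of its samples
    have any axis at or beyond ``0.99 * range_g``.
    """
    first, block_idx = _block_layout(rec, block_length_min)
    n_blocks = int(block_idx[-1]) + 1
    near_limit = np.any(np.abs(rec.data) >= 0.99 * range_g, axis=1)
    flags = np.full(n_blocks, WEAR, dtype=object)
    counts = np.bincount(block_idx, minlength=n_blocks)
    hits = np.bincount(block_idx, weights=near_limit.astype(float), minlength=n_blocks)
    frac = np.divide(hits, counts, out=np.zeros(n_blocks), where=counts > 0)
    flags[frac > frac_threshold] = CLIPPING
    return BlockFlagSeries(flags=flags, first_block=first, block_length_min=block_length_min)


def detect_nonwear(
    rec: TriaxialRecording,
    window_min: int = 60,
    step_min: int = 15,
    sd_threshold_g: float = 0.013,
    min_axes: int = 2,
    block_length_min: int = BLOCK_LENGTH_MIN,
) -> BlockFlagSeries:
    """Flag blocks inside prolonged near-static windows as non-wear.

    A sliding window (default 60 min, stepping one block) marks every
    block it covers as non-wear when at least ``min_axes`` axes have a
    sample SD below ``sd_threshold_g`` (default 13 mg).
    """
    first, block_idx = _block_layout(rec, block_length_min)
    n_blocks = int(block_idx[-1]) + 1
    flags = np.full(n_blocks, WEAR, dtype=object)
    win_samples = int(round(window_min * 60 * rec.fs))
    step_samples = int(round(step_min * 60 * rec.fs))
    if rec.n_samples < win_samples:
        warnings.warn(
            "recording shorter than one non-wear window; all blocks kept as wear",
            stacklevel=2,
        )
        return BlockFlagSeries(flags=flags, first_block=first, block_length_min=block_length_min)
    for start in range(0, rec.n_samples - win_samples + 1, step_samples):
        window = rec.data[start : start + win_samples]
        quiet_axes = int(np.sum(window.std(axis=0) < sd_threshold_g))
        if quiet_axes >= min_axes:
            covered = np.unique(block_idx[start : start + win_samples])
            flags[covered] = NONWEAR
    return BlockFlagSeries(flags=flags, first_block=first, block_length_min=block_length_min)


def combine_flags(*flag_series: BlockFlagSeries) -> BlockFlagSeries:
    """Merge flag series; clipping takes precedence over non-wear over wear."""
    if not flag_series:
        raise ValueError("need at least one flag series")
    base = flag_series[0]
    merged = np.array(base.flags, dtype=object)
    rank = {WEAR: 0, NONWEAR: 1, CLIPPING: 2}
    for other in flag_series[1:]:
        if other.first_block != base.first_block or other.n_blocks != base.n_blocks:
            raise ValueError("flag series must cover identical blocks")
        for i, flag in enumerate(other.flags):
            if rank[flag] > rank[merged[i]]:
                merged[i] = flag
    return BlockFlagSeries(
        flags=merged, first_block=base.first_block, block_length_min=base.block_length_min
    )


def epoch_average(
    series: MetricSeries, epoch_length_s: int = EPOCH_LENGTH_S, start_time: float = 0.0
) -> EpochSeries:
    """Mean metric value per consecutive non-overlapping epoch.

    ``fs * epoch_length_s`` must be a whole number of samples; a
    trailing partial epoch is dropped.
    """
    per_epoch = series.fs * epoch_length_s
    if abs(per_epoch - round(per_epoch)) > 1e-9:
        raise ValueError(
            f"epoch of {epoch_length_s} s is not a whole number of samples at "
            f"fs={series.fs} Hz"
        )
    per_epoch = int(round(per_epoch))
    n_epochs = series.n_samples // per_epoch
    values = series.values[: n_epochs * per_epoch].reshape(n_epochs, per_epoch).mean(axis=1)
    return EpochSeries(
        values=values,
        epoch_length_s=epoch_length_s,
        start_time=start_time,
        metric=series.name,
    )


def _epochs_per_block(epoch_length_s: int, block_length_min: int) -> int:
    block_s = block_length_min * 60
    if block_s % epoch_length_s:
        raise ValueError("block length must be a whole number of epochs")
    return block_s // epoch_length_s


def impute_blocks(
    epoch_stack: np.ndarray,
    flagged: np.ndarray,
    metric_name: str,
    epoch_length_s: int = EPOCH_LENGTH_S,
    block_length_min: int = BLOCK_LENGTH_MIN,
) -> Tuple[np.ndarray, np.ndarray]:
    """Replace flagged blocks with same-clock-time averages across days.

    Parameters
    ----------
    epoch_stack
        Array of shape ``(n_days, epochs_per_day)`` of per-epoch metric
        means, days aligned to local clock time.
    flagged
        Boolean array of shape ``(n_days, blocks_per_day)``; True marks
        a non-wear or clipping block to impute.
    metric_name
        Determines the fallback fill when a block is flagged on every
        day: 1 g for EN (a motionless sensor still reads gravity), 0 g
        for every other metric.

    Returns the imputed stack and a matching boolean "was imputed" mask
    per epoch.  The operation is idempotent: imputed values are computed
    from unflagged days only.
    """
    stack = np.array(epoch_stack, dtype=float)
    flagged = np.asarray(flagged, dtype=bool)
    n_days, n_epochs = stack.shape
    per_block = _epochs_per_block(epoch_length_s, block_length_min)
    n_blocks = n_epochs // per_block
    if flagged.shape != (n_days, n_blocks):
        raise ValueError(
            f"flags of shape {flagged.shape} do not match {n_days} days x {n_blocks} blocks"
        )
    fallback = 1.0 if metric_name == "EN" else 0.0
    imputed_mask = np.zeros_like(stack, dtype=bool)
    for b in range(n_blocks):
        sl = slice(b * per_block, (b + 1) * per_block)
        good_days = ~flagged[:, b]
        donor = stack[good_days, sl].mean(axis=0) if good_days.any() else None
        for d in range(n_days):
            if flagged[d, b]:
                stack[d, sl] = donor if donor is not None else fallback
                imputed_mask[d, sl] = True
    return stack, imputed_mask


@dataclass(frozen=True)
class ParticipantSummary:
    """Per-person record-level summary and the inclusion decision."""

    mean_g: float
    wear_fraction: float
    n_valid_days: int
    included: bool


def participant_summary(
    epoch_stack: np.ndarray,
    flagged: np.ndarray,
    metric_name: str,
    epoch_length_s: int = EPOCH_LENGTH_S,
    block_length_min: int = BLOCK_LENGTH_MIN,
    valid_day_wear_fraction: float = 0.5,
) -> ParticipantSummary:
    """Mean metric over the imputed record plus the inclusion rule.

    A participant is included with strictly more than 50% overall wear
    time and at least one valid day (a day whose own wear fraction
    exceeds ``valid_day_wear_fraction``); exactly 50% wear is excluded.
    """
    flagged = np.asarray(flagged, dtype=bool)
    imputed, _ = impute_blocks(
        epoch_stack, flagged, metric_name, epoch_length_s, block_length_min
    )
    wear_fraction = float(1.0 - flagged.mean())
    day_wear = 1.0 - flagged.mean(axis=1)
    n_valid_days = int(np.sum(day_wear > valid_day_wear_fraction))
    included = wear_fraction > 0.5 and n_valid_days >= 1
    return ParticipantSummary(
        mean_g=float(imputed.mean()),
        wear_fraction=wear_fraction,
        n_valid_days=n_valid_days,
        included=included,
    )
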