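"""Acceleration summary metrics for gravity-movement separation.

A raw acceleration signal mixes three components: acceleration due to body
(or rig) movement, the 1 g gravitational field projected onto the sensor
axes, and sensor noise.  The metrics here are the standard candidates for
summarising movement after removing gravity, each resting on a different
assumption:

``EN``
    Euclidean norm of the three raw axes; no gravity removal at all.
``ENMO``
    EN minus 1 g; removes gravity by assuming its magnitude is exactly
    1 g and that movement and gravity add along the same direction.
``HFEN``
    Euclidean norm of the three per-axis high-pass-filtered signals
    (4th-order Butterworth, 0.2 Hz default); removes gravity by assuming
    it lives below the cut-off frequency.
``LFEN``
    Euclidean norm of the per-axis low-pass-filtered signals; equals 1 g
    whenever the orientation changes slowly, and deviates from 1 g when
    rotation pushes gravity above the cut-off.
``HFEN+``
    HFEN + (LFEN - 1 g); a hybrid that adds back whatever low-frequency
    magnitude the high-pass filter misclassified.
``BFEN``
    Band-pass (0.2-15 Hz default) variant of HFEN, additionally
    suppressing high-frequency noise.

ENMO and HFEN+ can go negative; the ``truncate`` flag clamps negatives to
zero (the convention for free-living human data, whereas kinematic bench
evaluations keep the sign to expose the failure mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .errors import InvalidFilterError, TooShortError
from .recording import TriaxialRecording

__all__ = [
    "METRIC_NAMES",
    "FilterSpec",
    "MetricSeries",
    "apply_butterworth",
    "euclidean_norm",
    "enmo",
    "lfen",
    "hfen",
    "bfen",
    "hfen_plus",
    "compute_metric",
]

METRIC_NAMES = ("EN", "ENMO", "LFEN", "HFEN", "BFEN", "HFEN+")

DEFAULT_CUTOFF_HZ = 0.2
DEFAULT_BAND_HIGH_HZ = 15.0
DEFAULT_ORDER = 4


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter specification.

    ``kind`` is one of ``"high-pass"``, ``"low-pass"``, ``"band-pass"``.
    High/low-pass use ``cutoff_low_hz``; band-pass uses both bounds.
    """

    kind: str
    order: int = DEFAULT_ORDER
    cutoff_low_hz: Optional[float] = None
    cutoff_high_hz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("high-pass", "low-pass", "band-pass"):
            raise InvalidFilterError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise InvalidFilterError("filter order must be >= 1")
        if self.cutoff_low_hz is None:
            raise InvalidFilterError("cutoff_low_hz is required")
        if self.cutoff_low_hz <= 0:
            raise InvalidFilterError("cut-off frequencies must be positive")
        if self.kind == "band-pass":
            if self.cutoff_high_hz is None:
                raise InvalidFilterError("band-pass requires cutoff_high_hz")
            if not self.cutoff_high_hz > self.cutoff_low_hz:
                raise InvalidFilterError("band-pass needs cutoff_low_hz < cutoff_high_hz")

    def sos(self, fs: float):
        """Second-order-section coefficients for sampling frequency ``fs``."""
        nyq = fs / 2.0
        high = self.cutoff_high_hz if self.kind == "band-pass" else None
        top = high if high is not None else self.cutoff_low_hz
        if top >= nyq:
            raise InvalidFilterError(
                f"cut-off {top} Hz is at or above the Nyquist frequency {nyq} Hz"
            )
        if self.kind == "high-pass":
            return signal.butter(self.order, self.cutoff_low_hz, "highpass", fs=fs, output="sos")
        if self.kind == "low-pass":
            return signal.butter(self.order, self.cutoff_low_hz, "lowpass", fs=fs, output="sos")
        return signal.butter(
            self.order, [self.cutoff_low_hz, self.cutoff_high_hz], "bandpass", fs=fs, output="sos"
        )


@dataclass(frozen=True)
class MetricSeries:
    """Per-sample output of one named metric, in g."""

    name: str
    values: np.ndarray
    fs: float
    truncated: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def _filtfilt_padlen(sos: np.ndarray) -> int:
    # default padlen used by scipy.signal.sosfiltfilt
    n_sections = sos.shape[0]
    ntaps = 2 * n_sections + 1
    ntaps -= min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum())
    return 3 * ntaps


def apply_butterworth(
    rec: TriaxialRecording, spec: FilterSpec, zero_phase: bool = False
) -> TriaxialRecording:
    """Filter each axis of ``rec`` with the Butterworth filter in ``spec``.

    ``zero_phase=True`` applies the filter forward and backward
    (``sosfiltfilt``), giving zero phase distortion at the cost of
    squaring the magnitude response; ``zero_phase=False`` is a causal
    single pass from zero initial conditions.
    """
    sos = spec.sos(rec.fs)
    if zero_phase:
        padlen = _filtfilt_padlen(sos)
        if rec.n_samples <= padlen:
            raise TooShortError(
                f"recording of {rec.n_samples} samples is too short for "
                f"zero-phase filtering (needs > {padlen})"
            )
        out = signal.sosfiltfilt(sos, rec.data, axis=0)
    else:
        out = signal.sosfilt(sos, rec.data, axis=0)
    return rec.with_data(out)


def _norm(data: np.ndarray) -> np.ndarray:
    return np.sqrt(np.sum(data * data, axis=1))


def _maybe_truncate(values: np.ndarray, truncate: bool) -> np.ndarray:
    if truncate:
        return np.maximum(values, 0.0)
    return values


def euclidean_norm(rec: TriaxialRecording) -> MetricSeries:
    """EN: per-sample vector magnitude of the raw axes, gravity included."""
    return MetricSeries("EN", _norm(rec.data), rec.fs, truncated=False)


def enmo(rec: TriaxialRecording, truncate: bool = True) -> MetricSeries:
    """ENMO: Euclidean norm minus one (g); negatives optionally clamped."""
    values = _norm(rec.data) - 1.0
    return MetricSeries("ENMO", _maybe_truncate(values, truncate), rec.fs, truncated=truncate)


def lfen(
    rec: TriaxialRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
    zero_phase: bool = False,
) -> MetricSeries:
    """LFEN: Euclidean norm of per-axis low-pass-filtered signals."""
    spec = FilterSpec("low-pass", order=order, cutoff_low_hz=cutoff_hz)
    filtered = apply_butterworth(rec, spec, zero_phase=zero_phase)
    return MetricSeries("LFEN", _norm(filtered.data), rec.fs, truncated=False)


def hfen(
    rec: TriaxialRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
    truncate: bool = True,
    zero_phase: bool = False,
) -> MetricSeries:
    """HFEN: Euclidean norm of per-axis high-pass-filtered signals.

    Non-negative by construction; the ``truncate`` flag is recorded for
    interface symmetry but cannot change the values.
    """
    spec = FilterSpec("high-pass", order=order, cutoff_low_hz=cutoff_hz)
    filtered = apply_butterworth(rec, spec, zero_phase=zero_phase)
    return MetricSeries("HFEN", _norm(filtered.data), rec.fs, truncated=truncate)


def bfen(
    rec: TriaxialRecording,
    low_hz: float = DEFAULT_CUTOFF_HZ,
    high_hz: float = DEFAULT_BAND_HIGH_HZ,
    order: int = DEFAULT_ORDER,
    truncate: bool = True,
    zero_phase: bool = False,
) -> MetricSeries:
    """BFEN: Euclidean norm of per-axis band-pass-filtered signals."""
    spec = FilterSpec("band-pass", order=order, cutoff_low_hz=low_hz, cutoff_high_hz=high_hz)
    filtered = apply_butterworth(rec, spec, zero_phase=zero_phase)
    return MetricSeries("BFEN", _norm(filtered.data), rec.fs, truncated=truncate)


def hfen_plus(
    rec: TriaxialRecording,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_ORDER,
    truncate: bool = True,
    zero_phase: bool = False,
) -> MetricSeries:
    """HFEN+: HFEN plus (LFEN - 1 g).

    The low-frequency correction term adds back movement that leaked
    below the cut-off (LFEN > 1 g, e.g. sustained centripetal
    acceleration) and subtracts gravity that leaked above it
    (LFEN < 1 g, e.g. vertical-plane rotation).  When ``truncate`` is
    set, clamping is applied to the summed series, not per term.
    """
    h = hfen(rec, cutoff_hz=cutoff_hz, order=order, truncate=False, zero_phase=zero_phase)
    l = lfen(rec, cutoff_hz=cutoff_hz, order=order, zero_phase=zero_phase)
    values = h.values + l.values - 1.0
    return MetricSeries("HFEN+", _maybe_truncate(values, truncate), rec.fs, truncated=truncate)


def compute_metric(
    rec: TriaxialRecording,
    name: str,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    band_high_hz: float = DEFAULT_BAND_HIGH_HZ,
    order: int = DEFAULT_ORDER,
    truncate: bool = True,
    zero_phase: bool = False,
) -> MetricSeries:
    """Dispatch to one of the named metrics with shared filter settings."""
    if name == "EN":
        return euclidean_norm(rec)
    if name == "ENMO":
        return enmo(rec, truncate=truncate)
    if name == "LFEN":
        return lfen(rec, cutoff_hz=cutoff_hz, order=order, zero_phase=zero_phase)
    if name == "HFEN":
        return hfen(rec, cutoff_hz=cutoff_hz, order=order, truncate=truncate, zero_phase=zero_phase)
    if name == "BFEN":
        return bfen(
            rec,
            low_hz=cutoff_hz,
            high_hz=band_high_hz,
            order=order,
            truncate=truncate,
            zero_phase=zero_phase,
        )
    if name == "HFEN+":
        return hfen_plus(
            rec, cutoff_hz=cutoff_hz, order=order, truncate=truncate, zero_phase=zero_phase
        )
    raise ValueError(f"unknown metric {name!r}; choose from {METRIC_NAMES}")
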