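"""Tri-axial acceleration recordings.

The universal input of the package: a fixed-rate sequence of (x, y, z)
acceleration samples expressed in g units (1 g = 9.81 m s^-2).  Axis
conventions are left to the producer; every metric in
:mod:`gravsep.metrics` is a function of the per-sample vector and its
norm, so axis permutations and rotations do not change any norm-based
quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TriaxialRecording"]


@dataclass(frozen=True)
class TriaxialRecording:
    """A fixed-rate tri-axial acceleration recording in g units.

    Parameters
    ----------
    fs
        Sampling frequency in Hz; must be positive and constant for the
        whole recording.
    data
        Array of shape ``(n, 3)`` with columns x, y, z in g.
    start_time
        Clock time of the first sample, in seconds since local midnight.
        Used by the free-living chain to snap 15-min blocks to clock
        quarter-hours; irrelevant for the kinematics bench.
    """

    fs: float
    data: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[1] != 3:
            raise ValueError(f"data must have shape (n, 3), got {data.shape}")
        if data.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.all(np.isfinite(data)):
            raise ValueError("acceleration values must be finite")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        object.__setattr__(self, "data", data)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        """Duration covered by the samples (n / fs)."""
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample times relative to the first sample, in seconds."""
        return np.arange(self.n_samples) / self.fs

    @property
    def x(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.data[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.data[:, 2]

    def with_data(self, data: np.ndarray) -> "TriaxialRecording":
        """Return a copy carrying ``data`` but the same fs and start time."""
        return TriaxialRecording(fs=self.fs, data=data, start_time=self.start_time)
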