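"""Raw shank-acceleration series: container type, band-pass filtering,
100 ms moving integral, and CSV input/output.

The classification pipeline uses a single accelerometer axis (the
proximal-to-distal component of a shank-mounted sensor) sampled uniformly,
100 samples/s by default.  Everything downstream — segmentation, feature
extraction — operates on the band-passed signal and on its short-window
time integral, both defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

logger = logging.getLogger("gaitclass")

__all__ = [
    "AccelerationRecord",
    "FilterSpec",
    "bandpass",
    "moving_integral",
    "read_acceleration_csv",
    "write_acceleration_csv",
]


@dataclass
class AccelerationRecord:
    """Uniformly sampled single-axis acceleration series.

    Parameters
    ----------
    samples : array-like
        Acceleration values in m/s^2, time-ordered.
    fs : float
        Sampling rate in samples/s.  Default 100.
    t0 : float
        Time of the first sample, in seconds.
    """

    samples: np.ndarray
    fs: float = 100.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got fs={self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record duration in seconds (number of samples / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class FilterSpec:
    """Butterworth band-pass specification.

    Defaults are the 2–20 Hz, 4th-order band used for gait signals; the
    band keeps stride-rate harmonics and impact content while rejecting
    the gravity component (DC) and high-frequency sensor noise.

    ``mode`` selects causal filtering (``sosfilt``, suitable for on-line
    use) or zero-phase filtering (``sosfiltfilt``, forward-backward, no
    group delay, offline only).
    """

    low_hz: float = 2.0
    high_hz: float = 20.0
    order: int = 4
    mode: str = "causal"

    def validate(self, fs: float) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"need 0 < low_hz < high_hz, got ({self.low_hz}, {self.high_hz})"
            )
        if not self.high_hz < fs / 2:
            raise ValueError(
                f"high corner {self.high_hz} Hz must be below Nyquist {fs / 2} Hz"
            )
        if self.order < 2 or self.order % 2 != 0:
            raise ValueError(f"filter order must be even and >= 2, got {self.order}")
        if self.mode not in ("causal", "zero-phase"):
            raise ValueError(f"mode must be 'causal' or 'zero-phase', got {self.mode!r}")

    def sos(self, fs: float) -> np.ndarray:
        """Second-order-section coefficients for this band at rate ``fs``."""
        self.validate(fs)
        return sps.butter(
            self.order, [self.low_hz, self.high_hz], btype="bandpass", fs=fs, output="sos"
        )


def _min_length(spec: FilterSpec, sos: np.ndarray) -> int:
    if spec.mode == "zero-phase":
        # sosfiltfilt pads by 3 * (2 * n_sections + 1) samples on each side
        return 3 * (2 * sos.shape[0] + 1) + 1
    return 3 * spec.order + 1


def bandpass(record: AccelerationRecord, spec: FilterSpec | None = None) -> AccelerationRecord:
    """Band-pass filter an acceleration record.

    Applies the Butterworth band-pass of ``spec`` (default 2–20 Hz, order 4)
    either causally or zero-phase.  Output has the same length, rate and
    start time as the input.
    """
    if spec is None:
        spec = FilterSpec()
    sos = spec.sos(record.fs)
    n_min = _min_length(spec, sos)
    if len(record) < n_min:
        raise ValueError(
            f"record too short to filter: {len(record)} samples, "
            f"need at least {n_min} for a stable order-{spec.order} "
            f"{spec.mode} band-pass"
        )
    if spec.mode == "zero-phase":
        out = sps.sosfiltfilt(sos, record.samples)
    else:
        out = sps.sosfilt(sos, record.samples)
    return AccelerationRecord(out, fs=record.fs, t0=record.t0)


def moving_integral(record: AccelerationRecord, window_s: float = 0.1) -> np.ndarray:
    """Trailing-window time integral of acceleration (units m/s).

    Value ``i`` is the trapezoidal integral of the signal over the window
    ending at sample ``i``.  Leading samples, where a full window is not
    yet available, integrate over the samples seen so far (shrinking
    window, no padding).  Output length equals input length.
    """
    if window_s <= 0:
        raise ValueError(f"integration window must be positive, got {window_s}")
    m = int(round(window_s * record.fs))
    if m < 1:
        raise ValueError(
            f"window {window_s} s spans less than one sample at fs={record.fs}"
        )
    x = record.samples
    if x.size == 0:
        return np.zeros(0)
    ct = cumulative_trapezoid(x, dx=1.0 / record.fs, initial=0.0)
    lo = np.clip(np.arange(x.size) - m, 0, None)
    return ct - ct[lo]


def read_acceleration_csv(path, fs: float | None = None) -> AccelerationRecord:
    """Read a two-column ``time_s, acc_mps2`` CSV into a record.

    The sampling rate is inferred from the median timestep; if ``fs`` is
    given it is validated against the inferred rate to within 1%.
    """
    df = pd.read_csv(path)
    required = {"time_s", "acc_mps2"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"CSV {path} must have columns {sorted(required)}, got {list(df.columns)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"CSV {path} needs at least 2 samples to infer a rate")
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise ValueError(f"CSV {path} has non-increasing timestamps")
    fs_inferred = 1.0 / dt
    if fs is not None and abs(fs_inferred - fs) > 0.01 * fs:
        raise ValueError(
            f"declared fs={fs} differs from inferred {fs_inferred:.3f} by more than 1%"
        )
    return AccelerationRecord(
        df["acc_mps2"].to_numpy(dtype=float), fs=fs or fs_inferred, t0=float(t[0])
    )


def write_acceleration_csv(record: AccelerationRecord, path) -> None:
    """Write a record as a ``time_s, acc_mps2`` CSV."""
    pd.DataFrame({"time_s": record.times, "acc_mps2": record.samples}).to_csv(
        path, index=False
    )
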