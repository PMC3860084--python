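"""The 16-feature description of a segmented activity epoch.

Eight time-domain features (extrema values and timings, their temporal
distance, zero-crossing count, peak-to-peak and valley-to-valley
distances), four derivative/integral features (extrema of the time
derivative and of the 100 ms moving integral), and four frequency-domain
features (extrema of the instantaneous mean frequency, in linear and
logarithmic scale).

Instantaneous mean frequency (MNF) is the power-weighted first moment of
a short-time spectrum, computed over the 2-20 Hz analysis band with a
0.3 s Hann window at 50% hop.  The logarithmic MNF features use the
natural log with the MNF floored at 0.1 Hz; both the estimator windowing
and the log base are configurable, as the literature uses several
conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .signal import AccelerationRecord, moving_integral
from .segmentation import ActivityEpoch

logger = logging.getLogger("gaitclass")

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "FeatureVector",
    "extract_features",
    "mean_frequency_track",
    "count_zero_crossings",
]

#: Canonical feature order, used by feature CSVs and matrix conversion.
FEATURE_NAMES = [
    "t_max_rel", "v_max", "t_min_rel", "v_min", "dt_max_min", "n_zc",
    "dt_peaks", "dt_valleys", "dmax", "dmin", "imax", "imin",
    "mnf_min", "mnf_max", "mnf_min_log", "mnf_max_log",
]


@dataclass
class FeatureConfig:
    """Tunables of the feature extractor (defaults match the pipeline)."""

    stft_window_s: float = 0.3
    stft_hop_s: float = 0.15
    band_low_hz: float = 2.0
    band_high_hz: float = 20.0
    mnf_floor_hz: float = 0.1
    integral_window_s: float = 0.1


@dataclass
class FeatureVector:
    """The 16 per-epoch features, in canonical order.

    Timings are relative to epoch start (s); amplitudes in m/s^2,
    derivative extrema in m/s^3, integral extrema in m/s, MNF in Hz.
    """

    t_max_rel: float
    v_max: float
    t_min_rel: float
    v_min: float
    dt_max_min: float
    n_zc: float
    dt_peaks: float
    dt_valleys: float
    dmax: float
    dmin: float
    imax: float
    imin: float
    mnf_min: float
    mnf_max: float
    mnf_min_log: float
    mnf_max_log: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, a) -> "FeatureVector":
        a = np.asarray(a, dtype=float).ravel()
        if a.size != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {a.size}")
        return cls(**dict(zip(FEATURE_NAMES, a)))


def count_zero_crossings(x: np.ndarray) -> int:
    """Strict sign changes between consecutive samples.

    Exact zeros take the sign of the preceding non-zero sample, so a
    touch of zero without a sign flip does not count.
    """
    s = np.sign(np.asarray(x, dtype=float))
    nz = np.flatnonzero(s)
    if nz.size < 2:
        return 0
    sv = s[nz]
    return int(np.sum(sv[1:] * sv[:-1] < 0))


def mean_frequency_track(epoch, fs: float | None = None,
                         stft_window_s: float = 0.3, stft_hop_s: float = 0.15,
                         band: tuple = (2.0, 20.0)) -> np.ndarray:
    """Instantaneous mean frequency of an epoch, one value per STFT hop.

    MNF(t) = sum(f * P(f, t)) / sum(P(f, t)) over the analysis band of a
    Hann-windowed short-time power spectrum.  Frames with no power in the
    band carry the previous frame's value forward (the first frames carry
    the first defined value backward).
    """
    if isinstance(epoch, ActivityEpoch):
        if fs is None:
            raise ValueError("fs is required when passing an ActivityEpoch")
        x = epoch.samples
    elif isinstance(epoch, AccelerationRecord):
        x, fs = epoch.samples, epoch.fs
    else:
        x = np.asarray(epoch, dtype=float)
        if fs is None:
            raise ValueError("fs is required when passing a bare array")
    if stft_window_s < 0.1:
        raise ValueError(f"STFT window must be at least 0.1 s, got {stft_window_s}")
    n = x.size
    win = int(round(stft_window_s * fs))
    hop = max(1, int(round(stft_hop_s * fs)))
    if win > n:
        win = n  # single frame covering the whole (short) epoch
    w = np.hanning(win)
    freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"analysis band {band} contains no FFT bin for a {win}-sample frame")
    fb = freqs[mask]
    starts = range(0, n - win + 1, hop)
    vals: list = []
    for s0 in starts:
        frame = x[s0:s0 + win] * w
        p = np.abs(np.fft.rfft(frame))[mask] ** 2
        tot = p.sum()
        if tot <= 1e-300:
            vals.append(np.nan)
            logger.debug("all-zero STFT frame at sample %d; carrying MNF forward", s0)
        else:
            vals.append(float((fb * p).sum() / tot))
    vals = np.asarray(vals, dtype=float)
    if np.isnan(vals).all():
        raise ValueError("epoch has no spectral power in the analysis band")
    # forward fill, then backward fill the leading gap
    defined = np.flatnonzero(~np.isnan(vals))
    for i in range(vals.size):
        if np.isnan(vals[i]):
            prev = defined[defined < i]
            vals[i] = vals[prev[-1]] if prev.size else vals[defined[0]]
    return vals


def extract_features(epoch, fs: float | None = None,
                     config: FeatureConfig | None = None) -> FeatureVector:
    """Extract the 16-feature vector from one activity epoch.

    Accepts an :class:`ActivityEpoch` (with ``fs``) or a bare sample
    array.  Degenerate sub-features follow documented sentinel rules:
    with fewer than two detectable peaks (valleys), the peak (valley)
    distance falls back to the epoch duration.
    """
    config = config or FeatureConfig()
    if isinstance(epoch, ActivityEpoch):
        if fs is None:
            raise ValueError("fs is required when passing an ActivityEpoch")
        x = epoch.samples
    else:
        x = np.asarray(epoch, dtype=float).ravel()
    if fs is None or fs <= 0:
        raise ValueError("a positive sampling rate is required")
    if x.size < 0.1 * fs:
        raise ValueError(f"epoch too short: {x.size} samples, need >= {0.1 * fs:.0f}")
    if not np.any(x):
        raise ValueError("all-zero epoch has no extractable features")

    dur = x.size / fs
    imax_i = int(np.argmax(x))
    imin_i = int(np.argmin(x))
    t_max_rel = imax_i / fs
    t_min_rel = imin_i / fs
    v_max = float(x[imax_i])
    v_min = float(x[imin_i])

    dt_peaks = _pair_distance(x, fs, dur, valleys=False)
    dt_valleys = _pair_distance(x, fs, dur, valleys=True)

    d = np.gradient(x, 1.0 / fs)
    integ = moving_integral(AccelerationRecord(x, fs=fs), config.integral_window_s)

    mnf = mean_frequency_track(
        x, fs, config.stft_window_s, config.stft_hop_s,
        (config.band_low_hz, config.band_high_hz),
    )
    mnf_min = float(mnf.min())
    mnf_max = float(mnf.max())
    floor = config.mnf_floor_hz

    return FeatureVector(
        t_max_rel=t_max_rel,
        v_max=v_max,
        t_min_rel=t_min_rel,
        v_min=v_min,
        dt_max_min=abs(t_max_rel - t_min_rel),
        n_zc=float(count_zero_crossings(x)),
        dt_peaks=dt_peaks,
        dt_valleys=dt_valleys,
        dmax=float(d.max()),
        dmin=float(d.min()),
        imax=float(integ.max()),
        imin=float(integ.min()),
        mnf_min=mnf_min,
        mnf_max=mnf_max,
        mnf_min_log=float(np.log(max(mnf_min, floor))),
        mnf_max_log=float(np.log(max(mnf_max, floor))),
    )


def _pair_distance(x: np.ndarray, fs: float, dur: float, valleys: bool) -> float:
    """Time between the two most prominent local maxima (or minima).

    The two candidates are ranked by prominence, then taken in temporal
    order; with fewer than two, the epoch duration is the sentinel.
    """
    sig = -x if valleys else x
    locs, props = find_peaks(sig, prominence=0.0)
    if locs.size < 2:
        logger.debug("fewer than 2 %s; falling back to epoch duration",
                      "valleys" if valleys else "peaks")
        return dur
    top2 = locs[np.argsort(props["prominences"])[-2:]]
    return float(abs(int(top2.max()) - int(top2.min())) / fs)


def features_matrix(vectors) -> np.ndarray:
    """Stack feature vectors into an (n, 16) matrix in canonical order."""
    return np.vstack([v.to_array() for v in vectors])


__all__.append("features_matrix")
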