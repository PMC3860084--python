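"""On-line activity-epoch segmentation by integration and threshold.

An epoch (one walking stride, or one stair-climbing / stair-descending
step) is detected when the absolute value of the 100 ms moving integral
of the band-passed acceleration exceeds an adaptive threshold outside a
refractory period.  After each detected epoch both parameters adapt:

* threshold <- 0.75 x the epoch's peak moving integral (first guess 0.35 m/s),
* refractory <- 0.5 x the epoch's duration (first guess 600 ms).

The refractory period is measured from epoch onset by default, so a new
epoch cannot start too soon after the previous one regardless of how the
previous epoch terminated.  Because a trailing integral reports activity
that happened up to a window earlier, the reported onset is backdated by
the integration window (latency compensation; the samples are taken
from a lookback buffer so epoch bounds and content stay consistent).  An epoch closes when the integral stays below
``offset_frac`` (default 0.5) of the current threshold for
``offset_hold`` seconds (the offset is placed at the start of that
sub-threshold run), or when ``max_epoch`` is reached.  The hysteresis
fraction and the 200 ms hold are both needed because the moving integral
of a signed oscillation dips toward zero twice per cycle: closing at the
full onset threshold on a 50 ms lull would truncate epochs mid-burst.

The detector is streamable: :class:`EpochDetector` carries all adapted
state across ``process`` calls, so feeding a record in chunks yields the
same epochs as one call.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .signal import AccelerationRecord

logger = logging.getLogger("gaitclass")

__all__ = [
    "SegmenterConfig",
    "ActivityEpoch",
    "SegmentationResult",
    "EpochDetector",
    "detect_epochs",
]


@dataclass
class SegmenterConfig:
    """Adaptive integration-and-threshold segmenter parameters.

    All defaults are the published operating point of the method:
    threshold first guess 0.35 m/s adapted at 0.75x the previous epoch's
    peak 100 ms integral; refractory first guess 600 ms adapted at 0.5x
    the previous epoch duration.  ``threshold_floor`` keeps the adapted
    threshold from collapsing after a near-silent epoch; ``min_epoch`` /
    ``max_epoch`` bound plausible stride/step durations.
    """

    threshold0: float = 0.35
    threshold_adapt: float = 0.75
    refractory0: float = 0.6
    refractory_adapt: float = 0.5
    integral_window: float = 0.1
    min_epoch: float = 0.1
    max_epoch: float = 2.5
    offset_hold: float = 0.2
    offset_frac: float = 0.5
    threshold_floor: float = 0.05
    refractory_anchor: str = "onset"  # or "offset"

    def validate(self) -> None:
        for name in ("threshold0", "refractory0", "integral_window", "min_epoch",
                     "max_epoch", "offset_hold", "threshold_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0 < self.offset_frac <= 1:
            raise ValueError(f"offset_frac must be in (0, 1], got {self.offset_frac}")
        if not 0 < self.threshold_adapt < 1:
            raise ValueError(f"threshold_adapt must be in (0, 1), got {self.threshold_adapt}")
        if not 0 < self.refractory_adapt < 1:
            raise ValueError(f"refractory_adapt must be in (0, 1), got {self.refractory_adapt}")
        if self.min_epoch >= self.max_epoch:
            raise ValueError("min_epoch must be below max_epoch")
        if self.refractory_anchor not in ("onset", "offset"):
            raise ValueError(f"refractory_anchor must be 'onset' or 'offset', got {self.refractory_anchor!r}")


@dataclass
class ActivityEpoch:
    """One segmented activity epoch.

    ``samples`` holds the band-passed acceleration between the bounds;
    ``max_integral`` is the peak absolute 100 ms moving integral observed
    inside the epoch (the quantity the next threshold adapts to).
    """

    start_s: float
    end_s: float
    samples: np.ndarray
    max_integral: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.end_s > self.start_s:
            raise ValueError("epoch end must be after start")
        if self.max_integral < 0:
            raise ValueError("max_integral must be non-negative")

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SegmentationResult:
    epochs: list
    threshold: float
    refractory: float


class EpochDetector:
    """Stateful streaming epoch detector.

    Call :meth:`process` with successive chunks of band-passed samples and
    :meth:`finalize` once at end of stream.  Adapted threshold/refractory
    and any partially open epoch carry across calls, so chunk boundaries
    do not affect the result.
    """

    def __init__(self, config: SegmenterConfig | None = None, fs: float = 100.0,
                 t0: float = 0.0):
        self.config = config or SegmenterConfig()
        self.config.validate()
        self.fs = fs
        self.threshold = self.config.threshold0
        self.refractory = self.config.refractory0
        self._m = int(round(self.config.integral_window * fs))
        if self._m < 1:
            raise ValueError("integral window spans less than one sample")
        self._hold = max(1, int(round(self.config.offset_hold * fs)))
        self._n = 0                  # absolute sample counter
        self._t0 = t0
        self._ct = 0.0               # running cumulative trapezoid
        self._prev_x: float | None = None
        self._ct_hist = deque([0.0], maxlen=self._m + 1)
        # lookback for onset latency compensation: the threshold crossing
        # can lag the physical attack by the integral build-up plus filter
        # delay; the onset refinement in _close trims what proves quiet
        self._lookback = deque(maxlen=int(2.5 * self._m))
        self._free_from = 0          # first sample index not claimed by an epoch
        self._anchor = -math.inf     # refractory reference time
        self._in_epoch = False
        self._buf: list = []
        self._start_t = 0.0
        self._max_int = 0.0
        self._below = 0

    # -- internal -----------------------------------------------------------

    def _close(self, end_t: float, trim: int, epochs: list) -> None:
        cfg = self.config
        buf = self._buf[: len(self._buf) - trim] if trim else self._buf
        tail = self._buf[len(self._buf) - trim:] if trim else []
        self._in_epoch = False
        self._below = 0
        # samples after the epoch end become lookback for the next onset
        self._free_from = self._n - trim
        self._lookback.clear()
        self._lookback.extend(tail)
        start_t = self._start_t
        if buf:
            # refine the onset within the backdated lookback: the epoch
            # starts where the rectified signal first reaches 35% of its
            # peak, which locates the attack instead of the threshold
            # crossing (the crossing lags behind by the integral build-up);
            # the fraction sits above zero-phase pre-ringing levels
            ab = np.abs(np.asarray(buf))
            k0 = int(np.argmax(ab >= 0.35 * ab.max()))
            buf = buf[k0:]
            start_t += k0 / self.fs
        dur = end_t - start_t
        if dur < cfg.min_epoch or not buf:
            logger.debug("discarding %.3f s sub-minimum epoch at %.3f s", dur, start_t)
            self._buf = []
            return
        epochs.append(ActivityEpoch(start_t, end_t, np.asarray(buf), self._max_int))
        self.threshold = max(cfg.threshold_floor, cfg.threshold_adapt * self._max_int)
        self.refractory = cfg.refractory_adapt * dur
        if cfg.refractory_anchor == "offset":
            self._anchor = end_t
        self._buf = []

    # -- public -------------------------------------------------------------

    def process(self, samples: np.ndarray) -> list:
        """Feed a chunk of band-passed samples; return epochs completed in it."""
        samples = np.asarray(samples, dtype=float).ravel()
        cfg = self.config
        dt = 1.0 / self.fs
        epochs: list = []
        for x in samples:
            if self._prev_x is not None:
                self._ct += 0.5 * (self._prev_x + x) * dt
            self._prev_x = x
            self._ct_hist.append(self._ct)
            a = abs(self._ct - self._ct_hist[0])
            t = self._t0 + self._n * dt
            self._n += 1
            if not self._in_epoch:
                if a > self.threshold and t >= self._anchor + self.refractory:
                    # backdate the onset by up to half the integral window,
                    # without reclaiming samples of the previous epoch
                    back = list(self._lookback)
                    avail = (self._n - 1) - self._free_from
                    back = back[len(back) - min(len(back), avail):]
                    self._in_epoch = True
                    self._start_t = t - len(back) * dt
                    self._buf = back + [x]
                    self._max_int = a
                    self._below = 0
                    if cfg.refractory_anchor == "onset":
                        self._anchor = self._start_t
                else:
                    self._lookback.append(x)
            else:
                self._buf.append(x)
                self._max_int = max(self._max_int, a)
                if a < self.threshold * cfg.offset_frac:
                    self._below += 1
                else:
                    self._below = 0
                if self._below >= self._hold:
                    # offset at the first sub-threshold sample
                    end_t = t - (self._below - 1) * dt
                    self._close(end_t, trim=self._below, epochs=epochs)
                elif (t + dt) - self._start_t >= cfg.max_epoch:
                    self._close(t + dt, trim=0, epochs=epochs)
        return epochs

    def finalize(self) -> list:
        """Close any epoch still open at end of stream."""
        epochs: list = []
        if self._in_epoch:
            end_t = self._t0 + self._n / self.fs
            self._close(end_t, trim=0, epochs=epochs)
        return epochs


def detect_epochs(record: AccelerationRecord,
                  config: SegmenterConfig | None = None) -> SegmentationResult:
    """Segment a band-passed record into activity epochs.

    Returns the time-ordered epochs plus the final adapted threshold and
    refractory period.  An empty record yields an empty result.  Input
    that does not look band-passed (large DC offset relative to its
    spread) triggers a warning but is still processed.
    """
    config = config or SegmenterConfig()
    config.validate()
    x = record.samples
    if x.size:
        sd = float(np.std(x))
        if abs(float(np.mean(x))) > 0.5 * max(sd, 1e-12):
            logger.warning(
                "input has a large DC offset (mean %.3g, sd %.3g); "
                "expected a band-passed signal", float(np.mean(x)), sd,
            )
    det = EpochDetector(config, fs=record.fs, t0=record.t0)
    epochs = det.process(x)
    epochs += det.finalize()
    return SegmentationResult(epochs, det.threshold, det.refractory)
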