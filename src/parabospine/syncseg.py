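"""Time synchronization and gravity-phase segmentation.

Device streams (distance array, EMG transmitters) carry their own clocks;
their accelerometer channels mirror the aircraft's load factor, so the lag
maximizing the normalized cross-correlation against the operator gravity
trace recovers each device's clock offset.  The trace itself is segmented
by thresholding into micro / earth / hyper plateau runs, which are grouped
into parabolas by the hyper–micro–hyper motif; fixed-duration analysis
windows are then cut centrally from each segment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import signal as sps

from .core import (
    GravitySegment,
    GravityTrace,
    SegmentationConfig,
    UnsynchronizableStream,
)

logger = logging.getLogger(__name__)

__all__ = [
    "estimate_offset",
    "find_band_runs",
    "segment_gravity",
    "cut_window",
    "window_quantile",
    "BandRun",
]


# ---------------------------------------------------------------------------
# synchronization
# ---------------------------------------------------------------------------


def estimate_offset(
    device_time_s: np.ndarray,
    device_accel: np.ndarray,
    reference: GravityTrace,
    resample_hz: float = 10.0,
    corr_floor: float = 0.5,
) -> float:
    """Estimate a device's clock offset against the operator gravity trace.

    Both signals are resampled to ``resample_hz`` on their own supports and
    the lag maximizing the normalized cross-correlation is returned as the
    estimated offset (device clock minus reference clock): subtracting it
    from the device timestamps aligns the streams.  Resolution is one
    resample interval.

    Raises
    ------
    UnsynchronizableStream
        if the peak normalized correlation falls below ``corr_floor``.
    """
    device_time_s = np.asarray(device_time_s, dtype=float)
    device_accel = np.asarray(device_accel, dtype=float)
    if device_time_s.size < 2:
        raise ValueError("device stream too short to synchronize")

    dt = 1.0 / resample_hz
    td = np.arange(device_time_s[0], device_time_s[-1], dt)
    tr = np.arange(reference.time_s[0], reference.time_s[-1], dt)
    xd = np.interp(td, device_time_s, device_accel)
    xr = np.interp(tr, reference.time_s, reference.gz)

    xd = xd - xd.mean()
    xr = xr - xr.mean()
    denom = np.linalg.norm(xd) * np.linalg.norm(xr)
    if denom == 0:
        raise UnsynchronizableStream("flat signal; cannot correlate")

    corr = sps.correlate(xd, xr, mode="full")
    lags = sps.correlation_lags(xd.size, xr.size, mode="full")
    # full-energy normalization penalizes short truncated overlaps
    k = int(np.argmax(corr))
    peak = corr[k] / denom
    if peak < corr_floor:
        raise UnsynchronizableStream(
            f"peak normalized correlation {peak:.3f} below floor {corr_floor}"
        )
    lag_samples = lags[k]
    # device sample i matches reference sample i - lag: offset in seconds
    return float((td[0] - tr[0]) + lag_samples * dt)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandRun:
    """A maximal run of samples within one threshold band."""

    condition: str
    t_start: float
    t_end: float
    i_start: int
    i_end: int  # inclusive

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _classify(gz: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Band label per sample: micro/earth/hyper or '' outside every band."""
    lab = np.full(gz.shape, "", dtype="U5")
    lab[np.abs(gz) <= cfg.micro_max] = "micro"
    lab[(gz >= cfg.earth_band[0]) & (gz <= cfg.earth_band[1])] = "earth"
    lab[gz >= cfg.hyper_min] = "hyper"
    return lab


def find_band_runs(trace: GravityTrace, cfg: SegmentationConfig | None = None) -> list[BandRun]:
    """Maximal same-band runs of at least ``min_duration_s``.

    The trace is smoothed with a short centered moving average
    (``smooth_s``) before thresholding so that single noisy samples do not
    split a plateau; same-band runs separated by gaps shorter than
    ``merge_gap_s`` are merged for the same reason.  Ramps fall outside
    every band (and are far shorter than ``min_duration_s`` anyway), so the
    surviving runs are exactly the gravity plateaus.
    """
    cfg = cfg or SegmentationConfig()
    gz = trace.gz
    n_smooth = int(round(cfg.smooth_s * trace.sample_rate_hz))
    if n_smooth > 1:
        gz = ndi.uniform_filter1d(gz, size=n_smooth, mode="nearest")
    lab = _classify(gz, cfg)

    raw: list[BandRun] = []
    n = lab.size
    i = 0
    while i < n:
        if lab[i] == "":
            i += 1
            continue
        j = i
        while j + 1 < n and lab[j + 1] == lab[i]:
            j += 1
        raw.append(
            BandRun(
                condition=str(lab[i]),
                t_start=float(trace.time_s[i]),
                t_end=float(trace.time_s[j]),
                i_start=i,
                i_end=j,
            )
        )
        i = j + 1

    merged: list[BandRun] = []
    for run in raw:
        if (
            merged
            and merged[-1].condition == run.condition
            and run.t_start - merged[-1].t_end <= cfg.merge_gap_s
        ):
            prev = merged.pop()
            run = BandRun(run.condition, prev.t_start, run.t_end, prev.i_start, run.i_end)
        merged.append(run)
    return [r for r in merged if r.duration >= cfg.min_duration_s]


def segment_gravity(
    trace: GravityTrace, cfg: SegmentationConfig | None = None
) -> list[GravitySegment]:
    """Threshold-based segmentation of a gravity trace into labeled phases.

    Plateau runs are grouped into parabolas by the hyper–micro–hyper motif:
    each micro run flanked by hyper runs forms a parabola, and the level
    -flight (earth) run immediately preceding its entry hyper phase is
    attached as that parabola's earth segment.  Runs not part of any motif
    are dropped.  A trace with no complete motif yields zero parabolas with
    a warning.
    """
    cfg = cfg or SegmentationConfig()
    if trace.time_s.size > 1 and np.any(np.diff(trace.time_s) <= 0):
        raise ValueError("trace timestamps must be strictly increasing")
    runs = find_band_runs(trace, cfg)
    segments: list[GravitySegment] = []
    parabola = 0
    for k in range(1, len(runs) - 1):
        prev_run, run, next_run = runs[k - 1], runs[k], runs[k + 1]
        if run.condition != "micro":
            continue
        if prev_run.condition != "hyper" or next_run.condition != "hyper":
            continue
        parabola += 1
        if k >= 2 and runs[k - 2].condition == "earth":
            e = runs[k - 2]
            segments.append(
                GravitySegment("earth", parabola, "pre_earth", e.t_start, e.t_end)
            )
        segments.append(
            GravitySegment("hyper", parabola, "hyper_entry", prev_run.t_start, prev_run.t_end)
        )
        segments.append(GravitySegment("micro", parabola, "micro", run.t_start, run.t_end))
        segments.append(
            GravitySegment("hyper", parabola, "hyper_exit", next_run.t_start, next_run.t_end)
        )
    if parabola == 0:
        warnings.warn("no complete hyper-micro-hyper motif found; zero parabolas")
    return segments


def cut_window(segment: GravitySegment, duration: float) -> GravitySegment | None:
    """Cut the central sub-interval of exactly ``duration`` seconds.

    Returns ``None`` (segment dropped, reason logged) when the segment is
    shorter than the requested window.
    """
    if duration <= 0:
        raise ValueError("window duration must be positive")
    if segment.duration < duration:
        logger.info(
            "dropping %s segment of parabola %d: %.2f s < window %.2f s",
            segment.condition,
            segment.parabola_index,
            segment.duration,
            duration,
        )
        return None
    pad = (segment.duration - duration) / 2.0
    return GravitySegment(
        condition=segment.condition,
        parabola_index=segment.parabola_index,
        phase_position=segment.phase_position,
        t_start=segment.t_start + pad,
        t_end=segment.t_end - pad,
    )


def window_quantile(durations_s, q: float) -> float:
    """Linear-interpolation quantile of segment durations (q=0 → minimum).

    Used to derive cohort-level window lengths: the distance window is the
    0.25 quantile of segment durations, the EMG window the minimum.
    """
    d = np.asarray(list(durations_s), dtype=float)
    if d.size == 0:
        raise ValueError("durations list must be non-empty")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    return float(np.quantile(d, q))
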