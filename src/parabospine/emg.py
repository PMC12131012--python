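"""Surface-EMG processing chain for the five paraspinal transmitter sites.

Raw channels are band-passed (second-order Butterworth, 10–500 Hz, applied
forward–backward so segment windows stay aligned) and rectified; each
gravity segment is cut to the common analysis window (14.86 s, the shortest
recorded segment) and summarized by its root-mean-square amplitude.
Per-segment RMS values are screened for 3×IQR outliers, checked for a
parabola-order (novelty) effect with a robust trimmed-means repeated-
measures test — a significant order effect at any site removes the first
parabola for all EMG sites — and normalized per participant and site to the
grand mean over retained segments (or to the earth-g mean for the
association analysis).  ECG crosstalk present in the recordings is not
removed; it is part of the signal the RMS summarizes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import EmgChannel, GravitySegment
from .stats import StatTestResult, rm_anova_trimmed

logger = logging.getLogger(__name__)

__all__ = [
    "bandpass_rectify",
    "segment_rms",
    "iqr_outliers",
    "order_effect_check",
    "normalize_emg",
]


def bandpass_rectify(
    channel: EmgChannel, lo_hz: float = 10.0, hi_hz: float = 500.0, order: int = 2
) -> EmgChannel:
    """Zero-phase Butterworth band-pass followed by full-wave rectification.

    The filter is applied forward–backward (``sosfiltfilt``), which doubles
    the effective order but introduces no lag — segment-level RMS is phase-
    insensitive and lag would misalign the analysis windows.  Cutoffs at or
    above Nyquist are rejected.
    """
    nyquist = channel.fs_hz / 2.0
    if not 0 < lo_hz < hi_hz:
        raise ValueError("cutoffs must satisfy 0 < lo < hi")
    if hi_hz >= nyquist:
        raise ValueError(
            f"high cutoff {hi_hz} Hz must be below Nyquist ({nyquist} Hz); "
            "lower the cutoff or resample"
        )
    sos = sps.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=channel.fs_hz, output="sos")
    filtered = np.abs(sps.sosfiltfilt(sos, channel.emg))
    out = EmgChannel(
        site=channel.site,
        fs_hz=channel.fs_hz,
        start_time_s=channel.start_time_s,
        emg=filtered,
        accel_fs_hz=channel.accel_fs_hz,
        accel_start_time_s=channel.accel_start_time_s,
        accel_gz=channel.accel_gz,
        clock_offset_s=channel.clock_offset_s,
    )
    return out


def segment_rms(channel: EmgChannel, window: GravitySegment) -> float | None:
    """Root-mean-square of the processed signal inside an analysis window.

    Returns ``None`` (segment missing) when the window falls outside the
    recording.
    """
    t = channel.time_s
    m = (t >= window.t_start) & (t <= window.t_end)
    if not np.any(m):
        logger.info(
            "window [%.2f, %.2f] outside EMG recording for %s",
            window.t_start, window.t_end, channel.site,
        )
        return None
    x = channel.emg[m]
    return float(np.sqrt(np.mean(x**2)))


def iqr_outliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Flag values beyond ``k`` × IQR outside the first/third quartile.

    With fewer than 4 values the quartiles are meaningless; nothing is
    flagged and a warning is issued.  A constant list has IQR 0 and flags
    nothing (the bounds collapse onto the constant itself).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        warnings.warn("fewer than 4 values; outlier detection skipped")
        return np.zeros(x.shape, dtype=bool)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return (x < q1 - k * iqr) | (x > q3 + k * iqr)


def order_effect_check(
    rms_by_parabola: pd.DataFrame,
    trim: float = 0.2,
    alpha: float = 0.05,
    min_participants: int = 5,
) -> tuple[dict[str, StatTestResult], bool]:
    """Screen every site for a parabola-order effect on segment RMS.

    ``rms_by_parabola`` holds one row per participant, site and parabola
    with a ``value`` column (the parabola's mean RMS across conditions).
    Each participant is reduced to {first, intermediate-mean, last} cells
    and a trimmed-means repeated-measures test is run per site.  If any
    site is significant at ``alpha`` the first parabola is excluded for all
    EMG sites — a cohort-level rule, since a novelty effect is a property
    of the flight, not of one electrode.  With fewer than
    ``min_participants`` complete participants the screen is skipped (no
    exclusion) with a warning.
    """
    results: dict[str, StatTestResult] = {}
    exclude = False
    for site, grp in rms_by_parabola.groupby("site"):
        cells = _first_mid_last(grp)
        if len(cells) < min_participants:
            warnings.warn(
                f"site {site}: only {len(cells)} complete participants; "
                "order-effect screen skipped"
            )
            continue
        res = rm_anova_trimmed(cells.to_numpy(), trim=trim, alpha=alpha)
        results[site] = res
        if res.p_raw < alpha:
            exclude = True
    return results, exclude


def _first_mid_last(df: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for pid, grp in df.groupby("participant"):
        grp = grp.sort_values("parabola")
        vals = grp["value"].to_numpy()
        if vals.size < 3:
            logger.info("participant %s dropped from order screen (%d parabolas)", pid, vals.size)
            continue
        rows[pid] = [vals[0], vals[1:-1].mean(), vals[-1]]
    return pd.DataFrame.from_dict(rows, orient="index", columns=["first", "intermediate", "last"])


def normalize_emg(
    summaries: pd.DataFrame, mode: str = "grand_mean"
) -> pd.DataFrame:
    """Normalize retained per-segment RMS per participant and site, in percent.

    ``grand_mean`` divides by the participant-site mean over all retained
    segments, so 100% is the participant's average activity at that site
    regardless of condition (and the retained-segment mean of the output is
    exactly 100%).  ``earth_mean`` divides by the mean over retained earth-g
    segments (association analyses).  Participant-sites whose segments are
    all excluded are dropped with a log entry.

    Expects columns ``participant, site, condition, rms, excluded`` and adds
    ``rms_norm``; excluded rows get NaN.
    """
    if mode not in ("grand_mean", "earth_mean"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    out = summaries.copy()
    out["rms_norm"] = np.nan
    for (pid, site), grp in out.groupby(["participant", "site"]):
        retained = grp.loc[~grp["excluded"]]
        if retained.empty:
            logger.info("participant %s site %s: all segments excluded; dropped", pid, site)
            continue
        if mode == "grand_mean":
            ref = retained["rms"].mean()
        else:
            earth = retained.loc[retained["condition"] == "earth", "rms"]
            if earth.empty:
                logger.info("participant %s site %s: no earth segments; dropped", pid, site)
                continue
            ref = earth.mean()
        if not ref > 0:
            raise ValueError("normalization reference must be positive")
        out.loc[retained.index, "rms_norm"] = 100.0 * retained["rms"] / ref
    return out
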