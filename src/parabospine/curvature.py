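"""Spinal-curvature statistics from the windowed laser distance array.

Two proxies are computed per analysis window from the 15-sensor
plate-to-skin distance profile:

* the **enclosed area** between back and backplate — the trapezoidal
  integral of distance over sensor position (mm²), which decreases when the
  spine flattens toward the plate;
* **inter-sensor angles** — the planar angle formed at each sensor by its
  two neighbours, with 180° meaning locally straight, <180° local lordosis
  (profile bulging away from the plate) and >180° local kyphosis.

Cleaning rules applied before either statistic: the topmost sensor (C7) is
always excluded; a sensor masked by a bra elastic is repaired as the mean of
its vertical neighbours; sensors missing for a whole segment are clamped to
their recording limits (16 mm floor at sensors 8–10, 120 mm ceiling at
sensor 2); sensors below the inter-SIPS line are excluded using the
participant's C7–SIPS trunk length.  Areas are normalized per participant
to the grand mean over all windows (condition comparisons) or to the earth-g
mean (association analyses).
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .core import BackplateGeometry, DistanceProfile, DistanceStream, GravitySegment
from .stats import StatTestResult, rm_anova_gg

__all__ = [
    "window_mean_profile",
    "repair_bra_sensor",
    "clamp_missing_segment",
    "exclude_below_sips",
    "enclosed_area",
    "intersensor_angles",
    "normalize_area",
    "parabola_order_check",
]

#: Sensors whose recording floor (16 mm) replaces whole-segment dropouts.
CLAMP_MIN_SENSORS = (8, 9, 10)
#: Sensor whose recording ceiling (120 mm) replaces whole-segment dropouts.
CLAMP_MAX_SENSOR = 2


def window_mean_profile(
    stream: DistanceStream,
    window: GravitySegment,
    participant: str = "",
    exclude_topmost: bool = True,
) -> DistanceProfile:
    """Mean per-sensor distance over the samples inside an analysis window.

    The stream must already be on the reference clock.  Sensors with no
    usable in-window sample are marked missing (NaN).  The topmost sensor is
    excluded unconditionally by default (intermittent data loss makes it
    unusable as a rule, not per window).
    """
    m = (stream.time_s >= window.t_start) & (stream.time_s <= window.t_end)
    if not np.any(m):
        raise ValueError(
            f"window [{window.t_start:.2f}, {window.t_end:.2f}] contains no samples"
        )
    vals = stream.values_mm[m]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        means = np.nanmean(vals, axis=0)
    included = np.ones(15, dtype=bool)
    if exclude_topmost:
        included[0] = False
    return DistanceProfile(
        participant=participant,
        condition=window.condition,
        parabola_index=window.parabola_index,
        phase_position=window.phase_position,
        values_mm=means,
        included=included,
    )


def repair_bra_sensor(profile: DistanceProfile, idx: int) -> DistanceProfile:
    """Replace sensor ``idx`` (1-based) by the mean of its vertical neighbours.

    Used where a bra elastic crosses a sensor's beam.  Both neighbours must
    hold valid values; cascading interpolation is refused.
    """
    if not 1 < idx < 15:
        raise ValueError("can only repair interior sensors (2..14)")
    up, down = profile.values_mm[idx - 2], profile.values_mm[idx]
    if np.isnan(up) or np.isnan(down):
        raise ValueError(f"sensor {idx}: both neighbours must be present for repair")
    values = profile.values_mm.copy()
    values[idx - 1] = (up + down) / 2.0
    return replace(
        profile,
        values_mm=values,
        repaired=profile.repaired | {idx},
        notes=profile.notes + (f"sensor {idx} repaired from neighbours",),
    )


def clamp_missing_segment(
    profile: DistanceProfile, geometry: BackplateGeometry
) -> DistanceProfile:
    """Replace whole-segment dropouts by the sensors' recording limits.

    A posture drifting out of range saturates at a known bound: sensors
    8–10 are clamped to their 16 mm floor, sensor 2 to its 120 mm ceiling.
    Dropouts at other sensors have no principled replacement and stay
    missing (with a warning).
    """
    values = profile.values_mm.copy()
    notes = list(profile.notes)
    for idx in np.flatnonzero(np.isnan(values)) + 1:
        if not profile.included[idx - 1]:
            continue
        if idx in CLAMP_MIN_SENSORS:
            values[idx - 1] = geometry.limits_mm[idx - 1, 0]
            notes.append(f"sensor {idx} clamped to recording floor")
        elif idx == CLAMP_MAX_SENSOR:
            values[idx - 1] = geometry.limits_mm[idx - 1, 1]
            notes.append(f"sensor {idx} clamped to recording ceiling")
        else:
            warnings.warn(f"sensor {idx} missing for whole segment; left missing")
    return replace(profile, values_mm=values, notes=tuple(notes))


def exclude_below_sips(
    profile: DistanceProfile, trunk_length_cm: float, geometry: BackplateGeometry
) -> DistanceProfile:
    """Exclude sensors positioned below the participant's inter-SIPS line.

    Sensor ``i`` sits ``(i - 1) * spacing`` below C7; sensors beyond the
    measured C7–SIPS trunk length are outside the analyzed spinal span.
    """
    spacing_cm = geometry.spacing_mm / 10.0
    if trunk_length_cm < spacing_cm:
        raise ValueError("trunk length shorter than one sensor spacing")
    idx = np.arange(1, 16)
    below = (idx - 1) * spacing_cm > trunk_length_cm
    included = profile.included & ~below
    notes = profile.notes
    if np.any(below & profile.included):
        dropped = ", ".join(str(i) for i in idx[below & profile.included])
        notes = notes + (f"sensors {dropped} below SIPS line excluded",)
    return replace(profile, included=included, notes=notes)


def enclosed_area(profile: DistanceProfile, geometry: BackplateGeometry) -> float:
    """Trapezoidal enclosed area (mm²) between back and backplate.

    Integrates distance over sensor position across consecutive included
    sensors.  Gaps in the included set (after exclusions) split the profile
    into contiguous blocks that are integrated separately and summed, with
    a warning.  Missing values among included sensors are an error — repair
    or clamp first.
    """
    inc = np.flatnonzero(profile.included)
    if inc.size < 2:
        raise ValueError("need at least two included sensors for an area")
    if np.any(np.isnan(profile.values_mm[inc])):
        raise ValueError("missing values among included sensors; repair or clamp first")
    blocks = np.split(inc, np.flatnonzero(np.diff(inc) > 1) + 1)
    if len(blocks) > 1:
        warnings.warn("gap in included sensors; area computed per contiguous block")
    area = 0.0
    for b in blocks:
        d = profile.values_mm[b]
        if d.size >= 2:
            area += float(np.sum((d[:-1] + d[1:]) / 2.0) * geometry.spacing_mm)
    return area


def intersensor_angles(
    profile: DistanceProfile, geometry: BackplateGeometry
) -> dict[int, float]:
    """Signed inter-sensor angle (degrees) at every eligible interior sensor.

    Sensor ``i`` is embedded at plane point ``(d_i, (i - 1) * spacing)`` and
    the raw angle at the middle point is taken via the law of cosines on the
    vectors to its neighbours (always <= 180°).  Sign convention: when the
    middle distance exceeds the chord (mean of the neighbours) the profile
    bulges away from the plate and the raw angle is reported (lordotic,
    <180°); when it falls below the chord the reported angle is
    ``360° - raw`` (kyphotic, >180°); collinear sensors give exactly 180°.

    Angles are undefined (omitted) wherever any of the three sensors is
    excluded or missing.
    """
    angles: dict[int, float] = {}
    v = profile.values_mm
    s = geometry.spacing_mm
    for i in range(2, 15):  # middle sensor, 1-based
        trio = [i - 1, i, i + 1]
        if not all(profile.included[j - 1] for j in trio):
            continue
        d1, d2, d3 = (v[j - 1] for j in trio)
        if np.isnan(d1) or np.isnan(d2) or np.isnan(d3):
            continue
        u = np.array([d1 - d2, -s])
        w = np.array([d3 - d2, s])
        cosang = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
        raw = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        chord = (d1 + d3) / 2.0
        if d2 > chord:
            angles[i] = raw
        elif d2 < chord:
            angles[i] = 360.0 - raw
        else:
            angles[i] = 180.0
    return angles


def normalize_area(
    areas: np.ndarray,
    mode: str = "grand_mean",
    earth_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Express per-window areas as percent of a participant-level reference.

    ``grand_mean`` divides by the participant's mean over all windows (the
    within-participant mean of the result is then exactly 100%);
    ``earth_mean`` divides by the mean over earth-g windows (used for the
    association analysis).
    """
    areas = np.asarray(areas, dtype=float)
    if mode == "grand_mean":
        ref = areas.mean()
    elif mode == "earth_mean":
        if earth_mask is None:
            raise ValueError("earth_mean normalization requires earth_mask")
        earth_mask = np.asarray(earth_mask, dtype=bool)
        if not earth_mask.any():
            raise ValueError("no earth-g windows to normalize against")
        ref = areas[earth_mask].mean()
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if not ref > 0:
        raise ValueError("normalization reference must be positive")
    return 100.0 * areas / ref


def parabola_order_check(
    area_by_parabola: pd.DataFrame, alpha: float = 0.05
) -> tuple[StatTestResult, bool]:
    """Test whether parabola order affects mean-normalized area.

    ``area_by_parabola`` holds one row per participant and parabola with a
    ``value`` column (mean-normalized area averaged across the parabola's
    gravity conditions).  Each participant is reduced to three cells —
    first parabola, mean of intermediates, last — and a Greenhouse–Geisser
    adjusted repeated-measures ANOVA is run over them.  Returns the test
    and whether order effects warrant excluding parabolas (significant at
    ``alpha``).  Participants lacking any cell are dropped with a log entry.
    """
    cells = _first_mid_last(area_by_parabola)
    result = rm_anova_gg(cells.to_numpy())
    return result, result.p_raw < alpha


def _first_mid_last(df: pd.DataFrame) -> pd.DataFrame:
    """Participant x {first, intermediate-mean, last} cells from per-parabola values."""
    rows = {}
    for pid, grp in df.groupby("participant"):
        grp = grp.sort_values("parabola")
        vals = grp["value"].to_numpy()
        if vals.size < 3:
            import logging

            logging.getLogger(__name__).info(
                "participant %s dropped from order check (%d parabolas)", pid, vals.size
            )
            continue
        rows[pid] = [vals[0], vals[1:-1].mean(), vals[-1]]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["first", "intermediate", "last"]
    )
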