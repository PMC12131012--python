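"""Synthetic parabolic-flight data generator.

Emulates the four inputs of the measurement campaign so that every
downstream stage is testable without the (undeposited) study data:

* the operator gravity trace — per-parabola earth → hyper → micro → hyper →
  earth structure with linear ramps and additive sensor noise;
* the 15-channel laser distance stream (~1.26 Hz) with accelerometer
  sidecar, condition-dependent posture deltas, slow drift and measurement
  noise, clipped to the sensors' recording limits;
* the five surface-EMG channels (2000 Hz band-limited carriers whose
  envelope RMS is modulated by gravity condition, plus a periodic ECG-like
  crosstalk artifact) with 148 Hz accelerometer sidecars;
* whole cohorts with participant-level effect heterogeneity patterned on the
  observed condition means (micro-g area reduction concentrated at sensors
  7–12; site-specific EMG modulation; coupling between flattening and
  lumbar EMG reduction).

All operations are deterministic under a fixed seed.  Effects are injected
phenomenologically; there is no musculoskeletal modeling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    CONDITIONS,
    SITES,
    TRANSITION,
    BackplateGeometry,
    DistanceStream,
    EmgChannel,
    GravityTrace,
)

__all__ = [
    "FlightParams",
    "ParticipantParams",
    "EffectConfig",
    "ParticipantSession",
    "Cohort",
    "simulate_flight_profile",
    "simulate_distance_stream",
    "simulate_emg_stream",
    "draw_participant_params",
    "simulate_cohort",
    "simulate_segment_summaries",
]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlightParams:
    """Structure of one flight's gravity profile.

    Defaults reproduce the campaign pattern: 31 parabolas per flight, ~20 s
    hyper-g plateaus at 1.8 g flanking a ~22 s micro-g plateau, level flight
    at 1 g in between.  ``micro_duration_s`` must admit the 17 s distance
    analysis window.  The trace sample rate is a generator choice (the
    operator feed's rate is not dictated by the flight physics); 10 Hz
    resolves the 3 s ramps comfortably.
    """

    n_parabolas: int = 31
    earth_level: float = 1.0
    hyper_level: float = 1.8
    micro_level: float = 0.0
    hyper_duration_s: float = 20.0
    micro_duration_s: float = 22.0
    interparabola_earth_s: float = 25.0
    transition_s: float = 3.0
    trace_noise_sd: float = 0.01
    sample_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.n_parabolas < 1:
            raise ValueError("n_parabolas must be >= 1")
        for name in ("hyper_duration_s", "micro_duration_s", "interparabola_earth_s", "transition_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.micro_duration_s < 17.0:
            raise ValueError("micro_duration_s must be >= 17 s to admit the analysis window")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.trace_noise_sd < 0:
            raise ValueError("trace_noise_sd must be >= 0")


#: Smooth baseline plate-to-skin profile (mm), sensor 1 (C7) → sensor 15.
#: Small distances over the thoracic apex, a lumbar lordosis bulge peaking
#: around sensors 11–13, falling off toward the sacrum.
BASELINE_TEMPLATE_MM = np.array(
    [26.0, 23.0, 21.0, 21.0, 23.0, 27.0, 33.0, 41.0, 49.0, 56.0, 62.0, 65.0, 63.0, 58.0, 51.0]
)

#: Relative weights of the micro-g flattening across sensors 7–12 (1-based),
#: matching the observed localisation of the area reduction.
FLATTEN_WEIGHTS = {7: 0.5, 8: 1.0, 9: 1.5, 10: 1.5, 11: 1.0, 12: 0.5}


@dataclass
class ParticipantParams:
    """Ground-truth parameters of one synthetic participant.

    ``micro_flattening_mm`` / ``hyper_delta_mm`` are per-sensor posture
    changes applied during micro-g (subtracted) and hyper-g (added);
    ``emg_condition_scale[site][condition]`` multiplies the site's baseline
    envelope RMS in that condition.
    """

    participant_id: str
    baseline_profile_mm: np.ndarray
    micro_flattening_mm: np.ndarray
    hyper_delta_mm: np.ndarray
    emg_base_rms: dict[str, float]
    emg_condition_scale: dict[str, dict[str, float]]
    ecg_amplitude: float
    clock_offset_s: dict[str, float]
    backplate: str
    trunk_length_cm: float
    #: uniform plate-to-skin offset (mm) per condition — overall posture /
    #: backpack shift between gravity phases, independent of local curvature
    condition_shift_mm: dict[str, float] | None = None
    distance_noise_sd_mm: float = 0.05
    drift_amplitude_mm: float = 0.2
    drift_period_s: float = 90.0
    first_parabola_emg_scale: float = 1.0

    def __post_init__(self) -> None:
        self.baseline_profile_mm = np.asarray(self.baseline_profile_mm, dtype=float)
        self.micro_flattening_mm = np.asarray(self.micro_flattening_mm, dtype=float)
        self.hyper_delta_mm = np.asarray(self.hyper_delta_mm, dtype=float)
        for arr in (self.baseline_profile_mm, self.micro_flattening_mm, self.hyper_delta_mm):
            if arr.shape != (15,):
                raise ValueError("per-sensor parameters must have length 15")
        if np.any(self.micro_flattening_mm < 0):
            raise ValueError("micro_flattening_mm must be >= 0 elementwise")
        for site, scales in self.emg_condition_scale.items():
            if site not in SITES:
                raise ValueError(f"unknown site {site!r}")
            if any(s <= 0 for s in scales.values()):
                raise ValueError("emg_condition_scale entries must be > 0")
        geom = BackplateGeometry.from_backplate(self.backplate)
        lo, hi = geom.limits_mm[:, 0], geom.limits_mm[:, 1]
        if np.any(self.baseline_profile_mm < lo) or np.any(self.baseline_profile_mm > hi):
            raise ValueError("baseline profile must lie within the sensors' recording limits")

    @property
    def geometry(self) -> BackplateGeometry:
        return BackplateGeometry.from_backplate(self.backplate)


# ---------------------------------------------------------------------------
# flight profile
# ---------------------------------------------------------------------------


def simulate_flight_profile(params: FlightParams, seed: int) -> GravityTrace:
    """Simulate the operator gravity trace for one flight.

    The trace cycles earth → hyper → micro → hyper → earth per parabola with
    linear ramps of ``transition_s`` between plateaus, then adds Gaussian
    noise of ``trace_noise_sd``.  Ground-truth per-sample labels (condition,
    1-based parabola index, phase position) are attached; ramp samples are
    labeled ``transition``.
    """
    p = params
    rng = np.random.default_rng(seed)

    # knots: (time, level); plateaus contribute two knots, ramps are implicit
    knots_t: list[float] = [0.0]
    knots_g: list[float] = [p.earth_level]
    # label spans: (t_start, t_end, condition, parabola, phase_position)
    spans: list[tuple[float, float, str, int, str]] = []
    t = 0.0

    def plateau(level: float, dur: float, cond: str, parab: int, phase: str) -> None:
        nonlocal t
        t0 = t + (p.transition_s if knots_t else 0.0)
        if spans or t > 0:
            spans.append((t, t0, TRANSITION, parab, TRANSITION))
        knots_t.extend([t0, t0 + dur])
        knots_g.extend([level, level])
        spans.append((t0, t0 + dur, cond, parab, phase))
        t = t0 + dur

    # initial level flight anchors parabola 1's earth condition
    knots_t[:] = [0.0, p.interparabola_earth_s]
    knots_g[:] = [p.earth_level, p.earth_level]
    spans.append((0.0, p.interparabola_earth_s, "earth", 1, "pre_earth"))
    t = p.interparabola_earth_s

    for k in range(1, p.n_parabolas + 1):
        plateau(p.hyper_level, p.hyper_duration_s, "hyper", k, "hyper_entry")
        plateau(p.micro_level, p.micro_duration_s, "micro", k, "micro")
        plateau(p.hyper_level, p.hyper_duration_s, "hyper", k, "hyper_exit")
        if k < p.n_parabolas:
            plateau(p.earth_level, p.interparabola_earth_s, "earth", k + 1, "pre_earth")
    # closing level flight (not anchored to any parabola)
    t0 = t + p.transition_s
    spans.append((t, t0, TRANSITION, p.n_parabolas, TRANSITION))
    knots_t.extend([t0, t0 + p.interparabola_earth_s])
    knots_g.extend([p.earth_level, p.earth_level])
    spans.append((t0, t0 + p.interparabola_earth_s, "earth", 0, "post_earth"))
    total = t0 + p.interparabola_earth_s

    n = int(math.floor(total * p.sample_rate_hz)) + 1
    time_s = np.arange(n) / p.sample_rate_hz
    gz = np.interp(time_s, knots_t, knots_g)
    if p.trace_noise_sd > 0:
        gz = gz + rng.normal(0.0, p.trace_noise_sd, size=n)

    condition = np.empty(n, dtype="U10")
    parabola = np.zeros(n, dtype=int)
    phase = np.empty(n, dtype="U12")
    starts = np.array([s[0] for s in spans])
    # spans abut exactly; credit boundary samples to the plateau, not the
    # following ramp, by nudging ramp starts half a sample forward
    half_dt = 0.5 / p.sample_rate_hz
    for j, (t0_, _, cond, _, _) in enumerate(spans):
        if cond == TRANSITION:
            starts[j] = t0_ + half_dt
    idx = np.searchsorted(starts, time_s, side="right") - 1
    for j, (t0_, t1_, cond, parab, ph) in enumerate(spans):
        m = idx == j
        condition[m] = cond
        parabola[m] = parab if cond != "earth" or ph != "post_earth" else 0
        phase[m] = ph

    return GravityTrace(
        time_s=time_s,
        gz=gz,
        sample_rate_hz=p.sample_rate_hz,
        condition=condition,
        parabola=parabola,
        phase_position=phase,
    )


def _condition_weights(trace: GravityTrace) -> dict[str, np.ndarray]:
    """Per-sample mixing weight of each condition, ramped across transitions.

    On a plateau the weight of its condition is 1 and the others 0; across a
    ramp the weights interpolate linearly in time, so condition-dependent
    posture/EMG targets cross-fade smoothly in step with the gravity level.
    """
    if not trace.labeled:
        raise ValueError("trace must carry ground-truth labels")
    weights: dict[str, np.ndarray] = {}
    t = trace.time_s
    for cond in CONDITIONS:
        w = np.where(trace.condition == cond, 1.0, 0.0)
        plateau = trace.condition != TRANSITION
        # interpolate transition samples between neighbouring plateau values
        weights[cond] = np.interp(t, t[plateau], w[plateau])
    return weights


# ---------------------------------------------------------------------------
# distance stream
# ---------------------------------------------------------------------------


def simulate_distance_stream(
    trace: GravityTrace,
    p: ParticipantParams,
    seed: int,
    sample_rate_hz: float = 1.26,
) -> DistanceStream:
    """Simulate the 15-channel laser distance stream for one participant.

    Per-sample distance = baseline + condition delta (micro: −flattening,
    hyper: +delta, cross-faded over ramps) + slow sinusoidal within-condition
    drift + Gaussian measurement noise (default sd 0.05 mm, the sensors'
    stated accuracy), clipped to each sensor's recording limits.  Timestamps
    are shifted by the participant's distance-device clock offset; the
    accelerometer column mirrors the gravity trace.
    """
    if not trace.labeled:
        raise ValueError("trace must carry ground-truth labels")
    rng = np.random.default_rng(seed)
    geom = p.geometry

    t_true = np.arange(trace.time_s[0], trace.time_s[-1], 1.0 / sample_rate_hz)
    w = _condition_weights(trace)
    w_micro = np.interp(t_true, trace.time_s, w["micro"])
    w_hyper = np.interp(t_true, trace.time_s, w["hyper"])

    values = (
        p.baseline_profile_mm[None, :]
        - np.outer(w_micro, p.micro_flattening_mm)
        + np.outer(w_hyper, p.hyper_delta_mm)
    )
    if p.condition_shift_mm:
        w_earth = np.interp(t_true, trace.time_s, w["earth"])
        shift = (
            p.condition_shift_mm.get("earth", 0.0) * w_earth
            + p.condition_shift_mm.get("hyper", 0.0) * w_hyper
            + p.condition_shift_mm.get("micro", 0.0) * w_micro
        )
        values = values + shift[:, None]
    if p.drift_amplitude_mm > 0:
        phases = rng.uniform(0, 2 * np.pi, size=15)
        values = values + p.drift_amplitude_mm * np.sin(
            2 * np.pi * t_true[:, None] / p.drift_period_s + phases[None, :]
        )
    if p.distance_noise_sd_mm > 0:
        values = values + rng.normal(0.0, p.distance_noise_sd_mm, size=values.shape)
    values = np.clip(values, geom.limits_mm[:, 0], geom.limits_mm[:, 1])

    accel = np.interp(t_true, trace.time_s, trace.gz)
    offset = p.clock_offset_s.get("distance", 0.0)
    return DistanceStream(
        time_s=t_true + offset,
        values_mm=values,
        accel_gz=accel,
        sample_rate_hz=sample_rate_hz,
        clock_offset_s=offset,
    )


# ---------------------------------------------------------------------------
# EMG stream
# ---------------------------------------------------------------------------

_EMG_FS = 2000.0
_ACCEL_FS = 148.0
_ECG_RATE_BPM = 72.0


def _ecg_artifact(t: np.ndarray, amplitude: float, fs: float) -> np.ndarray:
    """Fixed-rate (72 bpm) biphasic pulse train emulating cardiac crosstalk."""
    out = np.zeros_like(t)
    if amplitude == 0.0:
        return out
    period = 60.0 / _ECG_RATE_BPM
    width = 0.08  # s, QRS-like
    n_pulse = int(width * fs)
    tau = np.arange(n_pulse) / fs
    pulse = amplitude * np.sin(2 * np.pi * tau / width) * np.hanning(n_pulse)
    n_beats = int((t[-1] - t[0]) / period) + 1
    for b in range(n_beats):
        i0 = int(round(b * period * fs))
        if i0 >= t.size:
            break
        seg = min(n_pulse, t.size - i0)
        out[i0 : i0 + seg] += pulse[:seg]
    return out


def simulate_emg_stream(
    trace: GravityTrace, p: ParticipantParams, site: str, seed: int
) -> EmgChannel:
    """Simulate one transmitter's surface-EMG channel.

    The carrier is Gaussian noise band-limited to 10–500 Hz (the recorded
    bandwidth) and normalized to unit RMS, then multiplied by an envelope
    whose per-phase level is ``emg_base_rms[site] * emg_condition_scale
    [site][condition]`` (cross-faded over ramps).  A fixed-rate biphasic
    ECG-like artifact of ``ecg_amplitude`` is added — crosstalk is part of
    the signal model, mirroring the recording conditions, and is never
    removed downstream.  The 148 Hz accelerometer sidecar mirrors the
    gravity trace; both streams are stamped on the device clock.
    """
    if site not in SITES:
        raise ValueError(f"unknown EMG site {site!r}; expected one of {SITES}")
    if not trace.labeled:
        raise ValueError("trace must carry ground-truth labels")
    rng = np.random.default_rng(seed)

    t0, t1 = float(trace.time_s[0]), float(trace.time_s[-1])
    n = int((t1 - t0) * _EMG_FS)
    t = t0 + np.arange(n) / _EMG_FS

    carrier = rng.standard_normal(n)
    sos = sps.butter(2, [10.0, 500.0], btype="bandpass", fs=_EMG_FS, output="sos")
    carrier = sps.sosfilt(sos, carrier)
    carrier /= carrier.std()

    w = _condition_weights(trace)
    base = p.emg_base_rms[site]
    scales = p.emg_condition_scale[site]
    envelope = np.zeros(n)
    for cond in CONDITIONS:
        envelope += scales[cond] * np.interp(t, trace.time_s, w[cond])
    envelope *= base
    if p.first_parabola_emg_scale != 1.0 and trace.parabola is not None:
        in_first = np.interp(
            t, trace.time_s, (trace.parabola == 1).astype(float)
        )
        envelope *= 1.0 + (p.first_parabola_emg_scale - 1.0) * in_first

    emg = carrier * envelope + _ecg_artifact(t - t0, p.ecg_amplitude, _EMG_FS)

    n_acc = int((t1 - t0) * _ACCEL_FS)
    t_acc = t0 + np.arange(n_acc) / _ACCEL_FS
    accel = np.interp(t_acc, trace.time_s, trace.gz)

    offset = p.clock_offset_s.get("emg", 0.0)
    return EmgChannel(
        site=site,
        fs_hz=_EMG_FS,
        start_time_s=t0 + offset,
        emg=emg,
        accel_fs_hz=_ACCEL_FS,
        accel_start_time_s=t0 + offset,
        accel_gz=accel,
        clock_offset_s=offset,
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _table_emg_scales() -> dict[str, dict[str, tuple[float, float]]]:
    # (mean, between-participant sd) of the condition multiplier per site,
    # patterned on the observed mean-normalized condition means/SDs (in
    # fractions of the participant grand mean).
    return {
        "ES upper": {"earth": (0.9219, 0.187), "hyper": (1.1916, 0.261), "micro": (0.8864, 0.313)},
        "ES upper middle": {"earth": (0.9663, 0.151), "hyper": (1.2460, 0.237), "micro": (0.7877, 0.253)},
        "ES lower middle": {"earth": (1.0326, 0.157), "hyper": (1.2081, 0.232), "micro": (0.7593, 0.258)},
        "ES lower": {"earth": (1.1164, 0.149), "hyper": (1.1752, 0.221), "micro": (0.7084, 0.186)},
        "MF": {"earth": (1.1334, 0.146), "hyper": (1.2253, 0.243), "micro": (0.6414, 0.305)},
    }


@dataclass(frozen=True)
class EffectConfig:
    """Population-level effect structure injected into a synthetic cohort.

    Area effects are expressed as per-condition multipliers of the
    participant's earth-g enclosed area, drawn per participant as
    ``Normal(mean, sd)``.  EMG effects are per-site condition multipliers of
    the participant's baseline envelope RMS.  ``emg_area_coupling`` sets the
    latent correlation between a participant's micro-g area multiplier and
    their micro-g EMG multiplier at the given sites, producing the positive
    flattening–deactivation association at the lower lumbar sites.
    """

    micro_area_ratio: tuple[float, float] = (0.939, 0.045)
    hyper_area_ratio: tuple[float, float] = (1.005, 0.03)
    earth_area_ratio: tuple[float, float] = (1.0, 0.012)
    emg_scales: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_table_emg_scales
    )
    emg_area_coupling: dict[str, float] = field(
        default_factory=lambda: {"ES lower": 0.8, "MF": 0.8}
    )
    #: within-participant correlation of a site's condition multipliers: a
    #: shared activation level makes condition contrasts more consistent
    #: within than between participants while preserving the marginal SDs
    emg_condition_rho: float = 0.5
    first_parabola_emg_scale: float = 1.15
    #: covariance (mm^2, condition order earth/hyper/micro) of the
    #: per-condition uniform plate shift; the null cohort's symmetric source
    #: of between-condition area variation.  The default null structure has
    #: heterogeneous SDs patterned on the observed condition spreads and a
    #: correlation that decays with gravity-level distance (the loaded
    #: conditions resemble each other more than the unloaded one), i.e. a
    #: genuinely non-spherical repeated-measures covariance
    condition_shift_cov_mm2: tuple[tuple[float, float, float], ...] | None = None
    within_area_frac_sd: float = 0.01
    within_emg_frac_sd: float = 0.08
    distance_noise_sd_mm: float = 0.05
    drift_amplitude_mm: float = 0.2
    ecg_amplitude_frac: float = 0.15

    @classmethod
    def table_patterned(cls) -> "EffectConfig":
        """Defaults patterned on the observed condition means (the study
        conditions): ~6% micro-g area reduction, site-specific EMG
        modulation, lower-site flattening/EMG coupling, first-parabola
        novelty elevation of EMG."""
        return cls()

    @classmethod
    def null(cls) -> "EffectConfig":
        """No condition effects: every condition multiplier has the same
        distribution, drawn independently per condition (exchangeable), for
        type-I-error calibration."""
        flat = {
            site: {c: (1.0, 0.15) for c in CONDITIONS} for site in SITES
        }
        return cls(
            micro_area_ratio=(1.0, 0.0),
            hyper_area_ratio=(1.0, 0.0),
            earth_area_ratio=(1.0, 0.0),
            condition_shift_cov_mm2=_null_shift_cov(),
            emg_scales=flat,
            emg_area_coupling={},
            first_parabola_emg_scale=1.0,
        )


def _null_shift_cov() -> tuple[tuple[float, float, float], ...]:
    sds = np.array([1.2, 1.4, 2.2])  # earth, hyper, micro (mm)
    corr = np.array([[1.0, 0.8, 0.1], [0.8, 1.0, 0.2], [0.1, 0.2, 1.0]])
    cov = np.outer(sds, sds) * corr
    return tuple(tuple(row) for row in cov)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def draw_participant_params(
    participant_id: str,
    effects: EffectConfig,
    rng: np.random.Generator,
    backplate: str | None = None,
) -> ParticipantParams:
    """Draw one participant's ground-truth parameters around the configured
    population means.

    The drawn micro/hyper area multipliers are converted into per-sensor
    posture deltas concentrated at sensors 7–12 such that the trapezoidal
    enclosed area of the full profile changes by exactly the drawn fraction.
    """
    trunk = rng.normal(47.0, 3.0)
    if backplate is None:
        backplate = "long" if trunk >= 45.0 else "short"
    geom = BackplateGeometry.from_backplate(backplate)

    baseline = BASELINE_TEMPLATE_MM + rng.normal(0.0, 4.0) + rng.normal(0.0, 1.5, size=15)
    baseline = np.clip(baseline, geom.limits_mm[:, 0] + 2.0, geom.limits_mm[:, 1] - 2.0)

    # area over the analyzed span (sensor 1 is always excluded downstream)
    d = baseline[1:]
    area0 = float(np.sum((d[:-1] + d[1:]) / 2.0) * geom.spacing_mm)

    w = np.zeros(15)
    for idx, wt in FLATTEN_WEIGHTS.items():
        w[idx - 1] = wt
    w /= w.sum()

    z_area = rng.standard_normal()
    m_mean, m_sd = effects.micro_area_ratio
    r_micro = np.clip(m_mean + m_sd * z_area, 0.70, 1.10)
    r_hyper = _truncated_normal(rng, *effects.hyper_area_ratio, 0.85, 1.15)
    r_earth = _truncated_normal(rng, *effects.earth_area_ratio, 0.85, 1.15)

    # interior-sensor trapezoid weight is exactly spacing_mm, so a per-sensor
    # reduction vector delta changes the area by spacing * sum(delta)
    micro_flattening = (r_earth - r_micro) * area0 * w / geom.spacing_mm
    micro_flattening = np.clip(micro_flattening, 0.0, None)
    hyper_delta = (r_hyper - r_earth) * area0 * w / geom.spacing_mm

    base_rms = {site: _truncated_normal(rng, 30.0, 8.0, 8.0, 80.0) for site in SITES}
    scales: dict[str, dict[str, float]] = {}
    rho_c = effects.emg_condition_rho
    for site in SITES:
        scales[site] = {}
        shared = rng.standard_normal()  # per-site activation level
        rho = effects.emg_area_coupling.get(site, 0.0)
        for cond in CONDITIONS:
            mean, sd = effects.emg_scales[site][cond]
            if cond == "micro" and rho != 0.0:
                # z_area is the standardized micro area multiplier: smaller
                # area (more flattening) couples to lower micro-g EMG
                idio = rho * z_area + math.sqrt(1.0 - rho**2) * rng.standard_normal()
            else:
                idio = rng.standard_normal()
            z = math.sqrt(rho_c) * shared + math.sqrt(1.0 - rho_c) * idio
            scales[site][cond] = float(np.clip(mean + sd * z, 0.05, None))

    if effects.condition_shift_cov_mm2 is not None:
        cov = np.asarray(effects.condition_shift_cov_mm2, dtype=float)
        draw = rng.multivariate_normal(np.zeros(3), cov, method="cholesky")
        shifts = dict(zip(CONDITIONS, (float(v) for v in draw)))
    else:
        shifts = {c: 0.0 for c in CONDITIONS}
    return ParticipantParams(
        participant_id=participant_id,
        baseline_profile_mm=baseline,
        micro_flattening_mm=micro_flattening,
        hyper_delta_mm=hyper_delta,
        condition_shift_mm=shifts,
        emg_base_rms=base_rms,
        emg_condition_scale=scales,
        ecg_amplitude=effects.ecg_amplitude_frac * float(np.mean(list(base_rms.values()))),
        clock_offset_s={
            "distance": float(rng.uniform(-5.0, 5.0)),
            "emg": float(rng.uniform(-5.0, 5.0)),
        },
        backplate=backplate,
        trunk_length_cm=float(np.clip(trunk, 38.0, 55.0)),
        distance_noise_sd_mm=effects.distance_noise_sd_mm,
        drift_amplitude_mm=effects.drift_amplitude_mm,
        first_parabola_emg_scale=effects.first_parabola_emg_scale,
    )


@dataclass
class ParticipantSession:
    """One participant's full synthetic recording set."""

    params: ParticipantParams
    trace: GravityTrace
    distances: DistanceStream
    emg: dict[str, EmgChannel]

    @property
    def participant_id(self) -> str:
        return self.params.participant_id


@dataclass
class Cohort:
    sessions: list[ParticipantSession]
    flight: FlightParams
    effects: EffectConfig
    seed: int

    def __len__(self) -> int:
        return len(self.sessions)


def simulate_cohort(
    n_participants: int,
    flight: FlightParams | None = None,
    effects: EffectConfig | None = None,
    seed: int = 0,
    emg_sites: tuple[str, ...] = SITES,
) -> Cohort:
    """Simulate a cohort of full sensor sessions.

    Each participant gets an independently drawn parameter set, their own
    flight trace realization (participants flew 10–11 parabolas each; pass a
    ``FlightParams`` with the desired count), the 15-channel distance stream
    and one EMG channel per requested site.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    flight = flight or FlightParams(n_parabolas=10)
    effects = effects or EffectConfig.table_patterned()
    root = np.random.default_rng(seed)
    sessions = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        prng = np.random.default_rng(root.integers(0, 2**31))
        params = draw_participant_params(pid, effects, prng)
        sub = prng.integers(0, 2**31, size=3 + len(emg_sites))
        trace = simulate_flight_profile(flight, seed=int(sub[0]))
        distances = simulate_distance_stream(trace, params, seed=int(sub[1]))
        emg = {
            site: simulate_emg_stream(trace, params, site, seed=int(sub[3 + j]))
            for j, site in enumerate(emg_sites)
        }
        sessions.append(ParticipantSession(params, trace, distances, emg))
    return Cohort(sessions=sessions, flight=flight, effects=effects, seed=seed)


# ---------------------------------------------------------------------------
# summary-level cohort (windowed-segment shortcut)
# ---------------------------------------------------------------------------


def simulate_segment_summaries(
    n_participants: int,
    n_parabolas: int = 10,
    effects: EffectConfig | None = None,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Draw per-window enclosed areas and per-segment EMG RMS directly.

    This is the distributional shortcut through the signal chain: it samples
    the same participant-level parameters as :func:`simulate_cohort` and
    emits what the windowing stages would produce from the full streams —
    one enclosed area per analysis window and one RMS per EMG segment, with
    within-participant window-to-window noise.  It exists so that
    replication-heavy statistical studies (power, type-I calibration) run in
    milliseconds; agreement with the full chain is established separately.

    Returns ``{"area": ..., "emg": ..., "truth": ...}`` data frames.  Each
    parabola contributes four windows (pre-earth, hyper entry, micro, hyper
    exit).
    """
    effects = effects or EffectConfig.table_patterned()
    root = np.random.default_rng(seed)
    area_rows, emg_rows, truth_rows = [], [], []
    phases = [("pre_earth", "earth"), ("hyper_entry", "hyper"), ("micro", "micro"), ("hyper_exit", "hyper")]

    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        prng = np.random.default_rng(root.integers(0, 2**31))
        params = draw_participant_params(pid, effects, prng)
        geom = params.geometry

        def area_of(profile: np.ndarray) -> float:
            d = profile[1:]
            return float(np.sum((d[:-1] + d[1:]) / 2.0) * geom.spacing_mm)

        shifts = params.condition_shift_mm or {}
        cond_area = {
            "earth": area_of(params.baseline_profile_mm + shifts.get("earth", 0.0)),
            "hyper": area_of(
                params.baseline_profile_mm + params.hyper_delta_mm + shifts.get("hyper", 0.0)
            ),
            "micro": area_of(
                params.baseline_profile_mm
                - params.micro_flattening_mm
                + shifts.get("micro", 0.0)
            ),
        }
        truth_rows.append(
            {
                "participant": pid,
                "earth_area_mm2": cond_area["earth"],
                "micro_area_ratio": cond_area["micro"] / cond_area["earth"],
                "hyper_area_ratio": cond_area["hyper"] / cond_area["earth"],
                "micro_scale_ES lower": params.emg_condition_scale["ES lower"]["micro"],
                "micro_scale_MF": params.emg_condition_scale["MF"]["micro"],
            }
        )
        for parab in range(1, n_parabolas + 1):
            for phase, cond in phases:
                a = cond_area[cond] * (1.0 + prng.normal(0.0, effects.within_area_frac_sd))
                area_rows.append(
                    {
                        "participant": pid,
                        "parabola": parab,
                        "condition": cond,
                        "phase_position": phase,
                        "area_mm2": a,
                    }
                )
                for site in SITES:
                    rms = (
                        params.emg_base_rms[site]
                        * params.emg_condition_scale[site][cond]
                        * (1.0 + prng.normal(0.0, effects.within_emg_frac_sd))
                    )
                    if parab == 1:
                        rms *= params.first_parabola_emg_scale
                    emg_rows.append(
                        {
                            "participant": pid,
                            "site": site,
                            "parabola": parab,
                            "condition": cond,
                            "phase_position": phase,
                            "rms": max(rms, 1e-9),
                        }
                    )

    return {
        "area": pd.DataFrame(area_rows),
        "emg": pd.DataFrame(emg_rows),
        "truth": pd.DataFrame(truth_rows),
    }
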