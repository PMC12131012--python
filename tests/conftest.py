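import numpy as np
import pytest

from parabospine.core import CONDITIONS, SITES, DistanceProfile
from parabospine.synth import FlightParams, ParticipantParams


@pytest.fixture(scope="session")
def small_flight() -> FlightParams:
    """Two-parabola flight with the default (0.01 g) trace noise."""
    return FlightParams(n_parabolas=2)


@pytest.fixture(scope="session")
def noiseless_flight() -> FlightParams:
    return FlightParams(n_parabolas=2, trace_noise_sd=0.0)


def make_participant(
    baseline: float | np.ndarray = 50.0,
    micro_flattening: np.ndarray | None = None,
    hyper_delta: np.ndarray | None = None,
    noise_sd: float = 0.05,
    drift: float = 0.2,
    clock_offsets: dict | None = None,
    emg_scales: dict | None = None,
    base_rms: float = 30.0,
    ecg_amplitude: float = 0.0,
    backplate: str = "long",
    trunk_length_cm: float = 50.0,
    first_parabola_emg_scale: float = 1.0,
) -> ParticipantParams:
    """Hand-built participant with explicit, mostly-noiseless defaults."""
    base = np.full(15, float(baseline)) if np.isscalar(baseline) else np.asarray(baseline, float)
    scales = emg_scales or {s: {c: 1.0 for c in CONDITIONS} for s in SITES}
    return ParticipantParams(
        participant_id="T01",
        baseline_profile_mm=base,
        micro_flattening_mm=micro_flattening if micro_flattening is not None else np.zeros(15),
        hyper_delta_mm=hyper_delta if hyper_delta is not None else np.zeros(15),
        emg_base_rms={s: base_rms for s in SITES},
        emg_condition_scale=scales,
        ecg_amplitude=ecg_amplitude,
        clock_offset_s=clock_offsets or {},
        backplate=backplate,
        trunk_length_cm=trunk_length_cm,
        distance_noise_sd_mm=noise_sd,
        drift_amplitude_mm=drift,
        first_parabola_emg_scale=first_parabola_emg_scale,
    )


def make_profile(values, included=None, **kwargs) -> DistanceProfile:
    """DistanceProfile from a 15-vector (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    if included is None:
        included = np.ones(15, dtype=bool)
        included[0] = False
    defaults = dict(
        participant="T01", condition="earth", parabola_index=1, phase_position="pre_earth"
    )
    defaults.update(kwargs)
    return DistanceProfile(values_mm=values, included=np.asarray(included, bool), **defaults)
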