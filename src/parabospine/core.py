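"""Core data model: gravity traces, segments, sensor streams, and test results.

The objects here are deliberately thin containers (frozen where practical)
shared by the generator, the segmentation stage, and the curvature/EMG
processing chains.  Conditions are always one of ``earth`` (level flight,
~1 g), ``hyper`` (pull-up / pull-out, ~1.8 g) and ``micro`` (~0 g); samples
on ramps between plateaus carry the pseudo-condition ``transition`` and are
never analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Canonical gravity conditions, in level order used for reporting.
CONDITIONS: tuple[str, ...] = ("earth", "hyper", "micro")

#: The five surface-EMG transmitter sites: four erector spinae (ES) sites
#: from L4 upward on the right, and one multifidus (MF) site at L5 on the
#: left.  Sites are labels, not vertebral levels.
SITES: tuple[str, ...] = (
    "ES upper",
    "ES upper middle",
    "ES lower middle",
    "ES lower",
    "MF",
)

#: ES sites form the Bonferroni family for the Friedman / Spearman batteries.
ES_SITES: tuple[str, ...] = SITES[:4]

TRANSITION = "transition"

#: Phase positions of the analysis segments inside one parabola.
PHASE_POSITIONS: tuple[str, ...] = ("pre_earth", "hyper_entry", "micro", "hyper_exit")


class UnsynchronizableStream(RuntimeError):
    """Raised when cross-correlation cannot align a device stream."""


# ---------------------------------------------------------------------------
# gravity trace and segments
# ---------------------------------------------------------------------------


@dataclass
class GravityTrace:
    """Timestamped scalar load factor (Gz, in multiples of g).

    ``condition``/``parabola``/``phase_position`` are per-sample ground-truth
    labels carried by synthetic traces (``parabola`` is 1-based, 0 outside any
    parabola).  Operator-supplied traces have no labels.
    """

    time_s: np.ndarray
    gz: np.ndarray
    sample_rate_hz: float
    condition: np.ndarray | None = None
    parabola: np.ndarray | None = None
    phase_position: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.gz = np.asarray(self.gz, dtype=float)
        if self.time_s.shape != self.gz.shape:
            raise ValueError("time_s and gz must have the same shape")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.time_s.size > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def labeled(self) -> bool:
        return self.condition is not None

    @property
    def n_samples(self) -> int:
        return self.time_s.size

    def restrict(self, t_start: float, t_end: float) -> "GravityTrace":
        """Return the sub-trace with ``t_start <= t <= t_end`` (labels kept)."""
        m = (self.time_s >= t_start) & (self.time_s <= t_end)
        return GravityTrace(
            time_s=self.time_s[m],
            gz=self.gz[m],
            sample_rate_hz=self.sample_rate_hz,
            condition=None if self.condition is None else self.condition[m],
            parabola=None if self.parabola is None else self.parabola[m],
            phase_position=(
                None if self.phase_position is None else self.phase_position[m]
            ),
        )


@dataclass(frozen=True)
class GravitySegment:
    """One labeled gravity interval.

    ``phase_position`` locates the segment inside its parabola; the two hyper
    phases of a parabola are kept as distinct segments and pooled into the
    single ``hyper`` condition only at the statistics stage.
    """

    condition: str
    parabola_index: int
    phase_position: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("segment must have positive duration")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def shifted(self, dt: float) -> "GravitySegment":
        return replace(self, t_start=self.t_start + dt, t_end=self.t_end + dt)


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds and window lengths for gravity-phase segmentation.

    The plateau bands comfortably separate the three nominal levels
    (0 g / 1 g / 1.8 g); ramps fall outside every band and are additionally
    rejected by ``min_duration_s``.  ``distance_window_s`` is the fixed
    analysis window for the distance array (0.25-quantile of observed segment
    durations in the reference campaign); ``emg_window_s`` is the shortest
    recorded segment for the EMG chain.
    """

    micro_max: float = 0.1
    earth_band: tuple[float, float] = (0.9, 1.1)
    hyper_min: float = 1.5
    min_duration_s: float = 10.0
    distance_window_s: float = 17.0
    emg_window_s: float = 14.86
    smooth_s: float = 0.5
    merge_gap_s: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.earth_band
        if not (self.micro_max < lo < hi < self.hyper_min):
            raise ValueError("bands must satisfy micro_max < earth < hyper_min")
        if self.min_duration_s <= 0:
            raise ValueError("min_duration_s must be positive")
        if self.distance_window_s <= 0 or self.emg_window_s <= 0:
            raise ValueError("analysis windows must be positive")
        if self.smooth_s < 0 or self.merge_gap_s < 0:
            raise ValueError("smoothing and merge-gap durations must be >= 0")


# ---------------------------------------------------------------------------
# distance sensor array
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BackplateGeometry:
    """Geometry of the 15-sensor laser array on one backplate.

    Sensor 1 sits at C7 and indices increase caudally; sensor ``i`` is at
    ``(i - 1) * spacing_mm`` below C7.  ``limits_mm`` holds each sensor's
    recording range (instrument range 16–120 mm).
    """

    spacing_mm: float
    n_sensors: int = 15
    limits_mm: np.ndarray = field(
        default_factory=lambda: np.tile([16.0, 120.0], (15, 1))
    )

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        lim = np.asarray(self.limits_mm, dtype=float)
        if lim.shape != (self.n_sensors, 2) or np.any(lim[:, 0] >= lim[:, 1]):
            raise ValueError("limits_mm must be (n_sensors, 2) with min < max")
        object.__setattr__(self, "limits_mm", lim)

    @classmethod
    def from_backplate(cls, backplate: str) -> "BackplateGeometry":
        """``short`` plate: 3.0 cm pitch; ``long`` plate: 3.5 cm pitch."""
        spacing = {"short": 30.0, "long": 35.0}.get(backplate)
        if spacing is None:
            raise ValueError(f"unknown backplate {backplate!r}")
        return cls(spacing_mm=spacing)

    def position_mm(self, idx: int | np.ndarray) -> np.ndarray:
        """Distance below C7 of 1-based sensor index ``idx``."""
        return (np.asarray(idx) - 1) * self.spacing_mm


@dataclass
class DistanceStream:
    """15-channel laser distance stream with accelerometer sidecar.

    ``time_s`` are the device-stamped times (possibly offset from the
    operator clock); ``values_mm`` is (n_samples, 15); ``accel_gz`` mirrors
    the gravity trace for synchronization.
    """

    time_s: np.ndarray
    values_mm: np.ndarray
    accel_gz: np.ndarray
    sample_rate_hz: float
    clock_offset_s: float = 0.0  # ground truth when synthetic

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.values_mm = np.asarray(self.values_mm, dtype=float)
        self.accel_gz = np.asarray(self.accel_gz, dtype=float)
        if self.values_mm.shape != (self.time_s.size, 15):
            raise ValueError("values_mm must be (n_samples, 15)")

    def with_time_correction(self, offset_s: float) -> "DistanceStream":
        """Return a copy with ``offset_s`` subtracted from the timestamps."""
        return DistanceStream(
            time_s=self.time_s - offset_s,
            values_mm=self.values_mm,
            accel_gz=self.accel_gz,
            sample_rate_hz=self.sample_rate_hz,
            clock_offset_s=self.clock_offset_s - offset_s,
        )


@dataclass
class DistanceProfile:
    """Per-window mean distance (mm) for each sensor, with inclusion mask.

    ``values_mm[i]`` is NaN when sensor ``i+1`` recorded nothing usable in the
    window.  ``included`` tracks exclusions (topmost sensor, below-SIPS
    sensors); excluded sensors never enter area or angle computations.
    """

    participant: str
    condition: str
    parabola_index: int
    phase_position: str
    values_mm: np.ndarray
    included: np.ndarray
    repaired: frozenset[int] = frozenset()
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values_mm = np.asarray(self.values_mm, dtype=float)
        self.included = np.asarray(self.included, dtype=bool)
        if self.values_mm.shape != (15,) or self.included.shape != (15,):
            raise ValueError("profiles carry exactly 15 sensors")

    def value(self, idx: int) -> float:
        """1-based sensor lookup."""
        return float(self.values_mm[idx - 1])


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------


@dataclass
class EmgChannel:
    """One transmitter's raw EMG (2000 Hz) plus accelerometer sidecar (148 Hz).

    Sample ``k`` of the EMG is stamped ``start_time_s + k / fs_hz`` on the
    device clock; the sidecar mirrors the aircraft gravity trace and is used
    for cross-correlation synchronization.
    """

    site: str
    fs_hz: float
    start_time_s: float
    emg: np.ndarray
    accel_fs_hz: float
    accel_start_time_s: float
    accel_gz: np.ndarray
    clock_offset_s: float = 0.0  # ground truth when synthetic

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown EMG site {self.site!r}; expected one of {SITES}")
        self.emg = np.asarray(self.emg, dtype=float)
        self.accel_gz = np.asarray(self.accel_gz, dtype=float)

    @property
    def time_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.emg.size) / self.fs_hz

    @property
    def accel_time_s(self) -> np.ndarray:
        return self.accel_start_time_s + np.arange(self.accel_gz.size) / self.accel_fs_hz

    def with_time_correction(self, offset_s: float) -> "EmgChannel":
        return EmgChannel(
            site=self.site,
            fs_hz=self.fs_hz,
            start_time_s=self.start_time_s - offset_s,
            emg=self.emg,
            accel_fs_hz=self.accel_fs_hz,
            accel_start_time_s=self.accel_start_time_s - offset_s,
            accel_gz=self.accel_gz,
            clock_offset_s=self.clock_offset_s - offset_s,
        )


# ---------------------------------------------------------------------------
# statistics results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StatTestResult:
    """Outcome of one named test with its correction bookkeeping.

    ``df`` may be fractional (Greenhouse–Geisser adjusted) and is stored as a
    tuple — ``(df1, df2)`` for F tests, ``(df,)`` otherwise, ``()`` when the
    statistic carries no degrees of freedom (e.g. Wilcoxon W).
    """

    name: str
    statistic: float
    stat_label: str  # "F", "chi2", "W", "t", "rho"
    df: tuple[float, ...]
    p_raw: float
    p_corrected: float
    correction: str = "none"  # "none" | "bonferroni"
    family_size: int = 1
    alpha: float = 0.05
    epsilon_gg: float | None = None
    n: int | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        for p in (self.p_raw, self.p_corrected):
            if not (0.0 <= p <= 1.0 or np.isnan(p)):
                raise ValueError("p-values must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_corrected < self.alpha)


def bonferroni(p_raw: float, family_size: int) -> float:
    """Bonferroni-corrected p: ``min(1, m * p)``."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return float(min(1.0, family_size * p_raw))


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for post-hoc power of a two-sided paired t-test."""

    effect_size_d: float
    n_pairs: int
    alpha: float = 0.05
    tails: int = 2

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def require_monotone(time_s: Sequence[float]) -> None:
    t = np.asarray(time_s, dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
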