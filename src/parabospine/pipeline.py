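"""End-to-end orchestration: sync → segment → window → curvature/EMG → stats.

:func:`analyze_cohort` drives full sensor sessions (synthetic or read from
disk) through the whole chain; :func:`analyze_tables` contains the shared
statistical back half and can be applied directly to windowed summary
tables.  Results are collected in a :class:`ReportBundle` holding the five
report tables (condition summary, erector spinae Friedman battery,
post-hoc battery, association battery, per-sensor profile) plus a QC log
accounting for every segment's retention or exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import curvature as curv
from . import emg as emg_mod
from . import syncseg
from .core import (
    CONDITIONS,
    ES_SITES,
    SITES,
    GravitySegment,
    SegmentationConfig,
    StatTestResult,
    PowerSpec,
)
from .stats import (
    friedman_bonferroni,
    paired_t_bonferroni,
    paired_t_power,
    rm_anova_gg,
    shapiro_gate,
    spearman_assoc,
    wilcoxon_posthoc,
)
from .synth import Cohort, ParticipantSession

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "analyze_cohort", "analyze_tables", "make_report"]

_PAIRS = [("earth", "hyper"), ("earth", "micro"), ("hyper", "micro")]


@dataclass(frozen=True)
class RunConfig:
    """Knobs of one analysis run; defaults are the campaign constants."""

    seg: SegmentationConfig = field(default_factory=SegmentationConfig)
    alpha: float = 0.05
    outlier_k: float = 3.0
    trim: float = 0.2
    drop_first: str = "auto"  # "auto" | "always" | "never"
    posthoc_family: int = 3
    es_family: int = 4
    sync: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.drop_first not in ("auto", "always", "never"):
            raise ValueError("drop_first must be auto, always or never")


@dataclass
class ReportBundle:
    """All tables and test objects produced by one run."""

    condition_summary: pd.DataFrame
    friedman_table: pd.DataFrame
    posthoc_table: pd.DataFrame
    association_table: pd.DataFrame
    sensor_profile: pd.DataFrame
    qc_log: pd.DataFrame
    area_windows: pd.DataFrame
    emg_segments: pd.DataFrame
    area_gate: object | None = None
    area_anova: StatTestResult | None = None
    area_posthocs: list[StatTestResult] = field(default_factory=list)
    area_power: dict[str, float] = field(default_factory=dict)
    area_order: StatTestResult | None = None
    emg_order: dict[str, StatTestResult] = field(default_factory=dict)
    emg_tests: dict[str, StatTestResult] = field(default_factory=dict)
    first_parabola_dropped: bool = False


# ---------------------------------------------------------------------------
# per-session signal processing
# ---------------------------------------------------------------------------


def process_session(
    session: ParticipantSession, cfg: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[dict]]:
    """One participant: sync, segment, window, curvature and EMG summaries.

    Returns (area windows, EMG segment summaries, per-sensor profile rows,
    QC entries).
    """
    pid = session.participant_id
    params = session.params
    geom = params.geometry
    trace = session.trace
    qc: list[dict] = []

    distances = session.distances
    if cfg.sync:
        off = syncseg.estimate_offset(distances.time_s, distances.accel_gz, trace)
        distances = distances.with_time_correction(off)

    segments = syncseg.segment_gravity(trace, cfg.seg)

    # --- curvature branch -------------------------------------------------
    area_rows, profile_rows = [], []
    for seg in segments:
        win = syncseg.cut_window(seg, cfg.seg.distance_window_s)
        if win is None:
            qc.append(_qc(pid, seg, "window_too_short", "distance"))
            continue
        profile = curv.window_mean_profile(distances, win, participant=pid)
        profile = curv.clamp_missing_segment(profile, geom)
        profile = curv.exclude_below_sips(profile, params.trunk_length_cm, geom)
        area = curv.enclosed_area(profile, geom)
        angles = curv.intersensor_angles(profile, geom)
        row = {
            "participant": pid,
            "parabola": seg.parabola_index,
            "condition": seg.condition,
            "phase_position": seg.phase_position,
            "area_mm2": area,
        }
        area_rows.append(row)
        for idx, ang in angles.items():
            profile_rows.append(
                {
                    "participant": pid,
                    "condition": seg.condition,
                    "sensor": idx,
                    "distance_mm": profile.value(idx),
                    "angle_deg": ang,
                }
            )

    # --- EMG branch -------------------------------------------------------
    emg_rows = []
    for site, channel in session.emg.items():
        if cfg.sync:
            off = syncseg.estimate_offset(
                channel.accel_time_s, channel.accel_gz, trace
            )
            channel = channel.with_time_correction(off)
        processed = emg_mod.bandpass_rectify(channel)
        for seg in segments:
            win = syncseg.cut_window(seg, cfg.seg.emg_window_s)
            if win is None:
                qc.append(_qc(pid, seg, "window_too_short", f"emg:{site}"))
                continue
            rms = emg_mod.segment_rms(processed, win)
            if rms is None:
                qc.append(_qc(pid, seg, "outside_recording", f"emg:{site}"))
                continue
            emg_rows.append(
                {
                    "participant": pid,
                    "site": site,
                    "parabola": seg.parabola_index,
                    "condition": seg.condition,
                    "phase_position": seg.phase_position,
                    "rms": rms,
                }
            )

    return (
        pd.DataFrame(area_rows),
        pd.DataFrame(emg_rows),
        pd.DataFrame(profile_rows),
        qc,
    )


def _qc(pid: str, seg: GravitySegment, reason: str, stream: str) -> dict:
    return {
        "participant": pid,
        "parabola": seg.parabola_index,
        "condition": seg.condition,
        "phase_position": seg.phase_position,
        "stream": stream,
        "reason": reason,
    }


# ---------------------------------------------------------------------------
# cohort-level statistics
# ---------------------------------------------------------------------------


def analyze_cohort(cohort: Cohort, cfg: RunConfig | None = None) -> ReportBundle:
    """Run the full pipeline on a cohort of sensor sessions.

    A participant whose processing fails is isolated (logged, skipped); the
    run continues with the rest.
    """
    cfg = cfg or RunConfig()
    area_parts, emg_parts, profile_parts, qc_rows = [], [], [], []
    for session in cohort.sessions:
        try:
            a, e, p, q = process_session(session, cfg)
        except Exception:
            logger.exception("participant %s failed; skipping", session.participant_id)
            qc_rows.append(
                {
                    "participant": session.participant_id,
                    "parabola": 0,
                    "condition": "",
                    "phase_position": "",
                    "stream": "all",
                    "reason": "processing_failed",
                }
            )
            continue
        area_parts.append(a)
        emg_parts.append(e)
        profile_parts.append(p)
        qc_rows.extend(q)
    area_df = pd.concat(area_parts, ignore_index=True) if area_parts else pd.DataFrame()
    emg_df = pd.concat(emg_parts, ignore_index=True) if emg_parts else pd.DataFrame()
    profile_df = (
        pd.concat(profile_parts, ignore_index=True) if profile_parts else pd.DataFrame()
    )
    return analyze_tables(area_df, emg_df, cfg, sensor_profile=profile_df, qc_rows=qc_rows)


def analyze_tables(
    area_df: pd.DataFrame,
    emg_df: pd.DataFrame,
    cfg: RunConfig | None = None,
    sensor_profile: pd.DataFrame | None = None,
    qc_rows: list[dict] | None = None,
) -> ReportBundle:
    """Statistical back half over windowed summary tables.

    ``area_df`` needs columns ``participant, parabola, condition,
    phase_position, area_mm2``; ``emg_df`` needs ``participant, site,
    parabola, condition, phase_position, rms``.  Either frame may be empty,
    in which case its branch is skipped.
    """
    cfg = cfg or RunConfig()
    qc_rows = list(qc_rows or [])
    bundle = ReportBundle(
        condition_summary=pd.DataFrame(),
        friedman_table=pd.DataFrame(),
        posthoc_table=pd.DataFrame(),
        association_table=pd.DataFrame(),
        sensor_profile=(
            _summarize_profiles(sensor_profile)
            if sensor_profile is not None and not sensor_profile.empty
            else pd.DataFrame()
        ),
        qc_log=pd.DataFrame(),
        area_windows=area_df,
        emg_segments=emg_df,
    )
    summary_rows: list[dict] = []
    area_assoc: pd.Series | None = None

    # --- curvature --------------------------------------------------------
    if not area_df.empty:
        area_df = _pool_hyper(area_df, "area_mm2")
        area_df["area_mean_norm"] = np.nan
        area_df["area_earth_norm"] = np.nan
        for pid, grp in area_df.groupby("participant"):
            vals = grp["area_mm2"].to_numpy()
            earth_mask = (grp["condition"] == "earth").to_numpy()
            area_df.loc[grp.index, "area_mean_norm"] = curv.normalize_area(vals)
            area_df.loc[grp.index, "area_earth_norm"] = curv.normalize_area(
                vals, mode="earth_mean", earth_mask=earth_mask
            )

        per_parab = (
            area_df.groupby(["participant", "parabola"])["area_mean_norm"]
            .mean()
            .reset_index()
            .rename(columns={"area_mean_norm": "value"})
        )
        try:
            bundle.area_order, order_sig = curv.parabola_order_check(per_parab, cfg.alpha)
        except ValueError:
            bundle.area_order, order_sig = None, False
        if order_sig:
            # mirror the EMG rule: a significant order effect drops parabola 1
            dropped = area_df["parabola"] == 1
            qc_rows.extend(
                _qc_row(r, "distance", "first_parabola")
                for _, r in area_df.loc[dropped].iterrows()
            )
            area_df = area_df.loc[~dropped]

        cond = (
            area_df.groupby(["participant", "condition"])["area_mean_norm"]
            .mean()
            .unstack("condition")
            .reindex(columns=list(CONDITIONS))
        )
        complete = cond.dropna()
        bundle.area_gate = shapiro_gate(
            {c: complete[c].to_numpy() for c in CONDITIONS}, cfg.alpha
        )
        if len(complete) >= 3:
            bundle.area_anova = rm_anova_gg(complete.to_numpy(), cfg.alpha)
            cells = {c: complete[c].to_numpy() for c in CONDITIONS}
            bundle.area_posthocs = paired_t_bonferroni(
                cells, _PAIRS, family_size=cfg.posthoc_family, alpha=cfg.alpha
            )
            for (a, b), res in zip(_PAIRS, bundle.area_posthocs):
                d = cells[a] - cells[b]
                sd = d.std(ddof=1)
                eff = abs(d.mean()) / sd if sd > 0 else 0.0
                bundle.area_power[f"{a} vs {b}"] = paired_t_power(
                    PowerSpec(eff, d.size, alpha=cfg.alpha / cfg.posthoc_family)
                )
        for c in CONDITIONS:
            summary_rows.append(
                _summary_row("area [%]", complete[c], c, len(complete))
            )
        micro_earthnorm = (
            area_df.loc[area_df["condition"] == "micro"]
            .groupby("participant")["area_earth_norm"]
            .mean()
        )
        area_assoc = micro_earthnorm
        bundle.area_windows = area_df

    # --- EMG --------------------------------------------------------------
    if not emg_df.empty:
        emg_df = _pool_hyper(emg_df, "rms", extra_keys=("site",))
        emg_df["outlier"] = False
        for (pid, site), grp in emg_df.groupby(["participant", "site"]):
            emg_df.loc[grp.index, "outlier"] = emg_mod.iqr_outliers(
                grp["rms"].to_numpy(), cfg.outlier_k
            )
        emg_df["excluded_reason"] = "none"

        per_parab = (
            emg_df.groupby(["participant", "site", "parabola"])["rms"]
            .mean()
            .reset_index()
            .rename(columns={"rms": "value"})
        )
        bundle.emg_order, order_sig = emg_mod.order_effect_check(
            per_parab, trim=cfg.trim, alpha=cfg.alpha
        )
        drop_first = cfg.drop_first == "always" or (
            cfg.drop_first == "auto" and order_sig
        )
        bundle.first_parabola_dropped = drop_first
        if drop_first:
            first = emg_df["parabola"] == 1
            emg_df.loc[first, "excluded_reason"] = "first_parabola"
            qc_rows.extend(
                _qc_row(r, f"emg:{r['site']}", "first_parabola")
                for _, r in emg_df.loc[first].iterrows()
            )
        emg_df["excluded"] = emg_df["excluded_reason"] != "none"

        emg_df = emg_mod.normalize_emg(emg_df, mode="grand_mean")
        earth_norm = emg_mod.normalize_emg(emg_df, mode="earth_mean")
        emg_df["rms_earth_norm"] = earth_norm["rms_norm"]
        bundle.emg_segments = emg_df

        posthoc_rows, friedman_rows, assoc_rows = [], [], []
        retained = emg_df.loc[~emg_df["excluded"]]
        for site in [s for s in SITES if s in set(retained["site"])]:
            sub = retained.loc[retained["site"] == site]
            cond = (
                sub.groupby(["participant", "condition"])["rms_norm"]
                .mean()
                .unstack("condition")
                .reindex(columns=list(CONDITIONS))
            )
            complete = cond.dropna()
            for c in CONDITIONS:
                summary_rows.append(
                    _summary_row(f"{site} [%]", complete[c], c, len(complete))
                )
            family = cfg.es_family if site in ES_SITES else 1
            fried = friedman_bonferroni(
                complete.to_numpy(), family_size=family,
                name=f"friedman[{site}]", alpha=cfg.alpha,
            )
            bundle.emg_tests[f"friedman[{site}]"] = fried
            friedman_rows.append(
                {
                    "site": site,
                    "n": fried.n,
                    "chi2": fried.statistic,
                    "df": fried.df[0],
                    "p_raw": fried.p_raw,
                    "p_corrected": fried.p_corrected,
                }
            )
            if fried.significant:
                cells = {c: complete[c].to_numpy() for c in CONDITIONS}
                for res in wilcoxon_posthoc(
                    cells, _PAIRS, family_size=cfg.posthoc_family, alpha=cfg.alpha
                ):
                    bundle.emg_tests[f"{site}:{res.name}"] = res
                    a, b = res.name[len("wilcoxon["):-1].split(" vs ")
                    posthoc_rows.append(
                        {
                            "site": site,
                            "comparison": f"{a} vs {b}",
                            "W": res.statistic,
                            "p_raw": res.p_raw,
                            "p_corrected": res.p_corrected,
                            "median_diff": float(np.median(cells[a] - cells[b])),
                        }
                    )

            if area_assoc is not None:
                micro_emg = (
                    sub.loc[sub["condition"] == "micro"]
                    .groupby("participant")["rms_earth_norm"]
                    .mean()
                )
                both = pd.concat([area_assoc, micro_emg], axis=1, join="inner").dropna()
                if len(both) >= 4:
                    rho = spearman_assoc(
                        both.iloc[:, 0].to_numpy(),
                        both.iloc[:, 1].to_numpy(),
                        family_size=family,
                        name=f"spearman[{site}]",
                        alpha=cfg.alpha,
                    )
                    bundle.emg_tests[f"spearman[{site}]"] = rho
                    assoc_rows.append(
                        {
                            "site": site,
                            "n": rho.n,
                            "rho": rho.statistic,
                            "p_raw": rho.p_raw,
                            "p_corrected": rho.p_corrected,
                        }
                    )
        bundle.friedman_table = pd.DataFrame(friedman_rows)
        bundle.posthoc_table = pd.DataFrame(posthoc_rows)
        bundle.association_table = pd.DataFrame(assoc_rows)

    bundle.condition_summary = pd.DataFrame(summary_rows)
    bundle.qc_log = pd.DataFrame(
        qc_rows,
        columns=["participant", "parabola", "condition", "phase_position", "stream", "reason"],
    )
    return bundle


_PHASE_OF = {"earth": "pre_earth", "hyper": "hyper_pooled", "micro": "micro"}


def _pool_hyper(df: pd.DataFrame, value_col: str, extra_keys: tuple[str, ...] = ()) -> pd.DataFrame:
    """Average each parabola's two hyper windows into one record.

    Balances the three conditions (one record each per parabola), matching
    the equal condition weighting evident in the reference campaign's
    normalized condition means; grand-mean normalization then weights every
    condition equally.
    """
    keys = ["participant", *extra_keys, "parabola", "condition"]
    pooled = df.groupby(keys, as_index=False)[value_col].mean()
    pooled["phase_position"] = pooled["condition"].map(_PHASE_OF)
    return pooled


def _summary_row(assessment: str, values: pd.Series, condition: str, n: int) -> dict:
    return {
        "assessment": assessment,
        "condition": condition,
        "n": n,
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
    }


def _summarize_profiles(profile_df: pd.DataFrame) -> pd.DataFrame:
    """Per-sensor condition means of distance and angle (descriptive only)."""
    return (
        profile_df.groupby(["condition", "sensor"])
        .agg(
            distance_mm=("distance_mm", "mean"),
            distance_sd=("distance_mm", "std"),
            angle_deg=("angle_deg", "mean"),
            angle_sd=("angle_deg", "std"),
        )
        .reset_index()
    )


def _qc_row(row: pd.Series, stream: str, reason: str) -> dict:
    return {
        "participant": row["participant"],
        "parabola": int(row["parabola"]),
        "condition": row["condition"],
        "phase_position": row["phase_position"],
        "stream": stream,
        "reason": reason,
    }


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def _fmt_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"= {p:.3f}"


def make_report(bundle: ReportBundle) -> str:
    """Human-readable summary of one run (deterministic for fixed inputs)."""
    lines: list[str] = ["# Gravity-condition analysis report", ""]

    if not bundle.condition_summary.empty:
        lines.append("## Condition summary (mean-normalized, % of participant mean)")
        for assessment, grp in bundle.condition_summary.groupby("assessment", sort=False):
            cells = ", ".join(
                f"{r['condition']}: {r['mean']:.1f} ± {r['sd']:.1f}"
                for _, r in grp.iterrows()
            )
            lines.append(f"- {assessment} (n = {int(grp['n'].iloc[0])}): {cells}")
        lines.append("")

    if bundle.area_anova is not None:
        a = bundle.area_anova
        lines.append("## Spinal curvature (enclosed area)")
        if bundle.area_order is not None:
            o = bundle.area_order
            lines.append(
                f"- parabola-order check: F ({o.df[0]:.2f}, {o.df[1]:.2f}) = "
                f"{o.statistic:.2f}, p {_fmt_p(o.p_raw)}"
            )
        lines.append(
            f"- gravity effect: F ({a.df[0]:.2f}, {a.df[1]:.2f}) = {a.statistic:.2f}, "
            f"p {_fmt_p(a.p_raw)} (GG epsilon = {a.epsilon_gg:.3f})"
        )
        for res in bundle.area_posthocs:
            pair = res.name[len("paired_t["):-1]
            power = bundle.area_power.get(pair)
            extra = f", power = {power:.0%}" if power is not None else ""
            lines.append(
                f"- {pair}: t ({res.df[0]:.0f}) = {res.statistic:.2f}, "
                f"p {_fmt_p(res.p_corrected)}{extra}"
            )
        lines.append("")

    if not bundle.friedman_table.empty:
        lines.append("## Erector spinae / multifidus EMG (Friedman)")
        if bundle.first_parabola_dropped:
            lines.append("- first parabola excluded for all EMG sites (order effect)")
        for _, r in bundle.friedman_table.iterrows():
            lines.append(
                f"- {r['site']}: chi2 ({r['df']:.0f}) = {r['chi2']:.2f}, "
                f"p {_fmt_p(r['p_corrected'])} (n = {int(r['n'])})"
            )
        lines.append("")

    if not bundle.posthoc_table.empty:
        lines.append("## Post-hoc Wilcoxon signed-rank comparisons")
        for _, r in bundle.posthoc_table.iterrows():
            lines.append(
                f"- {r['site']}, {r['comparison']}: W = {r['W']:.0f}, "
                f"p {_fmt_p(r['p_corrected'])}"
            )
        lines.append("")

    if not bundle.association_table.empty:
        lines.append("## Association with spinal flattening in micro-g (earth-normalized)")
        for _, r in bundle.association_table.iterrows():
            lines.append(
                f"- {r['site']}: rho = {r['rho']:.2f}, p {_fmt_p(r['p_corrected'])} "
                f"(n = {int(r['n'])})"
            )
        lines.append("")

    if not bundle.qc_log.empty:
        counts = bundle.qc_log.groupby("reason").size()
        lines.append("## QC")
        for reason, cnt in counts.items():
            lines.append(f"- {reason}: {cnt} segment(s)")
        lines.append("")
    return "\n".join(lines)
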