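"""Readers and writers for the delimited on-disk formats.

All formats are plain tab-separated text so recordings survive any toolchain:

* gravity trace — ``time_s, gz`` (synthetic ground-truth labels go to a
  ``*_labels.tsv`` sidecar: ``time_s, condition, parabola, phase_position``);
* distance stream — ``time_s, s1..s15, accel_gz``;
* EMG channel — ``time_s, emg_uV`` plus an accelerometer sidecar
  ``time_s, accel_gz``;
* cohort manifest — YAML mapping participant ids to metadata (backplate,
  trunk length) and file paths, with ground-truth effect parameters for
  synthetic cohorts;
* segment and results tables — pandas-written TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DistanceStream, EmgChannel, GravitySegment, GravityTrace

__all__ = [
    "write_gravity_trace",
    "read_gravity_trace",
    "write_distance_stream",
    "read_distance_stream",
    "write_emg_channel",
    "read_emg_channel",
    "write_segment_table",
    "read_segment_table",
    "write_manifest",
    "read_manifest",
]

_FLOAT_FMT = "%.6f"


def write_gravity_trace(trace: GravityTrace, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.time_s, "gz": trace.gz})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    if trace.labeled:
        labels = pd.DataFrame(
            {
                "time_s": trace.time_s,
                "condition": trace.condition,
                "parabola": trace.parabola,
                "phase_position": trace.phase_position,
            }
        )
        labels.to_csv(
            path.with_name(path.stem + "_labels.tsv"), sep="\t", index=False,
            float_format="%.6f",
        )


def read_gravity_trace(path: str | Path, sample_rate_hz: float | None = None) -> GravityTrace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    rate = sample_rate_hz or 1.0 / float(np.median(np.diff(t)))
    kwargs = {}
    label_path = path.with_name(path.stem + "_labels.tsv")
    if label_path.exists():
        lab = pd.read_csv(label_path, sep="\t")
        kwargs = {
            "condition": lab["condition"].to_numpy(dtype="U10"),
            "parabola": lab["parabola"].to_numpy(dtype=int),
            "phase_position": lab["phase_position"].to_numpy(dtype="U12"),
        }
    return GravityTrace(time_s=t, gz=df["gz"].to_numpy(), sample_rate_hz=rate, **kwargs)


def write_distance_stream(stream: DistanceStream, path: str | Path) -> None:
    cols = {"time_s": stream.time_s}
    for i in range(15):
        cols[f"s{i + 1}"] = stream.values_mm[:, i]
    cols["accel_gz"] = stream.accel_gz
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_distance_stream(path: str | Path) -> DistanceStream:
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    values = df[[f"s{i + 1}" for i in range(15)]].to_numpy()
    rate = 1.0 / float(np.median(np.diff(t)))
    return DistanceStream(
        time_s=t, values_mm=values, accel_gz=df["accel_gz"].to_numpy(),
        sample_rate_hz=rate,
    )


def write_emg_channel(channel: EmgChannel, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": channel.time_s, "emg_uV": channel.emg}).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
    pd.DataFrame(
        {"time_s": channel.accel_time_s, "accel_gz": channel.accel_gz}
    ).to_csv(
        path.with_name(path.stem + "_accel.tsv"), sep="\t", index=False,
        float_format="%.6f",
    )


def read_emg_channel(path: str | Path, site: str) -> EmgChannel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    acc = pd.read_csv(path.with_name(path.stem + "_accel.tsv"), sep="\t")
    t = df["time_s"].to_numpy()
    ta = acc["time_s"].to_numpy()
    return EmgChannel(
        site=site,
        fs_hz=1.0 / float(np.median(np.diff(t))),
        start_time_s=float(t[0]),
        emg=df["emg_uV"].to_numpy(),
        accel_fs_hz=1.0 / float(np.median(np.diff(ta))),
        accel_start_time_s=float(ta[0]),
        accel_gz=acc["accel_gz"].to_numpy(),
    )


def write_segment_table(
    segments: dict[str, list[GravitySegment]] | list[GravitySegment],
    path: str | Path,
) -> None:
    """Write segments (optionally keyed by participant) as a TSV table."""
    if isinstance(segments, list):
        segments = {"": segments}
    rows = [
        {
            "participant": pid,
            "parabola": s.parabola_index,
            "condition": s.condition,
            "phase_position": s.phase_position,
            "t_start": s.t_start,
            "t_end": s.t_end,
        }
        for pid, segs in segments.items()
        for s in segs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_segment_table(path: str | Path) -> dict[str, list[GravitySegment]]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out: dict[str, list[GravitySegment]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["participant"]), []).append(
            GravitySegment(
                condition=row["condition"],
                parabola_index=int(row["parabola"]),
                phase_position=row["phase_position"],
                t_start=float(row["t_start"]),
                t_end=float(row["t_end"]),
            )
        )
    return out


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
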