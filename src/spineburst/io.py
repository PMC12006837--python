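"""Readers and writers for the pipeline's on-disk formats.

Traces and sweeps travel as plain CSV (with an optional ``.npz`` array
container for large traces), stacks as one multi-page TIFF per timepoint
(page order = z), ROI annotations and tables as CSV, ground truth and
summaries as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .bursts import BurstEvent, BurstSummary, VoltageTrace
from .fepsp import SweepSeries
from .spines import RoiSpec, StackSeries


# --- voltage traces ---------------------------------------------------------

def write_trace_csv(path, trace: VoltageTrace) -> None:
    df = pd.DataFrame({"time_s": trace.times, "voltage_uV": trace.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def read_trace_csv(path, fs: float | None = None) -> VoltageTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    return VoltageTrace(df["voltage_uV"].to_numpy(), fs, float(t[0]))


def write_trace_npz(path, trace: VoltageTrace) -> None:
    np.savez_compressed(path, samples=trace.samples, fs=trace.fs, t0=trace.t0)


def read_trace_npz(path) -> VoltageTrace:
    z = np.load(path)
    return VoltageTrace(z["samples"], float(z["fs"]), float(z["t0"]))


# --- sweeps -----------------------------------------------------------------

def write_sweeps_csv(path, series: SweepSeries) -> None:
    frames = []
    for k in range(series.sweeps.shape[0]):
        frames.append(
            pd.DataFrame(
                {
                    "sweep_id": k,
                    "sweep_timestamp_min": series.timestamps_min[k],
                    "time_ms": series.time_ms,
                    "voltage_mV": series.sweeps[k],
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format="%.6f")


def read_sweeps_csv(path, stim_ms: float) -> SweepSeries:
    df = pd.read_csv(path)
    ids = np.sort(df["sweep_id"].unique())
    first = df[df["sweep_id"] == ids[0]]
    t = first["time_ms"].to_numpy()
    sweeps = np.stack([df[df["sweep_id"] == i]["voltage_mV"].to_numpy() for i in ids])
    stamps = np.array([df[df["sweep_id"] == i]["sweep_timestamp_min"].iloc[0] for i in ids])
    return SweepSeries(t, sweeps, stim_ms, stamps)


# --- stacks and ROIs --------------------------------------------------------

def write_stack_series(out_dir, series: StackSeries, prefix: str = "tp") -> list[Path]:
    """One multi-page TIFF per timepoint; page k is z-slice k."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, stack in enumerate(series.stacks):
        p = out_dir / f"{prefix}{k:03d}.tif"
        tifffile.imwrite(p, np.moveaxis(stack, 2, 0).astype(np.float32))
        paths.append(p)
    meta = {
        "timestamps_min": series.timestamps_min.tolist(),
        "pixel_um": series.pixel_um,
        "z_step_um": series.z_step_um,
    }
    (out_dir / f"{prefix}_meta.json").write_text(json.dumps(meta, indent=1))
    return paths


def read_stack_series(in_dir, prefix: str = "tp") -> StackSeries:
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob(f"{prefix}[0-9]*.tif"))
    if not paths:
        raise FileNotFoundError(f"no {prefix}*.tif stacks in {in_dir}")
    stacks = [np.moveaxis(tifffile.imread(p), 0, 2) for p in paths]
    meta = json.loads((in_dir / f"{prefix}_meta.json").read_text())
    return StackSeries(stacks, np.asarray(meta["timestamps_min"]), meta["pixel_um"], meta["z_step_um"])


def write_rois_csv(path, rois: Sequence[RoiSpec]) -> None:
    pd.DataFrame(
        [{"role": r.role, "cy": r.center[0], "cx": r.center[1], "size": r.size} for r in rois]
    ).to_csv(path, index=False)


def read_rois_csv(path) -> list[RoiSpec]:
    df = pd.read_csv(path)
    return [
        RoiSpec((float(r.cy), float(r.cx)), int(getattr(r, "size", 20)), str(r.role))
        for r in df.itertuples()
    ]


# --- events, summaries, ground truth ---------------------------------------

def write_events_csv(path, events: Sequence[BurstEvent]) -> None:
    pd.DataFrame(
        [
            {"onset_s": e.onset, "offset_s": e.offset, "duration_s": e.duration, "class": e.klass}
            for e in events
        ]
    ).to_csv(path, index=False, float_format="%.4f")


def read_events_csv(path) -> list[BurstEvent]:
    df = pd.read_csv(path)
    return [
        BurstEvent(float(row["onset_s"]), float(row["offset_s"]), str(row["class"]))
        for _, row in df.iterrows()
    ]


def write_summary_json(path, summary: BurstSummary) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "n_short": summary.n_short,
                "n_long": summary.n_long,
                "mean_duration_s": summary.mean_duration,
                "sem_duration_s": summary.sem_duration,
                "bursts_per_min": summary.burst_frequency,
            },
            indent=1,
            allow_nan=True,
        )
    )


def write_ground_truth(path, truth) -> None:
    payload = truth.to_jsonable()
    payload["data"].pop("params", None)  # dataclasses are echoed in manifests instead
    payload["data"].pop("rois", None)
    Path(path).write_text(json.dumps(payload, indent=1))


__all__ = [n for n in dir() if n.startswith(("read_", "write_"))]
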