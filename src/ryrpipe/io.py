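"""Stable on-disk formats: long-format plate tables, dose-response
tables, fiber traces and decay waveforms, all plain CSV.

Readers validate schemas eagerly (well-name syntax, duplicate wells,
required columns) and raise errors naming the offending file so pipeline
failures point at the input, not at a downstream stage.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .dose import DoseResponseSeries
from .fiber import FiberTrace
from .screen import PlateLayout, PlateRun
from .waveform import DecayWaveform

__all__ = [
    "write_plate_runs",
    "read_plate_runs",
    "write_dose_series",
    "read_dose_series",
    "write_fiber_trace",
    "read_fiber_trace",
    "write_waveform",
    "read_waveform",
]

WELL_RE = re.compile(r"^[A-Z]{1,2}\d{2}$")

PLATE_COLUMNS = [
    "plate_id",
    "run_id",
    "read_time_min",
    "well",
    "row",
    "col",
    "sample_type",
    "compound_id",
    "tau_ns",
    "integrated_intensity",
]


def write_plate_runs(runs: list[PlateRun], path: str | Path) -> None:
    """Write screen runs as one long-format plate table CSV."""
    frames = []
    for run in runs:
        df = run.wells.copy()
        df["run_id"] = run.run_id
        df["plate_id"] = run.run_id + "-" + df["sample_type"]
        df["integrated_intensity"] = df["intensity"]
        frames.append(df[PLATE_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_plate_runs(path: str | Path) -> list[PlateRun]:
    """Read a plate table CSV back into one PlateRun per run_id."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad_wells = df.loc[~df["well"].astype(str).str.match(WELL_RE), "well"]
    if not bad_wells.empty:
        raise ValueError(
            f"{path}: malformed well identifiers, e.g. {bad_wells.iloc[0]!r} "
            f"(row {bad_wells.index[0] + 2})"
        )
    dup = df.duplicated(subset=["run_id", "read_time_min", "sample_type", "well"])
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate well {first['well']} in {first['run_id']}/{first['sample_type']}"
        )
    df["intensity"] = df["integrated_intensity"]
    df["role"] = np.where(df["compound_id"].astype(str) == "DMSO", "control", "compound")
    runs = []
    for run_id, grp in df.groupby("run_id", sort=True):
        runs.append(PlateRun(run_id=str(run_id), wells=grp.reset_index(drop=True)))
    return runs


DOSE_COLUMNS = [
    "compound_id",
    "assay",
    "isoform",
    "redox",
    "free_ca_nM",
    "conc_uM",
    "replicate",
    "response",
]


def write_dose_series(series_list: list[DoseResponseSeries], path: str | Path) -> None:
    frames = []
    for s in series_list:
        df = s.points.rename(columns={"conc_um": "conc_uM"}).copy()
        df["compound_id"] = s.compound_id
        df["assay"] = s.assay
        df["isoform"] = s.isoform
        df["redox"] = s.redox
        df["free_ca_nM"] = s.free_ca_nM
        frames.append(df[DOSE_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dose_series(path: str | Path) -> list[DoseResponseSeries]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(DOSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    keys = ["compound_id", "assay", "isoform", "redox", "free_ca_nM"]
    for (cid, assay, isoform, redox, free_ca), grp in df.groupby(keys, sort=True):
        pts = grp.rename(columns={"conc_uM": "conc_um"})[
            ["conc_um", "replicate", "response"]
        ].reset_index(drop=True)
        out.append(
            DoseResponseSeries(
                compound_id=str(cid),
                points=pts,
                assay=str(assay),
                isoform=str(isoform),
                redox=str(redox),
                free_ca_nM=float(free_ca),
            )
        )
    return out


def write_fiber_trace(trace: FiberTrace, trace_path: str | Path, events_path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "fluorescence": trace.fluorescence}).to_csv(
        trace_path, index=False
    )
    pd.DataFrame(trace.events, columns=["time_s", "label"]).to_csv(events_path, index=False)


def read_fiber_trace(trace_path: str | Path, events_path: str | Path | None = None) -> FiberTrace:
    trace_path = Path(trace_path)
    df = pd.read_csv(trace_path)
    if not {"time_s", "fluorescence"} <= set(df.columns):
        raise ValueError(f"{trace_path}: need columns time_s, fluorescence")
    events = []
    if events_path is not None:
        ev = pd.read_csv(events_path)
        if not {"time_s", "label"} <= set(ev.columns):
            raise ValueError(f"{events_path}: need columns time_s, label")
        events = list(zip(ev["time_s"].astype(float), ev["label"].astype(str)))
    trace = FiberTrace(
        time=df["time_s"].to_numpy(float),
        fluorescence=df["fluorescence"].to_numpy(float),
        events=events,
    )
    trace.validate()
    return trace


def write_waveform(wf: DecayWaveform, path: str | Path) -> None:
    pd.DataFrame({"time_ns": wf.time, "counts": wf.counts}).to_csv(path, index=False)


def read_waveform(path: str | Path, well_id: str | None = None) -> DecayWaveform:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"time_ns", "counts"} <= set(df.columns):
        raise ValueError(f"{path}: need columns time_ns, counts")
    wf = DecayWaveform(
        time=df["time_ns"].to_numpy(float),
        counts=df["counts"].to_numpy(float),
        well_id=well_id if well_id is not None else path.stem,
    )
    wf.validate()
    return wf


def default_layout_from_table(df: pd.DataFrame) -> PlateLayout:
    """Infer a column-based layout from a plate table (compound vs DMSO columns)."""
    cmpd_cols = sorted(df.loc[df["compound_id"].astype(str) != "DMSO", "col"].unique())
    ctrl_cols = sorted(df.loc[df["compound_id"].astype(str) == "DMSO", "col"].unique())
    n_rows = df["row"].nunique()
    return PlateLayout(
        n_rows=int(n_rows),
        n_cols=int(df["col"].max()),
        compound_cols=tuple(int(c) for c in cmpd_cols),
        control_cols=tuple(int(c) for c in ctrl_cols),
    )
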