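"""File formats: readers and writers for every pipeline artifact.

Column dictionaries
-------------------
MI traces (long CSV)
    plate, well, treatment, concentration_um (empty for vehicle),
    frame_index (0-based MI sample), mi (nonnegative, arbitrary units)
Plate map (CSV)
    plate, well, role, treatment, concentration_um
Schedule (YAML/JSON)
    list of segment records: label, kind, start_s, end_s and optional
    wavelength_nm, irradiance_uw_mm2, strobe_hz
Frame stacks
    multipage grayscale TIFF plus an ROI JSON mapping well -> [r0, c0, r1, c1]
SMILES lists
    one ``SMILES<TAB>id`` per line; blank lines and ``#`` comments ignored
Ephys traces (CSV)
    time_s, current_na, with epochs in a JSON sidecar
    {label: [start_s, end_s], ...}
Mortality (CSV)
    dose_ug_per_well, well_id, replicate, n_larvae, n_dead, well_dead
Fingerprints (CSV)
    compound_id, n_bits, on_bits (space-separated bit indices)

All round-trips are lossless on the in-memory model; malformed input raises
with the file, row and field named.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .battery import StimulusSchedule
from .chem_clustering import CompoundRecord, Fingerprint
from .motion_index import FrameStack, WellTrace
from .pharmacology import EphysTrace

TRACE_COLUMNS = ["plate", "well", "treatment", "concentration_um", "frame_index", "mi"]


# ---------------------------------------------------------------------------
# MI traces
# ---------------------------------------------------------------------------

def write_traces_csv(traces: Sequence[WellTrace], path: str | Path) -> None:
    lengths = [t.mi.size for t in traces]
    conc = [np.nan if t.concentration_um is None else t.concentration_um for t in traces]
    df = pd.DataFrame(
        {
            "plate": np.repeat([t.plate for t in traces], lengths),
            "well": np.repeat([t.well for t in traces], lengths),
            "treatment": np.repeat([t.treatment for t in traces], lengths),
            "concentration_um": np.repeat(conc, lengths),
            "frame_index": np.concatenate([np.arange(k) for k in lengths]),
            "mi": np.concatenate([t.mi for t in traces]),
        }
    )
    df.to_csv(path, index=False)


def read_traces_csv(path: str | Path, frame_rate_hz: float = 25.0) -> list[WellTrace]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[df["mi"] < 0]
    if len(bad):
        row = int(bad[0])
        raise ValueError(f"{path}: row {row + 2}: negative MI value {df.at[row, 'mi']}")
    traces = []
    for (plate, well), g in df.groupby(["plate", "well"], sort=True, dropna=False):
        g = g.sort_values("frame_index")
        if not (g["frame_index"].to_numpy() == np.arange(len(g))).all():
            raise ValueError(f"{path}: well {plate}/{well}: non-contiguous frame_index")
        conc = g["concentration_um"].iloc[0]
        traces.append(
            WellTrace(
                plate=str(plate),
                well=str(well),
                treatment=str(g["treatment"].iloc[0]),
                concentration_um=None if pd.isna(conc) else float(conc),
                mi=g["mi"].to_numpy(dtype=float),
                frame_rate_hz=frame_rate_hz,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# plate maps
# ---------------------------------------------------------------------------

def write_plate_map(plate_map: pd.DataFrame, path: str | Path) -> None:
    plate_map.to_csv(path, index=False)


def read_plate_map(path: str | Path, traces: Optional[Sequence[WellTrace]] = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"plate", "well", "role", "treatment", "concentration_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dup = df.duplicated(["plate", "well"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ValueError(f"{path}: row {row + 2}: duplicate well {df.at[row, 'well']}")
    if traces is not None:
        have = {(t.plate, t.well) for t in traces}
        missing_wells = [
            f"{p}/{w}" for p, w in zip(df["plate"], df["well"]) if (p, w) not in have
        ]
        if missing_wells:
            raise ValueError(f"{path}: wells absent from traces: {missing_wells}")
    return df


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def write_schedule(schedule: StimulusSchedule, path: str | Path) -> None:
    path = Path(path)
    records = schedule.to_records()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump({"segments": records}, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps({"segments": records}, indent=2))
    else:
        raise ValueError(f"unsupported schedule format {path.suffix!r}")


def read_schedule(path: str | Path) -> StimulusSchedule:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    if not isinstance(data, dict) or "segments" not in data:
        raise ValueError(f"{path}: expected a mapping with a 'segments' list")
    return StimulusSchedule.from_records(data["segments"])


# ---------------------------------------------------------------------------
# frame stacks
# ---------------------------------------------------------------------------

def write_frames(stack: FrameStack, tiff_path: str | Path, roi_path: str | Path) -> None:
    tifffile.imwrite(tiff_path, stack.frames)
    meta = {
        "frame_rate_hz": stack.frame_rate_hz,
        "rois": {w: list(map(int, r)) for w, r in stack.rois.items()},
    }
    Path(roi_path).write_text(json.dumps(meta, indent=2))


def read_frames(tiff_path: str | Path, roi_path: str | Path) -> FrameStack:
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(Path(roi_path).read_text())
    return FrameStack(
        frames=frames,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        rois={w: tuple(r) for w, r in meta["rois"].items()},
    )


# ---------------------------------------------------------------------------
# SMILES and fingerprints
# ---------------------------------------------------------------------------

def read_smiles(path: str | Path) -> list[CompoundRecord]:
    records = []
    seen = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}: line {ln}: expected 'SMILES<TAB>id'")
        smiles, cid = parts[0], parts[1]
        if cid in seen:
            raise ValueError(f"{path}: line {ln}: duplicate compound id {cid!r}")
        seen.add(cid)
        records.append(CompoundRecord(cid, smiles))
    return records


def write_smiles(records: Sequence[CompoundRecord], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{r.smiles}\t{r.compound_id}\n" for r in records)
    )


def write_fingerprints_csv(fps: Sequence[Fingerprint], path: str | Path) -> None:
    rows = [
        {
            "compound_id": f.compound_id,
            "n_bits": f.n_bits,
            "on_bits": " ".join(map(str, np.flatnonzero(f.bits))),
        }
        for f in fps
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fingerprints_csv(path: str | Path) -> list[Fingerprint]:
    df = pd.read_csv(path)
    missing = {"compound_id", "n_bits", "on_bits"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    fps = []
    for i, row in df.iterrows():
        bits = np.zeros(int(row["n_bits"]), dtype=bool)
        field = row["on_bits"]
        if isinstance(field, str) and field.strip():
            idx = np.array(field.split(), dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= bits.size):
                raise ValueError(f"{path}: row {i + 2}: on_bits index out of range")
            bits[idx] = True
        fps.append(Fingerprint(str(row["compound_id"]), bits))
    return fps


# ---------------------------------------------------------------------------
# ephys
# ---------------------------------------------------------------------------

def write_ephys(trace: EphysTrace, csv_path: str | Path, epochs_path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "current_na": trace.current_na}).to_csv(
        csv_path, index=False
    )
    meta = {
        "sampling_hz": trace.sampling_hz,
        "oocyte_id": trace.oocyte_id,
        "treatment": trace.treatment,
        "holding_mv": trace.holding_mv,
        "epochs": {k: list(v) for k, v in trace.epochs.items()},
    }
    Path(epochs_path).write_text(json.dumps(meta, indent=2))


def read_ephys(csv_path: str | Path, epochs_path: str | Path) -> EphysTrace:
    df = pd.read_csv(csv_path, float_precision="round_trip")
    missing = {"time_s", "current_na"} - set(df.columns)
    if missing:
        raise ValueError(f"{csv_path}: missing columns {sorted(missing)}")
    meta = json.loads(Path(epochs_path).read_text())
    return EphysTrace(
        time_s=df["time_s"].to_numpy(),
        current_na=df["current_na"].to_numpy(),
        sampling_hz=float(meta["sampling_hz"]),
        epochs={k: tuple(v) for k, v in meta["epochs"].items()},
        oocyte_id=meta.get("oocyte_id", ""),
        treatment=meta.get("treatment", ""),
        holding_mv=float(meta.get("holding_mv", -60.0)),
    )


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------

def write_mortality(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_mortality(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "dose_ug_per_well" not in df.columns:
        raise ValueError(f"{path}: missing dose_ug_per_well column")
    if not ("well_dead" in df.columns or {"n_dead", "n_larvae"}.issubset(df.columns)):
        raise ValueError(f"{path}: needs well_dead or n_dead/n_larvae columns")
    bad = df.index[df["dose_ug_per_well"] <= 0]
    if len(bad):
        row = int(bad[0])
        raise ValueError(f"{path}: row {row + 2}: nonpositive dose")
    return df
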