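"""Reading and writing recordings, event tables and ground truth.

Container layout (HDF5): one group per recording; imaging groups hold a
``fluorescence`` (cells × frames) and ``coords_um`` (cells × 2) dataset,
ephys groups a ``vm`` dataset; both carry ``rate_hz``, ``start_time_s`` and
``area`` attributes. A plain-text CSV export/import of the same matrices is
provided for portability. Events and matches go to tab-separated tables;
ground truth to a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import DischargeEvent, DischargeMatch, EphysRecording, ImagingRecording
from .synthetic import ExperimentConfig, SyntheticGroundTruth

PathLike = Union[str, Path]


# ---------------------------------------------------------------- HDF5


def write_recording_h5(
    path: PathLike, rec: Union[ImagingRecording, EphysRecording], name: Optional[str] = None
) -> None:
    """Append one recording as a group to an HDF5 container."""
    with h5py.File(path, "a") as f:
        if isinstance(rec, ImagingRecording):
            g = f.create_group(name or rec.recording_id)
            g.create_dataset("fluorescence", data=rec.fluorescence)
            g.create_dataset("coords_um", data=rec.coords_um)
            g.attrs["rate_hz"] = rec.frame_rate_hz
        else:
            g = f.create_group(name or rec.cell_id)
            g.create_dataset("vm", data=rec.vm_mv)
            g.attrs["rate_hz"] = rec.sample_rate_hz
        g.attrs["start_time_s"] = rec.start_time_s
        g.attrs["area"] = rec.area


def read_recording_h5(
    path: PathLike, name: str
) -> Union[ImagingRecording, EphysRecording]:
    """Read one recording group; the dataset present decides the type."""
    with h5py.File(path, "r") as f:
        g = f[name]
        for attr in ("rate_hz", "start_time_s", "area"):
            if attr not in g.attrs:
                raise ValueError(f"recording {name!r} is missing attribute {attr!r}")
        if "fluorescence" in g:
            if "coords_um" not in g:
                raise ValueError(f"recording {name!r} is missing dataset 'coords_um'")
            return ImagingRecording(
                fluorescence=g["fluorescence"][()],
                frame_rate_hz=float(g.attrs["rate_hz"]),
                start_time_s=float(g.attrs["start_time_s"]),
                coords_um=g["coords_um"][()],
                area=str(g.attrs["area"]),
                recording_id=name,
            )
        if "vm" in g:
            return EphysRecording(
                vm_mv=g["vm"][()],
                sample_rate_hz=float(g.attrs["rate_hz"]),
                start_time_s=float(g.attrs["start_time_s"]),
                area=str(g.attrs["area"]),
                cell_id=name,
            )
        raise ValueError(f"recording {name!r} has neither 'fluorescence' nor 'vm'")


def list_recordings_h5(path: PathLike) -> List[str]:
    with h5py.File(path, "r") as f:
        return sorted(f.keys())


# ---------------------------------------------------------------- CSV


def _sibling(prefix: Path, ext: str) -> Path:
    return prefix.parent / (prefix.name + ext)


def write_imaging_csv(prefix: PathLike, rec: ImagingRecording) -> None:
    """Write ``<prefix>.fluor.csv`` / ``<prefix>.coords.csv`` / ``<prefix>.meta.json``."""
    prefix = Path(prefix)
    n_frames = rec.n_frames
    df = pd.DataFrame(
        rec.fluorescence, columns=[f"frame{j}" for j in range(n_frames)]
    )
    df.insert(0, "cell", np.arange(rec.n_cells))
    df.to_csv(_sibling(prefix, ".fluor.csv"), index=False)
    pd.DataFrame(rec.coords_um, columns=["x_um", "y_um"]).to_csv(
        _sibling(prefix, ".coords.csv"), index=False
    )
    _write_meta(prefix, rec.frame_rate_hz, rec.start_time_s, rec.area, "imaging")


def write_ephys_csv(prefix: PathLike, rec: EphysRecording) -> None:
    prefix = Path(prefix)
    pd.DataFrame({"vm_mv": rec.vm_mv}).to_csv(
        _sibling(prefix, ".vm.csv"), index=False
    )
    _write_meta(prefix, rec.sample_rate_hz, rec.start_time_s, rec.area, "ephys")


def _write_meta(prefix: Path, rate, start, area, kind) -> None:
    meta = {"rate_hz": rate, "start_time_s": start, "area": area, "kind": kind}
    _sibling(prefix, ".meta.json").write_text(json.dumps(meta, indent=1))


def read_recording_csv(prefix: PathLike) -> Union[ImagingRecording, EphysRecording]:
    """Read a recording from its CSV/JSON file set (see the writers above)."""
    prefix = Path(prefix)
    meta_path = _sibling(prefix, ".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(meta_path)
    meta = json.loads(meta_path.read_text())
    for key in ("rate_hz", "start_time_s", "area", "kind"):
        if key not in meta:
            raise ValueError(f"metadata file is missing field {key!r}")
    if meta["kind"] == "imaging":
        fluor = pd.read_csv(_sibling(prefix, ".fluor.csv"))
        coords = pd.read_csv(_sibling(prefix, ".coords.csv"))
        return ImagingRecording(
            fluorescence=fluor.drop(columns=["cell"]).to_numpy(),
            frame_rate_hz=float(meta["rate_hz"]),
            start_time_s=float(meta["start_time_s"]),
            coords_um=coords.to_numpy(),
            area=meta["area"],
            recording_id=prefix.name,
        )
    vm = pd.read_csv(_sibling(prefix, ".vm.csv"))
    return EphysRecording(
        vm_mv=vm["vm_mv"].to_numpy(),
        sample_rate_hz=float(meta["rate_hz"]),
        start_time_s=float(meta["start_time_s"]),
        area=meta["area"],
        cell_id=prefix.name,
    )


# ---------------------------------------------------------------- tables


def write_events_tsv(path: PathLike, events: List[DischargeEvent]) -> None:
    """BED-like tab-separated event table, times in seconds with 6 decimals."""
    df = pd.DataFrame(
        {
            "recording_id": [e.recording_id for e in events],
            "onset_s": [f"{e.onset_s:.6f}" for e in events],
            "offset_s": [f"{e.offset_s:.6f}" for e in events],
            "area": [e.area for e in events],
            "source": [e.source for e in events],
            "n_cells_active": [
                "" if e.n_cells_active is None else e.n_cells_active for e in events
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: PathLike) -> List[DischargeEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"n_cells_active": "Int64"})
    return [
        DischargeEvent(
            onset_s=float(row.onset_s),
            offset_s=float(row.offset_s),
            source=row.source,
            area=row.area,
            n_cells_active=None if pd.isna(row.n_cells_active) else int(row.n_cells_active),
            recording_id=str(row.recording_id),
        )
        for row in df.itertuples()
    ]


def write_matches_tsv(path: PathLike, matches: List[DischargeMatch]) -> None:
    rows = []
    for m in matches:
        rows.append(
            {
                "cortical_onset_s": f"{m.cortical_event.onset_s:.6f}",
                "cortical_offset_s": f"{m.cortical_event.offset_s:.6f}",
                "thalamic_onset_s": (
                    f"{m.thalamic_event.onset_s:.6f}" if m.matched else "NA"
                ),
                "lag_s": f"{m.lag_s:.6f}" if m.matched else "NA",
                "overlap_s": f"{m.overlap_s:.6f}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_raster_csv(path: PathLike, raster) -> None:
    """Sparse (cell, frame) pair list of a binary onset raster.

    A ``<path>.meta.json`` sidecar records the raster shape, source
    recording and frame times span so the sparse list is self-describing.
    """
    path = Path(path)
    cells, frames = np.nonzero(raster.onsets)
    pd.DataFrame({"cell": cells, "frame": frames}).to_csv(path, index=False)
    meta = {
        "n_cells": int(raster.n_cells),
        "n_frames": int(raster.n_frames),
        "source_recording": raster.source_recording,
        "first_frame_time_s": float(raster.frame_times_s[0]),
        "last_frame_time_s": float(raster.frame_times_s[-1]),
    }
    _sibling(path, ".meta.json").write_text(json.dumps(meta, indent=1))


def write_ground_truth_json(path: PathLike, truth: SyntheticGroundTruth) -> None:
    payload = {
        "duration_s": truth.duration_s,
        "event_times_s": np.asarray(truth.event_times_s).tolist(),
        "thalamic_coupled": np.asarray(truth.thalamic_coupled).astype(bool).tolist(),
        "true_lags_s": [
            None if np.isnan(v) else float(v) for v in np.asarray(truth.true_lags_s)
        ],
        "drifting_cells": {
            area: np.asarray(v).tolist() for area, v in truth.drifting_cells.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_experiment_config(path: PathLike) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML/JSON mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return ExperimentConfig(**data)
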