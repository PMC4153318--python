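"""Shared data containers for two-area (neocortex + thalamus) slice recordings.

Conventions used throughout the package:

* time is absolute seconds from experiment start; frame and sample indices
  are 0-based,
* event intervals are half-open ``[onset, offset)``; two events overlap only
  if their intersection has strictly positive length,
* areas are labelled ``"cortex"`` / ``"thalamus"``,
* positive lags mean cortex leads thalamus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

AREA_CORTEX = "cortex"
AREA_THALAMUS = "thalamus"


def _as_2d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D (got shape {arr.shape})")
    return arr


@dataclass
class ImagingRecording:
    """Per-cell fluorescence time series from one field of view.

    Parameters
    ----------
    fluorescence : ndarray, shape (n_cells, n_frames)
        ΔF traces, one row per cell.
    frame_rate_hz : float
        Imaging frame rate.
    start_time_s : float
        Absolute start of this recording within the experiment.
    coords_um : ndarray, shape (n_cells, 2)
        Somatic x, y positions in μm.
    area : str
        ``"cortex"`` or ``"thalamus"``.
    recording_id : str
        Identifier used in output tables.
    """

    fluorescence: np.ndarray
    frame_rate_hz: float
    start_time_s: float
    coords_um: np.ndarray
    area: str
    recording_id: str = "imaging"

    def __post_init__(self) -> None:
        self.fluorescence = _as_2d_float(self.fluorescence, "fluorescence")
        self.coords_um = _as_2d_float(self.coords_um, "coords_um")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be > 0")
        if self.coords_um.shape[0] != self.fluorescence.shape[0]:
            raise ValueError("coords_um rows must equal number of cells")
        if np.isnan(self.fluorescence).any():
            raise ValueError("fluorescence contains NaN")

    @property
    def n_cells(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]

    @property
    def frame_times_s(self) -> np.ndarray:
        """Absolute acquisition time of each frame."""
        return self.start_time_s + np.arange(self.n_frames) / self.frame_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class EphysRecording:
    """Single-cell membrane-potential trace (whole-cell current clamp)."""

    vm_mv: np.ndarray
    sample_rate_hz: float
    start_time_s: float
    area: str
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.vm_mv = np.asarray(self.vm_mv, dtype=float).ravel()
        if not self.sample_rate_hz > 0:
            raise ValueError("sample_rate_hz must be > 0")
        if not np.isfinite(self.vm_mv).all():
            raise ValueError("vm_mv contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.vm_mv.size

    @property
    def sample_times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class OnsetRaster:
    """Binary firing-onset raster derived from an imaging recording."""

    onsets: np.ndarray
    frame_times_s: np.ndarray
    source_recording: str = "imaging"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets)
        if not np.isin(self.onsets, (0, 1)).all():
            raise ValueError("onsets must be binary")
        self.onsets = self.onsets.astype(np.uint8)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float).ravel()
        if self.frame_times_s.size != self.onsets.shape[1]:
            raise ValueError("frame_times_s length must equal number of frames")

    @property
    def n_cells(self) -> int:
        return self.onsets.shape[0]

    @property
    def n_frames(self) -> int:
        return self.onsets.shape[1]


@dataclass
class DischargeEvent:
    """One detected epileptiform discharge, interval ``[onset_s, offset_s)``."""

    onset_s: float
    offset_s: float
    source: str  # "imaging" | "ephys"
    area: str  # "cortex" | "thalamus"
    n_cells_active: Optional[int] = None
    recording_id: str = ""

    def __post_init__(self) -> None:
        if self.offset_s < self.onset_s:
            raise ValueError("offset_s must be >= onset_s")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlap_s(self, other: "DischargeEvent") -> float:
        """Length of the intersection with ``other`` (0 if disjoint)."""
        return max(
            0.0,
            min(self.offset_s, other.offset_s) - max(self.onset_s, other.onset_s),
        )


@dataclass
class DischargeMatch:
    """A cortical discharge paired (or not) with an overlapping thalamic one."""

    cortical_event: DischargeEvent
    thalamic_event: Optional[DischargeEvent] = None
    lag_s: Optional[float] = None
    overlap_s: float = 0.0

    @property
    def matched(self) -> bool:
        return self.thalamic_event is not None


@dataclass
class CouplingPoint:
    """Coupling reliability (or fraction-correlated) of one recording."""

    recording_mid_time_s: float
    cr: float
    n_cortical_events: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.cr <= 1.0:
            raise ValueError("cr must lie in [0, 1]")


@dataclass
class AlignedTimeline:
    """Crossing-aligned, binned cohort timeline of a per-recording metric."""

    aligned_times_min: list
    values: list
    bin_edges_min: np.ndarray
    bin_means: np.ndarray
    bin_sems: np.ndarray
    n_slices_per_bin: np.ndarray


@dataclass
class CellEphysCorrelation:
    """Per-cell correlation with the remote (other-area) voltage trace."""

    cell_id: int
    r: float
    p_value: float
    correlated: bool


@dataclass
class EventZScoreSeries:
    """Event-aligned z-scored fluorescence of one cell, plus shuffle stats."""

    cell_id: int
    event_times_s: np.ndarray
    z_values: np.ndarray
    baseline_means: np.ndarray
    baseline_sds: np.ndarray
    slope: Optional[float] = None
    shuffle_p10: Optional[float] = None
    shuffle_p90: Optional[float] = None
    stationary: Optional[bool] = None


@dataclass
class PairCorrelation:
    """Correlation of one cell pair before and after thalamic recruitment."""

    cell_a: int
    cell_b: int
    distance_um: float
    r_before: float
    r_after: float


@dataclass
class SpatialProfile:
    """Distance-binned mean pairwise correlation with unique-cell-DOF SEM."""

    bin_edges_um: np.ndarray
    bin_mean_r: np.ndarray
    bin_sem_r: np.ndarray
    n_pairs_per_bin: np.ndarray
    n_unique_cells_per_bin: np.ndarray


@dataclass
class IntensityPair:
    """Per-discharge intensity in cortex (fraction) and thalamus (mV·s)."""

    event_id: int
    cortical_fraction: float
    thalamic_auc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cortical_fraction <= 1.0:
            raise ValueError("cortical_fraction must lie in [0, 1]")
        if self.thalamic_auc < 0:
            raise ValueError("thalamic_auc must be >= 0")


def require_sorted_events(events: Sequence[DischargeEvent], name: str) -> None:
    onsets = [e.onset_s for e in events]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError(f"{name} events must be sorted by onset")
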