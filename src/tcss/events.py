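"""Epileptiform-discharge detection.

Two detectors share one event model (`DischargeEvent`, half-open interval in
absolute experiment time):

* **imaging**: a circuit event starts when the number of distinct cells with
  a firing onset inside a trailing window reaches a population-size-dependent
  fraction of all cells, and ends when the count falls back below it;
* **electrophysiology**: a discharge is a maximal interval where the
  membrane potential exceeds a running-median baseline by a configurable
  depolarization threshold for a minimum duration.

Nearby events are merged when separated by less than ``merge_gap_s``.
"""

from __future__ import annotations

import math
import warnings
from typing import List, Optional

import numpy as np
import pandas as pd

from .core import DischargeEvent, EphysRecording, OnsetRaster

# population-threshold anchors: fraction of cells that must fire together
THRESHOLD_SMALL_POP = (400, 0.0025)  # populations below 400 cells
THRESHOLD_LARGE_POP = (1100, 0.0033)  # populations of ~1100 cells

DEFAULT_WINDOW_FRAMES = 1
DEFAULT_MERGE_GAP_S = 0.5
DEFAULT_AMP_THRESH_MV = 5.0
DEFAULT_MIN_DUR_S = 0.2
EPHYS_BASELINE_WINDOW_S = 30.0


def population_threshold_fraction(n_cells: int) -> float:
    """Fraction-of-cells threshold, interpolated linearly in population size.

    Anchored at 0.25% for populations under 400 cells and 0.33% at 1100
    cells, clipped outside that range.
    """
    (n0, f0), (n1, f1) = THRESHOLD_SMALL_POP, THRESHOLD_LARGE_POP
    if n_cells <= n0:
        return f0
    if n_cells >= n1:
        return f1
    return f0 + (f1 - f0) * (n_cells - n0) / (n1 - n0)


def _runs(mask: np.ndarray) -> List[tuple]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def _merge_intervals(intervals: List[tuple], merge_gap: float) -> List[tuple]:
    """Merge (onset, offset) pairs separated by less than ``merge_gap``."""
    if not intervals:
        return []
    merged = [list(intervals[0])]
    for on, off in intervals[1:]:
        if on - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], off)
        else:
            merged.append([on, off])
    return [tuple(iv) for iv in merged]


def detect_circuit_events(
    raster: OnsetRaster,
    threshold_fraction: Optional[float] = None,
    window_frames: int = DEFAULT_WINDOW_FRAMES,
    merge_gap_s: float = DEFAULT_MERGE_GAP_S,
    area: str = "cortex",
) -> List[DischargeEvent]:
    """Detect population discharges in a binary onset raster.

    Per frame, the number of distinct cells with an onset inside the
    trailing ``window_frames`` frames is compared with
    ``ceil(threshold_fraction * n_cells)``; contiguous supra-threshold runs
    are events. ``threshold_fraction`` defaults to the population-size
    interpolation of :func:`population_threshold_fraction`.
    """
    if window_frames < 1:
        raise ValueError("window_frames must be >= 1")
    n_cells = raster.n_cells
    if threshold_fraction is None:
        threshold_fraction = population_threshold_fraction(n_cells)
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    required = math.ceil(threshold_fraction * n_cells)
    if required == 0:
        raise ValueError("threshold_fraction yields a required count of 0")
    if raster.n_frames == 0 or n_cells == 0:
        return []

    onsets = raster.onsets.astype(bool)
    if window_frames == 1:
        active = onsets
    else:
        # cell contributes at frame f if it had an onset in the trailing window
        df = pd.DataFrame(onsets.T.astype(float))
        active = (
            df.rolling(window_frames, min_periods=1).sum().to_numpy().T > 0
        )
    counts = active.sum(axis=0)

    times = raster.frame_times_s
    frame_dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0
    intervals = [
        (times[a], times[b - 1] + frame_dt) for a, b in _runs(counts >= required)
    ]
    intervals = _merge_intervals(intervals, merge_gap_s)

    events = []
    for on, off in intervals:
        in_ev = (times >= on) & (times < off)
        n_active = int((onsets[:, in_ev].any(axis=1)).sum())
        events.append(
            DischargeEvent(
                onset_s=float(on),
                offset_s=float(off),
                source="imaging",
                area=area,
                n_cells_active=n_active,
                recording_id=raster.source_recording,
            )
        )
    return events


def running_median_baseline(
    vm: np.ndarray, sample_rate_hz: float, window_s: float = EPHYS_BASELINE_WINDOW_S
) -> np.ndarray:
    """Centered running-median baseline of a voltage trace.

    Traces shorter than the window fall back to the global median (with a
    warning), since a running window would be meaningless there.
    """
    vm = np.asarray(vm, dtype=float)
    window = int(round(window_s * sample_rate_hz)) | 1  # odd: symmetric window
    if vm.size < window:
        warnings.warn(
            "trace shorter than the baseline window; using the global median"
        )
        return np.full_like(vm, np.median(vm))
    ser = pd.Series(vm)
    return ser.rolling(window, center=True, min_periods=1).median().to_numpy()


def detect_ephys_discharges(
    rec: EphysRecording,
    amp_thresh_mv: float = DEFAULT_AMP_THRESH_MV,
    min_dur_s: float = DEFAULT_MIN_DUR_S,
    merge_gap_s: float = DEFAULT_MERGE_GAP_S,
    baseline_window_s: float = EPHYS_BASELINE_WINDOW_S,
) -> List[DischargeEvent]:
    """Detect depolarizing discharges in a membrane-potential trace.

    An event is a maximal interval where Vm exceeds the running-median
    baseline by ``amp_thresh_mv`` for at least ``min_dur_s``; events closer
    than ``merge_gap_s`` are merged afterwards.
    """
    if not amp_thresh_mv > 0:
        raise ValueError("amp_thresh_mv must be > 0")
    baseline = running_median_baseline(
        rec.vm_mv, rec.sample_rate_hz, baseline_window_s
    )
    mask = rec.vm_mv > baseline + amp_thresh_mv
    dt = 1.0 / rec.sample_rate_hz
    intervals = [
        (rec.start_time_s + a * dt, rec.start_time_s + b * dt)
        for a, b in _runs(mask)
        if (b - a) * dt >= min_dur_s
    ]
    intervals = _merge_intervals(intervals, merge_gap_s)
    return [
        DischargeEvent(
            onset_s=float(on),
            offset_s=float(off),
            source="ephys",
            area=rec.area,
            recording_id=rec.cell_id,
        )
        for on, off in intervals
    ]
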