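"""Cross-area discharge coupling: matching, reliability, lags, timelines.

Coupling reliability (CR) of one recording is the fraction of cortical
epileptiform discharges that have a temporally overlapping thalamic
discharge. Matching is one-to-one: the assignment maximizes the number of
matched pairs and, among assignments of equal size, the total overlap —
solved exactly with the Hungarian algorithm. Positive lags mean cortex
leads.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import t as t_dist

from .core import (
    AlignedTimeline,
    CellEphysCorrelation,
    CouplingPoint,
    DischargeEvent,
    DischargeMatch,
    EphysRecording,
    ImagingRecording,
    require_sorted_events,
)

CORRELATED_P_THRESHOLD = 0.05
CORRELATED_R_THRESHOLD = 0.1
DEFAULT_CROSSING_THRESHOLD = 0.5
DEFAULT_BIN_MIN = 20.0


def overlap_matrix(
    cortical: Sequence[DischargeEvent], thalamic: Sequence[DischargeEvent]
) -> np.ndarray:
    """Pairwise overlap lengths, shape (n_cortical, n_thalamic)."""
    out = np.zeros((len(cortical), len(thalamic)))
    for i, c in enumerate(cortical):
        for j, t in enumerate(thalamic):
            out[i, j] = c.overlap_s(t)
    return out


def match_discharges(
    cortical: Sequence[DischargeEvent], thalamic: Sequence[DischargeEvent]
) -> List[DischargeMatch]:
    """Assign thalamic discharges to overlapping cortical discharges.

    Returns one :class:`DischargeMatch` per cortical event (in order). Each
    thalamic event is used at most once. The assignment is the exact
    optimum that first maximizes the number of overlapping pairs matched
    and then the total overlap; ``lag_s`` is thalamic onset minus cortical
    onset.
    """
    require_sorted_events(cortical, "cortical")
    require_sorted_events(thalamic, "thalamic")
    matches = [DischargeMatch(cortical_event=c) for c in cortical]
    if not cortical or not thalamic:
        return matches

    ov = overlap_matrix(cortical, thalamic)
    valid = ov > 0
    if valid.any():
        # bonus larger than any achievable total overlap makes the optimum
        # lexicographic: matched count first, then total overlap
        bonus = ov.sum() + 1.0
        score = np.where(valid, ov + bonus, 0.0)
        rows, cols = linear_sum_assignment(score, maximize=True)
        for i, j in zip(rows, cols):
            if valid[i, j]:
                matches[i] = DischargeMatch(
                    cortical_event=cortical[i],
                    thalamic_event=thalamic[j],
                    lag_s=thalamic[j].onset_s - cortical[i].onset_s,
                    overlap_s=float(ov[i, j]),
                )
    return matches


def coupling_reliability(matches: Sequence[DischargeMatch]) -> float:
    """Fraction of cortical discharges with an overlapping thalamic one.

    Raises ``ValueError`` with zero cortical events — CR is undefined
    there, not 0.
    """
    if len(matches) == 0:
        raise ValueError("CR is undefined without cortical events")
    return sum(m.matched for m in matches) / len(matches)


def lag_statistics(matches: Sequence[DischargeMatch]) -> Dict[str, float]:
    """Median corticothalamic lag and cortex-leading fraction.

    A positive lag means the discharge was detected in cortex first; exact
    zero-lag ties count as not leading.
    """
    lags = np.array([m.lag_s for m in matches if m.matched])
    if lags.size == 0:
        raise ValueError("lag statistics are undefined without matched pairs")
    return {
        "median_lag_s": float(np.median(lags)),
        "fraction_cortex_leading": float((lags > 0).mean()),
        "n_matched": int(lags.size),
    }


def _crossing_time(times: np.ndarray, values: np.ndarray, threshold: float):
    """First sampled time at which the metric reaches the threshold.

    The crossing is the first point ``>= threshold`` that follows a point
    below it; a series that starts at or above threshold crosses at its
    first point. Returns ``None`` when the metric never reaches threshold.
    """
    at_or_above = values >= threshold
    if not at_or_above.any():
        return None
    first = int(np.argmax(at_or_above))
    if first == 0:
        return float(times[0])
    # argmax finds the first True, which necessarily follows a False
    return float(times[first])


def align_timeline(
    slices: Sequence[Sequence[CouplingPoint]],
    threshold: float = DEFAULT_CROSSING_THRESHOLD,
    bin_min: float = DEFAULT_BIN_MIN,
) -> AlignedTimeline:
    """Align per-slice metric timelines at their threshold crossing and bin.

    Each slice is a time-ordered sequence of per-recording points (CR or
    fraction-correlated). Times are shifted so the slice's first
    threshold crossing sits at 0, then pooled into contiguous ``bin_min``
    bins; the bin mean/SEM are computed over per-slice bin averages. Slices
    that never reach the threshold are excluded with a warning.
    """
    aligned_times: List[np.ndarray] = []
    values: List[np.ndarray] = []
    for k, pts in enumerate(slices):
        t = np.array([p.recording_mid_time_s for p in pts], dtype=float)
        v = np.array([p.cr for p in pts], dtype=float)
        cross = _crossing_time(t, v, threshold)
        if cross is None:
            warnings.warn(f"slice {k} never crosses {threshold}; excluded")
            continue
        aligned_times.append((t - cross) / 60.0)
        values.append(v)
    if not aligned_times:
        raise ValueError("no slice crosses the threshold")

    tmin = min(t.min() for t in aligned_times)
    tmax = max(t.max() for t in aligned_times)
    lo = np.floor(tmin / bin_min) * bin_min
    hi = np.ceil(tmax / bin_min) * bin_min
    if hi <= lo:
        hi = lo + bin_min
    edges = np.arange(lo, hi + bin_min / 2, bin_min)

    n_bins = edges.size - 1
    slice_means = np.full((len(aligned_times), n_bins), np.nan)
    for s, (t, v) in enumerate(zip(aligned_times, values)):
        which = np.digitize(t, edges) - 1
        which = np.clip(which, 0, n_bins - 1)
        for b in np.unique(which):
            slice_means[s, b] = v[which == b].mean()

    n_per_bin = (~np.isnan(slice_means)).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        bin_means = np.nanmean(slice_means, axis=0)
        sds = np.nanstd(slice_means, axis=0, ddof=1)
    bin_sems = np.where(n_per_bin >= 2, sds / np.sqrt(n_per_bin), np.nan)
    return AlignedTimeline(
        aligned_times_min=aligned_times,
        values=values,
        bin_edges_min=edges,
        bin_means=bin_means,
        bin_sems=bin_sems,
        n_slices_per_bin=n_per_bin,
    )


def downsample_by_frame_average(
    ephys: EphysRecording, frame_times_s: np.ndarray
) -> np.ndarray:
    """Average voltage samples into imaging frame bins, one value per frame.

    Frame ``i`` averages all samples with time in
    ``[frame_time_i, frame_time_{i+1})``; the last frame uses the nominal
    frame period. Empty bins carry the previous frame's value (warning).
    """
    frame_times = np.asarray(frame_times_s, dtype=float)
    if frame_times.size == 0:
        return np.array([])
    sample_times = ephys.sample_times_s
    if frame_times[0] < sample_times[0] - 1e-9 or frame_times[-1] > sample_times[-1] + 1e-9:
        raise ValueError("frame times fall outside the ephys recording span")
    period = (
        float(np.median(np.diff(frame_times))) if frame_times.size > 1 else 1.0
    )
    edges = np.concatenate([frame_times, [frame_times[-1] + period]])
    # a sample within 1 ns of a frame edge belongs to the bin starting there
    idx = np.searchsorted(sample_times, edges - 1e-9, side="left")
    out = np.empty(frame_times.size)
    prev = np.nan
    empty = 0
    for i in range(frame_times.size):
        a, b = idx[i], idx[i + 1]
        if b > a:
            prev = ephys.vm_mv[a:b].mean()
        else:
            empty += 1
        out[i] = prev
    if empty:
        warnings.warn(f"{empty} empty frame bins carried the previous value")
    return out


def _pearson_with_one_sided_p(x: np.ndarray, y: np.ndarray):
    """Pearson r of each row of ``x`` with ``y``; one-sided p for r > 0."""
    n = y.size
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
        r = np.clip(r, -1.0, 1.0)
        tval = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = t_dist.sf(tval, df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), np.where(r > 0, 0.0, 1.0), p)
    bad = denom == 0
    r[bad] = np.nan
    p[bad] = np.nan
    return r, p


def fraction_correlated_cells(
    imaging: ImagingRecording,
    remote_ephys: EphysRecording,
    min_overlap_s: float = 30.0,
) -> Dict[str, Union[float, list]]:
    """Fraction of imaged cells correlated with the remote voltage trace.

    The remote trace is frame-averaged to imaging resolution; each cell's
    full-length fluorescence is correlated with it. A cell counts as
    correlated when its correlation is significantly greater than zero
    (one-sided p < 0.05) and |r| > 0.1. Constant traces are counted as not
    correlated (warning).
    """
    frame_times = imaging.frame_times_s
    span = min(
        frame_times[-1], remote_ephys.sample_times_s[-1]
    ) - max(frame_times[0], remote_ephys.sample_times_s[0])
    if span < min_overlap_s:
        raise ValueError(
            f"overlapping time span {span:.1f}s is shorter than {min_overlap_s}s"
        )
    keep = (frame_times >= remote_ephys.sample_times_s[0]) & (
        frame_times <= remote_ephys.sample_times_s[-1]
    )
    vm_frames = downsample_by_frame_average(remote_ephys, frame_times[keep])
    traces = imaging.fluorescence[:, keep]

    r, p = _pearson_with_one_sided_p(traces, vm_frames)
    if np.isnan(r).any():
        warnings.warn("constant trace(s): correlation undefined, not correlated")
    correlated = (
        (p < CORRELATED_P_THRESHOLD)
        & (np.abs(r) > CORRELATED_R_THRESHOLD)
        & ~np.isnan(r)
    )
    cells = [
        CellEphysCorrelation(
            cell_id=i, r=float(r[i]), p_value=float(p[i]), correlated=bool(correlated[i])
        )
        for i in range(imaging.n_cells)
    ]
    return {"fraction": float(correlated.mean()), "cells": cells}
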