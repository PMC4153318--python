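"""Intracortical pairwise correlation before vs. after thalamic recruitment.

Workflow: per cell, event-aligned z-scored fluorescence (signal strength
relative to the 2-s pre-event baseline) feeds a permutation test on the
regression slope of z over time — cells whose slope falls outside the
10th–90th percentile of the shuffled-slope distribution show drifting
signal strength (e.g. bleaching) and are discarded. Surviving cells'
traces are detrended (30-s running median) and smoothed (3-frame moving
average); Pearson correlations of the filtered traces, per condition, are
binned by intersomatic distance in 100-μm bins with SEM computed on the
number of unique cells in each bin.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .core import (
    EphysRecording,
    EventZScoreSeries,
    ImagingRecording,
    PairCorrelation,
    SpatialProfile,
)
from .events import running_median_baseline

DEFAULT_BASELINE_WINDOW_S = 2.0
DEFAULT_N_SHUFFLES = 1000
EXACT_ENUMERATION_MAX_EVENTS = 6
SHUFFLE_PERCENTILES = (10.0, 90.0)
FILTER_MEDIAN_WINDOW_S = 30.0
FILTER_SMOOTH_FRAMES = 3
DEFAULT_BIN_UM = 100.0


def event_zscores(
    trace: np.ndarray,
    frame_times_s: np.ndarray,
    event_times_s: Sequence[float],
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
    cell_id: int = 0,
) -> EventZScoreSeries:
    """Event-aligned z-scored fluorescence of one cell.

    For each event at time ``t_i``, ``z = (F(t_i) - <F_b>) / sigma_Fb``
    where ``F(t_i)`` is the fluorescence at the frame nearest ``t_i`` and
    the baseline mean/SD (sample SD, n-1) are taken over the frames in the
    ``baseline_window_s`` seconds preceding ``t_i``. Events without a full
    baseline window, with fewer than two baseline frames, or with zero
    baseline SD are skipped with a warning.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    frame_times = np.asarray(frame_times_s, dtype=float).ravel()
    kept_t, zs, means, sds = [], [], [], []
    skipped = 0
    for t_i in event_times_s:
        if t_i - baseline_window_s < frame_times[0] - 1e-9 or t_i > frame_times[-1]:
            skipped += 1
            continue
        # 1 ns tolerance so frames landing exactly on the window edges are
        # classified consistently despite float rounding
        base = (frame_times >= t_i - baseline_window_s - 1e-9) & (
            frame_times < t_i - 1e-9
        )
        if base.sum() < 2:
            skipped += 1
            continue
        mu = trace[base].mean()
        sd = trace[base].std(ddof=1)
        if sd == 0:
            skipped += 1
            continue
        f_i = trace[int(np.argmin(np.abs(frame_times - t_i)))]
        kept_t.append(float(t_i))
        zs.append((f_i - mu) / sd)
        means.append(mu)
        sds.append(sd)
    if skipped:
        warnings.warn(f"{skipped} events skipped (short baseline or zero SD)")
    return EventZScoreSeries(
        cell_id=cell_id,
        event_times_s=np.array(kept_t),
        z_values=np.array(zs),
        baseline_means=np.array(means),
        baseline_sds=np.array(sds),
    )


def _slope_weights(t: np.ndarray) -> np.ndarray:
    """Least-squares slope of y on t is ``w @ y`` with these weights."""
    tc = t - t.mean()
    return tc / (tc**2).sum()


def stationarity_filter(
    series: EventZScoreSeries,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: Optional[int] = None,
) -> EventZScoreSeries:
    """Permutation test for a trend in event-aligned signal strength.

    The empirical regression slope of z on event time is compared with the
    distribution of slopes obtained by permuting the z values across the
    fixed event times. The cell is stationary when the slope lies within
    the 10th–90th percentiles of that distribution. With six or fewer
    events all permutations are enumerated exactly; otherwise
    ``n_shuffles`` random permutations are drawn from ``seed``.
    """
    t = np.asarray(series.event_times_s, dtype=float)
    z = np.asarray(series.z_values, dtype=float)
    if t.size < 3:
        raise ValueError("stationarity test needs at least 3 usable events")
    w = _slope_weights(t)
    slope = float(w @ z)

    if t.size <= EXACT_ENUMERATION_MAX_EVENTS:
        perms = np.array(list(itertools.permutations(z)))
    else:
        rng = np.random.default_rng(seed)
        perms = rng.permuted(np.tile(z, (n_shuffles, 1)), axis=1)
    shuffled = perms @ w
    p10, p90 = np.percentile(shuffled, SHUFFLE_PERCENTILES)

    series.slope = slope
    series.shuffle_p10 = float(p10)
    series.shuffle_p90 = float(p90)
    # numerical guard: a slope equal to a band edge up to rounding is inside
    tol = 1e-9 * max(1.0, float(np.abs(shuffled).max()))
    series.stationary = bool(p10 - tol <= slope <= p90 + tol)
    return series


def filter_trace(trace: np.ndarray, frame_rate_hz: float) -> np.ndarray:
    """Detrend (30-s running median) and smooth (3-frame moving average).

    Output length equals input length; edge frames use shrunken windows.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    detrended = trace - running_median_baseline(
        trace, frame_rate_hz, FILTER_MEDIAN_WINDOW_S
    )
    kernel = np.ones(FILTER_SMOOTH_FRAMES)
    num = np.convolve(detrended, kernel, mode="same")
    den = np.convolve(np.ones_like(detrended), kernel, mode="same")
    return num / den


def _active_in_any_event(
    rasters, events, n_cells: int
) -> np.ndarray:
    """Boolean mask of cells with >= 1 onset inside any event interval."""
    active = np.zeros(n_cells, dtype=bool)
    for raster in rasters:
        times = raster.frame_times_s
        in_any = np.zeros(raster.n_frames, dtype=bool)
        for ev in events:
            in_any |= (times >= ev.onset_s) & (times < ev.offset_s)
        active |= raster.onsets[:, in_any].astype(bool).any(axis=1)
    return active


def stationary_cells(
    recordings: Sequence[ImagingRecording],
    event_times_s: Sequence[float],
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: Optional[int] = None,
    min_events: int = 3,
) -> np.ndarray:
    """Mask of cells passing the stationarity filter across the experiment.

    The z-series of each cell pools all events from all recordings, each
    event z-scored against its own recording's trace. Cells with fewer
    than ``min_events`` usable events are excluded (mask False) and counted
    separately via the returned mask's complement.
    """
    n_cells = recordings[0].n_cells
    mask = np.zeros(n_cells, dtype=bool)
    for c in range(n_cells):
        ts, zs = [], []
        for rec in recordings:
            evs = [
                t
                for t in event_times_s
                if rec.frame_times_s[0] <= t <= rec.frame_times_s[-1]
            ]
            if not evs:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ser = event_zscores(
                    rec.fluorescence[c], rec.frame_times_s, evs, cell_id=c
                )
            ts.append(ser.event_times_s)
            zs.append(ser.z_values)
        t = np.concatenate(ts) if ts else np.array([])
        z = np.concatenate(zs) if zs else np.array([])
        if t.size < min_events:
            continue
        ser = EventZScoreSeries(
            cell_id=c,
            event_times_s=t,
            z_values=z,
            baseline_means=np.array([]),
            baseline_sds=np.array([]),
        )
        mask[c] = stationarity_filter(
            ser, n_shuffles=n_shuffles, seed=None if seed is None else seed + c
        ).stationary
    return mask


def pairwise_correlations(
    recordings_before: Sequence[ImagingRecording],
    recordings_after: Sequence[ImagingRecording],
    rasters_before=None,
    rasters_after=None,
    events_before=None,
    events_after=None,
    n_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: Optional[int] = None,
) -> List[PairCorrelation]:
    """Pairwise correlations of filtered traces before vs. after recruitment.

    Requires at least two recordings per condition. When rasters and events
    are supplied, cells must be active in at least one event in each
    condition and pass the stationarity filter (pooled over all events);
    otherwise all cells are eligible. Per condition, each recording's
    traces are filtered and concatenated in time before computing one
    Pearson r per cell pair.
    """
    if len(recordings_before) < 2 or len(recordings_after) < 2:
        raise ValueError("need at least two recordings per condition")
    n_cells = recordings_before[0].n_cells
    coords = recordings_before[0].coords_um

    eligible = np.ones(n_cells, dtype=bool)
    if rasters_before is not None and events_before is not None:
        eligible &= _active_in_any_event(rasters_before, events_before, n_cells)
    if rasters_after is not None and events_after is not None:
        eligible &= _active_in_any_event(rasters_after, events_after, n_cells)
    if events_before is not None or events_after is not None:
        all_events = sorted(
            [e.onset_s for e in (list(events_before or []) + list(events_after or []))]
        )
        if all_events:
            eligible &= stationary_cells(
                list(recordings_before) + list(recordings_after),
                all_events,
                n_shuffles=n_shuffles,
                seed=seed,
            )
    idx = np.flatnonzero(eligible)
    if idx.size < 2:
        raise ValueError("fewer than two eligible cells")

    def condition_r(recordings) -> np.ndarray:
        chunks = []
        for rec in recordings:
            filt = np.vstack(
                [filter_trace(rec.fluorescence[c], rec.frame_rate_hz) for c in idx]
            )
            chunks.append(filt)
        data = np.hstack(chunks)
        return np.corrcoef(data)

    r_before = condition_r(recordings_before)
    r_after = condition_r(recordings_after)

    pairs = []
    for a_pos, b_pos in itertools.combinations(range(idx.size), 2):
        a, b = int(idx[a_pos]), int(idx[b_pos])
        pairs.append(
            PairCorrelation(
                cell_a=a,
                cell_b=b,
                distance_um=float(np.linalg.norm(coords[a] - coords[b])),
                r_before=float(r_before[a_pos, b_pos]),
                r_after=float(r_after[a_pos, b_pos]),
            )
        )
    return pairs


def spatial_profile(
    pairs: Sequence[PairCorrelation],
    condition: str = "before",
    bin_um: float = DEFAULT_BIN_UM,
) -> SpatialProfile:
    """Distance-binned mean pairwise correlation.

    Pairs fall into contiguous bins [0, bin), [bin, 2·bin), …; per bin the
    mean correlation is reported with SEM = sample SD of the pair
    correlations divided by sqrt(number of unique cells in the bin) —
    unique cells, not pairs, set the degrees of freedom because one cell
    contributes to many pairs.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    if condition not in ("before", "after"):
        raise ValueError("condition must be 'before' or 'after'")
    rs = np.array(
        [p.r_before if condition == "before" else p.r_after for p in pairs]
    )
    dist = np.array([p.distance_um for p in pairs])
    n_bins = int(math.floor(dist.max() / bin_um)) + 1
    edges = np.arange(n_bins + 1) * bin_um
    which = np.minimum((dist // bin_um).astype(int), n_bins - 1)

    means = np.full(n_bins, np.nan)
    sems = np.full(n_bins, np.nan)
    n_pairs = np.zeros(n_bins, dtype=int)
    n_unique = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        n_pairs[b] = int(sel.sum())
        if n_pairs[b] == 0:
            continue
        cells = set()
        for p, s in zip(pairs, sel):
            if s:
                cells.update((p.cell_a, p.cell_b))
        n_unique[b] = len(cells)
        means[b] = rs[sel].mean()
        if n_pairs[b] >= 2:
            sems[b] = rs[sel].std(ddof=1) / math.sqrt(n_unique[b])
        else:
            sems[b] = 0.0 if n_unique[b] else np.nan
    return SpatialProfile(
        bin_edges_um=edges,
        bin_mean_r=means,
        bin_sem_r=sems,
        n_pairs_per_bin=n_pairs,
        n_unique_cells_per_bin=n_unique,
    )


def before_after_test(pairs: Sequence[PairCorrelation]) -> Dict[str, float]:
    """Paired test of the per-pair correlation change across recruitment.

    Reports the mean of ``r_before - r_after`` (negative when correlations
    rise after recruitment) and a two-sided Wilcoxon signed-rank p-value.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    d = np.array([p.r_before - p.r_after for p in pairs])
    if np.all(d == 0):
        return {"mean_diff": 0.0, "p_value": 1.0}
    stat = stats.wilcoxon(d)
    return {"mean_diff": float(d.mean()), "p_value": float(stat.pvalue)}


def dual_patch_zero_lag(ephys_a: EphysRecording, ephys_b: EphysRecording) -> float:
    """Zero-lag Pearson correlation of two simultaneous voltage traces.

    Traces of unequal length are truncated to the common overlap with a
    warning; both traces are mean-removed first.
    """
    if ephys_a.sample_rate_hz != ephys_b.sample_rate_hz:
        raise ValueError("sample rates must match")
    a, b = ephys_a.vm_mv, ephys_b.vm_mv
    if a.size != b.size:
        warnings.warn("length mismatch; truncating to the common overlap")
        n = min(a.size, b.size)
        a, b = a[:n], b[:n]
    a = a - a.mean()
    b = b - b.mean()
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


def group_compare(group1: Sequence[float], group2: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value on per-slice correlation values."""
    return float(stats.ranksums(group1, group2).pvalue)
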