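"""Per-discharge intensity in cortex and thalamus and their correlation.

Cortical intensity of a discharge is the fraction of "ever-active" cells
(cells with at least one onset in any recording from the same field of
view) that fire during the discharge. Thalamic intensity is the area under
the depolarization curve (mV·s) above the running-median baseline during
the discharge. A field of view counts as intensity-coupled when the Pearson
correlation between the two intensities across discharges is significantly
different from zero (two-sided p < 0.05).
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
from scipy import stats

from .core import DischargeEvent, DischargeMatch, EphysRecording, IntensityPair, OnsetRaster
from .events import EPHYS_BASELINE_WINDOW_S, running_median_baseline

SIGNIFICANCE_P = 0.05


def ever_active_cells(rasters: Sequence[OnsetRaster]) -> Set[int]:
    """Cells with at least one onset in any recording of one field of view."""
    if not rasters:
        raise ValueError("need at least one raster")
    active: Set[int] = set()
    for raster in rasters:
        active.update(np.flatnonzero(raster.onsets.any(axis=1)).tolist())
    return active


def cortical_intensity(
    event: DischargeEvent, raster: OnsetRaster, ever_active: Set[int]
) -> float:
    """Fraction of ever-active cells with an onset during the discharge."""
    if not ever_active:
        raise ValueError("ever_active must be nonempty")
    times = raster.frame_times_s
    if event.onset_s > times[-1] or event.offset_s < times[0]:
        raise ValueError("event lies outside the raster's time span")
    in_ev = (times >= event.onset_s) & (times < event.offset_s)
    active = set(np.flatnonzero(raster.onsets[:, in_ev].any(axis=1)).tolist())
    return len(active & ever_active) / len(ever_active)


def thalamic_intensity(
    event: DischargeEvent,
    ephys: EphysRecording,
    baseline_window_s: float = EPHYS_BASELINE_WINDOW_S,
    baseline: Optional[np.ndarray] = None,
) -> float:
    """Depolarization area (mV·s) above baseline during the discharge.

    Trapezoidal integral of ``max(Vm - baseline, 0)`` over the event
    window; excursions below baseline contribute nothing rather than
    cancelling depolarization.
    """
    t = ephys.sample_times_s
    if event.onset_s < t[0] - 1e-9 or event.offset_s > t[-1] + 1e-9:
        raise ValueError("event lies outside the ephys recording span")
    if baseline is None:
        baseline = running_median_baseline(
            ephys.vm_mv, ephys.sample_rate_hz, baseline_window_s
        )
    depol = np.clip(ephys.vm_mv - baseline, 0.0, None)
    sel = (t >= event.onset_s) & (t <= event.offset_s)
    if sel.sum() < 2:
        return 0.0
    return float(np.trapezoid(depol[sel], t[sel]))


def intensity_pairs_from_matches(
    matches: Sequence[DischargeMatch],
    raster: OnsetRaster,
    ever_active: Set[int],
    ephys: EphysRecording,
) -> List[IntensityPair]:
    """Build per-discharge intensity pairs from matched discharges.

    The measurement window is the cortical event's interval, extended to
    the matched thalamic offset when that is later (the thalamic discharge
    lags cortex; truncating at the cortical offset would bias the AUC low).
    Only matched discharges contribute a pair.
    """
    baseline = running_median_baseline(ephys.vm_mv, ephys.sample_rate_hz)
    out = []
    for k, m in enumerate(matches):
        if not m.matched:
            continue
        offset = max(m.cortical_event.offset_s, m.thalamic_event.offset_s)
        window = DischargeEvent(
            onset_s=m.cortical_event.onset_s,
            offset_s=min(offset, float(ephys.sample_times_s[-1])),
            source="ephys",
            area="thalamus",
        )
        out.append(
            IntensityPair(
                event_id=k,
                cortical_fraction=cortical_intensity(
                    m.cortical_event, raster, ever_active
                ),
                thalamic_auc=thalamic_intensity(window, ephys, baseline=baseline),
            )
        )
    return out


def intensity_correlation(pairs: Sequence[IntensityPair]) -> Dict[str, float]:
    """Pearson correlation of cortical vs. thalamic discharge intensities."""
    if len(pairs) < 3:
        raise ValueError("need at least three intensity pairs")
    x = np.array([p.cortical_fraction for p in pairs])
    y = np.array([p.thalamic_auc for p in pairs])
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance in intensities; correlation undefined")
        return {"r": float("nan"), "p_value": float("nan"), "significant": False}
    res = stats.pearsonr(x, y)
    return {
        "r": float(res.statistic),
        "p_value": float(res.pvalue),
        "significant": bool(res.pvalue < SIGNIFICANCE_P),
    }
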