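"""End-to-end run: simulate (or ingest) → infer → detect → couple → report.

A run covers one simulated slice session: ground truth is drawn over the
whole session, two-minute recordings are rendered at regular intervals in
both areas (imaging + patch), and every analysis stage of the package is
applied in order. All intermediate artifacts (rasters, event tables,
matches, coupling timeline, pair tables, intensity tables) and a summary
report (JSON + human-readable text) are written to the output directory.

Two runs with the same configuration and seed produce byte-identical
outputs; the run log echoes every parameter in force.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io
from .core import AREA_CORTEX, AREA_THALAMUS, CouplingPoint
from .coupling import (
    align_timeline,
    coupling_reliability,
    fraction_correlated_cells,
    lag_statistics,
    match_discharges,
)
from .circuit import (
    before_after_test,
    pairwise_correlations,
    spatial_profile,
)
from .events import detect_circuit_events, detect_ephys_discharges
from .intensity import (
    ever_active_cells,
    intensity_correlation,
    intensity_pairs_from_matches,
)
from .onsets import infer_onsets
from .synthetic import (
    ExperimentConfig,
    generate_event_schedule,
    render_ephys,
    render_fluorescence,
)

logger = logging.getLogger("tcss")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one input mode is active: a synthetic experiment (default) or a
    pre-recorded HDF5 container (``input_h5``). Session parameters place
    repeated two-minute recordings inside a longer experiment; stage
    parameters are forwarded to the corresponding analysis functions.
    """

    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    input_h5: Optional[str] = None
    session_duration_s: float = 4800.0
    recording_interval_s: float = 600.0
    # analysis-stage parameters
    decay_s: float = 1.0
    k_mad: float = 3.0
    noise_scale: Optional[float] = 3.0
    threshold_fraction: Optional[float] = None
    window_frames: int = 1
    merge_gap_s: float = 0.5
    amp_thresh_mv: float = 5.0
    min_dur_s: float = 0.2
    n_shuffles: int = 200
    crossing_threshold: float = 0.5
    bin_min: float = 20.0
    outdir: str = "tcss-run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        exp = ExperimentConfig(**data.pop("experiment", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown run-config fields: {sorted(unknown)}")
        return cls(experiment=exp, **data)

    def recording_starts(self) -> np.ndarray:
        rec_dur = self.experiment.duration_s
        return np.arange(0.0, self.session_duration_s - rec_dur + 1e-9,
                         self.recording_interval_s)


def _log_config(cfg: RunConfig) -> None:
    logger.info("run configuration (all parameters in force):")
    for f in dataclasses.fields(cfg):
        value = getattr(cfg, f.name)
        if dataclasses.is_dataclass(value):
            for g in dataclasses.fields(value):
                logger.info("  experiment.%s = %r", g.name, getattr(value, g.name))
        else:
            logger.info("  %s = %r", f.name, value)


def run_pipeline(cfg: RunConfig) -> Dict:
    """Execute every stage on one (synthetic) session and write the report.

    Returns the summary dictionary that is also written to
    ``<outdir>/summary.json``. Any stage failure raises with the stage name
    in the message.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(cfg, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _run(cfg: RunConfig, outdir: Path) -> Dict:
    _log_config(cfg)
    exp = cfg.experiment
    starts = cfg.recording_starts()
    rec_dur = exp.duration_s

    # ---- stage: simulate / ingest ------------------------------------
    if cfg.input_h5 is not None:
        raise NotImplementedError(
            "container ingest is provided via tcss.io.read_recording_h5; "
            "the end-to-end pipeline currently drives the synthetic generator"
        )
    truth = _stage("simulate")(generate_event_schedule)(
        exp, duration_s=cfg.session_duration_s
    )
    logger.info("simulate: %d ground-truth events, %d coupled",
                truth.n_events, int(np.asarray(truth.thalamic_coupled).sum()))
    io.write_ground_truth_json(outdir / "ground_truth.json", truth)

    imaging = {AREA_CORTEX: [], AREA_THALAMUS: []}
    ephys = {AREA_CORTEX: [], AREA_THALAMUS: []}
    for start in starts:
        for area in (AREA_CORTEX, AREA_THALAMUS):
            imaging[area].append(
                render_fluorescence(truth, exp, area, start_time_s=start,
                                    duration_s=rec_dur)
            )
            ephys[area].append(
                render_ephys(truth, exp, area, start_time_s=start,
                             duration_s=rec_dur,
                             cell_id=f"{area}-patch-{start:.0f}s")
            )

    # ---- stage: onset inference --------------------------------------
    infer = _stage("onset-inference")(infer_onsets)
    rasters = {
        area: [
            infer(rec, decay_s=cfg.decay_s, k_mad=cfg.k_mad,
                  noise_scale=cfg.noise_scale)
            for rec in imaging[area]
        ]
        for area in imaging
    }
    for area in rasters:
        for raster in rasters[area]:
            io.write_raster_csv(
                outdir / f"raster-{raster.source_recording}.csv", raster
            )

    # ---- stage: event detection --------------------------------------
    det_img = _stage("event-detection")(detect_circuit_events)
    det_eph = _stage("event-detection")(detect_ephys_discharges)
    events_img = {
        area: [
            det_img(r, threshold_fraction=cfg.threshold_fraction,
                    window_frames=cfg.window_frames,
                    merge_gap_s=cfg.merge_gap_s, area=area)
            for r in rasters[area]
        ]
        for area in rasters
    }
    events_eph = {
        area: [
            det_eph(r, amp_thresh_mv=cfg.amp_thresh_mv,
                    min_dur_s=cfg.min_dur_s, merge_gap_s=cfg.merge_gap_s)
            for r in ephys[area]
        ]
        for area in ephys
    }
    all_events = [e for area in events_img for evs in events_img[area] for e in evs]
    all_events += [e for area in events_eph for evs in events_eph[area] for e in evs]
    io.write_events_tsv(outdir / "events.tsv", sorted(all_events, key=lambda e: e.onset_s))
    for area in events_eph:
        logger.info("event-detection: %s ephys events per recording: %s", area,
                    [len(evs) for evs in events_eph[area]])

    # ---- stage: coupling ---------------------------------------------
    match = _stage("coupling")(match_discharges)
    cr_points: List[CouplingPoint] = []
    all_matches = []
    for k, start in enumerate(starts):
        matches = match(events_eph[AREA_CORTEX][k], events_eph[AREA_THALAMUS][k])
        all_matches.extend(matches)
        if matches:
            cr_points.append(
                CouplingPoint(
                    recording_mid_time_s=start + rec_dur / 2,
                    cr=coupling_reliability(matches),
                    n_cortical_events=len(matches),
                )
            )
    io.write_matches_tsv(outdir / "matches.tsv", all_matches)
    cr_df = pd.DataFrame(
        {
            "mid_time_s": [p.recording_mid_time_s for p in cr_points],
            "cr": [p.cr for p in cr_points],
            "n_cortical_events": [p.n_cortical_events for p in cr_points],
        }
    )
    cr_df.to_csv(outdir / "cr_timeline.tsv", sep="\t", index=False)

    matched = [m for m in all_matches if m.matched]
    lag_stats = lag_statistics(matched) if matched else None
    cr_timeline = None
    if any(p.cr >= cfg.crossing_threshold for p in cr_points):
        cr_timeline = align_timeline([cr_points], threshold=cfg.crossing_threshold,
                                     bin_min=cfg.bin_min)

    # fraction of thalamic cells correlated with the cortical patch
    frac = _stage("coupling")(fraction_correlated_cells)
    frac_points = []
    for k, start in enumerate(starts):
        res = frac(imaging[AREA_THALAMUS][k], ephys[AREA_CORTEX][k])
        frac_points.append(
            CouplingPoint(
                recording_mid_time_s=start + rec_dur / 2,
                cr=res["fraction"],
                n_cortical_events=len(events_eph[AREA_CORTEX][k]),
            )
        )
    frac_df = pd.DataFrame(
        {
            "mid_time_s": [p.recording_mid_time_s for p in frac_points],
            "fraction_correlated": [p.cr for p in frac_points],
        }
    )
    frac_df.to_csv(outdir / "fraction_correlated_timeline.tsv", sep="\t", index=False)
    frac_timeline = None
    if any(p.cr >= cfg.crossing_threshold for p in frac_points):
        frac_timeline = align_timeline([frac_points],
                                       threshold=cfg.crossing_threshold,
                                       bin_min=cfg.bin_min)

    # ---- stage: circuit correlation ----------------------------------
    circuit_summary = None
    recruit_time = _first_crossing(cr_points, cfg.crossing_threshold)
    if recruit_time is not None:
        before_idx = [k for k, p in enumerate(cr_points)
                      if p.recording_mid_time_s < recruit_time]
        after_idx = [k for k, p in enumerate(cr_points)
                     if p.recording_mid_time_s >= recruit_time]
        if len(before_idx) >= 2 and len(after_idx) >= 2:
            corr = _stage("circuit-correlation")(pairwise_correlations)
            pairs = corr(
                [imaging[AREA_CORTEX][k] for k in before_idx],
                [imaging[AREA_CORTEX][k] for k in after_idx],
                rasters_before=[rasters[AREA_CORTEX][k] for k in before_idx],
                rasters_after=[rasters[AREA_CORTEX][k] for k in after_idx],
                events_before=[e for k in before_idx
                               for e in events_img[AREA_CORTEX][k]],
                events_after=[e for k in after_idx
                              for e in events_img[AREA_CORTEX][k]],
                n_shuffles=cfg.n_shuffles,
                seed=exp.seed,
            )
            logger.info("circuit-correlation: %d eligible pairs", len(pairs))
            pd.DataFrame(
                {
                    "cell_a": [p.cell_a for p in pairs],
                    "cell_b": [p.cell_b for p in pairs],
                    "distance_um": [f"{p.distance_um:.2f}" for p in pairs],
                    "r_before": [f"{p.r_before:.6f}" for p in pairs],
                    "r_after": [f"{p.r_after:.6f}" for p in pairs],
                }
            ).to_csv(outdir / "pair_correlations.tsv", sep="\t", index=False)
            profiles = {}
            for cond in ("before", "after"):
                prof = spatial_profile(pairs, condition=cond)
                profiles[cond] = prof
                pd.DataFrame(
                    {
                        "bin_start_um": prof.bin_edges_um[:-1],
                        "bin_end_um": prof.bin_edges_um[1:],
                        "mean_r": prof.bin_mean_r,
                        "sem_r": prof.bin_sem_r,
                        "n_pairs": prof.n_pairs_per_bin,
                        "n_unique_cells": prof.n_unique_cells_per_bin,
                    }
                ).to_csv(outdir / f"spatial_profile_{cond}.tsv", sep="\t",
                         index=False)
            test = before_after_test(pairs)
            circuit_summary = {
                "n_pairs": len(pairs),
                "mean_diff_before_minus_after": test["mean_diff"],
                "p_value": test["p_value"],
                "mean_r_before": float(np.mean([p.r_before for p in pairs])),
                "mean_r_after": float(np.mean([p.r_after for p in pairs])),
            }
        else:
            logger.warning(
                "circuit-correlation skipped: need >=2 recordings per condition"
            )
    else:
        logger.warning("circuit-correlation skipped: CR never crosses threshold")

    # ---- stage: intensity coupling -----------------------------------
    intensity_summary = None
    cortex_rasters = rasters[AREA_CORTEX]
    ever = ever_active_cells(cortex_rasters)
    pairs_int = []
    for k in range(len(starts)):
        matches = match(events_img[AREA_CORTEX][k], events_eph[AREA_THALAMUS][k])
        pairs_int.extend(
            intensity_pairs_from_matches(
                matches, cortex_rasters[k], ever, ephys[AREA_THALAMUS][k]
            )
        )
    if len(pairs_int) >= 3:
        stats = _stage("intensity")(intensity_correlation)(pairs_int)
        intensity_summary = {"n_discharges": len(pairs_int), **stats}
        pd.DataFrame(
            {
                "event_id": range(len(pairs_int)),
                "cortical_fraction": [f"{p.cortical_fraction:.6f}" for p in pairs_int],
                "thalamic_auc_mv_s": [f"{p.thalamic_auc:.6f}" for p in pairs_int],
            }
        ).to_csv(outdir / "intensity_pairs.tsv", sep="\t", index=False)
    else:
        logger.warning("intensity stage skipped: fewer than 3 matched discharges")

    # ---- report ------------------------------------------------------
    summary = {
        "n_recordings": int(len(starts)),
        "cr_per_recording": [round(p.cr, 6) for p in cr_points],
        "cr_timeline": _timeline_dict(cr_timeline),
        "lag_stats": lag_stats,
        "fraction_correlated_per_recording": [round(p.cr, 6) for p in frac_points],
        "fraction_correlated_timeline": _timeline_dict(frac_timeline),
        "circuit_correlation": circuit_summary,
        "intensity_coupling": intensity_summary,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (outdir / "report.txt").write_text(_render_report(summary))
    logger.info("pipeline complete")
    return summary


def _first_crossing(points: List[CouplingPoint], threshold: float):
    below_seen = False
    for p in points:
        if p.cr >= threshold and (below_seen or p is points[0]):
            return p.recording_mid_time_s
        if p.cr < threshold:
            below_seen = True
    for p in points:  # series that starts above threshold
        if p.cr >= threshold:
            return p.recording_mid_time_s
    return None


def _timeline_dict(tl):
    if tl is None:
        return None
    return {
        "bin_edges_min": np.asarray(tl.bin_edges_min).tolist(),
        "bin_means": [None if np.isnan(v) else round(float(v), 6)
                      for v in tl.bin_means],
        "bin_sems": [None if np.isnan(v) else round(float(v), 6)
                     for v in tl.bin_sems],
        "n_slices_per_bin": np.asarray(tl.n_slices_per_bin).tolist(),
    }


def _render_report(summary: Dict) -> str:
    lines = ["thalamocortical seizure-spread analysis — run summary", ""]
    lines.append(f"recordings analysed: {summary['n_recordings']}")
    lines.append(
        "coupling reliability per recording: "
        + ", ".join(f"{v:.3f}" for v in summary["cr_per_recording"])
    )
    if summary["lag_stats"]:
        ls = summary["lag_stats"]
        lines.append(
            f"median corticothalamic lag: {ls['median_lag_s']*1000:.1f} ms "
            f"({ls['n_matched']} matched discharges, "
            f"cortex leading in {ls['fraction_cortex_leading']*100:.1f}%)"
        )
    lines.append(
        "fraction of thalamic cells correlated with cortex, per recording: "
        + ", ".join(f"{v:.3f}" for v in summary["fraction_correlated_per_recording"])
    )
    cc = summary["circuit_correlation"]
    if cc:
        lines.append(
            f"cortical pairwise correlation: mean r {cc['mean_r_before']:.3f} before "
            f"vs {cc['mean_r_after']:.3f} after recruitment "
            f"(paired Wilcoxon p = {cc['p_value']:.2e}, {cc['n_pairs']} pairs)"
        )
    ic = summary["intensity_coupling"]
    if ic:
        lines.append(
            f"cortico-thalamic intensity correlation: r = {ic['r']:.3f} "
            f"(p = {ic['p_value']:.2e}, {ic['n_discharges']} discharges, "
            f"significant: {ic['significant']})"
        )
    return "\n".join(lines) + "\n"
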