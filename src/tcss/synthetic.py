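"""Synthetic two-area slice experiments with known ground truth.

The generator emulates the statistical structure of paired
imaging/electrophysiology recordings from an acutely hyperexcitable
thalamocortical slice:

* recurring epileptiform discharges in cortex (renewal process with a
  refractory floor),
* a time-varying probability that each cortical discharge recruits thalamus,
  with recruited (coupled) discharges lagging cortex by a positive,
  right-skewed (log-normal) delay,
* per-cell discharge participation with spatial structure — each event
  activates a few Gaussian "hotspots", so nearby cells participate together,
* a shared per-event strength that scales participation in both areas, which
  makes discharge intensity correlated across areas; an optional
  participation schedule lets recruited epochs carry higher shared
  participation (the local-coherence change that accompanies recruitment),
* calcium fluorescence rendered by an AR(1) (exponential-decay) forward
  model with additive Gaussian noise and optional linear bleaching drift,
* membrane potential rendered as a baseline plus a rise–plateau–decay
  depolarizing envelope per discharge, with additive Gaussian noise.

Every random stage draws from its own stream derived from the single
configured seed, so regenerating any one artifact is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Union

import numpy as np

from .core import AREA_CORTEX, AREA_THALAMUS, EphysRecording, ImagingRecording

ScheduleLike = Union[Callable[[float], float], dict, float]

# stream indices for the splittable per-stage RNGs
_STREAM_SCHEDULE = 0
_STREAM_FLUOR = {AREA_CORTEX: 1, AREA_THALAMUS: 2}
_STREAM_EPHYS = {AREA_CORTEX: 3, AREA_THALAMUS: 4}

_SPIKE_JITTER_S = 0.05  # per-cell onset jitter within a discharge
_N_HOTSPOTS = 3  # Gaussian participation hotspots per event
# shared per-event intensity scale; the range sets how strongly discharge
# intensity covaries across areas (median cross-area r ≈ 0.7 at defaults)
_EVENT_STRENGTH_RANGE = (0.2, 1.0)
_VM_BASELINE_MV = -65.0


def constant_schedule(p: float) -> Callable[[float], float]:
    """Coupling probability fixed at ``p`` for all times."""
    return lambda t: p


def step_schedule(t0_s: float, before: float = 0.0, after: float = 1.0):
    """Coupling probability jumping from ``before`` to ``after`` at ``t0_s``."""
    return lambda t: after if t >= t0_s else before


def sigmoid_schedule(t0_s: float, width_s: float, lo: float = 0.0, hi: float = 1.0):
    """Smooth logistic transition from ``lo`` to ``hi`` centred at ``t0_s``."""
    return lambda t: lo + (hi - lo) / (1.0 + math.exp(-(t - t0_s) / width_s))


def make_schedule(spec: ScheduleLike) -> Callable[[float], float]:
    """Build a coupling schedule from a callable, a constant, or a dict spec.

    Dict specs (YAML-friendly): ``{"kind": "constant", "p": 0.5}``,
    ``{"kind": "step", "t0_s": 600, "before": 0, "after": 1}``,
    ``{"kind": "sigmoid", "t0_s": 600, "width_s": 120, "lo": 0, "hi": 1}``.
    """
    if callable(spec):
        return spec
    if isinstance(spec, (int, float)):
        return constant_schedule(float(spec))
    if isinstance(spec, dict):
        kind = spec.get("kind")
        if kind == "constant":
            return constant_schedule(float(spec["p"]))
        if kind == "step":
            return step_schedule(
                float(spec["t0_s"]),
                float(spec.get("before", 0.0)),
                float(spec.get("after", 1.0)),
            )
        if kind == "sigmoid":
            return sigmoid_schedule(
                float(spec["t0_s"]),
                float(spec.get("width_s", 60.0)),
                float(spec.get("lo", 0.0)),
                float(spec.get("hi", 1.0)),
            )
        raise ValueError(f"unknown schedule kind {kind!r}")
    raise TypeError(f"cannot build a schedule from {type(spec)}")


@dataclass
class ExperimentConfig:
    """Parameters of one synthetic two-area experiment.

    Defaults describe a two-minute recording from a juvenile-mouse
    thalamocortical slice under zero-Mg²⁺-like hyperexcitability: a few
    hundred imaged cells per area, discharges every ~15 s, coupled
    discharges lagging cortex by a median of 66 ms.
    """

    duration_s: float = 120.0
    imaging_rate_hz: float = 13.64
    ephys_rate_hz: float = 1000.0
    n_cells_cortex: int = 300
    n_cells_thalamus: int = 250
    fov_size_um: float = 500.0
    event_rate_hz: float = 0.0667
    coupling_schedule: ScheduleLike = 1.0
    participation_schedule: ScheduleLike = 1.0
    lag_median_s: float = 0.066
    lag_spread: float = 0.5
    participation_base: float = 0.6
    spatial_corr_length_um: float = 100.0
    calcium_decay_s: float = 1.0
    transient_amplitude: float = 1.0
    noise_sd: float = 0.05
    bleach_fraction: float = 0.1
    bleach_slope: float = -0.002
    discharge_amp_mv: float = 20.0
    discharge_dur_s: float = 1.0
    vm_noise_sd_mv: float = 0.3
    refractory_s: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        for name in ("imaging_rate_hz", "ephys_rate_hz", "event_rate_hz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_cells_cortex < 1 or self.n_cells_thalamus < 1:
            raise ValueError("need at least one cell per area")
        if not self.lag_median_s > 0:
            raise ValueError("lag_median_s must be > 0")
        sched = make_schedule(self.coupling_schedule)
        part = make_schedule(self.participation_schedule)
        for t in np.linspace(0.0, self.duration_s, 7):
            p = sched(float(t))
            if not 0.0 <= p <= 1.0:
                raise ValueError("coupling_schedule values must lie in [0, 1]")
            if part(float(t)) < 0.0:
                raise ValueError("participation_schedule values must be >= 0")

    def n_cells(self, area: str) -> int:
        return self.n_cells_cortex if area == AREA_CORTEX else self.n_cells_thalamus

    def rng(self, *stream: int) -> np.random.Generator:
        """Dedicated RNG stream derived from the single experiment seed."""
        return np.random.default_rng(
            np.random.SeedSequence((self.seed,) + tuple(stream))
        )


@dataclass
class SyntheticGroundTruth:
    """True event schedule, coupling, lags, spikes and artifacts of one run."""

    event_times_s: np.ndarray
    thalamic_coupled: np.ndarray  # bool per cortical event
    true_lags_s: np.ndarray  # per event; NaN where uncoupled
    cell_spike_times: Dict[str, list]  # area -> list of per-cell arrays
    participating: Dict[str, np.ndarray]  # area -> (n_events, n_cells) bool
    drifting_cells: Dict[str, np.ndarray]  # area -> sorted cell indices
    cell_coords_um: Dict[str, np.ndarray]  # area -> (n_cells, 2)
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times_s, dtype=float)
        if t.size > 1 and not (np.diff(t) > 0).all():
            raise ValueError("event times must be strictly increasing")
        coupled = np.asarray(self.thalamic_coupled, dtype=bool)
        lags = np.asarray(self.true_lags_s, dtype=float)
        if coupled.size and not (lags[coupled] > 0).all():
            raise ValueError("coupled events must carry positive lags")

    @property
    def n_events(self) -> int:
        return int(np.asarray(self.event_times_s).size)

    @property
    def coupled_lags_s(self) -> np.ndarray:
        return np.asarray(self.true_lags_s)[np.asarray(self.thalamic_coupled)]

    def per_event_participation(self, area: str) -> np.ndarray:
        """Fraction of cells active per event in ``area``."""
        part = self.participating[area]
        if part.size == 0:
            return np.zeros(self.n_events)
        return part.mean(axis=1)

    def event_times_in(self, area: str) -> np.ndarray:
        """Discharge onset times as seen in ``area`` (thalamus adds the lag)."""
        t = np.asarray(self.event_times_s, dtype=float)
        if area == AREA_CORTEX:
            return t
        coupled = np.asarray(self.thalamic_coupled, dtype=bool)
        return t[coupled] + np.asarray(self.true_lags_s)[coupled]


def _hotspot_participation(
    coords: np.ndarray,
    strengths: np.ndarray,
    hotspots: np.ndarray,
    base: float,
    corr_length_um: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample a (n_events, n_cells) boolean participation matrix.

    Each event activates cells with probability proportional to a Gaussian
    hotspot mixture evaluated at the cell position, scaled by the shared
    event strength; cells closer than the correlation length therefore have
    similar participation.
    """
    n_events = strengths.size
    n_cells = coords.shape[0]
    out = np.zeros((n_events, n_cells), dtype=bool)
    two_ell2 = 2.0 * corr_length_um**2
    for e in range(n_events):
        d2 = ((coords[None, :, :] - hotspots[e][:, None, :]) ** 2).sum(axis=2)
        w = np.exp(-d2 / two_ell2).sum(axis=0)
        mean_w = w.mean()
        if mean_w > 0:
            p = np.clip(strengths[e] * base * w / mean_w, 0.0, 1.0)
        else:  # pragma: no cover - degenerate geometry
            p = np.full(n_cells, strengths[e] * base)
        out[e] = rng.random(n_cells) < p
    return out


def generate_event_schedule(
    config: ExperimentConfig, duration_s: Optional[float] = None
) -> SyntheticGroundTruth:
    """Draw the ground-truth discharge schedule of one experiment.

    Cortical discharges follow a renewal process: inter-event intervals are
    the refractory floor plus an exponential chosen so the mean rate equals
    ``event_rate_hz``. Each discharge recruits thalamus with probability
    ``coupling_schedule(t)``; recruited discharges carry a log-normal lag
    with the configured median and spread. Per-cell spike times and
    hotspot-structured participation are drawn for both areas.
    """
    config.validate()
    duration = config.duration_s if duration_s is None else float(duration_s)
    if not duration > 0:
        raise ValueError("duration must be > 0")
    rng = config.rng(_STREAM_SCHEDULE)
    schedule = make_schedule(config.coupling_schedule)

    mean_gap = 1.0 / config.event_rate_hz
    exp_mean = max(mean_gap - config.refractory_s, 1e-6)
    times = []
    t = config.refractory_s + rng.exponential(exp_mean)
    while t < duration:
        times.append(t)
        t += config.refractory_s + rng.exponential(exp_mean)
    event_times = np.asarray(times)
    n_events = event_times.size

    p_coupled = np.array([schedule(float(tt)) for tt in event_times])
    coupled = rng.random(n_events) < p_coupled
    lags = np.full(n_events, np.nan)
    lags[coupled] = config.lag_median_s * np.exp(
        config.lag_spread * rng.standard_normal(int(coupled.sum()))
    )

    # shared per-event strength, scaled by the (time-varying) participation
    # schedule: epochs with a higher scale recruit more cells per discharge
    part_schedule = make_schedule(config.participation_schedule)
    strengths = rng.uniform(*_EVENT_STRENGTH_RANGE, size=n_events)
    strengths = strengths * np.array(
        [part_schedule(float(tt)) for tt in event_times]
    )

    coords: Dict[str, np.ndarray] = {}
    participating: Dict[str, np.ndarray] = {}
    spikes: Dict[str, list] = {}
    drifting: Dict[str, np.ndarray] = {}
    for area in (AREA_CORTEX, AREA_THALAMUS):
        n_cells = config.n_cells(area)
        coords[area] = rng.uniform(0.0, config.fov_size_um, size=(n_cells, 2))
        hotspots = rng.uniform(
            0.0, config.fov_size_um, size=(n_events, _N_HOTSPOTS, 2)
        )
        part = _hotspot_participation(
            coords[area],
            strengths,
            hotspots,
            config.participation_base,
            config.spatial_corr_length_um,
            rng,
        )
        if area == AREA_THALAMUS:
            part[~coupled] = False  # thalamus silent during focal discharges
        participating[area] = part

        onset = event_times.copy()
        if area == AREA_THALAMUS:
            onset = onset + np.where(coupled, lags, np.nan)
        cell_spikes = []
        for c in range(n_cells):
            ev = np.nonzero(part[:, c])[0]
            st = onset[ev] + rng.exponential(_SPIKE_JITTER_S, size=ev.size)
            cell_spikes.append(np.sort(st[st < duration]))
        spikes[area] = cell_spikes

        n_drift = int(round(config.bleach_fraction * n_cells))
        drifting[area] = np.sort(
            rng.choice(n_cells, size=n_drift, replace=False)
        )

    return SyntheticGroundTruth(
        event_times_s=event_times,
        thalamic_coupled=coupled,
        true_lags_s=lags,
        cell_spike_times=spikes,
        participating=participating,
        drifting_cells=drifting,
        cell_coords_um=coords,
        duration_s=duration,
    )


def render_fluorescence(
    truth: SyntheticGroundTruth,
    config: ExperimentConfig,
    area: str = AREA_CORTEX,
    start_time_s: float = 0.0,
    duration_s: Optional[float] = None,
    recording_id: Optional[str] = None,
) -> ImagingRecording:
    """Render the calcium fluorescence of one imaging recording.

    Each spike injects an impulse of ``transient_amplitude`` one frame after
    the spike (the indicator responds after the action potential), decaying
    with time constant ``calcium_decay_s`` under an AR(1) recursion.
    Drifting cells get a linear bleaching ramp in absolute experiment time;
    Gaussian noise of SD ``noise_sd`` is added to every sample.
    """
    duration = config.duration_s if duration_s is None else float(duration_s)
    rate = config.imaging_rate_hz
    n_frames = int(round(duration * rate))
    n_cells = config.n_cells(area)
    # key the stream on the window start so successive recordings from the
    # same experiment get independent noise
    rng = config.rng(_STREAM_FLUOR[area], int(round(start_time_s * 1000)))

    gamma = math.exp(-1.0 / (rate * config.calcium_decay_s))
    impulses = np.zeros((n_cells, n_frames))
    for c, st in enumerate(truth.cell_spike_times[area]):
        st = np.asarray(st)
        st = st[(st >= start_time_s) & (st < start_time_s + duration)]
        if st.size == 0:
            continue
        # response appears at the first frame strictly after the spike
        frames = np.floor((st - start_time_s) * rate).astype(int) + 1
        frames = frames[frames < n_frames]
        np.add.at(impulses[c], frames, config.transient_amplitude)

    fluor = np.empty_like(impulses)
    fluor[:, 0] = impulses[:, 0]
    for f in range(1, n_frames):
        fluor[:, f] = gamma * fluor[:, f - 1] + impulses[:, f]

    frame_times = start_time_s + np.arange(n_frames) / rate
    drift_rows = truth.drifting_cells[area]
    if drift_rows.size:
        fluor[drift_rows] += config.bleach_slope * frame_times[None, :]
    if config.noise_sd > 0:
        fluor += rng.normal(0.0, config.noise_sd, size=fluor.shape)

    return ImagingRecording(
        fluorescence=fluor,
        frame_rate_hz=rate,
        start_time_s=start_time_s,
        coords_um=truth.cell_coords_um[area],
        area=area,
        recording_id=recording_id or f"{area}-img-{start_time_s:.0f}s",
    )


def _envelope(n: int, rise: int, decay: int) -> np.ndarray:
    """Rise–plateau–decay shape of a discharge, peak normalized to 1."""
    env = np.ones(n)
    if rise > 0:
        env[:rise] = np.linspace(0.0, 1.0, rise, endpoint=False)
    if decay > 0:
        env[n - decay :] = np.linspace(1.0, 0.0, decay + 1)[1:]
    return env


def render_ephys(
    truth: SyntheticGroundTruth,
    config: ExperimentConfig,
    area: str = AREA_CORTEX,
    start_time_s: float = 0.0,
    duration_s: Optional[float] = None,
    cell_id: Optional[str] = None,
) -> EphysRecording:
    """Render a whole-cell membrane-potential trace for one area.

    Each discharge seen in ``area`` (thalamus: coupled discharges only,
    shifted by their lag) adds a rise–plateau–decay depolarizing envelope of
    duration ``discharge_dur_s`` whose peak equals that event's
    participation fraction times ``discharge_amp_mv``.
    """
    duration = config.duration_s if duration_s is None else float(duration_s)
    rate = config.ephys_rate_hz
    n = int(round(duration * rate))
    rng = config.rng(_STREAM_EPHYS[area], int(round(start_time_s * 1000)))
    vm = np.full(n, _VM_BASELINE_MV)

    onsets = truth.event_times_in(area)
    fractions = truth.per_event_participation(area)
    if area == AREA_THALAMUS:
        fractions = fractions[np.asarray(truth.thalamic_coupled, dtype=bool)]

    n_env = max(int(round(config.discharge_dur_s * rate)), 1)
    env = _envelope(n_env, rise=max(n_env // 10, 1), decay=max(n_env * 3 // 10, 1))
    for onset, frac in zip(onsets, fractions):
        i0 = int(round((onset - start_time_s) * rate))
        if i0 >= n or i0 + n_env <= 0:
            continue
        lo, hi = max(i0, 0), min(i0 + n_env, n)
        vm[lo:hi] += frac * config.discharge_amp_mv * env[lo - i0 : hi - i0]

    if config.vm_noise_sd_mv > 0:
        vm += rng.normal(0.0, config.vm_noise_sd_mv, size=n)

    return EphysRecording(
        vm_mv=vm,
        sample_rate_hz=rate,
        start_time_s=start_time_s,
        area=area,
        cell_id=cell_id or f"{area}-patch",
    )
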