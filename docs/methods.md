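# Methods

This note documents the models, conventions and design choices behind
`tcss`, in the order the pipeline runs. Time is absolute seconds from
experiment start everywhere; frame and sample indices are 0-based; event
intervals are half-open `[onset, offset)` and two events overlap only when
their intersection has strictly positive length; positive lags mean cortex
leads thalamus.

## Synthetic two-area experiments

The generator emulates a hyperexcitable thalamocortical slice monitored
with two-minute imaging recordings (5–30 Hz frame rate, a few hundred
cells) and kHz whole-cell recordings, repeated every 5–10 min over a
session.

**Event process.** Cortical epileptiform discharges follow a renewal
process: inter-event intervals are a 2-s refractory floor plus an
exponential whose mean is chosen so the overall rate equals
`event_rate_hz` (default 0.0667 events/s ≈ 8 discharges per two-minute
recording, matching how discrete and well-separated these discharges are).

**Coupling.** Each discharge recruits thalamus with probability
`coupling_schedule(t)` — a constant, step, or sigmoid of session time.
Recruited discharges carry a log-normal lag with configurable median
(default 66 ms) and log-SD `lag_spread` (default 0.5): positive support
and right skew are the two robust facts about onset delays between a
leading and a recruited area.

**Participation.** Each event activates cells with probability
proportional to a mixture of three spatial Gaussian hotspots (SD
`spatial_corr_length_um`, default 100 μm) scaled by
`participation_base` (default 0.6) and by a shared per-event strength
drawn uniformly from [0.2, 1]. The hotspot mechanism is the simplest one
that produces the observed distance fall-off of pairwise correlations;
the shared strength couples discharge intensity across areas (its range
is set so the per-FOV cross-area intensity correlation has median ≈ 0.7,
the magnitude this class of preparation shows). An optional
`participation_schedule` scales the per-event strength over session time,
so recruited epochs can carry higher shared participation — the
local-coherence change that accompanies recruitment; it defaults to 1
(stationary cortical dynamics).

**Rendering.** Fluorescence follows the AR(1) forward model: each spike
injects an impulse of `transient_amplitude` at the first frame strictly
after the spike (the indicator responds after the action potential),
decaying with time constant `calcium_decay_s` (default 1.0 s, the
order of magnitude of a high-affinity ratiometric indicator at room
temperature). Per-cell spike times jitter behind the discharge onset by
an exponential with 50-ms mean. A configurable fraction of cells gets a
linear bleaching ramp in absolute session time; Gaussian noise is added
per sample. Membrane potential is a −65 mV baseline plus, per discharge
seen in that area, a rise–plateau–decay envelope (10%/60%/30% of
`discharge_dur_s`, default 1 s) whose peak is the event's participation
fraction times `discharge_amp_mv` (default 20 mV), plus Gaussian noise.
Discharge durations and amplitudes are free parameters of the generator,
not calibrated claims.

All randomness derives from one seed through per-stage seed sequences
(schedule, per-area fluorescence, per-area ephys, keyed additionally by
recording start time), so any artifact can be regenerated independently
and bit-identically.

What the generator does **not** emulate: biophysical membrane dynamics,
indicator saturation and nonlinearity, motion and segmentation errors,
inhibition, or any receptor-level mechanism. Passing recovery tests on
this generator shows the analysis chain is self-consistent and correctly
inverts the stated forward models — not that it is robust to every
artifact of real recordings.

## Onset inference

Per cell, a running 20th-percentile baseline (30-s centered window) is
subtracted — a low percentile tracks resting fluorescence even in
discharge-dense epochs — and the trace is deconvolved under the AR(1)
model by non-negative least squares (pool-adjacent-violators), the core
of the standard fast spike-inference algorithms for this model class. An
optional sparsification zeroes deconvolved amplitudes below
`noise_scale` robust noise SDs (the pipeline default is 3).
Binarization marks one onset per rising crossing of
`median + k·MAD` (default k = 3, a conventional robust threshold); the
MAD is floored at 10⁻³ of the cell's signal maximum so noiseless sparse
signals do not produce a degenerate zero threshold. One onset is emitted
per rising edge, not per underlying spike.

## Discharge detection

*Imaging*: per frame, the number of distinct cells with an onset inside a
trailing window (default one frame — the strictest reading of
"simultaneous") is compared with `ceil(f·n_cells)`, where `f`
interpolates linearly from 0.25% (populations < 400 cells) to 0.33% (at
1100 cells). These printed fractions imply required counts of only ~1–4
cells; they are kept verbatim as defaults and `threshold_fraction` is
exposed in configuration for users who want stricter detection.
*Ephys*: an event is a maximal interval with Vm above a running-median
baseline (30-s window, forced odd length so centered windows are
symmetric) plus `amp_thresh_mv` (default 5 mV), lasting at least 0.2 s.
In both detectors, events closer than `merge_gap_s` (default 0.5 s) are
merged. Event times are absolute, so imaging- and ephys-detected events
are directly comparable.

## Discharge matching and CR

Matching is one-to-one between sorted cortical and thalamic event lists:
the assignment maximizes the number of overlapping pairs matched and,
among assignments of equal size, the total overlap, computed exactly with
the Hungarian algorithm (a large per-pair bonus makes the objective
lexicographic). A greedy descending-overlap heuristic was considered and
rejected: there are four-interval instances where the single
largest-overlap pair blocks two compatible smaller pairs, so greedy
under-counts matched discharges; the exact optimum is equally
deterministic and auditable. CR is matched over total cortical
discharges; it is undefined (raises) without cortical events rather than
silently 0. Lags are thalamic onset minus cortical onset; exact zero-lag
ties count as "not leading".

## Aligned cohort timelines

Per slice, the CR (or fraction-correlated) series crosses threshold 0.5
at the first sampled point at or above it (no interpolation — recordings
are 5–10 min apart, so the crossing is a sampled recording); a series
already above threshold at its first point crosses there. Aligned times
are pooled into contiguous 20-min bins; bin mean and SEM are computed
over per-slice bin averages (SEM needs ≥ 2 slices). Slices that never
reach threshold are excluded with a warning.

## Correlated-cell rule

The remote voltage trace is down-sampled by averaging all samples inside
each imaging frame interval (empty bins carry the previous value with a
warning; the last frame uses the nominal frame period). A cell counts as
correlated when its Pearson r with that trace is significantly greater
than zero (one-sided p < 0.05) **and** |r| > 0.1. Both clauses are kept
even though the sign requirement makes the absolute-value gate partly
redundant: the rule is a fixed published convention, and changing it
would silently change the fraction.

## Stationarity filter

For each event at `tᵢ`, `z(tᵢ) = (F(tᵢ) − ⟨F_b⟩)/σ_Fb`, with `F(tᵢ)` the
single frame nearest `tᵢ` and the baseline mean/SD over frames in
`[tᵢ − 2 s, tᵢ)`. All SDs and SEMs in the package use the sample
convention (n−1). The least-squares slope of z on event time is compared
with the slopes of permuted z-series over the same times: 1000 random
permutations by default, exact enumeration of all n! permutations for
n ≤ 6 events. Cells outside the 10th–90th percentile band are discarded;
by construction this removes ≈ 20% of cells even under exchangeability —
a deliberate, calibrated cost of guarding against bleaching-driven
correlation artifacts. Cells with fewer than three usable events are
excluded separately. Slope comparisons carry a relative tolerance of
10⁻⁹ so a slope equal to a band edge up to floating-point rounding
counts as inside.

## Pairwise correlations and spatial profile

Cells must be active in at least one event before and one after
recruitment and pass the stationarity filter (z-series pooled over all
events of the experiment). Traces are filtered — 30-s running-median
detrend plus 3-frame centered moving average (shrunken windows at the
edges) — chosen to remove the slow drift the stationarity filter targets
and frame-rate shot noise; the filter identity is configurable and logged
because the upstream convention fixes only that traces are "filtered".
Per condition, each recording's filtered traces are concatenated in time
and one Pearson r is computed per pair; at least two recordings per
condition are required. Pairs are binned by Euclidean intersomatic
distance in 100-μm bins; the bin SEM divides the sample SD of pair
correlations by √(number of unique cells in the bin), because one cell
enters many pairs and pairs are not independent. The before/after
comparison reports the mean of `r_before − r_after` with a two-sided
Wilcoxon signed-rank p-value — a distribution-free paired test, chosen
because no parametric form is justified for correlation differences. The
dual-patch control correlates two simultaneous voltage traces at zero lag
(mean-removed Pearson) and compares slice groups with a two-sided
Wilcoxon rank-sum test.

## Intensity coupling

Cortical intensity of a discharge is the number of distinct cells with an
onset inside the discharge window divided by the number of cells ever
active in any recording of that field of view. Thalamic intensity is the
trapezoidal integral of `max(Vm − baseline, 0)` over the window — only
depolarization counts, since hyperpolarizing excursions would cancel
genuine discharge area. The window is the cortical event's interval
extended to the matched thalamic offset when that is later, because the
thalamic discharge lags cortex and truncating at the cortical offset
would bias the area low; both the baseline convention and the extension
rule are configuration, not measurement. A field of view counts as
intensity-coupled when the Pearson correlation across its discharges is
significantly different from zero (two-sided p < 0.05).

## Problem sizes in the test suite

Validation suites run the pipeline at sizes chosen to make the targeted
statistical checks well-powered while staying desk-scale: cohort CR
recovery uses 6 slices × 100-min sessions with staggered coupling steps
(voltage-only detection); lag recovery uses ~2000 matched discharges;
stationarity calibration uses 1000 simulated cells × 18 events;
intensity-coupling recovery uses 20 slices of ~50 discharges with 100
imaged cortical cells; noiseless onset recovery uses 60 cells over two
minutes. Tolerances asserted in tests are stated inline with each test.

## Known limitations

* One onset per rising edge: bursts within a single calcium transient are
  not resolved into spike counts, and no absolute fluorescence-to-spike
  calibration is attempted.
* The ephys discharge detector is threshold-based; discharges whose peak
  depolarization stays below `amp_thresh_mv` are invisible to it, which
  slightly range-restricts downstream intensity correlations.
* The matcher resolves a thalamic event overlapping two cortical events
  by global optimality; the underlying convention is not fixed by any
  published rule, and other admissible choices exist.
* CR timelines can be computed from imaging- or ephys-detected cortical
  events; the pipeline accepts either source and the run log records
  which was used.
* The synthetic generator's limitations listed above bound what passing
  tests demonstrate about real recordings.
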