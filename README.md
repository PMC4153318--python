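# tcss — thalamocortical seizure-spread analysis

`tcss` quantifies how focal neocortical epileptiform discharges recruit
thalamus in two-area slice experiments that combine high-speed calcium
imaging of one area with whole-cell patch recordings in the other. It is
written for experimenters analysing paired imaging/electrophysiology
recordings from hyperexcitable thalamocortical preparations (e.g. the
zero-Mg²⁺ model), and for methodologists who want a tested, synthetic-data-
validated reference implementation of the analysis chain.

## What it computes

Given per-cell fluorescence matrices (cells × frames, with coordinates) and
membrane-potential traces on a shared experiment clock, the pipeline runs:

1. **Onset inference** — non-negative deconvolution of each fluorescence
   trace under a first-order autoregressive calcium model
   (`F_t = γ·F_{t−1} + A·s_t`, `γ = exp(−Δt/τ)`), then per-cell
   binarization at `median + k·MAD` (rising edges only).
2. **Discharge detection** — population events where the number of
   simultaneous cell onsets reaches a population-size-dependent fraction
   (0.25% of cells below 400 cells, 0.33% at 1100, interpolated), and
   depolarization events where Vm exceeds a running-median baseline by a
   threshold for a minimum duration.
3. **Coupling reliability (CR)** — one-to-one interval matching of
   cortical and thalamic discharges;
   `CR = matched cortical discharges / all cortical discharges`.
4. **Lag statistics** — median of thalamic-minus-cortical onset lags and
   the fraction of discharges in which cortex leads.
5. **Aligned timelines** — per-slice CR (or fraction-correlated) series
   aligned at their first crossing of 0.5 and pooled into 20-min bins.
6. **Correlated-cell fractions** — per-cell Pearson correlation between
   fluorescence and the frame-averaged remote voltage; a cell counts when
   r is significantly greater than zero (one-sided p < 0.05) and |r| > 0.1.
7. **Circuit correlation** — event-aligned z-scored fluorescence
   `z(tᵢ) = (F(tᵢ) − ⟨F_b⟩)/σ_Fb` (2-s pre-event baseline) feeds a
   permutation test on the regression slope of z over time; cells outside
   the 10th–90th percentile of the shuffled-slope distribution are
   discarded as non-stationary (bleaching guard). Surviving cells'
   filtered traces give pairwise correlations before vs. after thalamic
   recruitment, binned in 100-μm distance bins with SEM computed on the
   number of unique cells per bin.
8. **Intensity coupling** — per discharge, the fraction of ever-active
   cells recruited (imaging) and the depolarization area above baseline in
   mV·s (ephys), and their Pearson correlation per field of view.

A bundled synthetic generator produces two-area experiments with known
ground truth (event schedule, coupling indicators, log-normal lags,
hotspot-structured participation, AR(1) fluorescence, envelope-shaped
depolarizations) so that every stage is testable without lab data.

## Worked example

```python
from tcss import ExperimentConfig, RunConfig, run_pipeline

exp = ExperimentConfig(
    duration_s=120.0,              # two-minute recordings
    n_cells_cortex=60,
    n_cells_thalamus=50,
    coupling_schedule={"kind": "step", "t0_s": 1500.0},       # recruitment at 25 min
    participation_schedule={"kind": "step", "t0_s": 1500.0,
                            "before": 0.7, "after": 1.2},     # coherence rise
    seed=42,
)
cfg = RunConfig(experiment=exp, session_duration_s=4200.0,
                recording_interval_s=600.0, n_shuffles=200,
                outdir="demo-run")
run_pipeline(cfg)
print(open("demo-run/report.txt").read())
```

prints

```
thalamocortical seizure-spread analysis — run summary

recordings analysed: 7
coupling reliability per recording: 0.000, 0.000, 0.000, 1.000, 1.000, 1.000, 1.000
median corticothalamic lag: 63.0 ms (20 matched discharges, cortex leading in 95.0%)
fraction of thalamic cells correlated with cortex, per recording: 0.000, 0.020, 0.000, 0.900, 0.980, 1.000, 0.940
cortical pairwise correlation: mean r 0.250 before vs 0.332 after recruitment (paired Wilcoxon p = 4.96e-36, 946 pairs)
cortico-thalamic intensity correlation: r = 0.546 (p = 8.58e-03, 22 discharges, significant: True)
```

Reading the numbers: the seven two-minute recordings tile a 70-min
session whose cortex→thalamus coupling probability steps from 0 to 1 at
25 min. CR per recording recovers that step exactly; the matched
discharges lag cortex by a median 63 ms with cortex leading in 95% of
cases (the generator draws log-normal lags with median 66 ms). The
fraction of thalamic cells correlated with the cortical patch jumps with
recruitment, cortical pairwise correlations are significantly higher
after recruitment (the configured participation step), and discharge
intensities in the two areas are significantly correlated.

The same stages are available from the shell:

```bash
tcss simulate --output demo.h5
tcss detect-events --input demo.h5 --recording cortex-patch --output events-c.tsv
tcss detect-events --input demo.h5 --recording thalamus-patch --output events-t.tsv
tcss coupling --cortex-events events-c.tsv --thalamus-events events-t.tsv --out matches.tsv
tcss run-all --outdir full-run
```

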