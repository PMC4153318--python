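"""Cross-area matching, CR, lag statistics, alignment, downsampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcss import (
    CouplingPoint,
    EphysRecording,
    ExperimentConfig,
    ImagingRecording,
    align_timeline,
    coupling_reliability,
    downsample_by_frame_average,
    fraction_correlated_cells,
    generate_event_schedule,
    lag_statistics,
    match_discharges,
)
from conftest import make_event
from oracles import brute_force_match, random_disjoint_intervals


def events_from(intervals, area):
    return [make_event(a, b, area=area) for a, b in intervals]


class TestMatchDischarges:
    def test_overlapping_pair_matches_with_lag(self):
        m = match_discharges(
            [make_event(0, 1)], [make_event(0.5, 1.5, area="thalamus")]
        )
        assert m[0].matched
        assert m[0].lag_s == pytest.approx(0.5)
        assert m[0].overlap_s == pytest.approx(0.5)

    def test_disjoint_events_unmatched(self):
        m = match_discharges(
            [make_event(0, 1)], [make_event(2, 3, area="thalamus")]
        )
        assert not m[0].matched

    def test_thalamic_event_assigned_to_larger_overlap(self):
        """T=[0.9,1.4] overlaps C₁=[0,1] by 0.1 and C₂=[1.2,2.2] by 0.2."""
        m = match_discharges(
            [make_event(0, 1), make_event(1.2, 2.2)],
            [make_event(0.9, 1.4, area="thalamus")],
        )
        assert not m[0].matched
        assert m[1].matched
        assert m[1].overlap_s == pytest.approx(0.2)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            match_discharges([make_event(5, 6), make_event(0, 1)], [])

    def test_blocking_instance_prefers_more_matches(self):
        """A large-overlap pair must not block two smaller valid pairs."""
        cortical = events_from([(0, 10), (11, 20)], "cortex")
        thalamic = events_from([(0.2, 5), (5, 15.9)], "thalamus")
        m = match_discharges(cortical, thalamic)
        assert all(x.matched for x in m)
        count, total = brute_force_match(cortical, thalamic)
        assert sum(x.matched for x in m) == count
        assert sum(x.overlap_s for x in m) == pytest.approx(total)

    @pytest.mark.parametrize("seed", range(40))
    def test_oracle_equivalence_random_instances(self, seed):
        """Matching agrees with exhaustive enumeration for ≤6 events/area."""
        rng = np.random.default_rng(seed)
        cortical = events_from(random_disjoint_intervals(rng, 6), "cortex")
        thalamic = events_from(random_disjoint_intervals(rng, 6), "thalamus")
        m = match_discharges(cortical, thalamic)
        count, total = brute_force_match(cortical, thalamic)
        assert sum(x.matched for x in m) == count
        assert sum(x.overlap_s for x in m) == pytest.approx(total)
        if cortical:
            assert coupling_reliability(m) == count / len(cortical)

    @given(shift=st.floats(-1e4, 1e4, allow_nan=False), seed=st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_cr_invariant_to_common_time_shift(self, shift, seed):
        rng = np.random.default_rng(seed)
        cortical = random_disjoint_intervals(rng, 5)
        thalamic = random_disjoint_intervals(rng, 5)
        if not cortical:
            return
        base = match_discharges(
            events_from(cortical, "cortex"), events_from(thalamic, "thalamus")
        )
        moved = match_discharges(
            events_from([(a + shift, b + shift) for a, b in cortical], "cortex"),
            events_from([(a + shift, b + shift) for a, b in thalamic], "thalamus"),
        )
        assert coupling_reliability(base) == pytest.approx(
            coupling_reliability(moved)
        )


class TestCouplingReliability:
    def test_one_of_eight_overlaps(self):
        """Low-coupling example: 8 cortical discharges, 1 overlapping pair."""
        cortical = events_from([(10 * k, 10 * k + 1) for k in range(8)], "cortex")
        thalamic = [make_event(30.5, 31.5, area="thalamus")]
        assert coupling_reliability(match_discharges(cortical, thalamic)) == 0.125

    def test_seven_of_seven_overlap(self):
        cortical = events_from([(10 * k, 10 * k + 1) for k in range(7)], "cortex")
        thalamic = events_from(
            [(10 * k + 0.1, 10 * k + 1.1) for k in range(7)], "thalamus"
        )
        assert coupling_reliability(match_discharges(cortical, thalamic)) == 1.0

    def test_no_matches_gives_zero(self):
        cortical = events_from([(0, 1), (5, 6)], "cortex")
        assert coupling_reliability(match_discharges(cortical, [])) == 0.0

    def test_undefined_without_cortical_events(self):
        with pytest.raises(ValueError):
            coupling_reliability([])


class TestLagStatistics:
    def test_all_positive_lags(self):
        cortical = events_from([(0, 1), (10, 11), (20, 21)], "cortex")
        thalamic = events_from(
            [(0.05, 1.05), (10.07, 11.07), (20.10, 21.10)], "thalamus"
        )
        stats = lag_statistics(match_discharges(cortical, thalamic))
        assert stats["median_lag_s"] == pytest.approx(0.07)
        assert stats["fraction_cortex_leading"] == 1.0
        assert stats["n_matched"] == 3

    def test_mixed_signs_and_zero_tie(self):
        cortical = events_from([(0, 1), (10, 11)], "cortex")
        thalamic = events_from([(-0.1, 0.9), (10.1, 11.1)], "thalamus")
        stats = lag_statistics(match_discharges(cortical, thalamic))
        assert stats["median_lag_s"] == pytest.approx(0.0)
        assert stats["fraction_cortex_leading"] == 0.5

    def test_undefined_without_matches(self):
        with pytest.raises(ValueError):
            lag_statistics(match_discharges(events_from([(0, 1)], "cortex"), []))

    def test_lognormal_lag_recovery_from_generator(self):
        """n≈2000 coupled discharges: recovered median within ±5 ms of truth."""
        cfg = ExperimentConfig(coupling_schedule=1.0, event_rate_hz=0.5, seed=17)
        truth = generate_event_schedule(cfg, duration_s=4100.0)
        assert truth.n_events >= 2000
        cortical = events_from(
            [(t, t + cfg.discharge_dur_s) for t in truth.event_times_s], "cortex"
        )
        thal_onsets = truth.event_times_in("thalamus")
        thalamic = events_from(
            [(t, t + cfg.discharge_dur_s) for t in thal_onsets], "thalamus"
        )
        stats = lag_statistics(match_discharges(cortical, thalamic))
        assert stats["median_lag_s"] == pytest.approx(
            np.median(truth.coupled_lags_s), abs=0.005
        )
        true_leading = (truth.coupled_lags_s > 0).mean()
        assert abs(stats["fraction_cortex_leading"] - true_leading) <= 0.02


def cr_series(times_min, values):
    return [
        CouplingPoint(recording_mid_time_s=60.0 * t, cr=v, n_cortical_events=10)
        for t, v in zip(times_min, values)
    ]


class TestAlignTimeline:
    def test_single_slice_crossing_alignment(self):
        tl = align_timeline([cr_series([0, 10, 20], [0.0, 0.0, 1.0])])
        np.testing.assert_allclose(tl.aligned_times_min[0], [-20, -10, 0])

    def test_two_identical_slices_sem_zero(self):
        s = cr_series([0, 10, 20, 30], [0.0, 0.2, 0.8, 1.0])
        tl = align_timeline([s, s])
        valid = tl.n_slices_per_bin >= 2
        assert valid.any()
        np.testing.assert_allclose(tl.bin_sems[valid], 0.0)

    def test_slice_never_crossing_excluded_with_warning(self):
        s1 = cr_series([0, 10, 20], [0.0, 0.0, 1.0])
        s2 = cr_series([0, 10, 20], [0.0, 0.1, 0.2])
        with pytest.warns(UserWarning, match="never crosses"):
            tl = align_timeline([s1, s2])
        assert len(tl.aligned_times_min) == 1

    def test_invariant_to_slice_relabeling(self):
        slices = [
            cr_series([0, 10, 20, 30], [0.0, 0.1, 0.9, 1.0]),
            cr_series([0, 10, 20, 30], [0.0, 0.4, 0.6, 1.0]),
            cr_series([0, 10, 20, 30], [0.1, 0.2, 0.7, 0.9]),
        ]
        a = align_timeline(slices)
        b = align_timeline(slices[::-1])
        np.testing.assert_allclose(a.bin_means, b.bin_means)
        np.testing.assert_allclose(a.bin_edges_min, b.bin_edges_min)


class TestDownsample:
    def make_ephys(self, vm, rate=1000.0):
        return EphysRecording(vm_mv=vm, sample_rate_hz=rate, start_time_s=0.0,
                              area="cortex")

    def test_constant_trace(self):
        rec = self.make_ephys(np.ones(1000))
        out = downsample_by_frame_average(rec, np.arange(0, 1.0, 0.1))
        np.testing.assert_allclose(out, 1.0)

    def test_ramp_frame_means(self):
        """1 kHz ramp 0..999 at 10 Hz frames: frame 0 averages samples 0..99."""
        rec = self.make_ephys(np.arange(1000, dtype=float))
        out = downsample_by_frame_average(rec, np.arange(0, 1.0, 0.1))
        np.testing.assert_allclose(out, 49.5 + 100 * np.arange(10))

    def test_single_sample_per_frame_identity(self):
        rec = self.make_ephys(np.array([3.0, 1.0, 4.0, 1.0]), rate=10.0)
        out = downsample_by_frame_average(rec, np.arange(4) / 10.0)
        np.testing.assert_allclose(out, [3.0, 1.0, 4.0, 1.0])

    def test_empty_bin_carries_previous_value(self):
        rec = self.make_ephys(np.array([2.0, 4.0]), rate=10.0)
        with pytest.warns(UserWarning, match="empty frame bins"):
            out = downsample_by_frame_average(rec, np.array([0.0, 0.02, 0.1]))
        np.testing.assert_allclose(out, [2.0, 2.0, 4.0])


class TestFractionCorrelatedCells:
    def make_pair(self, traces, vm, img_rate=10.0, ephys_rate=1000.0):
        traces = np.atleast_2d(traces)
        img = ImagingRecording(
            fluorescence=traces, frame_rate_hz=img_rate, start_time_s=0.0,
            coords_um=np.zeros((traces.shape[0], 2)), area="thalamus",
        )
        eph = EphysRecording(vm_mv=vm, sample_rate_hz=ephys_rate,
                             start_time_s=0.0, area="cortex")
        return img, eph

    def test_trace_equal_to_voltage_is_correlated(self, rng):
        vm = rng.normal(0, 1, 60_000)
        frames = downsample_by_frame_average(
            EphysRecording(vm_mv=vm, sample_rate_hz=1000.0, start_time_s=0.0,
                           area="cortex"),
            np.arange(600) / 10.0,
        )
        img, eph = self.make_pair(frames, vm)
        res = fraction_correlated_cells(img, eph)
        assert res["cells"][0].r == pytest.approx(1.0)
        assert res["cells"][0].correlated

    def test_anticorrelated_trace_fails_sign_rule(self, rng):
        vm = rng.normal(0, 1, 60_000)
        frames = downsample_by_frame_average(
            EphysRecording(vm_mv=vm, sample_rate_hz=1000.0, start_time_s=0.0,
                           area="cortex"),
            np.arange(600) / 10.0,
        )
        img, eph = self.make_pair(-frames, vm)
        res = fraction_correlated_cells(img, eph)
        assert res["cells"][0].r == pytest.approx(-1.0)
        assert not res["cells"][0].correlated
        assert res["fraction"] == 0.0

    def test_constant_cell_not_correlated_with_warning(self, rng):
        vm = rng.normal(0, 1, 60_000)
        traces = np.vstack([np.zeros(600), rng.normal(0, 1, 600)])
        img, eph = self.make_pair(traces, vm)
        with pytest.warns(UserWarning, match="constant"):
            res = fraction_correlated_cells(img, eph)
        assert not res["cells"][0].correlated

    def test_short_overlap_rejected(self, rng):
        img, eph = self.make_pair(rng.normal(0, 1, (2, 100)),
                                  rng.normal(0, 1, 10_000))
        with pytest.raises(ValueError, match="overlap"):
            fraction_correlated_cells(img, eph)

    def test_event_locked_fraction_recovered(self):
        """60% of thalamic cells event-locked → recovered fraction ≈ 0.6."""
        cfg = ExperimentConfig(
            coupling_schedule=1.0, seed=23, noise_sd=0.01,
            n_cells_thalamus=100, n_cells_cortex=20, bleach_fraction=0.0,
            vm_noise_sd_mv=0.05, participation_base=1.0,
        )
        truth = generate_event_schedule(cfg)
        # silence 40% of thalamic cells, lock the remaining 60% to every event
        part = truth.participating["thalamus"]
        part[:, :] = False
        part[:, :60] = True
        for c in range(100):
            ev = np.nonzero(part[:, c])[0]
            truth.cell_spike_times["thalamus"][c] = (
                truth.event_times_in("thalamus")[ev] + 0.02
            )
        from tcss import render_ephys, render_fluorescence

        img = render_fluorescence(truth, cfg, "thalamus")
        eph = render_ephys(truth, cfg, "cortex")
        res = fraction_correlated_cells(img, eph)
        assert res["fraction"] == pytest.approx(0.6, abs=0.05)
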