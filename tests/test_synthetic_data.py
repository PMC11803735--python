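"""Generator contracts: schedules, traces, plates, frames, ephys, mortality,
fingerprints — determinism and the statistical structure downstream stages assume."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import strobescreen as ss
from strobescreen.battery import Segment
from strobescreen.behavior_scoring import default_baseline_interval, strobe_windows
from strobescreen.motion_index import battery_average_mi, compute_mi, lethality_flag
from strobescreen.synthetic_data import (
    PhenotypeParams,
    SimConfig,
    default_plate_map,
    gen_battery_schedule,
    gen_ephys_trace,
    gen_fingerprints,
    gen_frames,
    gen_mortality,
    gen_plate,
    gen_well_trace,
    loglogistic_mortality,
)


class TestBatterySchedule:
    def test_default_battery_has_both_strobes_at_4hz_120s(self, schedule):
        strobes = schedule.strobe_segments()
        assert [s.label for s in strobes] == ["blue_strobe", "green_strobe"]
        for s in strobes:
            assert s.duration_s == 120.0
            assert s.strobe_hz == 4.0
        assert 15 * 60 <= schedule.total_s <= 25 * 60

    def test_minimal_battery_is_strobes_plus_rest(self, mini_schedule):
        kinds = {s.kind for s in mini_schedule}
        assert kinds == {"rest", "strobe"}
        assert len(mini_schedule.strobe_segments()) == 2

    def test_trace_length_matches_summed_durations_at_25hz(self, schedule, phenos):
        t = gen_well_trace(schedule, phenos["vehicle"], seed=0)
        assert t.mi.size == int(schedule.total_s * 25)

    def test_zero_duration_segment_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            Segment("x", "rest", 10.0, 10.0)


class TestWellTraces:
    def test_noiseless_trace_is_piecewise_constant(self, schedule):
        p = PhenotypeParams(baseline_mi=10.0, noise_sd=0.0,
                            acoustic_gain=1.0, strobe_gain=0.0)
        t = gen_well_trace(schedule, p, seed=0)
        for seg in schedule:
            i0, i1 = int(seg.start_s * 25), int(seg.end_s * 25)
            expected = 0.0 if seg.kind == "strobe" else 10.0
            assert np.all(t.mi[i0:i1] == expected)

    def test_lethal_profile_averages_below_one(self, schedule, phenos):
        t = gen_well_trace(schedule, phenos["lethal_control"], seed=3)
        assert battery_average_mi(t) < 1.0

    def test_seed_determinism(self, mini_schedule, phenos):
        a = gen_well_trace(mini_schedule, phenos["vehicle"], seed=7)
        b = gen_well_trace(mini_schedule, phenos["vehicle"], seed=7)
        c = gen_well_trace(mini_schedule, phenos["vehicle"], seed=8)
        assert np.array_equal(a.mi, b.mi)
        assert not np.array_equal(a.mi, c.mi)

    def test_negative_concentration_rejected(self, mini_schedule, phenos):
        with pytest.raises(ValueError, match="concentration"):
            gen_well_trace(mini_schedule, phenos["vehicle"], concentration_um=-1.0)

    def test_toxic_concentration_switches_to_lethal(self, mini_schedule, phenos):
        t = gen_well_trace(mini_schedule, phenos["endosulfan_like"], 100.0, seed=1)
        assert battery_average_mi(t) < 1.0

    def test_vehicle_freezes_and_hyperactive_exceeds_under_strobe(
        self, mini_schedule, phenos
    ):
        """Monte-Carlo ordering: the hyperactive phenotype's strobe score is
        strictly above the vehicle's in every replicate."""
        wins = strobe_windows(mini_schedule, "blue_strobe")
        base = default_baseline_interval(mini_schedule, "blue_strobe")
        for seed in range(10):
            v = gen_well_trace(mini_schedule, phenos["vehicle"], seed=seed)
            h = gen_well_trace(
                mini_schedule, phenos["endosulfan_like"], 0.39, seed=1000 + seed
            )
            sv = ss.strobe_score(v, wins, base)
            sh = ss.strobe_score(h, wins, base)
            assert sv < 0 < sh


class TestPlates:
    def test_default_plate_counts(self):
        cfg = SimConfig(full_battery=False, seed=1)
        traces, pm = gen_plate(cfg)
        assert len(traces) == 96
        assert (pm["role"] == "vehicle").sum() == 8

    def test_lethal_control_wells_flag_lethal(self):
        cfg = SimConfig(full_battery=False, seed=2)
        traces, pm = gen_plate(cfg)
        lethal_wells = set(pm.loc[pm["role"] == "lethal_control", "well"])
        for t in traces:
            if t.well in lethal_wells:
                assert lethality_flag(battery_average_mi(t))

    def test_plate_without_vehicle_rejected(self):
        cfg = SimConfig(full_battery=False)
        pm = default_plate_map(cfg)
        pm = pm[pm["role"] != "vehicle"]
        with pytest.raises(ValueError, match="vehicle"):
            gen_plate(cfg, plate_map=pm)

    def test_full_determinism_under_seed(self):
        cfg = SimConfig(full_battery=False, seed=11)
        ta, ma = gen_plate(cfg)
        tb, mb = gen_plate(cfg)
        pd.testing.assert_frame_equal(ma, mb)
        for a, b in zip(ta, tb):
            assert np.array_equal(a.mi, b.mi)


class TestFrameFixtures:
    def test_zero_target_gives_identical_frames(self):
        st_ = gen_frames([0, 0, 0])
        assert np.all(st_.frames == st_.frames[0])

    def test_single_step_single_pixel(self):
        st_ = gen_frames([10])
        diff = np.abs(st_.frames[1].astype(int) - st_.frames[0].astype(int))
        assert diff.sum() == 10
        assert (diff > 0).sum() == 1

    @given(st.lists(st.integers(min_value=0, max_value=100000), min_size=1, max_size=40))
    def test_roundtrip_through_compute_mi_is_exact(self, target):
        stack = gen_frames(target)
        trace = compute_mi(stack, "A1")
        assert np.array_equal(trace.mi.astype(np.int64), np.asarray(target))

    def test_unrepresentable_target_rejected(self):
        with pytest.raises(ValueError, match="not representable"):
            gen_frames([10**9], shape=(2, 2), dtype=np.uint8)

    def test_non_integer_target_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            gen_frames([1.5])


class TestEphysGenerator:
    def test_null_compound_flat_across_gaba_epochs(self):
        tr = gen_ephys_trace(block_frac=0.0, rundown_frac=0.0, noise_sd=0.0)
        pre = ss.epoch_amplitude(tr, "gaba_only_pre")
        co = ss.epoch_amplitude(tr, "coapplication")
        post = ss.epoch_amplitude(tr, "gaba_only_post")
        assert pre == pytest.approx(co) == pytest.approx(post)

    def test_full_block_returns_to_baseline(self):
        tr = gen_ephys_trace(block_frac=1.0, rundown_frac=0.0, noise_sd=0.0)
        assert ss.epoch_amplitude(tr, "coapplication") == pytest.approx(0.0, abs=1e-9)

    def test_planted_block_recovered_across_seeds(self):
        for seed in range(5):
            ctrl = [
                gen_ephys_trace(block_frac=0.0, rundown_frac=0.1, noise_sd=1.0,
                                seed=100 + seed + i)
                for i in range(3)
            ]
            r = ss.rundown_fraction(ctrl)
            tr = gen_ephys_trace(block_frac=0.6, rundown_frac=0.1, noise_sd=1.0,
                                 seed=seed)
            assert ss.percent_block(tr, r) == pytest.approx(60.0, abs=3.0)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            gen_ephys_trace(block_frac=1.5)
        with pytest.raises(ValueError):
            gen_ephys_trace(rundown_frac=1.0)


class TestMortalityGenerator:
    def test_zero_potency_limit_all_alive(self):
        tab = gen_mortality([2, 4, 8, 16], lc50=np.inf, slope=4, seed=0)
        assert tab["n_dead"].sum() == 0

    def test_saturation_limit_all_dead(self):
        tab = gen_mortality([100.0], lc50=1.0, slope=30, seed=0)
        assert tab["well_dead"].all()

    def test_design_produces_84_well_records(self):
        tab = gen_mortality([2, 2.83, 4, 5.66, 8, 11.3, 16], lc50=8.6, slope=4, seed=0)
        assert len(tab) == 7 * 12
        assert tab["n_larvae"].between(3, 5).all()

    def test_nonpositive_lc50_rejected(self):
        with pytest.raises(ValueError, match="lc50"):
            gen_mortality([2.0], lc50=0.0, slope=4)

    def test_per_larva_rate_converges_to_loglogistic(self):
        """Empirical death rate at each dose within a 4-sigma binomial band."""
        doses = [2.0, 8.6, 16.0]
        tab = gen_mortality(doses, lc50=8.6, slope=4, n_reps=400, seed=42)
        for d in doses:
            sub = tab[tab["dose_ug_per_well"] == d]
            n = sub["n_larvae"].sum()
            p_hat = sub["n_dead"].sum() / n
            p = loglogistic_mortality(d, 8.6, 4)
            assert abs(p_hat - p) < 4 * np.sqrt(p * (1 - p) / n) + 1e-12


class TestFingerprintGenerator:
    def test_singleton_clusters_stay_singletons(self):
        fps, _ = gen_fingerprints(5, 1, within_sim=0.8, seed=0)
        assignment = ss.cluster_compounds(fps, threshold=0.45)
        assert assignment.n_clusters == 5

    def test_within_sim_one_duplicates_bit_vectors(self):
        fps, labels = gen_fingerprints(2, 3, within_sim=1.0, seed=0)
        for lab in set(labels):
            members = [f for f, l in zip(fps, labels) if l == lab]
            for m in members[1:]:
                assert np.array_equal(m.bits, members[0].bits)

    def test_infeasible_similarity_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            gen_fingerprints(100, 50, n_bits=64, within_sim=0.2, n_on=32)

    def test_planted_within_similarity_holds(self):
        fps, labels = gen_fingerprints(4, 3, within_sim=0.6, seed=1)
        for i in range(len(fps)):
            for j in range(i + 1, len(fps)):
                sim = ss.tanimoto(fps[i], fps[j])
                if labels[i] == labels[j]:
                    assert sim >= 0.6
                else:
                    assert sim == 0.0
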