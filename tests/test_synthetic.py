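"""Generator properties: kinematics, kernels, Poisson spiking, determinism."""

import numpy as np
import pandas as pd
import pytest

from saccadeflow import SimConfig, synthetic as syn
from saccadeflow.response_stats import peth, windowed_counts


class TestConfig:
    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(session_length_s=-1)
        with pytest.raises(ValueError):
            SimConfig(integration_gain=0.0)
        with pytest.raises(ValueError):
            SimConfig(condition="swimming")

    def test_freely_moving_defaults(self):
        cfg = SimConfig.freely_moving()
        assert cfg.frame_rate == 90.0
        assert cfg.saccade_rate_per_min == pytest.approx(44.2)


class TestEyeTraceGeneration:
    def test_noiseless_single_saccade_displacement_exact(self):
        cfg = SimConfig(
            session_length_s=60.0, saccade_rate_per_min=10.0, noise_sd=0.0, seed=4
        )
        trace, events = syn.make_eye_trace(cfg)
        net = trace.azimuth[-1] - trace.azimuth[0]
        signed = np.where(events["direction_label"] == "nasal", 1.0, -1.0)
        assert net == pytest.approx(float((signed * events["amplitude"]).sum()), abs=1e-9)

    def test_event_count_matches_rate(self):
        counts = []
        for seed in range(8):
            cfg = SimConfig(session_length_s=3600.0, seed=seed)
            _, events = syn.make_eye_trace(cfg)
            counts.append(len(events))
        # 60 min at 3.1/min -> ~186 events, Poisson-ish spread
        assert 140 <= np.mean(counts) <= 210

    def test_fixed_seed_bit_identical(self):
        cfg = SimConfig(session_length_s=600.0, seed=11)
        t1, e1 = syn.make_eye_trace(cfg)
        t2, e2 = syn.make_eye_trace(cfg)
        assert np.array_equal(t1.azimuth, t2.azimuth)
        pd.testing.assert_frame_equal(e1, e2)

    def test_session_too_short_fails(self):
        with pytest.raises(ValueError):
            syn.make_eye_trace(SimConfig(session_length_s=1.0))

    def test_quiet_periods_enforced(self):
        cfg = SimConfig(session_length_s=1200.0, seed=2)
        _, events = syn.make_eye_trace(cfg)
        gaps = events["onset_t"].to_numpy()[1:] - events["offset_t"].to_numpy()[:-1]
        assert (gaps >= cfg.quiet_min_s - 1e-9).all()


class TestGroundTruth:
    def test_preference_independence(self):
        cfg = SimConfig(n_units=400, seed=5)
        gt = syn.make_ground_truth(cfg)
        # correlation of the circular coordinates vanishes ~ 2/sqrt(n)
        r = np.corrcoef(
            np.cos(np.radians(gt["pref_dir_visual"])),
            np.cos(np.radians(gt["pref_dir_nonvisual"])),
        )[0, 1]
        assert abs(r) <= 2.0 / np.sqrt(len(gt))

    def test_nonnegative_baselines(self):
        gt = syn.make_ground_truth(SimConfig(n_units=100, seed=1))
        assert (gt["baseline"] >= 0).all()
        assert (gt["suppression_amp"] <= gt["nonvisual_amp"]).all()


class TestKernels:
    cfg = SimConfig()
    unit = pd.Series(
        {
            "pref_dir_nonvisual": 0.0,
            "pref_dir_visual": 0.0,
            "nonvisual_amp": 10.0,
            "visual_amp": 6.0,
            "suppression_amp": 5.0,
            "baseline": 4.0,
        }
    )

    def test_nonvisual_peak_at_preferred(self):
        k = syn.nonvisual_rate_kernel(self.unit, 0.0, self.cfg)
        t = np.arange(-300.0, 400.0, 1.0)
        assert k(t).max() == pytest.approx(10.0, abs=1e-9)

    def test_nonvisual_suppression_opposite(self):
        k = syn.nonvisual_rate_kernel(self.unit, 180.0, self.cfg)
        t = np.arange(-300.0, 400.0, 1.0)
        assert k(t).min() == pytest.approx(-5.0, abs=1e-9)

    def test_nonvisual_pre_onset_build_up(self):
        k = syn.nonvisual_rate_kernel(self.unit, 0.0, self.cfg)
        t = np.arange(-200.0, 0.0, 1.0)
        assert np.sum(k(t)) > 0.0
        assert k(np.array([-self.cfg.pre_onset_lead_ms - 1.0]))[0] == 0.0

    def test_visual_strictly_causal(self):
        k = syn.visual_rate_kernel(self.unit, "nasal", 10.0, self.cfg)
        t = np.arange(-200.0, self.cfg.visual_latency_ms, 1.0)
        assert np.all(k(t[t < self.cfg.visual_latency_ms]) == 0.0)
        assert k(np.array([-10.0]))[0] == 0.0

    def test_visual_no_suppression_and_pref_ratio(self):
        t = np.arange(0.0, 300.0, 1.0)
        k_pref = syn.visual_rate_kernel(self.unit, "nasal", 10.0, self.cfg)
        k_anti = syn.visual_rate_kernel(self.unit, "temporal", 10.0, self.cfg)
        assert np.all(k_anti(t) >= 0.0)
        assert k_pref(t).max() > k_anti(t).max() > 0.0

    def test_visual_amplitude_scaling(self):
        t = np.arange(0.0, 300.0, 1.0)
        small = syn.visual_rate_kernel(self.unit, "nasal", 5.0, self.cfg)(t).max()
        large = syn.visual_rate_kernel(self.unit, "nasal", 20.0, self.cfg)(t).max()
        zero = syn.visual_rate_kernel(self.unit, "nasal", 0.0, self.cfg)(t)
        assert large > small > 0.0
        assert np.all(zero == 0.0)


class TestSimulateSpikes:
    def test_homogeneous_poisson_mean(self, rng):
        rate = np.full(100_000, 10.0)  # 10 Hz for 100 s at 1-ms bins
        n = len(syn.simulate_spikes(rate, 0.001, np.random.default_rng(0)))
        assert abs(n - 1000) < 4 * np.sqrt(1000)

    def test_spike_times_sorted_within_span(self):
        rate = np.full(5000, 30.0)
        st = syn.simulate_spikes(rate, 0.001, np.random.default_rng(1), t0_s=2.0)
        assert np.all(np.diff(st) >= 0)
        assert st.min() >= 2.0 and st.max() <= 7.0

    def test_grating_equals_gain_times_sum(self):
        # high baseline so the non-negativity clip never binds: windowed
        # grating response = g * (grey-screen + pseudo responses)
        cfg = SimConfig(
            session_length_s=40.0,
            n_units=3,
            baseline_rate_range=(30.0, 40.0),
            nonvisual_gain_range=(5.0, 15.0),
            visual_gain_range=(3.0, 8.0),
            nonvisual_trial_gain_sd=0.0,
            seed=6,
        )
        gt = syn.make_ground_truth(cfg)
        onsets = np.arange(1.0, 39.0, 1.0)
        events = pd.DataFrame(
            {
                "onset_t": np.tile(onsets, 1),
                "amplitude": 10.0,
                "direction_deg": 0.0,
                "direction_label": "nasal",
            }
        )
        rng = np.random.default_rng(3)
        means = {}
        for cond in ("grey_screen", "pseudo", "grating"):
            resp = []
            for rep in range(60):
                spikes = syn.simulate_condition(gt, events, cond, cfg, rng, duration_s=40.0)
                for uid, st in spikes.items():
                    counts = windowed_counts(st, onsets)
                    resp.append((counts["response"] - counts["baseline"]).mean())
            means[cond] = np.mean(resp)
        expected = cfg.integration_gain * (means["grey_screen"] + means["pseudo"])
        assert means["grating"] == pytest.approx(expected, abs=0.06)

    def test_silenced_condition_no_pre_onset_modulation(self):
        cfg = SimConfig(session_length_s=60.0, n_units=4, seed=8)
        gt = syn.make_ground_truth(cfg)
        onsets = np.arange(1.0, 59.0, 1.0)
        events = pd.DataFrame(
            {
                "onset_t": onsets,
                "amplitude": 10.0,
                "direction_deg": gt.loc[0, "pref_dir_nonvisual"],
                "direction_label": "nasal",
            }
        )
        rng = np.random.default_rng(9)
        spikes = syn.simulate_condition(
            gt, events, "pulvinar_silenced", cfg, rng, duration_s=60.0
        )
        pre = []
        for uid, st in spikes.items():
            counts = windowed_counts(
                st, onsets, response_ms=(-200.0, 0.0), baseline_ms=(-450.0, -250.0)
            )
            pre.append((counts["response"] - counts["baseline"]).mean())
        assert np.mean(pre) == pytest.approx(0.0, abs=0.05)


class TestSessionLevel:
    def test_session_determinism(self):
        cfg = SimConfig(session_length_s=120.0, n_units=6, seed=13)
        s1 = syn.generate_session(cfg, conditions=("grey_screen",))
        s2 = syn.generate_session(cfg, conditions=("grey_screen",))
        assert np.array_equal(s1.trace.azimuth, s2.trace.azimuth)
        pd.testing.assert_frame_equal(s1.ground_truth, s2.ground_truth)
        for uid in s1.spikes["grey_screen"]:
            assert np.array_equal(
                s1.spikes["grey_screen"][uid], s2.spikes["grey_screen"][uid]
            )

    def test_peth_divergence_timing(self, small_session):
        """Grey-screen responses build up before onset; pseudo responses do not."""
        sess = small_session
        cfg = sess.config
        sac = sess.saccades["onset_t"].to_numpy()
        pse = sess.pseudos["onset_t"].to_numpy()
        pre_mod, causal_ok = [], []
        for _, unit in sess.ground_truth.iterrows():
            uid = int(unit["unit_id"])
            p_grey = peth(sess.spikes["grey_screen"][uid], sac)
            p_pseudo = peth(sess.spikes["pseudo"][uid], pse)
            base = p_grey.loc[p_grey["bin_right_ms"] <= -200, "mean_rate_hz"].mean()
            pre = p_grey.loc[
                (p_grey["bin_left_ms"] >= -100) & (p_grey["bin_right_ms"] <= 0),
                "mean_rate_hz",
            ].mean()
            pre_mod.append(pre - base)
            base_p = p_pseudo.loc[p_pseudo["bin_right_ms"] <= 0, "mean_rate_hz"].mean()
            pre_p = p_pseudo.loc[
                (p_pseudo["bin_left_ms"] >= -40) & (p_pseudo["bin_right_ms"] <= 40),
                "mean_rate_hz",
            ].mean()
            causal_ok.append(abs(pre_p - base_p))
        # population-average pre-onset build-up on grey screen only
        assert np.mean(pre_mod) > 0.2
        assert np.mean(causal_ok) < np.mean(pre_mod)


class TestResponseTable:
    def test_noiseless_linear_relation_exact(self):
        cfg = SimConfig(n_units=32, seed=3)
        gt = syn.make_ground_truth(cfg)
        tab = syn.make_response_table(gt, cfg, noise="none")
        lhs = tab["y_grating"].to_numpy()
        rhs = cfg.integration_gain * (tab["x_visual"] + tab["x_nonvisual"]).to_numpy()
        assert np.allclose(lhs, rhs)

    def test_poisson_table_deterministic_given_rng(self):
        cfg = SimConfig(n_units=16, seed=3)
        gt = syn.make_ground_truth(cfg)
        t1 = syn.make_response_table(gt, cfg, rng=np.random.default_rng(5))
        t2 = syn.make_response_table(gt, cfg, rng=np.random.default_rng(5))
        pd.testing.assert_frame_equal(t1, t2)
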