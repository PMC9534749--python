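"""Windowed counts, PETHs, discriminability, responsiveness and unit metadata."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from saccadeflow import response_stats as rs


def brute_force_gini(nasal, temporal):
    """O(n^2) pair-counting oracle for the signed NT discriminability."""
    wins = ties = 0
    for a in nasal:
        for b in temporal:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    aroc = (wins + 0.5 * ties) / (len(nasal) * len(temporal))
    return 2.0 * aroc - 1.0


class TestWindowedCounts:
    def test_half_open_response_window(self):
        spikes = np.array([10.010, 10.050, 10.099, 10.150])
        out = rs.windowed_counts(spikes, np.array([10.0]))
        assert out.loc[0, "response"] == 3  # +150 ms falls outside [0, 100)
        assert out.loc[0, "baseline"] == 0

    def test_no_spikes(self):
        out = rs.windowed_counts(np.array([]), np.array([5.0]))
        assert (out.loc[0] == 0).all()

    def test_poisson_rate_recovered(self, rng):
        spikes = np.sort(rng.uniform(0, 1000, 20000))  # 20 Hz homogeneous
        onsets = rng.uniform(10, 990, 400)
        out = rs.windowed_counts(spikes, onsets)
        assert out["response"].mean() == pytest.approx(2.0, rel=0.1)
        assert out["baseline"].mean() == pytest.approx(2.0, rel=0.1)

    def test_edge_events_dropped(self):
        out = rs.windowed_counts(
            np.array([0.5]), np.array([0.1, 5.0]), recording_span=(0.0, 10.0)
        )
        assert list(out.index) == [1]  # first event's baseline window < 0


class TestPeth:
    def test_flat_rate_flat_peth(self, rng):
        spikes = np.sort(rng.uniform(0, 500, 5000))  # 10 Hz
        onsets = rng.uniform(5, 495, 300)
        p = rs.peth(spikes, onsets)
        assert p["mean_rate_hz"].mean() == pytest.approx(10.0, rel=0.1)
        assert p["mean_rate_hz"].std() < 2.0

    def test_zero_spikes_zero_peth(self):
        p = rs.peth(np.array([]), np.array([1.0, 2.0]))
        assert (p["mean_rate_hz"] == 0).all()

    def test_single_spike_lands_in_its_bin(self):
        p = rs.peth(np.array([5.030]), np.array([5.0]))
        hot = p[p["mean_rate_hz"] > 0]
        assert len(hot) == 1
        assert hot.iloc[0]["bin_left_ms"] == 20.0
        assert hot.iloc[0]["mean_rate_hz"] == pytest.approx(50.0)  # 1 spike / 20 ms


class TestNormalizeAndAverage:
    @staticmethod
    def fake_peth(rates):
        edges = np.arange(-500.0, 501.0, 20.0)
        return pd.DataFrame(
            {
                "bin_left_ms": edges[:-1],
                "bin_right_ms": edges[1:],
                "mean_rate_hz": rates,
                "sem_hz": 0.0,
                "n_events": 10,
            }
        )

    def test_all_below_floor_fails(self):
        peths = [self.fake_peth(np.full(50, 5.0))] * 3
        with pytest.raises(ValueError):
            rs.normalize_and_average_peths(peths, np.full(3, 0.4))

    def test_identical_units_average_is_individual(self):
        peths = [self.fake_peth(np.full(50, 8.0))] * 4
        out = rs.normalize_and_average_peths(peths, np.full(4, 2.0))
        assert np.allclose(out["mean"], 6.0)  # 8 Hz - 2 Hz baseline

    def test_known_mixture(self):
        peths = [self.fake_peth(np.full(50, 4.0)), self.fake_peth(np.full(50, 10.0))]
        out = rs.normalize_and_average_peths(peths, np.array([1.0, 3.0]))
        assert np.allclose(out["mean"], ((4 - 1) + (10 - 3)) / 2)

    def test_divide_mode(self):
        peths = [self.fake_peth(np.full(50, 4.0))]
        out = rs.normalize_and_average_peths(peths, np.array([2.0]), mode="divide")
        assert np.allclose(out["mean"], 2.0)


class TestBinwiseDirectionTest:
    def test_null_produces_no_flags(self, rng):
        rates = rng.normal(10.0, 2.0, size=(40, 50))
        out = rs.binwise_direction_test(rates, rates.copy())
        assert not out["significant"].any()

    def test_shifted_central_bins_flagged(self, rng):
        nonpref = rng.normal(10.0, 1.0, size=(50, 50))
        pref = nonpref + 0.0
        pref = pref.copy()
        pref[:, 22:27] += 2.0
        out = rs.binwise_direction_test(pref, nonpref)
        assert out.loc[22:26, "significant"].all()
        assert out.drop(index=range(22, 27))["significant"].sum() == 0

    def test_too_few_units_untestable(self, rng):
        rates = rng.normal(10, 1, size=(4, 10))
        out = rs.binwise_direction_test(rates, rates + 1.0)
        assert not out["testable"].any()
        assert out["p_value"].isna().all()


class TestNtDiscriminability:
    def test_perfect_separation(self):
        r = rs.nt_discriminability([5, 6, 7], [1, 2, 3])
        assert r.gini == pytest.approx(1.0)

    def test_identical_samples(self):
        r = rs.nt_discriminability([2, 2, 2], [2, 2, 2])
        assert r.gini == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_worked_example(self):
        # nasal {2,3}, temporal {1,2}: pairs (2>1), (2=2: half), (3>1), (3>2)
        r = rs.nt_discriminability([2, 3], [1, 2])
        assert r.gini == pytest.approx(2 * (3.5 / 4) - 1)
        assert r.gini == pytest.approx(0.75)

    def test_antisymmetry(self, rng):
        a = rng.poisson(3, 15)
        b = rng.poisson(5, 12)
        assert rs.nt_discriminability(a, b).gini == pytest.approx(
            -rs.nt_discriminability(b, a).gini
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rs.nt_discriminability([], [1, 2])

    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle(self, data):
        nasal = data.draw(
            st.lists(st.integers(0, 8), min_size=1, max_size=12), label="nasal"
        )
        temporal = data.draw(
            st.lists(st.integers(0, 8), min_size=1, max_size=12), label="temporal"
        )
        r = rs.nt_discriminability(nasal, temporal)
        assert r.gini == pytest.approx(brute_force_gini(nasal, temporal), abs=1e-12)
        assert abs(r.gini) <= 1.0


class TestResponsivenessHeadFixed:
    @staticmethod
    def unit_counts(rng, base_hz, resp_hz_nasal, resp_hz_temporal, n=40):
        window = 0.1
        return {
            "nasal": pd.DataFrame(
                {
                    "response": rng.poisson(resp_hz_nasal * window, n),
                    "baseline": rng.poisson(base_hz * window, n),
                }
            ),
            "temporal": pd.DataFrame(
                {
                    "response": rng.poisson(resp_hz_temporal * window, n),
                    "baseline": rng.poisson(base_hz * window, n),
                }
            ),
        }

    def test_strong_response_detected(self, rng):
        counts = {u: self.unit_counts(rng, 5.0, 30.0, 30.0) for u in range(8)}
        out = rs.responsiveness_head_fixed(counts)
        assert out["responsive"].all()

    def test_zero_spikes_not_responsive(self, rng):
        counts = {0: self.unit_counts(rng, 0.0, 0.0, 0.0)}
        out = rs.responsiveness_head_fixed(counts)
        assert not out["responsive"].any()

    def test_too_few_events_rejected(self, rng):
        counts = {0: self.unit_counts(rng, 5.0, 10.0, 10.0, n=10)}
        with pytest.raises(ValueError):
            rs.responsiveness_head_fixed(counts)

    def test_null_false_positive_rate_controlled(self, rng):
        fdps = []
        for _ in range(200):
            counts = {u: self.unit_counts(rng, 8.0, 8.0, 8.0, n=20) for u in range(20)}
            out = rs.responsiveness_head_fixed(counts)
            n_pos = int(out["responsive"].sum())
            fdps.append(1.0 if n_pos > 0 else 0.0)
        assert np.mean(fdps) <= 0.12  # FDR target 10% + Monte-Carlo slack


class TestResponsivenessFreelyMoving:
    @staticmethod
    def sector_counts(rng, rates_hz, base_hz=5.0, n=25):
        return {
            s: pd.DataFrame(
                {
                    "response": rng.poisson(rates_hz[s] * 0.1, n),
                    "baseline": rng.poisson(base_hz * 0.1, n),
                }
            )
            for s in range(8)
        }

    def test_single_direction_modulation_detected(self, rng):
        rates = np.full(8, 5.0)
        rates[2] = 40.0
        hits = sum(
            rs.responsiveness_freely_moving(self.sector_counts(rng, rates))
            for _ in range(10)
        )
        assert hits >= 8

    def test_null_unit_rarely_flagged(self, rng):
        hits = sum(
            rs.responsiveness_freely_moving(self.sector_counts(rng, np.full(8, 5.0)))
            for _ in range(60)
        )
        assert hits <= 3  # alpha 0.05

    def test_all_zero_degenerate(self, rng):
        counts = self.sector_counts(rng, np.zeros(8), base_hz=0.0)
        assert rs.responsiveness_freely_moving(counts) is False


class TestPreferredDirectionFree:
    def test_single_hot_sector(self, rng):
        counts = {s: np.zeros(20) for s in range(8)}
        counts[2] = np.full(20, 5.0)
        out = rs.preferred_direction_and_discriminability_free(counts)
        assert out["pref_sector"] == 2
        assert out["pref_dir_deg"] == 90.0
        assert out["abs_gini"] == pytest.approx(1.0)

    def test_uniform_low_gini(self, rng):
        counts = {s: rng.poisson(3, 40).astype(float) for s in range(8)}
        out = rs.preferred_direction_and_discriminability_free(counts)
        assert out["abs_gini"] < 0.35

    def test_cosine_tuned_recovery(self, rng):
        true_pref = 3  # sector index
        sectors = np.arange(8)
        rates = 6.0 + 5.0 * np.cos(np.radians(45.0 * (sectors - true_pref)))
        counts = {s: rng.poisson(rates[s] * 0.4, 80).astype(float) for s in range(8)}
        out = rs.preferred_direction_and_discriminability_free(counts)
        assert min(abs(out["pref_sector"] - true_pref), 8 - abs(out["pref_sector"] - true_pref)) <= 1


class TestDSI:
    @pytest.mark.parametrize("pref,nonpref,expected", [(10, 10, 0.0), (10, 0, 1.0), (15, 5, 0.5)])
    def test_values(self, pref, nonpref, expected):
        assert rs.direction_selectivity_index(pref, nonpref) == pytest.approx(expected)

    def test_undefined_at_zero(self):
        with pytest.raises(ValueError):
            rs.direction_selectivity_index(0.0, 0.0)


class TestEyePositionExclusion:
    def test_position_coupled_unit_dropped(self, rng):
        # baseline systematically higher before nasal saccades
        flagged = rs.exclude_eye_position_units(
            {0: (rng.poisson(8, 60), rng.poisson(3, 60))}
        )
        assert not flagged.loc[0, "keep"]

    def test_direction_agnostic_unit_kept(self, rng):
        flagged = rs.exclude_eye_position_units(
            {0: (rng.poisson(5, 60), rng.poisson(5, 60))}
        )
        assert flagged.loc[0, "keep"]

    def test_null_population_drop_fraction(self, rng):
        counts = {u: (rng.poisson(5, 40), rng.poisson(5, 40)) for u in range(300)}
        flagged = rs.exclude_eye_position_units(counts)
        drop_rate = 1.0 - flagged["keep"].mean()
        assert drop_rate <= 0.08  # alpha 0.05 + Monte-Carlo slack


class TestRaoSpacingTest:
    def test_even_spacing_is_minimum(self):
        u, _ = rs.rao_spacing_test(np.arange(0, 360, 30.0), n_resamples=200)
        assert u == pytest.approx(0.0, abs=1e-9)

    def test_identical_angles_maximum(self):
        n = 6
        u, p = rs.rao_spacing_test(np.full(n, 123.4), n_resamples=500)
        # spacings: (n-1) zeros and one full circle
        assert u == pytest.approx(360.0 * (n - 1) / n)
        assert p < 0.05

    def test_null_pvalues_roughly_uniform(self, rng):
        ps = [
            rs.rao_spacing_test(rng.uniform(0, 360, 12), n_resamples=400, seed=i)[1]
            for i in range(80)
        ]
        assert 0.25 < np.mean(ps) < 0.75
        assert min(ps) < 0.25 and max(ps) > 0.75


class TestUnitMetadata:
    @pytest.mark.parametrize("width,expected", [(0.6, "RS"), (0.3, "FS"), (0.5, "FS")])
    def test_spike_width_classes(self, width, expected):
        assert rs.classify_spike_width(width) == expected

    def test_layer_assignment_worked_example(self):
        depth = np.arange(100.0, 1000.0, 50.0)
        rate = np.exp(-((depth - 600.0) ** 2) / (2 * 50.0**2))
        out = rs.assign_layers(depth, rate)
        assert not out["ambiguous"].any()
        assert out["border_um"].iloc[0] == pytest.approx(475.0)
        assert (out.loc[(depth >= 475) & (depth <= 675), "layer"] == "L5").all()
        assert (out.loc[(depth >= 325) & (depth < 475), "layer"] == "L4").all()
        assert (out.loc[depth < 325, "layer"] == "L2/3").all()
        assert (out.loc[depth > 675, "layer"] == "L6").all()

    def test_flat_profile_ambiguous(self):
        out = rs.assign_layers(np.arange(5) * 100.0, np.ones(5))
        assert out["ambiguous"].all()
        assert (out["layer"] == "unknown").all()

    def test_two_peaks_flagged(self):
        rate = np.array([0.0, 1.0, 0.5, 1.0, 0.0])
        out = rs.assign_layers(np.arange(5) * 100.0, rate)
        assert out["ambiguous"].all()


class TestAntidromicId:
    def test_reliable_low_jitter_identified(self, rng):
        pulses = np.arange(100) * 6.0
        spikes = pulses + 0.002 + rng.normal(0, 0.0001, 100)  # 2 ms +- 0.1 ms
        out = rs.antidromic_id(np.sort(spikes), pulses)
        assert out["identified"]

    def test_unreliable_not_identified(self, rng):
        pulses = np.arange(100) * 6.0
        spikes = pulses[:10] + 0.002  # 10% reliability
        out = rs.antidromic_id(spikes, pulses)
        assert not out["identified"]
        assert out["response_probability"] == pytest.approx(0.1)

    def test_high_jitter_not_identified(self, rng):
        pulses = np.arange(100) * 6.0
        spikes = np.sort(pulses[:50] + np.abs(rng.normal(0.002, 0.0008, 50)))
        out = rs.antidromic_id(spikes, pulses)
        assert not out["identified"]

    def test_no_pulses_fails(self):
        with pytest.raises(ValueError):
            rs.antidromic_id(np.array([1.0]), np.array([]))
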