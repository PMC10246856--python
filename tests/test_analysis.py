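"""Observables: contact maps, mixing index, P(s), fits, MSD, R_g."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromix.analysis import (CONTACT_CUTOFF, ContactMap, MixingTrace,
                              UndefinedMixingIndexError, classify_mixing_state,
                              compute_contact_map, contact_probability,
                              extrapolate_mixing_time, fit_power_law,
                              ideal_mixing_alpha, mixing_index, mixing_trace,
                              msd, radius_of_gyration)
from chromix.hic_io import synth_contact_fixture, synth_gaussian_chain_sample
from chromix.model_core import ScalingFit


class TestContactMap:
    def test_cutoff_is_inclusive_below_1p5_sigma(self):
        offsets = [0, 1, 2]
        for r, expected in [(1.4, 10), (1.6, 0)]:
            pos = np.array([[0.0, 0, 0], [r, 0, 0]])
            frames = np.repeat(pos[None], 10, axis=0)
            cmap = compute_contact_map(frames, offsets)
            assert cmap.counts[0, 1] == expected

    def test_map_is_symmetric(self, rng):
        frames = rng.uniform(-3, 3, (5, 40, 3))
        cmap = compute_contact_map(frames, [0, 20, 40])
        assert np.array_equal(cmap.counts, cmap.counts.T)

    def test_matches_brute_force_scan(self, rng):
        pos = rng.uniform(-3, 3, (50, 3))
        offsets = np.array([0, 25, 50])
        cmap = compute_contact_map(pos, offsets)
        chain = np.repeat([0, 1], 25)
        expect = np.zeros((50, 50))
        for i in range(50):
            for j in range(i + 1, 50):
                if chain[i] == chain[j] and j - i <= 1:
                    continue
                if np.linalg.norm(pos[i] - pos[j]) < CONTACT_CUTOFF:
                    expect[i, j] = expect[j, i] = 1
        assert np.array_equal(cmap.counts, expect)

    def test_empty_frames_rejected(self):
        with pytest.raises(ValueError):
            compute_contact_map(np.empty((0, 10, 3)), [0, 10])

    def test_offsets_validated(self):
        with pytest.raises(ValueError):
            ContactMap(counts=np.zeros((4, 4)), chain_offsets=[0, 2, 3])


class TestMixingIndex:
    def test_ideal_four_equal_chains_gives_three(self):
        cmap, alpha = synth_contact_fixture("ideal_mixing", [100] * 4)
        assert mixing_index(cmap) == pytest.approx(3.0, abs=1e-12)
        assert alpha == pytest.approx(3.0, abs=1e-12)

    def test_two_equal_chains_give_one(self):
        cmap, _ = synth_contact_fixture("ideal_mixing", [80, 80])
        assert mixing_index(cmap) == pytest.approx(1.0, abs=1e-12)

    def test_block_diagonal_gives_zero(self):
        cmap, alpha = synth_contact_fixture("block_diagonal", [50] * 4)
        assert mixing_index(cmap) == 0.0 == alpha

    def test_invariant_under_chain_relabeling(self):
        cmap, _ = synth_contact_fixture("graded", [30, 40, 50], mixing=0.4)
        a0 = mixing_index(cmap)
        # reverse the chain order (permute blocks)
        offs = cmap.chain_offsets
        order = np.concatenate([
            np.arange(offs[c], offs[c + 1]) for c in [2, 1, 0]
        ])
        permuted = ContactMap(
            counts=cmap.counts[np.ix_(order, order)],
            chain_offsets=[0, 50, 90, 120],
        )
        assert mixing_index(permuted) == pytest.approx(a0, rel=1e-12)

    def test_invariant_under_count_scaling(self):
        cmap, _ = synth_contact_fixture("graded", [40] * 3, mixing=0.7)
        scaled = ContactMap(counts=cmap.counts * 17.3,
                            chain_offsets=cmap.chain_offsets)
        assert mixing_index(scaled) == pytest.approx(mixing_index(cmap),
                                                     rel=1e-12)

    def test_zero_intra_contacts_undefined(self):
        counts = np.zeros((4, 4))
        counts[0, 2] = counts[2, 0] = 5  # inter only
        cmap = ContactMap(counts=counts, chain_offsets=[0, 2, 4])
        with pytest.raises(UndefinedMixingIndexError):
            mixing_index(cmap)

    def test_single_chain_rejected(self):
        cmap = ContactMap(counts=np.zeros((3, 3)), chain_offsets=[0, 3])
        with pytest.raises(ValueError):
            mixing_index(cmap)

    def test_finite_size_ideal_limits(self):
        assert ideal_mixing_alpha([10 ** 6] * 4) == pytest.approx(3.0,
                                                                  abs=1e-4)
        assert ideal_mixing_alpha([200] * 4) == pytest.approx(3.0457,
                                                              abs=1e-3)


class TestMixingTrace:
    def test_static_separated_chains_stay_zero(self):
        pos = np.zeros((20, 3))
        pos[:10, 0] = np.arange(10)
        pos[10:, 0] = np.arange(10) + 100.0
        frames = np.repeat(pos[None], 5, axis=0)

        class T:
            pass

        t = T()
        t.frames = frames
        t.times = np.arange(5.0)
        mt = mixing_trace(t, chain_offsets=[0, 10, 20])
        assert np.all(mt.alpha == 0.0)
        assert mt.alpha_bar == 0.0

    def test_trace_length_matches_frames(self, rng):
        frames = rng.uniform(-2, 2, (8, 30, 3))

        class T:
            pass

        t = T()
        t.frames = frames
        t.times = np.arange(8.0)
        mt = mixing_trace(t, chain_offsets=[0, 15, 30])
        assert len(mt.alpha) == len(mt.times) <= 8
        assert mt.alpha_max == 1.0

    def test_negative_alpha_rejected_by_container(self):
        with pytest.raises(ValueError):
            MixingTrace(times=np.arange(3.0), alpha=np.array([0.1, -0.2, 0.3]),
                        alpha_max=3.0)


class TestContactProbability:
    def test_straight_chain_has_no_distant_contacts(self):
        pos = np.zeros((50, 3))
        pos[:, 0] = np.arange(50)
        s, p = contact_probability(pos)
        assert np.all(p == 0.0)
        assert s[0] == 2  # bonded pairs excluded

    def test_probabilities_bounded(self, rng):
        frames = rng.normal(scale=1.0, size=(4, 60, 3))
        s, p = contact_probability(frames, [0, 30, 60])
        assert np.all((p >= 0) & (p <= 1))

    def test_ideal_chain_exponent_is_three_halves(self):
        # direct-sampled freely-jointed chains; modest size for speed
        sv = np.unique(np.geomspace(20, 200, 12).astype(int))
        batches = synth_gaussian_chain_sample(1000, 3000, seed=8,
                                              batch_size=500)
        s, p = contact_probability(batches, s_values=sv)
        fit = fit_power_law(s, p, decay=True)
        assert fit.exponent == pytest.approx(1.5, abs=0.06)


class TestPowerLawFit:
    def test_noiseless_decay_recovered_exactly(self):
        x = np.geomspace(1, 100, 20)
        fit = fit_power_law(x, x ** -2, decay=True)
        assert fit.exponent == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_growth_recovered(self, rng):
        x = np.geomspace(1, 1e4, 100)
        y = 0.1 * x ** 0.25 * np.exp(rng.normal(0, 0.05, 100))
        fit = fit_power_law(x, y)
        assert fit.exponent == pytest.approx(0.25, abs=0.02)
        assert fit.prefactor == pytest.approx(0.1, rel=0.15)

    def test_two_regime_recovery(self, rng):
        x = np.geomspace(1, 1e4, 60)
        xb = 100.0
        y = np.where(x < xb, 0.05 * x ** 0.19,
                     0.05 * xb ** 0.19 * (x / xb) ** 0.04)
        y *= np.exp(rng.normal(0, 0.02, 60))
        fit = fit_power_law(x, y, two_regime=True)
        assert fit.breakpoint is not None
        assert xb / 2 <= fit.breakpoint <= xb * 2
        assert fit.exponent == pytest.approx(0.19, abs=0.03)
        assert fit.second_exponent == pytest.approx(0.04, abs=0.03)

    def test_two_regime_prefers_single_when_unbroken(self, rng):
        x = np.geomspace(1, 1e3, 40)
        y = 2.0 * x ** 0.5 * np.exp(rng.normal(0, 0.03, 40))
        fit = fit_power_law(x, y, two_regime=True)
        assert fit.breakpoint is None

    def test_window_and_validation(self):
        x = np.geomspace(1, 100, 30)
        fit = fit_power_law(x, x ** 1.0, window=(5, 50))
        assert fit.window[0] >= 5 and fit.window[1] <= 50
        with pytest.raises(ValueError):
            fit_power_law(x[:4], x[:4])
        with pytest.raises(ValueError):
            fit_power_law(x, -x)


class TestExtrapolation:
    @staticmethod
    def _trace(t_ref, alpha_ref):
        return MixingTrace(times=np.array([t_ref / 2, t_ref]),
                           alpha=np.array([alpha_ref, alpha_ref]),
                           alpha_max=3.0)

    def test_closed_form_example(self):
        # alpha(1e6 tau) = 0.3, beta = 0.25 -> full mixing at 1e10 tau
        beta = 0.25
        fit = ScalingFit(exponent=beta, prefactor=0.3 / 1e6 ** beta,
                         window=(1e4, 1e6), r_squared=1.0)
        t = extrapolate_mixing_time(self._trace(1e6, 0.3), fit, alpha_max=3.0)
        assert t == pytest.approx(1e10, rel=1e-9)

    def test_already_mixed_returns_reference_time(self):
        fit = ScalingFit(exponent=0.25, prefactor=3.0 / 1e6 ** 0.25,
                         window=(1e4, 1e6), r_squared=1.0)
        t = extrapolate_mixing_time(self._trace(1e6, 3.0), fit, alpha_max=3.0)
        assert t == pytest.approx(1e6)

    def test_vanishing_exponent_never_mixes(self):
        fit = ScalingFit(exponent=0.0, prefactor=0.3, window=(1e4, 1e6),
                         r_squared=1.0)
        assert extrapolate_mixing_time(self._trace(1e6, 0.3), fit,
                                       alpha_max=3.0) == math.inf

    def test_two_regime_uses_final_segment(self):
        fit = ScalingFit(exponent=0.19, prefactor=0.05, window=(1.0, 1e6),
                         r_squared=1.0, breakpoint=100.0,
                         second_exponent=0.04)
        t = extrapolate_mixing_time(self._trace(1e6, 0.1), fit, alpha_max=3.0)
        a_ref = 0.05 * 100 ** 0.19 * (1e6 / 100) ** 0.04
        assert t == pytest.approx(1e6 * (3.0 / a_ref) ** (1 / 0.04), rel=1e-6)


class TestClassification:
    def test_fastest_pair_mixes_within_tc(self):
        out = classify_mixing_state(6.2e7)
        assert out["label"] == "mixes_within_tc"
        assert out["decade"] == 7

    def test_infinite_time_is_rare_mixing(self):
        out = classify_mixing_state(math.inf)
        assert out["label"] == "rare_mixing"
        assert out["decade"] == 16

    def test_boundary_inclusive(self):
        assert classify_mixing_state(2.68e12)["label"] == "mixes_within_tc"

    def test_beta_band_consistency(self):
        assert classify_mixing_state(1e10, beta=0.2)["beta_band_consistent"]
        assert not classify_mixing_state(1e10,
                                         beta=0.05)["beta_band_consistent"]
        assert classify_mixing_state(1e15, beta=0.05)["beta_band_consistent"]


class TestMSD:
    def test_static_beads_zero(self):
        frames = np.ones((20, 5, 3))

        class T:
            pass

        t = T()
        t.frames = frames
        t.times = np.arange(20.0)
        lags, vals, _ = msd(t)
        assert np.allclose(vals, 0.0, atol=1e-10)

    def test_single_origin_matches_direct(self, rng):
        frames = rng.normal(size=(15, 4, 3)).cumsum(axis=0)

        class T:
            pass

        t = T()
        t.frames = frames
        t.times = np.arange(15.0)
        lags, vals, _ = msd(t, origin_mode="single")
        direct = np.mean(np.sum((frames[5] - frames[0]) ** 2, axis=1))
        assert vals[4] == pytest.approx(direct, rel=1e-9)

    def test_multiple_origin_matches_direct_average(self, rng):
        frames = rng.normal(size=(30, 3, 3)).cumsum(axis=0)

        class T:
            pass

        t = T()
        t.frames = frames
        t.times = np.arange(30.0)
        lags, vals, _ = msd(t, origin_mode="multiple")
        lag = 7
        direct = np.mean([
            np.sum((frames[k + lag] - frames[k]) ** 2, axis=1)
            for k in range(30 - lag)
        ])
        assert vals[lag - 1] == pytest.approx(direct, rel=1e-9)

    def test_empty_subset_rejected(self, rng):
        class T:
            pass

        t = T()
        t.frames = rng.normal(size=(12, 4, 3))
        t.times = np.arange(12.0)
        with pytest.raises(ValueError):
            msd(t, bead_subset=[])


class TestSerialization:
    def test_mixing_grid_roundtrip(self, tmp_path):
        from chromix.analysis import read_mixing_grid, write_mixing_grid
        records = [
            {"phi": 0.1, "eps": 0.25, "beta": 0.21, "t_mix": 3.1e9,
             "decade": 9},
            {"phi": 0.4, "eps": 0.3, "beta": 0.25, "t_mix": 6.2e7,
             "decade": 7},
        ]
        path = tmp_path / "grid.tsv"
        write_mixing_grid(records, path)
        back = read_mixing_grid(path)
        assert back[1]["t_mix"] == pytest.approx(6.2e7)
        assert back[0]["beta"] == pytest.approx(0.21)

    def test_fit_record_is_json_ready(self):
        import json
        fit = ScalingFit(exponent=1.5, prefactor=2.0, window=(1.0, 10.0),
                         r_squared=0.99)
        rec = json.loads(json.dumps(fit.to_dict()))
        assert rec["exponent"] == 1.5
        assert rec["breakpoint"] is None


class TestRadiusOfGyration:
    def test_two_beads_two_sigma_apart(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(pos) == pytest.approx(1.0)

    def test_ideal_chain_closed_form(self):
        # <Rg^2> = (M^2 - 1)/(6 M) sigma^2 for a freely-jointed chain
        M = 400
        ens = synth_gaussian_chain_sample(M, 800, seed=3)
        rg2 = np.mean([radius_of_gyration(c) ** 2 for c in ens])
        assert rg2 == pytest.approx((M * M - 1) / (6 * M), rel=0.05)

    def test_per_chain_output(self, rng):
        pos = rng.normal(size=(20, 3))
        cid = np.repeat([0, 1], 10)
        rgs = radius_of_gyration(pos, cid, per_chain=True)
        assert len(rgs) == 2
        assert rgs[0] == pytest.approx(radius_of_gyration(pos[:10]))

    @settings(derandomize=True, max_examples=20)
    @given(shift=st.floats(-50, 50))
    def test_translation_invariance(self, shift):
        pos = np.array([[0.0, 0, 0], [1, 1, 0], [2, 0, 1]])
        assert radius_of_gyration(pos + shift) == pytest.approx(
            radius_of_gyration(pos), rel=1e-9
        )
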