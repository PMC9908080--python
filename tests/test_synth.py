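"""Synthetic cohort, montage and planted-effect EEG generators."""

import numpy as np
import pandas as pd
import pytest

from oualt.container import EpochedEEG
from oualt import synth
from oualt.design import generate_schedule
from oualt.synth import (
    generate_cohort,
    generate_gamma_coupling,
    generate_montage,
    generate_response_locked_eeg,
    generate_stimulus_locked_eeg,
    pink_noise,
)


class TestMontage:
    def test_channel_count_and_names(self, montage128):
        assert montage128.n_channels == 128
        assert len(set(montage128.ch_names)) == 128

    def test_adjacency_symmetric_no_self_edges(self, montage128):
        a = montage128.adjacency.toarray()
        assert np.array_equal(a, a.T)
        assert not a.diagonal().any()

    def test_interior_degree_six(self, montage128):
        pos = montage128.positions
        r = np.linalg.norm(pos, axis=1)
        interior = r < r.max() - 1.0
        deg = np.asarray(montage128.adjacency.sum(axis=1)).ravel()
        assert deg[interior].mean() == pytest.approx(6.0)

    def test_labeled_sets_nonempty_connected_disjoint(self, montage128):
        from scipy.sparse.csgraph import connected_components

        seen = set()
        for name, idx in montage128.sets.items():
            assert idx.size >= 4
            sub = montage128.adjacency[np.ix_(idx, idx)]
            ncomp, _ = connected_components(sub, directed=False)
            assert ncomp == 1
            assert not (set(idx.tolist()) & seen)
            seen.update(idx.tolist())

    def test_anterior_posterior_layout(self, montage128):
        pos = montage128.positions
        assert pos[montage128.sets["centrofrontal_cluster"], 1].mean() > 0
        assert pos[montage128.sets["parietal_cluster"], 1].mean() < 0
        assert (
            pos[montage128.sets["parietal_cluster"], 1].mean()
            < pos[montage128.sets["centroparietal_cluster"], 1].mean()
        )

    def test_disconnected_radius_rejected(self):
        with pytest.raises(ValueError):
            generate_montage(64, neighbor_radius=0.5)

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            generate_montage(8)


class TestCohort:
    @pytest.fixture(scope="class")
    def cohort38(self, design):
        return generate_cohort(38, design, seed=23)

    def test_deterministic(self, design):
        t1, b1 = generate_cohort(4, design, seed=9)
        t2, b2 = generate_cohort(4, design, seed=9)
        for p1, p2 in zip(t1.participants, t2.participants):
            assert p1["params"] == p2["params"]
            assert p1["group"] == p2["group"]
        for pid in b1:
            assert b1[pid].equals(b2[pid])

    def test_omega_means_near_group_values(self, cohort38):
        truth, _ = cohort38
        w_adv = [p["params"]["ADV"].omega for p in truth.participants]
        w_dis = [p["params"]["DIS"].omega for p in truth.participants]
        # within 2 printed standard errors of the group means
        assert abs(np.mean(w_adv) - 0.15) < 0.04
        assert abs(np.mean(w_dis) - 0.10) < 0.04

    def test_group_split_balanced_and_consistent(self, cohort38):
        truth, _ = cohort38
        groups = truth.groups()
        assert abs(groups.count("MA") - groups.count("LA")) <= 1
        med = np.median([p["params"]["DIS"].omega for p in truth.participants])
        for p in truth.participants:
            if p["params"]["DIS"].omega > med:
                assert p["group"] == "MA"
            elif p["params"]["DIS"].omega < med:
                assert p["group"] == "LA"

    def test_behavior_covers_design(self, cohort38, design):
        _, behavior = cohort38
        b = behavior["sub-00"]
        assert len(b) == 416
        assert set(b.trial_index) == set(design.table.trial_index)

    def test_planted_b2_sign_tracks_group(self, cohort38):
        truth, _ = cohort38
        for p in truth.participants:
            if p["group"] == "MA":
                assert p["planted"]["b2_dis"] > 0
            else:
                assert p["planted"]["b2_dis"] <= 0

    def test_drawn_params_inside_fitting_bounds(self, cohort38):
        from oualt.fitting import DEFAULT_BOUNDS

        truth, _ = cohort38
        for p in truth.participants:
            for ctx in ("DIS", "ADV"):
                q = p["params"][ctx]
                assert DEFAULT_BOUNDS["alpha"][0] <= q.alpha <= DEFAULT_BOUNDS["alpha"][1]
                assert DEFAULT_BOUNDS["kappa"][0] <= q.kappa <= DEFAULT_BOUNDS["kappa"][1]
                assert DEFAULT_BOUNDS["tau"][0] <= q.tau <= DEFAULT_BOUNDS["tau"][1]
                assert abs(q.beta) <= 0.9 * q.alpha

    def test_too_small_cohort_rejected(self, design):
        with pytest.raises(ValueError):
            generate_cohort(1, design, seed=1)


@pytest.fixture(scope="module")
def small_response_eeg(design, mean_params, montage64):
    traces, ttimes = synth.ea_traces_for_design(mean_params, design, seed=31, n=120)
    eeg = generate_response_locked_eeg(
        pd.DataFrame(), traces, ttimes, montage64, seed=32,
        trial_table=design.table,
    )
    return eeg, traces, ttimes


class TestResponseLockedEEG:
    def test_shapes_and_metadata(self, small_response_eeg, montage64):
        eeg, traces, _ = small_response_eeg
        assert eeg.alignment == "response"
        assert eeg.data.shape == (montage64.n_channels, len(eeg.times), 416)
        assert eeg.times[0] == pytest.approx(-1.0)
        assert eeg.times[-1] == pytest.approx(0.2)

    def test_noiseless_limit_correlates_perfectly(self, design, mean_params, montage64):
        traces, ttimes = synth.ea_traces_for_design(
            mean_params, design, seed=41, n=60
        )
        eeg = generate_response_locked_eeg(
            pd.DataFrame(), traces, ttimes, montage64, seed=42, snr=1e6,
            trial_table=design.table,
        )
        ch = montage64.sets["parietal_cluster"][0]
        m = eeg.time_mask(-0.6, -0.1)
        trial = int(np.argmax(np.ptp(traces, axis=1)))
        sig = eeg.data[ch, m, trial]
        r = np.corrcoef(sig, np.interp(eeg.times[m], ttimes, traces[trial]))[0, 1]
        assert r > 0.999

    def test_weights_zero_outside_parietal(self, design, mean_params, montage64):
        traces, ttimes = synth.ea_traces_for_design(mean_params, design, seed=43, n=60)
        a = generate_response_locked_eeg(
            pd.DataFrame(), traces, ttimes, montage64, seed=44, snr=1e6,
            trial_table=design.table,
        )
        outside = np.setdiff1d(np.arange(montage64.n_channels),
                               montage64.sets["parietal_cluster"])
        # with negligible noise, non-parietal channels carry ~nothing
        assert np.abs(a.data[outside]).max() < np.abs(a.data).max() * 1e-3

    def test_determinism(self, design, mean_params, montage64):
        traces, ttimes = synth.ea_traces_for_design(mean_params, design, seed=45, n=40)
        a = generate_response_locked_eeg(pd.DataFrame(), traces, ttimes,
                                         montage64, seed=46, trial_table=design.table)
        b = generate_response_locked_eeg(pd.DataFrame(), traces, ttimes,
                                         montage64, seed=46, trial_table=design.table)
        assert np.array_equal(a.data, b.data)

    def test_nonpositive_snr_rejected(self, design, mean_params, montage64):
        traces, ttimes = synth.ea_traces_for_design(mean_params, design, seed=47, n=20)
        with pytest.raises(ValueError):
            generate_response_locked_eeg(pd.DataFrame(), traces, ttimes,
                                         montage64, seed=48, snr=0.0,
                                         trial_table=design.table)


class TestStimulusLockedEEG:
    def test_null_coefficients_give_null_betas(self, design, montage64):
        from oualt.eeg import glm_beta_maps

        planted = dict(b1_early={"DIS": 0.0, "ADV": 0.0},
                       b1_late={"DIS": 0.0, "ADV": 0.0}, b2_dis=0.0)
        eeg = generate_stimulus_locked_eeg(design, planted, montage64, seed=51)
        bm = glm_beta_maps(eeg, context="DIS")
        n_trials = (design.table.context == "DIS").sum()
        se = 1.0 / np.sqrt(n_trials)  # unit-RMS noise, standardized regressor
        assert np.abs(bm.beta(1)).max() < 6 * se
        assert np.abs(bm.beta(1)).mean() < 2 * se

    def test_scale_invariance_of_standardized_regressors(self, design, montage64):
        from oualt.eeg import glm_beta_maps

        planted = dict(b1_early={"DIS": 0.7, "ADV": -0.7},
                       b1_late={"DIS": -0.7, "ADV": 0.7}, b2_dis=0.3)
        eeg = generate_stimulus_locked_eeg(design, planted, montage64, seed=52)
        bm1 = glm_beta_maps(eeg, context="DIS")
        scaled = EpochedEEG(
            data=eeg.data, times=eeg.times, sfreq=eeg.sfreq,
            ch_names=eeg.ch_names, positions=eeg.positions,
            trial_table=eeg.trial_table.assign(
                delta_self=eeg.trial_table.delta_self * 10
            ),
            alignment="stimulus",
        )
        bm2 = glm_beta_maps(scaled, context="DIS")
        np.testing.assert_allclose(bm1.coefficients, bm2.coefficients)

    def test_context_sign_flip_recovered(self, design, montage64):
        from oualt.eeg import glm_beta_maps

        planted = dict(b1_early={"DIS": 0.8, "ADV": -0.8},
                       b1_late={"DIS": -0.8, "ADV": 0.8}, b2_dis=0.0)
        eeg = generate_stimulus_locked_eeg(design, planted, montage64, seed=53)
        cp = montage64.sets["centroparietal_cluster"]
        early = slice(6, 9)  # 240-360 ms
        b_dis = glm_beta_maps(eeg, context="DIS").beta(1)[cp, early].mean()
        b_adv = glm_beta_maps(eeg, context="ADV").beta(1)[cp, early].mean()
        assert b_dis > 0.4 and b_adv < -0.4


class TestGammaCoupling:
    @pytest.fixture(scope="class")
    def silent_eeg(self, montage64):
        times = np.arange(-1.0, 0.2 + 1e-9, 1 / 500.0)
        n_trials = 200
        return EpochedEEG(
            data=np.zeros((montage64.n_channels, times.size, n_trials)),
            times=times, sfreq=500.0, ch_names=montage64.ch_names,
            positions=montage64.positions,
            trial_table=pd.DataFrame(dict(trial_index=np.arange(n_trials))),
            alignment="response",
        )

    def test_amplitude_matched_between_groups(self, silent_eeg, montage64):
        ma = generate_gamma_coupling(silent_eeg, "MA", montage64, seed=61)
        la = generate_gamma_coupling(silent_eeg, "LA", montage64, seed=61)
        f = montage64.sets["centrofrontal_cluster"]
        p_ma = np.mean(ma.data[f] ** 2)
        p_la = np.mean(la.data[f] ** 2)
        assert abs(p_ma - p_la) / p_ma < 0.05

    def test_burst_confined_to_window(self, silent_eeg, montage64):
        ma = generate_gamma_coupling(silent_eeg, "MA", montage64, seed=62)
        outside = ~silent_eeg.time_mask(-0.55, -0.43)
        assert np.abs(ma.data[:, outside, :]).max() == 0.0

    def test_unknown_group_rejected(self, silent_eeg, montage64):
        with pytest.raises(ValueError):
            generate_gamma_coupling(silent_eeg, "XX", montage64, seed=63)


class TestPinkNoise:
    def test_spectrum_slopes_down(self):
        rng = np.random.default_rng(0)
        x = pink_noise(rng, 2, 2048, 8, spatial_scale=0.0)
        f = np.fft.rfftfreq(2048, 1 / 500.0)
        pxx = np.abs(np.fft.rfft(x[0], axis=0)) ** 2
        low = pxx[(f > 2) & (f < 10)].mean()
        high = pxx[(f > 80) & (f < 150)].mean()
        assert low > 5 * high

    def test_unit_rms(self):
        rng = np.random.default_rng(1)
        x = pink_noise(rng, 4, 512, 16)
        assert x.std() == pytest.approx(1.0, abs=1e-6)
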