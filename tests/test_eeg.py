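"""EEG analyses: EA regression, build-up rates, GLM maps, cluster tests."""

import numpy as np
import pandas as pd
import pytest

from oualt.container import EpochedEEG
from oualt import synth
from oualt.eeg import (
    buildup_rate,
    cluster_permutation,
    crossval_ea_regression,
    glm_beta_maps,
)


def _flat_eeg(montage, n_trials=40, value=0.0, epoch=(-1.0, 0.2)):
    times = np.arange(epoch[0], epoch[1] + 1e-9, 1 / 500.0)
    data = np.full((montage.n_channels, times.size, n_trials), float(value))
    return EpochedEEG(
        data=data, times=times, sfreq=500.0, ch_names=montage.ch_names,
        positions=montage.positions,
        trial_table=pd.DataFrame(dict(trial_index=np.arange(n_trials))),
        alignment="response",
    )


class TestCrossvalEARegression:
    @pytest.fixture(scope="class")
    def planted(self, design, mean_params, montage64):
        traces, ttimes = synth.ea_traces_for_design(
            mean_params, design, seed=71, n=150
        )
        eeg = synth.generate_response_locked_eeg(
            pd.DataFrame(), traces, ttimes, montage64, seed=72,
            trial_table=design.table,
        )
        idx = np.where((design.table.context == "DIS").to_numpy())[0]
        return eeg.pick_trials(idx), traces[idx]

    def test_even_odd_split_partitions_trials(self, planted, montage64):
        eeg, traces = planted
        n = eeg.n_trials
        even = np.arange(n)[::2]
        odd = np.arange(n)[1::2]
        assert len(even) + len(odd) == n
        assert not (set(even) & set(odd))

    def test_selection_scale_invariant(self, planted, montage64):
        eeg, traces = planted
        a = crossval_ea_regression(eeg, traces, montage64)
        b = crossval_ea_regression(eeg, traces * 3.7, montage64)
        assert np.array_equal(a.selected_channels, b.selected_channels)
        assert a.heldout_r2 == pytest.approx(b.heldout_r2)

    def test_pure_noise_selects_nothing(self, design, mean_params, montage64):
        traces, ttimes = synth.ea_traces_for_design(
            mean_params, design, seed=73, n=80
        )
        idx = np.where((design.table.context == "DIS").to_numpy())[0]
        n_selected = 0
        for seed in range(10):
            rng = np.random.default_rng(900 + seed)
            noise = synth.pink_noise(
                rng, montage64.n_channels, 601, len(idx),
                positions=montage64.positions,
            )
            times = np.arange(-1.0, 0.2 + 1e-9, 1 / 500.0)
            eeg = EpochedEEG(
                data=noise, times=times, sfreq=500.0,
                ch_names=montage64.ch_names, positions=montage64.positions,
                trial_table=design.table.iloc[idx].reset_index(drop=True),
                alignment="response",
            )
            res = crossval_ea_regression(eeg, traces[idx], montage64)
            n_selected += res.selected_channels.size
            if res.selected_channels.size == 0:
                assert res.status == "empty"
                assert np.isnan(res.heldout_r2)
        assert n_selected <= 2

    def test_trace_count_mismatch_rejected(self, planted, montage64):
        eeg, traces = planted
        with pytest.raises(ValueError):
            crossval_ea_regression(eeg, traces[:-5], montage64)


class TestBuildupRate:
    def test_known_ramp_slope(self, montage64):
        eeg = _flat_eeg(montage64)
        m = eeg.time_mask(-1.0, 0.2)
        eeg.data[:] = (10.0 * eeg.times)[None, :, None]  # 10 uV/s everywhere
        assert buildup_rate(eeg, [0, 1, 2]) == pytest.approx(10.0, abs=1e-6)

    def test_flat_waveform_zero_slope(self, montage64):
        eeg = _flat_eeg(montage64, value=3.3)
        assert buildup_rate(eeg, [4, 5]) == pytest.approx(0.0, abs=1e-9)

    def test_positive_ramp_on_planted_accumulation_signal(
        self, design, montage64
    ):
        # the planted parietal evidence-accumulation component rises toward
        # the response, so the pre-response build-up rate is positive
        from oualt.behavior import OUParams

        for i, kappa in enumerate((0.45, 0.7, 1.0)):
            p = {
                "DIS": OUParams(alpha=1.34, beta=0.134, kappa=kappa,
                                omega=0.10, lambda_=-1.0, tau=0.3),
            }
            traces, ttimes = synth.ea_traces_for_design(
                p, design, seed=80 + i, n=100
            )
            idx = np.where((design.table.context == "DIS").to_numpy())[0]
            eeg = synth.generate_response_locked_eeg(
                pd.DataFrame(), traces[idx], ttimes, montage64, seed=85 + i,
                trial_table=design.table.iloc[idx],
            )
            assert buildup_rate(eeg, montage64.sets["parietal_cluster"]) > 0


class TestGLMBetaMaps:
    def test_bin_count_is_25(self, design, montage64):
        planted = dict(b1_early={"DIS": 0.5, "ADV": -0.5},
                       b1_late={"DIS": -0.5, "ADV": 0.5}, b2_dis=0.2)
        eeg = synth.generate_stimulus_locked_eeg(design, planted, montage64, seed=91)
        bm = glm_beta_maps(eeg, context="DIS")
        assert bm.n_bins == 25
        assert bm.coefficients.shape == (3, montage64.n_channels, 25)

    def test_planted_coefficient_recovered_in_block(self, design, montage64):
        planted = dict(b1_early={"DIS": 0.8, "ADV": -0.8},
                       b1_late={"DIS": 0.0, "ADV": 0.0}, b2_dis=0.0)
        eeg = synth.generate_stimulus_locked_eeg(design, planted, montage64, seed=92)
        bm = glm_beta_maps(eeg, context="DIS")
        cp = montage64.sets["centroparietal_cluster"]
        block = bm.beta(1)[cp, 6:9]
        n = (design.table.context == "DIS").sum()
        se = 1.0 / np.sqrt(n)
        assert abs(block.mean() - 0.8) < 2 * se

    def test_collinear_regressors_rejected(self, design, montage64):
        planted = dict(b1_early={"DIS": 0.0, "ADV": 0.0},
                       b1_late={"DIS": 0.0, "ADV": 0.0}, b2_dis=0.0)
        eeg = synth.generate_stimulus_locked_eeg(design, planted, montage64, seed=93)
        broken = EpochedEEG(
            data=eeg.data, times=eeg.times, sfreq=eeg.sfreq,
            ch_names=eeg.ch_names, positions=eeg.positions,
            trial_table=eeg.trial_table.assign(
                delta_other=eeg.trial_table.delta_self * 2
            ),
            alignment="stimulus",
        )
        with pytest.raises(ValueError, match="collinear"):
            glm_beta_maps(broken, context="DIS")


class TestClusterPermutation:
    def test_no_suprathreshold_points_gives_empty_list(self, montage64):
        a = np.ones((10, 64, 8))
        b = np.ones((10, 64, 8))
        out = cluster_permutation(a, b, "paired", montage64, n_perm=200, seed=1)
        assert out == []

    def test_planted_effect_detected(self, montage64, spatial_noise_maker):
        rng = np.random.default_rng(5)
        hits = 0
        chans = montage64.sets["centroparietal_cluster"]
        for r in range(10):
            a = spatial_noise_maker(montage64, 12, 10, rng)
            b = spatial_noise_maker(montage64, 12, 10, rng)
            a[:, chans, 3:8] += 2.0  # Cohen's d ~ 1.4 on the paired difference
            cl = cluster_permutation(a, b, "paired", montage64, n_perm=500, seed=r)
            hits += any(
                c.p_value < 0.05 and c.polarity > 0
                and set(chans.tolist()) & set(c.channels.tolist())
                for c in cl
            )
        assert hits >= 9

    def test_independent_contrast_antisymmetric(self, montage64, spatial_noise_maker):
        rng = np.random.default_rng(6)
        a = spatial_noise_maker(montage64, 10, 6, rng)
        b = spatial_noise_maker(montage64, 10, 6, rng)
        a[:, montage64.sets["parietal_cluster"], 2:5] += 1.2
        c1 = cluster_permutation(a, b, "independent", montage64, n_perm=300, seed=7)
        c2 = cluster_permutation(b, a, "independent", montage64, n_perm=300, seed=7)
        m1 = sorted(round(c.mass, 6) for c in c1)
        m2 = sorted(round(-c.mass, 6) for c in c2)
        assert m1 == m2

    def test_channel_relabeling_invariance(self, spatial_noise_maker):
        # permuting channel identities consistently in maps and montage
        # leaves cluster masses and p-values unchanged
        from oualt.synth import Montage, generate_montage
        from scipy.sparse import csr_matrix

        mont = generate_montage(24, neighbor_radius=1.3)
        rng = np.random.default_rng(8)
        a = spatial_noise_maker(mont, 9, 5, rng)
        b = spatial_noise_maker(mont, 9, 5, rng)
        a[:, mont.sets["parietal_cluster"], 1:4] += 1.5
        perm = rng.permutation(24)
        adj = mont.adjacency.toarray()[np.ix_(perm, perm)]
        mont_p = Montage(
            ch_names=[mont.ch_names[i] for i in perm],
            positions=mont.positions[perm], adjacency=csr_matrix(adj),
            sets={},
        )
        c1 = cluster_permutation(a, b, "paired", mont, n_perm=300, seed=9)
        c2 = cluster_permutation(a[:, perm], b[:, perm], "paired", mont_p,
                                 n_perm=300, seed=9)
        assert [round(c.mass, 8) for c in c1] == [round(c.mass, 8) for c in c2]
        assert [c.p_value for c in c1] == [c.p_value for c in c2]

    def test_small_n_perm_rejected(self, montage64):
        a = np.zeros((5, 64, 4))
        with pytest.raises(ValueError):
            cluster_permutation(a, a, "paired", montage64, n_perm=50)

    def test_min_channel_rule(self, montage64, spatial_noise_maker):
        # a strong effect confined to a single channel never yields a
        # cluster under the three-channel rule
        rng = np.random.default_rng(10)
        a = rng.standard_normal((12, 64, 8))
        b = a.copy()
        b[:, 30, :] -= 5.0  # paired difference nonzero on one channel only
        cl = cluster_permutation(a, b, "paired", montage64, n_perm=200, seed=11)
        assert cl == []
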