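"""Sliding-window connectivity, model selection, states, occupancy, entropy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fusiconn import dyn_conn as dc
from fusiconn import preprocess as pp
from fusiconn import synthgen as sg


def _roits(signals, fs=1.0, t0=0.0, valid=None, meta=None):
    t = t0 + np.arange(signals.shape[1]) / fs
    labels = tuple(f"r{i}" for i in range(signals.shape[0]))
    return pp.RoiTimeSeries(signals=signals, time_s=t, fs=fs, valid=valid,
                            labels=labels, meta=meta or {})


class TestSlidingWindow:
    def test_full_session_window_count(self):
        rng = np.random.default_rng(0)
        r = _roits(rng.standard_normal((22, 3601)), t0=-1200.0)
        swc = dc.sliding_window_fc(r)
        assert swc.n_windows == 3572
        assert swc.windows.shape[1] == 484

    def test_single_window(self):
        rng = np.random.default_rng(1)
        swc = dc.sliding_window_fc(_roits(rng.standard_normal((22, 30))))
        assert swc.n_windows == 1

    @given(T=st.integers(min_value=30, max_value=200))
    @settings(max_examples=20, deadline=None)
    def test_window_count_identity(self, T):
        rng = np.random.default_rng(T)
        swc = dc.sliding_window_fc(_roits(rng.standard_normal((4, T))))
        assert swc.n_windows == T - 30 + 1

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            dc.sliding_window_fc(_roits(np.zeros((4, 10))))

    def test_rows_reshape_to_unit_diagonal_symmetric(self):
        rng = np.random.default_rng(2)
        swc = dc.sliding_window_fc(_roits(rng.standard_normal((6, 80))))
        for row in swc.windows[::13]:
            m = row.reshape(6, 6)
            assert np.allclose(m, m.T, atol=1e-12)
            assert np.allclose(np.diag(m), 1.0)

    def test_stationary_window_statistics(self):
        """Windowed r̂ for a planted 0.9 pair: mean ≈ 0.9 with the n=30
        sampling spread of Pearson r."""
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.standard_normal(n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        sig = np.vstack([x, y, rng.standard_normal((2, n))])
        swc = dc.sliding_window_fc(_roits(sig))
        rs = swc.windows[:, 1]                 # entry (0, 1)
        assert abs(rs.mean() - 0.9) < 0.02
        sd_expected = (1 - 0.81) / np.sqrt(29)
        assert 0.5 * sd_expected < rs.std() < 2.0 * sd_expected

    def test_low_validity_windows_flagged(self):
        rng = np.random.default_rng(4)
        valid = np.ones(100, bool)
        valid[40:60] = False
        swc = dc.sliding_window_fc(_roits(rng.standard_normal((4, 100)),
                                          valid=valid))
        assert swc.flagged[35]                 # window 35..64 has 15/30 valid
        assert not swc.flagged[0]


class TestConcatCohort:
    def _sequences(self, n_sessions=3, n_windows=40):
        rng = np.random.default_rng(5)
        out = []
        for i in range(n_sessions):
            out.append(dc.SwcSequence(
                windows=rng.standard_normal((n_windows, 484)),
                window_centers_s=np.arange(n_windows, dtype=float),
                meta={"subject": f"s{i}", "sex": "M", "condition": "VEH+KET"},
            ))
        return out

    def test_row_count_and_round_trip(self):
        seqs = self._sequences()
        x, idx = dc.concat_cohort(seqs)
        assert x.shape == (120, 484)
        row = idx.iloc[77]
        orig = seqs[row.session].windows[row.session_row]
        assert np.array_equal(x[77], orig)

    def test_single_session_passthrough(self):
        seqs = self._sequences(1)
        x, idx = dc.concat_cohort(seqs)
        assert np.array_equal(x, seqs[0].windows)

    def test_column_mismatch_rejected(self):
        seqs = self._sequences(2)
        seqs[1].windows = seqs[1].windows[:, :231]
        with pytest.raises(ValueError, match="column"):
            dc.concat_cohort(seqs)


class TestSvdElbow:
    def _matrix_with_spectrum(self, s, n=300, seed=0):
        rng = np.random.default_rng(seed)
        u, _ = np.linalg.qr(rng.standard_normal((n, len(s))))
        v, _ = np.linalg.qr(rng.standard_normal((len(s), len(s))))
        return (u * s) @ v.T

    def test_planted_spectrum_gives_three(self):
        s = np.array([100.0, 99.0, 98.0] + [1.0] * 8 + [0.5, 0.2, 0.1])
        x = self._matrix_with_spectrum(s)
        res = dc.svd_elbow(x, var_threshold=0.9999999)
        assert res.k_opt == 3
        res2 = dc.svd_elbow(x, var_threshold=0.9999999, method="steepest_drop")
        assert res2.k_opt == 3

    def test_rank_one_warns_k_one(self):
        x = np.outer(np.arange(1.0, 50.0), np.ones(20))
        with pytest.warns(UserWarning, match="rank-1"):
            res = dc.svd_elbow(x)
        assert res.k_opt == 1

    def test_isotropic_noise_has_low_saliency(self):
        rng = np.random.default_rng(6)
        noise = dc.svd_elbow(rng.standard_normal((400, 60)))
        s = np.array([80.0, 79.0, 78.0, 77.0] + [2.0] * 30)
        structured = dc.svd_elbow(self._matrix_with_spectrum(s, n=400, seed=7),
                                  var_threshold=0.9999999)
        assert noise.saliency < structured.saliency


class TestClusterStates:
    def test_separable_clouds_perfect_agreement(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((150, 484)) * 0.05
        b = rng.standard_normal((150, 484)) * 0.05 + 1.0
        x = np.vstack([a, b])
        truth = np.array([0] * 150 + [1] * 150)
        model = dc.cluster_states(x, 2, seed=0, n_init=5)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_sorting_contract_state_one_most_connected(self):
        rng = np.random.default_rng(8)
        lo = rng.standard_normal((100, 484)) * 0.02
        hi = lo + 0.8
        model = dc.cluster_states(np.vstack([lo, hi]), 2, seed=0, n_init=5)
        conn = model.mean_connectivity()
        assert conn[0] > conn[1]
        assert set(model.labels) == {1, 2}

    def test_k_floor(self):
        with pytest.raises(ValueError, match="k must be"):
            dc.cluster_states(np.zeros((10, 4)), 1)


class TestPhaseDifference:
    def test_identical_signals_give_unit_cos(self):
        rng = np.random.default_rng(9)
        x = pp.bandpass(rng.standard_normal(600), fs=1.0)
        sig = np.vstack([x, x, x])
        feats = dc.phase_difference_features(_roits(sig), check_band=False)
        assert np.allclose(feats, 1.0, atol=1e-9)

    def test_quadrature_sinusoids_near_zero(self):
        t = np.arange(1200.0)
        a = np.sin(2 * np.pi * 0.05 * t)
        b = np.sin(2 * np.pi * 0.05 * t + np.pi / 2)
        feats = dc.phase_difference_features(_roits(np.vstack([a, b])),
                                             check_band=False)
        mid = feats[200:-200, 1]
        assert np.abs(mid).max() < 0.05

    def test_broadband_input_warns(self):
        rng = np.random.default_rng(10)
        with pytest.warns(UserWarning, match="broadband"):
            dc.phase_difference_features(_roits(rng.standard_normal((3, 500))))

    def test_phase_features_reproduce_swc_partition(self):
        """Clustering phase features recovers the same 5-state partition as
        sliding-window correlation (adjusted Rand ≥ 0.6)."""
        cfg = sg.SessionConfig(t_start_min=-10, t_end_min=10)
        sessions = sg.generate_cohort(n_per_sex=3, conditions=("VEH+KET",),
                                      seed=3, config=cfg, n_states=5)
        from sklearn.metrics import adjusted_rand_score
        swc_feats, phase_feats, planted = [], [], []
        for s in sessions:
            sig = pp.bandpass(s.roits.signals, fs=1.0)
            rf = pp.RoiTimeSeries(signals=sig, time_s=s.roits.time_s, fs=1.0)
            swc = dc.sliding_window_fc(rf)
            swc_feats.append(swc.windows)
            # align phase timestamps with window centres
            ph = dc.phase_difference_features(rf, check_band=False)
            centers = (swc.window_centers_s - rf.time_s[0]).astype(int)
            phase_feats.append(ph[centers])
            st_seq = s.truth.state_sequence
            planted.append(np.array([
                st_seq[a] if (st_seq[a:a + 30] == st_seq[a]).all() else -1
                for a in range(len(st_seq) - 29)
            ]))
        x_swc = np.vstack(swc_feats)
        x_ph = np.vstack(phase_feats)
        keep = np.concatenate(planted) > 0
        m_swc = dc.cluster_states(x_swc, 5, seed=0, n_init=10)
        m_ph = dc.cluster_states(x_ph, 5, seed=0, n_init=10)
        ari = adjusted_rand_score(m_swc.labels[keep], m_ph.labels[keep])
        assert ari >= 0.6


class TestStateMetrics:
    def test_time_fraction_definition(self):
        m = dc.state_metrics(np.array([1, 1, 2, 2, 2]), np.arange(5.0), 2,
                             (0, 1), with_transitions=False)
        assert m.time_fraction[0] == pytest.approx(0.4)
        assert m.time_fraction[1] == pytest.approx(0.6)
        assert m.time_fraction.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dwell_time_run_arithmetic(self):
        m = dc.state_metrics(np.array([1, 1, 2, 1]), np.arange(4.0), 2,
                             (0, 1), with_transitions=False)
        assert m.dwell_time_s[0] == pytest.approx(1.5)   # runs (2, 1)
        assert m.dwell_time_s[1] == pytest.approx(1.0)

    def test_constant_labels(self):
        m = dc.state_metrics(np.full(60, 3), np.arange(60.0), 3, (0, 1))
        assert m.time_fraction[2] == 1.0
        assert m.dwell_time_s[2] == pytest.approx(60.0)
        assert np.isnan(m.dwell_time_s[0])

    def test_exclusion_gap_not_bridged(self):
        labels = np.full(20, 1)
        times = np.arange(20.0)
        m = dc.state_metrics(labels, times, 1, (0, 20 / 60),
                             exclusions_min=[(8 / 60, 11 / 60)],
                             with_transitions=False)
        # two clipped runs of 8 samples each, not one run of 16
        assert m.dwell_time_s[0] == pytest.approx(8.0)

    def test_dwell_weighted_by_runs_reproduces_time_fraction(self):
        rng = np.random.default_rng(11)
        labels = rng.integers(1, 4, size=400)
        times = np.arange(400.0)
        m = dc.state_metrics(labels, times, 3, (0, 400 / 60))
        counts = np.bincount(labels, minlength=4)[1:]
        np.testing.assert_allclose(m.time_fraction, counts / counts.sum())

    def test_empty_period_rejected(self):
        with pytest.raises(ValueError, match="no labelled windows"):
            dc.state_metrics(np.array([1, 2]), np.array([0.0, 1.0]), 2,
                             (10, 11))


class TestTransitionMatrix:
    def test_alternating_labels(self):
        p = dc.transition_matrix(np.array([1, 2, 1, 2, 1]))
        assert np.allclose(p, [[0, 1], [1, 0]])

    def test_constant_labels_self_probability_one(self):
        p = dc.transition_matrix(np.array([3, 3, 3]), k=3)
        assert p[2, 2] == 1.0
        assert np.isnan(p[0]).all()            # never-visited rows flagged

    def test_planted_chain_recovered(self):
        """Counting oracle: empirical P̂ within ±0.02 at 50k steps."""
        truth = sg.biased_transition(4, stay=0.7, target=2, bias=0.1)
        seq = sg.plant_state_sequence(truth, 50_000, seed=12)
        p = dc.transition_matrix(seq)
        assert np.max(np.abs(p - truth)) < 0.02

    def test_single_label_rejected(self):
        with pytest.raises(ValueError, match="2 labels"):
            dc.transition_matrix(np.array([1]))


class TestMarkovEntropy:
    def test_deterministic_cycle_zero(self):
        p = np.roll(np.eye(5), 1, axis=1)
        assert dc.markov_entropy(p) == 0.0

    def test_uniform_five_states(self):
        p = np.full((5, 5), 0.2)
        assert dc.markov_entropy(p) == pytest.approx(5 * np.log(5), abs=1e-12)

    def test_two_state_half(self):
        p = np.full((2, 2), 0.5)
        assert dc.markov_entropy(p) == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_zero_log_zero_handled(self):
        p = np.array([[1.0, 0.0], [0.5, 0.5]])
        assert dc.markov_entropy(p) == pytest.approx(np.log(2), abs=1e-12)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            dc.markov_entropy(np.array([[0.5, 0.4], [0.5, 0.5]]))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_uniform_rows_maximize_entropy(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        p = rng.dirichlet(np.ones(k), size=k)
        assert dc.markov_entropy(p) <= k * np.log(k) + 1e-9


class TestLeaveOneGroupOut:
    def _blobs(self, rng, centers, n=80, scale=0.05):
        return np.vstack([c + scale * rng.standard_normal((n, len(c)))
                          for c in centers])

    def test_duplicated_groups_give_unit_similarity(self):
        rng = np.random.default_rng(13)
        centers = [rng.standard_normal(484) for _ in range(3)]
        x1 = self._blobs(rng, centers)
        x2 = self._blobs(rng, centers)
        x = np.vstack([x1, x2])
        groups = np.array(["g1"] * len(x1) + ["g2"] * len(x2))
        report = dc.leave_one_group_out(x, groups, k=3, seed=0, n_init=5)
        assert (report["cosine_similarity"] > 0.999).all()

    def test_adversarial_group_flagged_by_similarity_drop(self):
        rng = np.random.default_rng(14)
        centers = [rng.standard_normal(100) for _ in range(3)]
        normal = [self._blobs(rng, centers, n=60) for _ in range(3)]
        weird = self._blobs(rng, [10 * c for c in centers], n=60)
        x = np.vstack(normal + [weird])
        groups = np.concatenate([
            np.full(180, "a"), np.full(180, "b"), np.full(180, "c"),
            np.full(180, "weird")])
        report = dc.leave_one_group_out(x, groups, k=3, seed=0, n_init=5)
        per_holdout = report.groupby("holdout")["cosine_similarity"].min()
        # removing the aberrant group changes centroids the most
        assert per_holdout["weird"] <= per_holdout.drop("weird").min() + 1e-9

    def test_holdout_cohort_stability(self):
        """Planted 5-state cohort: every sex × treatment holdout reproduces
        the full-data centroids (matched cosine ≥ 0.9)."""
        cfg = sg.SessionConfig(t_start_min=-10, t_end_min=10)
        sessions = sg.generate_cohort(n_per_sex=2,
                                      conditions=("VEH+KET", "NTX+KET"),
                                      seed=17, config=cfg, n_states=5)
        seqs = [dc.sliding_window_fc(pp.RoiTimeSeries(
            signals=pp.bandpass(s.roits.signals, fs=1.0),
            time_s=s.roits.time_s, fs=1.0, valid=s.roits.valid,
            meta=s.roits.meta)) for s in sessions]
        x, idx = dc.concat_cohort(seqs)
        groups = (idx["sex"] + "|" + idx["condition"]).to_numpy()
        report = dc.leave_one_group_out(x, groups, k=5, seed=0, n_init=10)
        assert report["cosine_similarity"].min() >= 0.9

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            dc.leave_one_group_out(np.zeros((10, 4)), np.full(10, "a"), k=2)
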