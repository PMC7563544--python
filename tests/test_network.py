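"""Cross-correlation networks, clustering coefficients, heart edges."""

import numpy as np
import pytest

from intentnet.errors import InsufficientDataError
from intentnet.kinematics import linear_speed
from intentnet.network import (
    AdjacencyMatrix,
    build_adjacency,
    clustering_coefficients,
    heart_body_connectivity,
    max_xcorr,
    windowed_xcorr,
)
from intentnet.pipeline import analyze_session
from intentnet.preprocessing import bandpass_ecg, segment_trials, target_distance_series
from intentnet.synthetic import SessionConfig, generate_session


class TestMaxXcorr:
    def test_identity_gives_unit_coefficient_zero_lag(self, rng):
        x = rng.standard_normal(500)
        res = max_xcorr(x, x, rate=100.0)
        assert res.coefficient == pytest.approx(1.0, abs=1e-9)
        assert res.lag_s == 0.0

    def test_delayed_copy_recovers_positive_lag(self, rng):
        # y delayed by 10 samples means x leads: lag = +10 samples
        x = rng.standard_normal(4000)
        y = np.roll(x, 10)
        res = max_xcorr(x, y, rate=200.0)
        assert res.lag_s == pytest.approx(10 / 200.0)
        assert res.coefficient > 0.9

    def test_white_noise_null_is_small(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            res = max_xcorr(r.standard_normal(10000), r.standard_normal(10000),
                            rate=240.0, max_lag=1.0)
            hits += res.coefficient < 0.1
        assert hits >= 19

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            max_xcorr(np.ones(100), np.arange(100.0), rate=10.0)

    def test_lag_antisymmetry(self, rng):
        x = rng.standard_normal(1000)
        y = np.roll(x, 7) + 0.1 * rng.standard_normal(1000)
        a = max_xcorr(x, y, rate=100.0)
        b = max_xcorr(y, x, rate=100.0)
        assert a.lag_s == pytest.approx(-b.lag_s)
        assert a.coefficient == pytest.approx(b.coefficient, abs=1e-9)


class TestWindowedXcorr:
    def test_constructed_shift_recovered(self, rng):
        n = 4000
        t = np.arange(n)
        y_bump = np.exp(-0.5 * ((t - 2000) / 60.0) ** 2)
        shift = 38  # x's feature earlier by 38 samples -> x leads
        x = np.roll(y_bump, -shift) + 0.01 * rng.standard_normal(n)
        res = windowed_xcorr(x, y_bump[1800:2200], 1800, rate=256.0, max_lag=0.4)
        assert res.lag_s == pytest.approx(shift / 256.0, abs=1.0 / 256.0)


def _micro_session(**kw):
    defaults = dict(n_trials=8, seed=19)
    defaults.update(kw)
    return generate_session(SessionConfig(**defaults))


class TestAdjacency:
    def test_common_source_gives_unit_weights(self):
        # all sensors driven by the same profile, no noise, full coupling
        s = _micro_session(coupling=1.0, background_frac=0.0, noise_sd=0.0,
                           path_fluct_m={"forward": 0.0, "backward": 0.0},
                           anticipation_ms={"performing": 0.0, "non_performing": 0.0,
                                            "midline": 0.0})
        ee = s.config.end_effector.label
        speeds = {lab: linear_speed(s.kinematics.parts[lab].pos, 240.0).values
                  for lab in s.kinematics.parts}
        windows = list(zip(s.trials["window_start"], s.trials["window_end"]))
        dist = target_distance_series(s.kinematics.parts[ee].pos, windows,
                                      s.ground_truth.targets)
        seg = segment_trials(speeds[ee], dist, trial_windows=windows)
        adj = build_adjacency(speeds, seg, "forward", 240.0)
        off = adj.weights[~np.eye(len(adj.labels), dtype=bool)]
        assert np.all(off > 0.999)

    def test_zero_coupling_null_has_low_weights(self):
        s = _micro_session(n_trials=30, coupling=0.0)
        ee = s.config.end_effector.label
        speeds = {lab: linear_speed(s.kinematics.parts[lab].pos, 240.0).values
                  for lab in s.kinematics.parts}
        windows = list(zip(s.trials["window_start"], s.trials["window_end"]))
        dist = target_distance_series(s.kinematics.parts[ee].pos, windows,
                                      s.ground_truth.targets)
        seg = segment_trials(speeds[ee], dist, trial_windows=windows)
        adj = build_adjacency(speeds, seg, "forward", 240.0)
        non_ee = [i for i, lab in enumerate(adj.labels) if lab != ee]
        off = [adj.weights[i, j] for i in non_ee for j in non_ee if i < j]
        assert np.median(off) < 0.2

    def test_symmetry_and_zero_diagonal(self, small_metrics):
        for segname in ("forward", "backward"):
            adj = small_metrics.adjacency[segname]
            assert np.allclose(adj.weights, adj.weights.T)
            assert np.allclose(np.diag(adj.weights), 0.0)
            assert np.allclose(adj.lags, -adj.lags.T)

    def test_insufficient_trials_raise(self, small_session):
        s = small_session
        speeds = {lab: linear_speed(s.kinematics.parts[lab].pos, 240.0).values
                  for lab in s.kinematics.parts}
        from intentnet.preprocessing import TrialSegment, TrialSegmentation

        seg = TrialSegmentation(
            [TrialSegment(0, (100, 200), (260, 380))], rate=240.0
        )
        with pytest.raises(InsufficientDataError):
            build_adjacency(speeds, seg, "forward", 240.0)


def _brute_force_clustering(weights):
    w = weights / weights.max()
    k = len(w)
    c = np.zeros(k)
    for i in range(k):
        deg = np.sum(weights[i] > 0)
        if deg < 2:
            continue
        t = 0.0
        for j in range(k):
            for h in range(j + 1, k):
                if j == i or h == i:
                    continue
                t += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        c[i] = 2.0 * t / (deg * (deg - 1))
    return c


class TestClustering:
    def test_complete_unit_triangle_is_one(self):
        w = np.ones((3, 3)) - np.eye(3)
        adj = AdjacencyMatrix(["a", "b", "c"], w, np.zeros((3, 3)))
        nm = clustering_coefficients(adj)
        assert np.allclose(nm.clustering, 1.0)

    def test_star_center_has_no_triangles(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 0.8
        adj = AdjacencyMatrix(list("abcd"), w, np.zeros((4, 4)))
        nm = clustering_coefficients(adj)
        assert nm.clustering[0] == 0.0
        assert np.all(nm.clustering[1:] == 0.0)  # leaves have degree 1

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(30):
            k = int(rng.integers(3, 9))
            w = rng.uniform(0.0, 1.0, (k, k))
            w = np.triu(w, 1)
            w = w + w.T
            w[w < 0.2] = 0.0  # some missing edges
            if w.max() == 0:
                continue
            adj = AdjacencyMatrix([str(i) for i in range(k)], w, np.zeros((k, k)))
            nm = clustering_coefficients(adj)
            assert np.allclose(nm.clustering, _brute_force_clustering(w), atol=1e-12)

    def test_matches_networkx_onnela(self, rng):
        import networkx as nx

        k = 7
        w = rng.uniform(0.1, 1.0, (k, k))
        w = np.triu(w, 1)
        w = w + w.T
        adj = AdjacencyMatrix([str(i) for i in range(k)], w, np.zeros((k, k)))
        nm = clustering_coefficients(adj)
        g = nx.Graph()
        for i in range(k):
            for j in range(i + 1, k):
                g.add_edge(str(i), str(j), weight=w[i, j])
        ref = nx.clustering(g, weight="weight")
        assert np.allclose(nm.clustering, [ref[str(i)] for i in range(k)], atol=1e-12)

    def test_monotone_under_uniform_weight_increase(self, rng):
        k = 6
        w = rng.uniform(0.1, 0.6, (k, k))
        w = np.triu(w, 1)
        w = w + w.T
        adj_lo = AdjacencyMatrix([str(i) for i in range(k)], w, np.zeros((k, k)))
        # raising all weights toward 1 on the same topology cannot decrease C_i
        w_hi = 1.0 - 0.5 * (1.0 - w)
        np.fill_diagonal(w_hi, 0.0)
        adj_hi = AdjacencyMatrix([str(i) for i in range(k)], w_hi, np.zeros((k, k)))
        lo = clustering_coefficients(adj_lo).clustering
        hi = clustering_coefficients(adj_hi).clustering
        assert np.all(hi >= lo - 1e-12)

    def test_empty_graph_all_zeros(self):
        adj = AdjacencyMatrix(["a", "b"], np.zeros((2, 2)), np.zeros((2, 2)))
        nm = clustering_coefficients(adj)
        assert np.all(nm.clustering == 0.0)


class TestHeartBody:
    def _lags_for(self, lead_f_ms, lead_b_ms, seed):
        cfg = SessionConfig(
            n_trials=12, seed=seed,
            heart_lead_ms={"forward": lead_f_ms, "backward": lead_b_ms},
            anticipation_ms={"performing": 0.0, "non_performing": 0.0, "midline": 0.0},
        )
        s = generate_session(cfg)
        sm = analyze_session(s.kinematics, s.ecg, s.trials, cfg.handedness)
        ee = cfg.end_effector.label
        out = {}
        for segname in ("forward", "backward"):
            edge = next(e for e in sm.heart[segname] if e.part == ee)
            out[segname] = edge.lag_s
        return out

    def test_injected_leads_recovered_with_sign(self):
        lags = self._lags_for(150.0, -150.0, seed=41)
        assert lags["forward"] == pytest.approx(0.150, abs=2.0 / 256.0)
        assert lags["backward"] == pytest.approx(-0.150, abs=2.0 / 256.0)

    def test_reversed_lead_flips_sign(self):
        lags = self._lags_for(-150.0, 150.0, seed=43)
        assert lags["forward"] == pytest.approx(-0.150, abs=2.0 / 256.0)
        assert lags["backward"] == pytest.approx(0.150, abs=2.0 / 256.0)

    def test_identical_histograms_give_zero_emd(self, small_metrics):
        from intentnet.stochastic import emd

        h = small_metrics.ekg_hists["forward"]
        assert emd(h, h) == 0.0

    def test_rate_mismatch_raises(self, small_session, small_metrics):
        from intentnet.errors import RateMismatchError

        s = small_session
        ecg_f = bandpass_ecg(s.ecg)
        speeds = {"x": np.zeros(1000)}
        with pytest.raises(RateMismatchError):
            heart_body_connectivity(ecg_f, speeds, small_metrics.segmentation, "forward")
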