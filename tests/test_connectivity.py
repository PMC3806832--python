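import numpy as np
import pytest

from ictalnet import connectivity as conn
from ictalnet import simulate as sim


def _stable_var2(rng, m=3):
    A = np.zeros((2, m, m))
    A[0] = np.diag(rng.uniform(0.3, 0.6, m))
    A[1] = np.diag(rng.uniform(-0.4, -0.1, m))
    A[0, 1, 0] = 0.3
    A[1, 2, 0] = -0.25
    return A


def _simulate_var(A, n, rng, burn=500):
    p, m, _ = A.shape
    x = np.zeros((n + burn, m))
    e = rng.standard_normal((n + burn, m))
    for t in range(p, n + burn):
        x[t] = e[t] + sum(A[k] @ x[t - 1 - k] for k in range(p))
    out = x[burn:].T
    return out - out.mean(axis=1, keepdims=True)


class TestFit:
    def test_known_var2_recovered(self, rng):
        A = _stable_var2(rng)
        x = _simulate_var(A, 20000, np.random.default_rng(0))
        model = conn.fit_mvar(x, 2, fs=200.0)
        rmse = np.sqrt(np.mean((model.coefficients - A) ** 2))
        assert rmse < 0.05
        assert model.stable

    def test_matches_statsmodels(self, rng):
        """Independent oracle: statsmodels VAR on the same data."""
        from statsmodels.tsa.api import VAR

        x = _simulate_var(_stable_var2(rng), 5000, np.random.default_rng(1))
        ours = conn.fit_mvar(x, 3, fs=1.0)
        ref = VAR(x.T).fit(3, trend="n")
        assert np.allclose(ours.coefficients, ref.coefs, atol=1e-10)
        assert np.allclose(ours.sigma, ref.sigma_u, rtol=1e-6)

    def test_deterministic(self, rng):
        x = rng.standard_normal((3, 3000))
        x -= x.mean(axis=1, keepdims=True)
        m1 = conn.fit_mvar(x, 4, fs=1.0)
        m2 = conn.fit_mvar(x, 4, fs=1.0)
        assert np.array_equal(m1.coefficients, m2.coefficients)
        assert np.array_equal(m1.sigma, m2.sigma)

    def test_white_noise_coefficients_within_standard_errors(self):
        hits = total = 0
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal((3, 5000))
            model = conn.fit_mvar(x, 3, fs=1.0)
            m = 3
            for k in range(model.order):
                for i in range(m):
                    for j in range(m):
                        var = model.sigma[i, i] * \
                            model.xtx_inv[k * m + j, k * m + j]
                        hits += abs(model.coefficients[k, i, j]) \
                            < 3 * np.sqrt(var)
                        total += 1
        assert hits / total >= 0.95

    def test_short_data_rejected(self, rng):
        with pytest.raises(ValueError, match="samples"):
            conn.fit_mvar(rng.standard_normal((3, 50)), 5)

    def test_rank_deficient_design_rejected(self):
        x = np.zeros((2, 500))
        x[0] = 1e-3
        with pytest.raises(np.linalg.LinAlgError):
            conn.fit_mvar(x, 2)


class TestOrderSelection:
    def test_pmax_one_returns_one(self, rng):
        assert conn.select_order_aic(rng.standard_normal((2, 500)), 1) == 1

    def test_var3_order_recovered_mostly(self):
        A = np.zeros((3, 3, 3))
        A[0] = np.diag([0.5, 0.4, 0.5])
        A[1] = np.diag([-0.3, -0.2, -0.3])
        A[2] = np.diag([0.3, 0.35, 0.3])
        A[2, 1, 0] = 0.25
        hits = sum(conn.select_order_aic(
            _simulate_var(A, 5000, np.random.default_rng(s)), 10) == 3
            for s in range(5))
        assert hits >= 4

    def test_white_noise_prefers_minimal_order(self):
        small = sum(conn.select_order_aic(
            np.random.default_rng(s).standard_normal((2, 3000)), 8) <= 2
            for s in range(10))
        assert small >= 8


class TestPDC:
    def test_column_normalization(self, rng):
        for seed in range(5):
            A = _stable_var2(np.random.default_rng(seed))
            model = conn.MVARModel(order=2, coefficients=A, sigma=np.eye(3),
                                   xtx_inv=np.eye(6), n_samples=1000,
                                   fs=200.0)
            pdc = conn.compute_pdc(model, np.linspace(0.5, 99.0, 23))
            colnorm = (pdc ** 2).sum(axis=1)
            assert np.abs(colnorm - 1.0).max() < 1e-10

    def test_diagonal_model_has_no_cross_terms(self):
        A = np.zeros((2, 3, 3))
        A[0] = np.diag([0.5, 0.4, 0.3])
        model = conn.MVARModel(order=2, coefficients=A, sigma=np.eye(3),
                               xtx_inv=np.eye(6), n_samples=1000, fs=200.0)
        pdc = conn.compute_pdc(model, [5.0, 20.0])
        off = pdc * (1 - np.eye(3))
        assert np.allclose(off, 0.0)

    def test_unidirectional_reverse_is_zero(self):
        A = np.zeros((1, 2, 2))
        A[0] = [[0.5, 0.0], [0.4, 0.5]]   # 1 -> 2 only
        model = conn.MVARModel(order=1, coefficients=A, sigma=np.eye(2),
                               xtx_inv=np.eye(2), n_samples=1000, fs=200.0)
        pdc = conn.compute_pdc(model, [10.0])
        assert pdc[0, 0, 1] == 0.0        # no 2 -> 1 influence
        assert pdc[0, 1, 0] > 0.0


class TestRPDC:
    def test_null_law_chi2(self):
        """Under zero coupling n*lambda is asymptotically chi-squared(2)."""
        vals = []
        for seed in range(60):
            x = np.random.default_rng(seed).standard_normal((2, 1000))
            model = conn.fit_mvar(x, 3, fs=200.0)
            lam = conn.compute_rpdc(model, [10.0, 30.0, 60.0])
            vals.extend(model.n_samples * lam[:, 0, 1])
            vals.extend(model.n_samples * lam[:, 1, 0])
        assert 1.5 <= np.mean(vals) <= 2.5

    def test_scale_invariance(self, rng):
        A = _stable_var2(rng)
        x = _simulate_var(A, 8000, np.random.default_rng(2))
        freqs = np.linspace(5.0, 40.0, 8)
        m1 = conn.fit_mvar(x, 2, fs=200.0)
        lam1 = conn.compute_rpdc(m1, freqs)
        pdc1 = conn.compute_pdc(m1, freqs)
        x2 = x.copy()
        x2[1] *= 10.0
        m2 = conn.fit_mvar(x2, 2, fs=200.0)
        lam2 = conn.compute_rpdc(m2, freqs)
        pdc2 = conn.compute_pdc(m2, freqs)
        rel = np.abs(lam2[:, 1, 0] - lam1[:, 1, 0]) / lam1[:, 1, 0]
        assert rel.max() < 0.05
        pdc_rel = np.abs(pdc2[:, 1, 0] - pdc1[:, 1, 0]) / pdc1[:, 1, 0]
        assert pdc_rel.max() > 0.2   # plain PDC is not scale invariant

    def test_unidirectional_asymmetry(self):
        A = np.zeros((2, 2, 2))
        A[0] = [[1.2, 0.0], [0.5, 1.2]]
        A[1] = [[-0.6, 0.0], [0.0, -0.6]]
        x = _simulate_var(A, 10000, np.random.default_rng(3))
        model = conn.fit_mvar(x, 2, fs=200.0)
        fc = 200.0 / (2 * np.pi) * np.arccos(1.2 / (2 * np.sqrt(0.6)))
        lam = conn.compute_rpdc(model, [fc]).squeeze(0)
        assert lam[1, 0] > 10 * lam[0, 1]


class TestBootstrap:
    def _null_rates(self, rule, runs=100):
        fp = 0
        pairs = 0
        for seed in range(runs):
            x = np.random.default_rng(seed).standard_normal((2, 600))
            res = conn.bootstrap_rpdc_null(x, 100.0, (10.0, 30.0), order=2,
                                           rule=rule, seed=seed)
            fp += res.significant.sum()
            pairs += 2
        return fp / pairs

    def test_mean_rule_is_permissive(self):
        """The literal surrogate-mean rule fires on about half of the null
        pairs, which motivates the rank-rule option."""
        rate = self._null_rates("mean")
        assert 0.3 <= rate <= 0.7

    def test_rank_rule_is_calibrated(self):
        assert self._null_rates("rank") <= 0.1

    def test_strong_coupling_detected_under_both_rules(self):
        A = np.zeros((2, 2, 2))
        A[0] = [[1.2, 0.0], [0.5, 1.2]]
        A[1] = [[-0.6, 0.0], [0.0, -0.6]]
        for rule in ("mean", "rank"):
            hits = 0
            for seed in range(10):
                x = _simulate_var(A, 2000, np.random.default_rng(seed))
                res = conn.bootstrap_rpdc_null(x, 200.0, (20.0, 35.0),
                                               order=2, rule=rule, seed=seed)
                hits += bool(res.significant[1, 0])
            assert hits >= 9

    def test_too_short_for_windows_rejected(self, rng):
        with pytest.raises(ValueError, match="window"):
            conn.bootstrap_rpdc_null(rng.standard_normal((2, 150)), 100.0,
                                     (10.0, 30.0), order=1)


class TestDecimation:
    def test_band_content_preserved(self):
        scen = sim.SourceScenario(((0, 0, 0.03),), ((0, 0, 1),),
                                  band=(16.0, 20.0))
        x = sim.simulate_coupled_sources(scen, 20000, 200.0)
        y, fs2 = conn.decimate_for_band(x, 200.0, (16.0, 20.0))
        assert fs2 == 50.0
        from scipy import signal as sps
        f, p = sps.periodogram(y[0], fs=fs2)
        assert 16.0 <= f[np.argmax(p)] <= 20.0

    def test_no_decimation_when_band_near_nyquist(self, rng):
        x = rng.standard_normal((2, 1000))
        y, fs2 = conn.decimate_for_band(x, 200.0, (60.0, 80.0))
        assert fs2 == 200.0
        assert y is x


class TestClassification:
    def _net(self, n, edges):
        return conn.DirectedNetwork(node_labels=[str(i) for i in range(n)],
                                    coordinates=None,
                                    edges=[(s, d, 1.0) for s, d in edges])

    def test_star_pattern(self):
        assert conn.classify_flow_pattern(
            self._net(3, [(0, 1), (0, 2)]), primary=0) == "star_out"

    def test_circular_pattern(self):
        assert conn.classify_flow_pattern(
            self._net(3, [(0, 1), (1, 2), (2, 0)]), primary=0) == "circular"

    def test_mixed_pattern(self):
        assert conn.classify_flow_pattern(
            self._net(3, [(0, 1), (2, 1)]), primary=0) == "mixed"

    def test_empty_pattern(self):
        assert conn.classify_flow_pattern(self._net(3, []), primary=0) == \
            "empty"

    def test_two_cycle_is_not_circular(self):
        assert conn.classify_flow_pattern(
            self._net(3, [(0, 1), (1, 0)]), primary=0) == "mixed"

    def test_primary_outside_network_rejected(self):
        with pytest.raises(ValueError, match="primary"):
            conn.classify_flow_pattern(self._net(3, [(0, 1)]), primary=7)

    def test_retention_and_isolation(self):
        m = 4
        observed = np.zeros((m, m))
        significant = np.zeros((m, m), bool)
        # strong true edges 0->1, 0->2; weak artifact 3->2
        observed[1, 0], observed[2, 0], observed[2, 3] = 1.0, 0.9, 0.1
        significant[1, 0] = significant[2, 0] = significant[2, 3] = True
        res = conn.RPDCResult(frequencies=np.array([18.0]),
                              rpdc=observed[None], observed_band=observed,
                              null_band=np.zeros((m, m)),
                              significant=significant, band=(16, 20),
                              rule="rank", n_shuffles=19, order=5)
        net = conn.build_directed_network(res, list("abcd"), primary=0,
                                          min_fraction_of_max=0.4,
                                          drop_isolated=True)
        assert net.topology_class == "star_out"
        assert len(net.node_labels) == 3   # node d dropped


class TestExports:
    def _result(self):
        m = 3
        obs = np.random.default_rng(0).uniform(0, 1, (m, m))
        np.fill_diagonal(obs, 0)
        sig = obs > 0.5
        np.fill_diagonal(sig, False)
        return conn.RPDCResult(frequencies=np.linspace(16, 20, 5),
                               rpdc=np.tile(obs, (5, 1, 1)),
                               observed_band=obs, null_band=obs * 0.5,
                               significant=sig, band=(16, 20), rule="rank",
                               n_shuffles=19, order=4)

    def test_csv_graphml_figure(self, tmp_path):
        import networkx as nx
        import pandas as pd

        res = self._result()
        conn.rpdc_to_csv(res, tmp_path / "rpdc.csv")
        df = pd.read_csv(tmp_path / "rpdc.csv")
        assert len(df) == 6 * 5
        net = conn.build_directed_network(res, list("abc"))
        conn.network_to_graphml(net, tmp_path / "net.graphml")
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_nodes() == 3
        conn.plot_rpdc_bars(res, tmp_path / "bars.svg")
        assert (tmp_path / "bars.svg").stat().st_size > 0
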