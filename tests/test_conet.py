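"""Association inference and bipartite network construction."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from edtia import conet


def _tables(rng, n=20, nm=4, nt=3):
    peaks = pd.DataFrame(rng.random((n, nm)) + 0.01,
                         columns=[f"m{i}" for i in range(nm)])
    otus = pd.DataFrame(rng.integers(1, 500, (n, nt)).astype(float),
                        columns=[f"g{j}" for j in range(nt)])
    return peaks, otus


class TestPrevalenceFilter:
    def test_majority_rule_boundary(self, rng):
        n = 150
        t = pd.DataFrame({
            "keep": ([1.0] * 75 + [0.0] * 75),
            "drop": ([1.0] * 74 + [0.0] * 76),
            "always": np.ones(n),
        })
        filtered, dropped = conet.prevalence_filter(t, 0.5)
        assert "keep" in filtered.columns and "always" in filtered.columns
        assert dropped == ["drop"]

    def test_zero_threshold_is_identity(self, rng):
        t = pd.DataFrame(rng.random((10, 5)) * (rng.random((10, 5)) < 0.3))
        filtered, dropped = conet.prevalence_filter(t, 0.0)
        assert list(filtered.columns) == list(t.columns) and dropped == []

    def test_empty_result_errors(self):
        t = pd.DataFrame({"a": [0.0, 1.0, 0.0, 0.0]})
        with pytest.raises(ValueError):
            conet.prevalence_filter(t, 0.5)


class TestSpearman:
    def test_monotone_and_antimonotone(self):
        x = pd.DataFrame({"m": [1.0, 2, 3, 4, 5, 6]})
        up = pd.DataFrame({"g": [2.0, 4, 5, 7, 8, 11]})
        down = pd.DataFrame({"g": [11.0, 8, 7, 5, 4, 2]})
        assert conet.spearman_matrix(x, up).rho.iloc[0, 0] == pytest.approx(1.0)
        assert conet.spearman_matrix(x, down).rho.iloc[0, 0] == pytest.approx(-1.0)

    def test_six_point_toy_matches_rank_formula(self, rng):
        peaks, otus = _tables(rng, n=6)
        c = conet.spearman_matrix(peaks, otus)
        for m in peaks.columns:
            for g in otus.columns:
                rho, p = spearmanr(peaks[m], otus[g])
                assert c.rho.loc[m, g] == pytest.approx(rho, abs=1e-12)
                assert c.p.loc[m, g] == pytest.approx(p, abs=1e-12)

    def test_mismatched_samples_error(self, rng):
        peaks, otus = _tables(rng)
        with pytest.raises(ValueError):
            conet.spearman_matrix(peaks, otus.iloc[::-1])


class TestDeltaRho:
    def _corr(self, rows):
        rho = pd.DataFrame(rows, index=["mol"], columns=[f"g{i}" for i in
                                                         range(len(rows[0]))])
        return conet.CorrelationMatrix(rho=rho)

    def test_mixed_signs(self):
        res = conet.delta_rho(self._corr([[0.6, 0.8, -0.5]]))
        assert res.loc["mol", "delta_rho"] == pytest.approx(0.2)
        assert res.loc["mol", "flag"] == ""

    def test_positive_only_flagged(self):
        res = conet.delta_rho(self._corr([[0.4, np.nan]]))
        assert res.loc["mol", "delta_rho"] == pytest.approx(0.4)
        assert res.loc["mol", "flag"] == "positive_only"

    def test_symmetric_sets_cancel(self):
        res = conet.delta_rho(self._corr([[0.3, 0.5, -0.3, -0.5]]))
        assert res.loc["mol", "delta_rho"] == pytest.approx(0.0)

    def test_no_usable_correlations_missing(self):
        res = conet.delta_rho(self._corr([[np.nan, np.nan]]))
        assert res.loc["mol", "flag"] == "missing"


class TestSparCC:
    def test_independent_components_stay_weak(self, rng):
        n, nm, nt = 150, 30, 15
        peaks = pd.DataFrame(np.exp(rng.normal(0, 1, (n, nm))),
                             columns=[f"m{i}" for i in range(nm)])
        peaks = peaks.div(peaks.sum(axis=1), axis=0)
        otus = pd.DataFrame(
            rng.poisson(np.exp(rng.normal(4, 1, (n, nt)))).astype(float),
            columns=[f"g{j}" for j in range(nt)])
        corr = conet.sparcc_correlations(peaks, otus, n_bootstrap=20, seed=1,
                                         n_permutations=0)
        frac = (np.abs(corr.rho.to_numpy()) >= 0.3).mean()
        assert frac <= 0.05

    def test_shared_basis_signal_detected(self, rng):
        n = 150
        base = rng.normal(0, 1, n)
        logs = rng.normal(0, 1, (n, 20))
        logs[:, 0] = 0.9 * base + math.sqrt(1 - 0.81) * rng.normal(0, 1, n)
        peaks = pd.DataFrame(np.exp(logs), columns=[f"m{i}" for i in range(20)])
        peaks = peaks.div(peaks.sum(axis=1), axis=0)
        logt = rng.normal(0, 1, (n, 10))
        logt[:, 0] = 0.9 * base + math.sqrt(1 - 0.81) * rng.normal(0, 1, n)
        otus = pd.DataFrame(np.exp(logt) * 1000,
                            columns=[f"g{j}" for j in range(10)])
        corr = conet.sparcc_correlations(peaks, otus, n_bootstrap=20, seed=2,
                                         n_permutations=0)
        assert corr.rho.loc["m0", "g0"] >= 0.5

    def test_sample_order_permutation_invariant(self, rng):
        peaks, otus = _tables(rng, n=60, nm=20, nt=10)
        c1 = conet.sparcc_correlations(peaks, otus, n_bootstrap=0, seed=3,
                                       n_permutations=0)
        perm = rng.permutation(60)
        c2 = conet.sparcc_correlations(peaks.iloc[perm], otus.iloc[perm],
                                       n_bootstrap=0, seed=3, n_permutations=0)
        assert np.allclose(c1.rho.to_numpy(), c2.rho.to_numpy(), atol=1e-12)

    def test_too_few_components_error(self, rng):
        peaks, otus = _tables(rng, nm=1, nt=2)
        with pytest.raises(ValueError):
            conet.sparcc_correlations(peaks, otus.iloc[:, :1])


class TestBuildBipartite:
    def _corr(self):
        rho = pd.DataFrame([[0.29, -0.42], [0.31, 0.05]],
                           index=["m0", "m1"], columns=["g0", "g1"])
        return conet.CorrelationMatrix(rho=rho, method="sparcc")

    def test_threshold_and_weights(self):
        neg = conet.build_bipartite(self._corr(), sign="negative")
        assert len(neg.edges) == 1
        edge = neg.edges.iloc[0]
        assert (edge["molecule"], edge["genus"]) == ("m0", "g1")
        assert edge["weight"] == 4200
        pos = conet.build_bipartite(self._corr(), sign="positive")
        assert len(pos.edges) == 1  # 0.29 excluded, 0.31 kept
        assert pos.edges.iloc[0]["weight"] == 3100

    def test_zero_threshold_counts_all_of_sign(self):
        pos = conet.build_bipartite(self._corr(), threshold=0.0, sign="positive")
        assert len(pos.edges) == 3

    def test_edge_count_monotone_in_threshold(self, rng):
        rho = pd.DataFrame(rng.uniform(-1, 1, (10, 8)))
        corr = conet.CorrelationMatrix(rho=rho, method="sparcc")
        counts = []
        for thr in (0.1, 0.3, 0.5, 0.7):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                n_edges = sum(
                    len(conet.build_bipartite(corr, thr, s).edges)
                    for s in ("negative", "positive"))
            counts.append(n_edges)
        assert counts == sorted(counts, reverse=True)

    def test_empty_network_warns(self):
        rho = pd.DataFrame([[0.1]], index=["m"], columns=["g"])
        with pytest.warns(UserWarning):
            net = conet.build_bipartite(
                conet.CorrelationMatrix(rho=rho, method="sparcc"), sign="negative")
        assert net.edges.empty


class TestSampleSubnetwork:
    def _setup(self, rng):
        peaks = pd.DataFrame([[1.0, 0.0], [1.0, 1.0]], index=["s1", "s2"],
                             columns=["m0", "m1"])
        otus = pd.DataFrame([[5, 0], [5, 5]], index=["s1", "s2"],
                            columns=["g0", "g1"])
        rho = pd.DataFrame([[0.5, 0.6], [0.7, 0.8]],
                           index=["m0", "m1"], columns=["g0", "g1"])
        net = conet.build_bipartite(
            conet.CorrelationMatrix(rho=rho, method="sparcc"), sign="positive")
        return net, peaks, otus

    def test_full_sample_keeps_network(self, rng):
        net, peaks, otus = self._setup(rng)
        sub = conet.sample_subnetwork(net, peaks, otus, "s2")
        assert len(sub.edges) == 4

    def test_membership_matches_set_logic_oracle(self, rng):
        net, peaks, otus = self._setup(rng)
        sub = conet.sample_subnetwork(net, peaks, otus, "s1")
        mols = set(peaks.columns[peaks.loc["s1"] > 0])
        gens = set(otus.columns[otus.loc["s1"] > 0])
        expected = {(m, g) for _, (m, g) in
                    net.edges[["molecule", "genus"]].iterrows()
                    if m in mols and g in gens}
        got = set(zip(sub.edges["molecule"], sub.edges["genus"]))
        assert got == expected == {("m0", "g0")}

    def test_absent_sample_errors(self, rng):
        net, peaks, otus = self._setup(rng)
        with pytest.raises(KeyError):
            conet.sample_subnetwork(net, peaks, otus, "nope")


class TestEdgeSummaries:
    def test_mean_negative_and_counts(self):
        rho = pd.DataFrame([[-0.4, -0.6, 0.2, 0.35]],
                           index=["m"], columns=list("abcd"))
        s = conet.network_edge_summaries(
            conet.CorrelationMatrix(rho=rho, method="sparcc"))
        assert s["mean_negative_rho"] == pytest.approx(-0.5)
        assert s["n_negative_edges"] == 2
        assert s["n_positive_edges"] == 1
        assert s["pct_strong_negative"] == pytest.approx(50.0)

    def test_no_negative_edges(self):
        rho = pd.DataFrame([[0.1, 0.2]], index=["m"], columns=["a", "b"])
        s = conet.network_edge_summaries(
            conet.CorrelationMatrix(rho=rho, method="sparcc"))
        assert s["pct_strong_negative"] == 0.0
        assert s["mean_negative_rho"] == 0.0
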