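"""Surrogate thresholds, binomial group test, contrast, node-degree nulls."""

import numpy as np
import pytest
from scipy import stats

from fixnet import mvar_gpdc as mg
from fixnet import netstats
from fixnet.errors import InvalidArgumentError
from fixnet.roitc import ROIEpochSet

FS = 250.0


def banded_cm(values, roi_names=None):
    return mg.CausalityMatrix(values=np.asarray(values, dtype=float),
                              bands=dict(mg.BANDS), roi_names=roi_names or [])


class TestSurrogateThreshold:
    def test_single_surrogate_degenerate_percentile(self):
        """With one surrogate any percentile equals that surrogate's bin maxima."""
        rng = np.random.default_rng(0)
        data = rng.standard_normal((20, 3, 120))
        e = ROIEpochSet(data, FS, 0)
        recorded = {}

        def pipeline(surr):
            A, s2 = mg._fit_gram(surr, 1)
            vals = mg.gpdc_values(A, s2, np.arange(1.0, 41.0), FS)
            off = ~np.eye(3, dtype=bool)
            recorded["bin_max"] = vals[:, off].max(axis=1)
            return vals

        thr = netstats.surrogate_threshold(e, 1, n_surrogates=1, seed=3,
                                           pipeline=pipeline)
        for name, band in mg.BANDS.items():
            idx = mg._band_indices(np.arange(1.0, 41.0), band)
            assert thr[name] == pytest.approx(recorded["bin_max"][idx].mean())

    def test_planted_edge_exceeds_threshold(self):
        A = np.zeros((2, 6, 6))
        A[0][np.diag_indices(6)] = 0.3
        A[0][1, 0] = 0.5
        rng = np.random.default_rng(1)
        data = mg.simulate_var(A, np.ones(6), 100, 300, rng)
        e = ROIEpochSet(data, FS, 0)
        m = mg.fit_mvar(e, 2)
        banded = mg.band_average(mg.gpdc(m))
        thr = netstats.surrogate_threshold(e, 2, n_surrogates=50, seed=1)
        mask = netstats.threshold_matrix(banded, thr)
        assert mask[:, 1, 0].any()

    def test_shuffling_destroys_structure(self):
        """Surrogate thresholds sit far below a strong planted-edge GPDC."""
        A = np.zeros((1, 2, 2))
        A[0] = [[0.5, 0.0], [0.6, 0.5]]
        rng = np.random.default_rng(2)
        data = mg.simulate_var(A, np.ones(2), 100, 300, rng)
        e = ROIEpochSet(data, FS, 0)
        banded = mg.band_average(mg.gpdc(mg.fit_mvar(e, 1)))
        thr = netstats.surrogate_threshold(e, 1, n_surrogates=50, seed=2)
        assert banded.values[:, 1, 0].min() > 3 * max(thr.values())


class TestThresholdMatrix:
    def test_all_zero_values_give_empty_network(self):
        cm = banded_cm(np.zeros((6, 3, 3)))
        mask = netstats.threshold_matrix(cm, {b: 0.1 for b in mg.BANDS})
        assert not mask.any()

    def test_value_exactly_at_threshold_kept(self):
        vals = np.zeros((6, 2, 2))
        vals[0, 1, 0] = 0.25
        mask = netstats.threshold_matrix(banded_cm(vals), {b: 0.25 for b in mg.BANDS})
        assert mask[0, 1, 0]
        assert mask.sum() == 1

    def test_diagonal_always_off(self):
        vals = np.ones((6, 3, 3))
        mask = netstats.threshold_matrix(banded_cm(vals), {b: 0.0 for b in mg.BANDS})
        for b in range(6):
            assert not np.diag(mask[b]).any()

    def test_matches_bruteforce_comparison(self, rng):
        vals = rng.uniform(size=(6, 4, 4))
        thr = {b: rng.uniform(0.2, 0.8) for b in mg.BANDS}
        mask = netstats.threshold_matrix(banded_cm(vals), thr)
        for b, name in enumerate(mg.BANDS):
            for m in range(4):
                for n in range(4):
                    expect = (m != n) and vals[b, m, n] >= thr[name]
                    assert mask[b, m, n] == expect


class TestGroupBinomial:
    def test_exact_tail_oracle_all_k_at_n31(self):
        for k in range(32):
            brute = sum(stats.binom.pmf(j, 31, 0.5) for j in range(k, 32))
            assert netstats.binomial_tail(k, 31) == pytest.approx(brute, rel=1e-9)
        assert netstats.binomial_tail(16, 31) == 0.5
        assert netstats.binomial_tail(31, 31) == 2.0 ** -31

    def test_group_network_counts_and_significance(self):
        n, bands = 31, 6
        edges = np.zeros((n, bands, 3, 3), dtype=bool)
        edges[:25, 0, 1, 0] = True     # carried by 25 -> p < 0.001
        edges[:24, 0, 2, 0] = True     # carried by 24 -> p > 0.001
        g = netstats.group_binomial(edges, alpha=0.001)
        assert g.counts[0, 1, 0] == 25
        assert g.significant[0, 1, 0]
        assert not g.significant[0, 2, 0]
        assert g.p_values[0, 1, 0] == pytest.approx(netstats.binomial_tail(25, 31))

    def test_significance_implies_p_below_alpha(self, rng):
        edges = rng.random((31, 6, 4, 4)) < 0.5
        g = netstats.group_binomial(edges, alpha=0.001)
        assert np.all(g.p_values[g.significant] < 0.001)


class TestExpandAndContrast:
    def _net(self, names, strength, sig):
        n = len(names)
        b = strength.shape[0]
        return netstats.GroupNetwork(
            roi_names=list(names), bands=dict(list(mg.BANDS.items())[:b]),
            counts=(sig * 31).astype(int), p_values=np.where(sig, 1e-5, 0.5),
            significant=sig, mean_strength=strength, n_participants=31,
            alpha=0.001)

    def test_identical_networks_contrast_to_zero(self, rng):
        s = rng.uniform(size=(2, 3, 3))
        sig = s > 0.5
        res = netstats.expand_and_contrast(self._net("abc", s, sig),
                                           self._net("abc", s.copy(), sig.copy()))
        assert np.allclose(res.contrast, 0.0)
        assert np.array_equal(res.shared, sig)
        assert not res.fv_only.any() and not res.vs_only.any()

    def test_fv_only_roi_has_zero_vs_rows(self, rng):
        s_fv = rng.uniform(size=(1, 3, 3))
        s_vs = rng.uniform(size=(1, 2, 2))
        res = netstats.expand_and_contrast(
            self._net(["a", "b", "c"], s_fv, s_fv > 0.3),
            self._net(["a", "b"], s_vs, s_vs > 0.3))
        assert res.roi_names == ["a", "b", "c"]
        # VS contribution at ROI "c" must be zero: contrast row equals FV row
        assert np.allclose(res.contrast[0][2, :2], s_fv[0][2, :2])
        assert np.allclose(res.contrast[0][:2, 2], s_fv[0][:2, 2])

    def test_hand_example_union_placement(self, rng):
        s_fv = rng.uniform(size=(1, 3, 3))
        s_vs = rng.uniform(size=(1, 4, 4))
        fv_names, vs_names = ["a", "b", "c"], ["b", "d", "a", "e"]
        res = netstats.expand_and_contrast(
            self._net(fv_names, s_fv, s_fv > 0.5),
            self._net(vs_names, s_vs, s_vs > 0.5))
        assert res.roi_names == ["a", "b", "c", "d", "e"]
        for i, ni in enumerate(vs_names):
            for j, nj in enumerate(vs_names):
                ui, uj = res.roi_names.index(ni), res.roi_names.index(nj)
                expected_fv = s_fv[0][fv_names.index(ni), fv_names.index(nj)] \
                    if ni in fv_names and nj in fv_names else 0.0
                assert res.contrast[0, ui, uj] == pytest.approx(
                    expected_fv - s_vs[0, i, j])

    def test_embedding_restricts_back_exactly(self, rng):
        s_fv = rng.uniform(size=(2, 3, 3))
        s_vs = rng.uniform(size=(2, 2, 2))
        g_fv = self._net(["x", "y", "z"], s_fv, s_fv > 0.5)
        g_vs = self._net(["y", "w"], s_vs, s_vs > 0.5)
        res = netstats.expand_and_contrast(g_fv, g_vs)
        idx = [res.roi_names.index(n) for n in g_fv.roi_names]
        assert np.array_equal(res.fv_significant[np.ix_(range(2), idx, idx)],
                              g_fv.significant)

    def test_duplicate_roi_names_rejected(self, rng):
        s = rng.uniform(size=(1, 2, 2))
        with pytest.raises(InvalidArgumentError):
            netstats.expand_and_contrast(self._net(["a", "a"], s, s > 0.5),
                                         self._net(["a", "b"], s, s > 0.5))


class TestNodeDegree:
    def _group(self, sig, names=None):
        sig = np.asarray(sig, dtype=bool)
        n = sig.shape[-1]
        names = names or [f"r{i}" for i in range(n)]
        bands = {name: band for name, band in list(mg.BANDS.items())[:sig.shape[0]]}
        return netstats.GroupNetwork(
            roi_names=names, bands=bands, counts=sig.astype(int) * 31,
            p_values=np.where(sig, 1e-5, 0.5), significant=sig,
            mean_strength=sig.astype(float), n_participants=31, alpha=0.001)

    def test_complete_network_degrees(self):
        n = 5
        sig = np.ones((1, n, n), dtype=bool)
        sig[0][np.diag_indices(n)] = False
        g = self._group(sig)
        assert np.all(g.degree() == 2 * (n - 1))

    def test_empty_network_flags_nothing(self):
        g = self._group(np.zeros((2, 6, 6), dtype=bool))
        rep = netstats.node_degree_test(g, n_randomizations=2000, seed=0)
        assert not rep.high_degree.any()
        assert np.all(rep.degrees == 0)

    def test_star_hub_flagged_leaves_not(self):
        n = 10
        sig = np.zeros((1, n, n), dtype=bool)
        sig[0, 1:, 0] = True            # hub 0 sends to all others
        g = self._group(sig)
        rep = netstats.node_degree_test(g, n_randomizations=100_000, seed=1)
        assert rep.high_degree[0]
        assert not rep.high_degree[1:].any()

    def test_null_redistribution_preserves_edge_count(self):
        # all-pairs edge budget forces max degree 2(N-1) in every draw
        from fixnet.netstats import _null_max_degree
        n = 5
        null = _null_max_degree(n, n * (n - 1), 500,
                                np.random.default_rng(0))
        assert np.all(null == 2 * (n - 1))

    def test_null_mean_total_degree_matches_edge_budget(self):
        from fixnet.netstats import _null_max_degree
        # with 1 edge the max degree is always exactly 1 at two nodes
        null = _null_max_degree(6, 1, 300, np.random.default_rng(1))
        assert np.all(null == 1)
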