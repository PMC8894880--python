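"""Cluster permutation testing: recovery, symmetry, filtering rules, and an
independent cross-check of the clustering against MNE's implementation."""

import numpy as np
import pytest
from scipy import sparse, stats

from fixnet import scpt
from fixnet import synthgen as sg
from fixnet._windows import analysis_slice
from fixnet.errors import UnlabeledVertexError


def planted_contrast(mesh, vertices, amplitude, n_runs=30, seed=1, n_samples=50):
    planted = sg.PlantedCluster(np.asarray(vertices), (40, 160), amplitude)
    img, crs = sg.simulate_vertex_fra(mesh, planted, n_runs, 1.0, seed=seed,
                                      n_samples=n_samples)
    return scpt.make_contrast(img, crs)


PATCH = [85, 86, 87, 105, 106, 107, 125, 126, 127, 145, 146, 147]


class TestClusterTest:
    def test_planted_cluster_recovered(self, grid20):
        c = planted_contrast(grid20, PATCH, amplitude=10.0)
        res = scpt.cluster_test(c, (0, 200), n_permutations=300, seed=2)
        sig = scpt.filter_clusters(res)
        assert sig.clusters, "no significant cluster found"
        best = sig.clusters[0]
        overlap = np.intersect1d(best.vertex_set, PATCH).size / len(PATCH)
        assert overlap >= 0.8

    def test_sign_flip_gives_identical_geometry(self, grid20):
        c = planted_contrast(grid20, PATCH, amplitude=6.0, n_runs=12)
        flipped = scpt.ContrastData(values=-c.values, adjacency=c.adjacency,
                                    sampling_rate=c.sampling_rate,
                                    t0_index=c.t0_index)
        r1 = scpt.cluster_test(c, (0, 200), n_permutations=150, seed=5)
        r2 = scpt.cluster_test(flipped, (0, 200), n_permutations=150, seed=5)
        geo1 = {frozenset(zip(cl.vertices.tolist(), cl.times.tolist())):
                (cl.mass, cl.p) for cl in r1.clusters}
        geo2 = {frozenset(zip(cl.vertices.tolist(), cl.times.tolist())):
                (cl.mass, cl.p) for cl in r2.clusters}
        assert geo1.keys() == geo2.keys()
        for k in geo1:
            assert geo1[k][0] == pytest.approx(geo2[k][0])
            assert geo1[k][1] == pytest.approx(geo2[k][1])

    def test_vertex_relabeling_invariance(self, grid8):
        c = planted_contrast(grid8, [9, 10, 17, 18], amplitude=6.0, n_runs=12)
        perm = np.random.default_rng(0).permutation(64)
        inv = np.argsort(perm)
        # relabel vertex v -> perm[v]
        adj = c.adjacency.tocoo()
        adj2 = sparse.coo_matrix((adj.data, (perm[adj.row], perm[adj.col])),
                                 shape=adj.shape)
        c2 = scpt.ContrastData(values=c.values[:, inv, :], adjacency=adj2,
                               sampling_rate=c.sampling_rate)
        r1 = scpt.cluster_test(c, (0, 120), n_permutations=120, seed=3)
        r2 = scpt.cluster_test(c2, (0, 120), n_permutations=120, seed=3)
        sets1 = {frozenset(zip(cl.vertices.tolist(), cl.times.tolist()))
                 for cl in r1.clusters}
        sets2 = {frozenset(zip(inv[cl.vertices].tolist(), cl.times.tolist()))
                 for cl in r2.clusters}
        assert sets1 == sets2

    def test_matches_mne_cluster_geometry_and_mass(self, grid8):
        mne_stats = pytest.importorskip("mne.stats")
        c = planted_contrast(grid8, [9, 10, 17, 18, 25, 26], amplitude=5.0,
                             n_runs=20, seed=4, n_samples=50)
        res = scpt.cluster_test(c, (0, 200), n_permutations=150, seed=0)
        sl = analysis_slice(0, 200, c.sampling_rate, 0, 50)
        x = c.values[:, :, sl].transpose(0, 2, 1)      # (obs, time, vertex)
        thr = stats.t.ppf(0.975, x.shape[0] - 1)
        t_obs, clusters, _, _ = mne_stats.spatio_temporal_cluster_1samp_test(
            x, adjacency=sparse.coo_matrix(c.adjacency), threshold=thr,
            n_permutations=100, tail=0, out_type="indices", seed=0,
            verbose=False)
        mine = {frozenset(zip(cl.vertices.tolist(), cl.times.tolist())): cl.mass
                for cl in res.clusters}
        theirs = {}
        for tidx, vidx in clusters:
            pts = frozenset(zip(np.asarray(vidx).tolist(),
                                np.asarray(tidx).tolist()))
            theirs[pts] = float(np.abs(t_obs[tidx, vidx]).sum())
        assert mine.keys() == theirs.keys()
        for k in mine:
            assert mine[k] == pytest.approx(theirs[k], abs=1e-9)


def _result_with(clusters, rate=1000.0, n_vertices=200):
    return scpt.ClusterResult(clusters=clusters, alpha=0.05, n_permutations=1000,
                              sampling_rate=rate, window_ms=(0, 200),
                              n_vertices=n_vertices)


def _cluster(vertices, times, p=0.01):
    vertices = np.asarray(vertices)
    times = np.asarray(times)
    return scpt.Cluster(vertices=vertices, times=times, mass=float(len(times)),
                        p=p, sign=1)


class TestFilterClusters:
    def test_small_cluster_removed(self):
        cl = _cluster([1, 2, 3, 4] * 20, np.tile(np.arange(20), 4))  # 4 vertices
        out = scpt.filter_clusters(_result_with([cl]), min_vertices=5,
                                   min_duration_ms=20.0)
        assert out.clusters == []

    def test_exactly_20ms_extent_removed(self):
        # 21 samples at 1000 Hz span exactly 20.0 ms
        cl = _cluster(np.repeat(np.arange(12), 21), np.tile(np.arange(21), 12))
        out = scpt.filter_clusters(_result_with([cl]))
        assert out.clusters == []

    def test_just_over_20ms_kept(self):
        cl = _cluster(np.repeat(np.arange(12), 22), np.tile(np.arange(22), 12))
        out = scpt.filter_clusters(_result_with([cl]))
        assert len(out.clusters) == 1

    def test_nonsignificant_cluster_removed(self):
        cl = _cluster(np.repeat(np.arange(12), 40), np.tile(np.arange(40), 12),
                      p=0.2)
        assert scpt.filter_clusters(_result_with([cl])).clusters == []

    def test_empty_result_passes_through(self):
        assert scpt.filter_clusters(_result_with([])).clusters == []


class TestPartitionRois:
    def _labels(self, n, name="A"):
        return np.array([name] * n, dtype=object)

    def test_fourteen_percent_discarded(self):
        cl = _cluster(np.arange(14), np.zeros(14, dtype=int))
        rois = scpt.partition_rois(_result_with([cl], n_vertices=100),
                                   self._labels(100), min_fraction=0.15)
        assert rois == []

    def test_fifteen_percent_kept(self):
        cl = _cluster(np.arange(15), np.zeros(15, dtype=int))
        rois = scpt.partition_rois(_result_with([cl], n_vertices=100),
                                   self._labels(100), min_fraction=0.15)
        assert len(rois) == 1
        assert rois[0].significant_fraction == pytest.approx(0.15)

    def test_two_clusters_in_one_label_become_one_roi(self):
        c1 = _cluster(np.arange(10), np.zeros(10, dtype=int))
        c2 = _cluster(np.arange(20, 30), np.zeros(10, dtype=int))
        rois = scpt.partition_rois(_result_with([c1, c2], n_vertices=50),
                                   self._labels(50), min_fraction=0.15)
        assert len(rois) == 1
        assert rois[0].member_vertices.size == 20

    def test_order_independence(self):
        c1 = _cluster(np.arange(10), np.zeros(10, dtype=int))
        c2 = _cluster(np.arange(20, 30), np.zeros(10, dtype=int))
        a = scpt.partition_rois(_result_with([c1, c2], n_vertices=50),
                                self._labels(50))
        b = scpt.partition_rois(_result_with([c2, c1], n_vertices=50),
                                self._labels(50))
        assert [(r.label, tuple(r.member_vertices)) for r in a] == \
            [(r.label, tuple(r.member_vertices)) for r in b]

    def test_unlabeled_vertex_rejected(self):
        labels = self._labels(50)
        labels[5] = ""
        cl = _cluster(np.arange(10), np.zeros(10, dtype=int))
        with pytest.raises(UnlabeledVertexError):
            scpt.partition_rois(_result_with([cl], n_vertices=50), labels)
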