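"""Spatiotemporal cluster permutation testing (SCPT) and ROI definition.

The test controls the family-wise error of mass-univariate vertex x time
statistics.  Per (vertex, time) point a one-sample t statistic across runs is
computed for the condition contrast; points exceeding a two-sided
cluster-forming threshold are grouped into spatiotemporally connected
clusters — connected means same vertex at adjacent time samples, or adjacent
vertices at the same sample — separately for positive and negative effects.
A cluster's mass is the sum of |t| over its points.  The null distribution of
the maximum cluster mass is built by randomly sign-flipping whole runs (the
exchangeability move of a one-sample contrast design), and each observed
cluster gets p = (1 + #{null >= mass}) / (1 + n_permutations).

Accepted clusters are filtered by spatial extent (at least five vertices) and
temporal extent (strictly more than 20 ms), then split along atlas labels
into ROIs; a label whose significant-vertex fraction is below 15% is
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse, stats
from scipy.sparse import csgraph

from ._windows import analysis_slice
from .errors import InvalidArgumentError, UnlabeledVertexError

__all__ = [
    "ContrastData",
    "Cluster",
    "ClusterResult",
    "ROISpec",
    "make_contrast",
    "cluster_test",
    "filter_clusters",
    "partition_rois",
]


@dataclass
class ContrastData:
    """Per-run condition differences: runs x vertices x samples plus geometry."""

    values: np.ndarray
    adjacency: sparse.spmatrix
    sampling_rate: float
    t0_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidArgumentError("contrast values must be (runs, vertices, samples)")
        if self.values.shape[0] < 2:
            raise InvalidArgumentError("need at least 2 runs for a t statistic")
        self.adjacency = sparse.csr_matrix(self.adjacency)
        if self.adjacency.shape[0] != self.values.shape[1]:
            raise InvalidArgumentError("adjacency does not cover all vertices")


def make_contrast(image, fixation_cross) -> ContrastData:
    """Run-wise difference of two VertexData conditions (image - fixation cross)."""
    if image.data.shape != fixation_cross.data.shape:
        raise InvalidArgumentError("conditions must share runs/vertices/samples")
    return ContrastData(values=image.data - fixation_cross.data,
                        adjacency=image.mesh.adjacency,
                        sampling_rate=image.sampling_rate,
                        t0_index=image.t0_index)


@dataclass
class Cluster:
    """One spatiotemporal cluster: parallel vertex/time index arrays."""

    vertices: np.ndarray          # vertex id per point
    times: np.ndarray             # sample index (within the tested window)
    mass: float
    p: float
    sign: int

    @property
    def vertex_set(self) -> np.ndarray:
        return np.unique(self.vertices)

    def extent_ms(self, sampling_rate: float) -> float:
        return float((self.times.max() - self.times.min()) / sampling_rate * 1000.0)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    alpha: float
    n_permutations: int
    sampling_rate: float
    window_ms: tuple[float, float]
    n_vertices: int

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= self.alpha]


class _STGraph:
    """Edge lists of the spatiotemporal graph over vertices x window samples."""

    def __init__(self, adjacency: sparse.spmatrix, n_times: int):
        adj = sparse.triu(sparse.csr_matrix(adjacency), k=1).tocoo()
        n_v = adjacency.shape[0]
        t_idx = np.arange(n_times)
        # spatial edges replicated at every time sample
        su = (adj.row[:, None] * n_times + t_idx[None, :]).ravel()
        sv = (adj.col[:, None] * n_times + t_idx[None, :]).ravel()
        # temporal edges: consecutive samples of one vertex
        v_idx = np.arange(n_v)
        tu = (v_idx[:, None] * n_times + t_idx[None, :-1]).ravel()
        tv = tu + 1
        self.e0 = np.concatenate([su, tu])
        self.e1 = np.concatenate([sv, tv])
        self.n_nodes = n_v * n_times
        self.n_times = n_times

    def components(self, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Connected-component label per masked node; (labels, node_ids)."""
        nodes = np.flatnonzero(mask)
        if nodes.size == 0:
            return np.empty(0, dtype=int), nodes
        remap = np.cumsum(mask) - 1
        keep = mask[self.e0] & mask[self.e1]
        g = sparse.coo_matrix(
            (np.ones(int(keep.sum())), (remap[self.e0[keep]], remap[self.e1[keep]])),
            shape=(nodes.size, nodes.size))
        _, labels = csgraph.connected_components(g, directed=False)
        return labels, nodes


def _masses(tvals: np.ndarray, threshold: float, graph: _STGraph) -> np.ndarray:
    """Cluster masses (sum |t|) over both signs for one flattened t map."""
    out = []
    for sign in (1, -1):
        mask = (sign * tvals) > threshold
        labels, nodes = graph.components(mask)
        if nodes.size:
            out.append(np.bincount(labels, weights=np.abs(tvals[nodes])))
    return np.concatenate(out) if out else np.empty(0)


def _t_from_signs(signs: np.ndarray, flat: np.ndarray, ssq: np.ndarray) -> np.ndarray:
    """One-sample t for sign-flipped runs; flat is (runs, points)."""
    n = flat.shape[0]
    mean = signs @ flat / n
    var = (ssq[None, :] - n * mean ** 2) / (n - 1)
    var = np.maximum(var, np.finfo(float).tiny)
    return mean / np.sqrt(var / n)


def cluster_test(c: ContrastData, window_ms: tuple[float, float],
                 n_permutations: int = 1000, alpha: float = 0.05,
                 seed: int = 0, cluster_p: float = 0.05,
                 chunk: int = 128) -> ClusterResult:
    """SCPT over a time window of the contrast data.

    ``cluster_p`` sets the two-sided point-wise cluster-forming threshold
    (t quantile at df = runs - 1).  Permutations flip the sign of whole runs.
    """
    if n_permutations < 100:
        raise InvalidArgumentError("need at least 100 permutations")
    sl = analysis_slice(window_ms[0], window_ms[1], c.sampling_rate,
                        c.t0_index, c.values.shape[2])
    x = c.values[:, :, sl]
    n_runs, n_v, n_t = x.shape
    flat = x.reshape(n_runs, n_v * n_t)
    ssq = np.einsum("ij,ij->j", flat, flat)
    threshold = float(stats.t.ppf(1.0 - cluster_p / 2.0, n_runs - 1))
    graph = _STGraph(c.adjacency, n_t)

    t_obs = _t_from_signs(np.ones((1, n_runs)), flat, ssq)[0]

    # observed clusters with point memberships
    observed: list[tuple[np.ndarray, float, int]] = []
    for sign in (1, -1):
        mask = (sign * t_obs) > threshold
        labels, nodes = graph.components(mask)
        for lab in range(labels.max() + 1 if labels.size else 0):
            pts = nodes[labels == lab]
            observed.append((pts, float(np.abs(t_obs[pts]).sum()), sign))

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_permutations)
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        signs = rng.choice([-1.0, 1.0], size=(m, n_runs))
        t_perm = _t_from_signs(signs, flat, ssq)
        for i in range(m):
            masses = _masses(t_perm[i], threshold, graph)
            null_max[done + i] = masses.max() if masses.size else 0.0
        done += m

    clusters = []
    for pts, mass, sign in observed:
        p = (1.0 + float(np.sum(null_max >= mass))) / (1.0 + n_permutations)
        clusters.append(Cluster(vertices=pts // n_t, times=pts % n_t,
                                mass=mass, p=p, sign=sign))
    clusters.sort(key=lambda cl: cl.p)
    return ClusterResult(clusters=clusters, alpha=alpha,
                         n_permutations=n_permutations,
                         sampling_rate=c.sampling_rate, window_ms=window_ms,
                         n_vertices=n_v)


def filter_clusters(r: ClusterResult, min_vertices: int = 5,
                    min_duration_ms: float = 20.0) -> ClusterResult:
    """Keep significant clusters with enough spatial and temporal extent.

    The duration rule is strict: a cluster spanning exactly ``min_duration_ms``
    is removed.  The vertex rule is inclusive (>= min_vertices distinct
    vertices).
    """
    kept = [cl for cl in r.significant
            if cl.vertex_set.size >= min_vertices
            and cl.extent_ms(r.sampling_rate) > min_duration_ms]
    return replace(r, clusters=kept)


@dataclass
class ROISpec:
    """An accepted ROI: the significant vertices of one atlas label."""

    label: str
    member_vertices: np.ndarray
    significant_fraction: float
    label_size: int
    peak_vertex: int | None = None
    neighborhood: np.ndarray | None = None
    signs: np.ndarray | None = None


def partition_rois(r: ClusterResult, labels: np.ndarray | list[str],
                   min_fraction: float = 0.15) -> list[ROISpec]:
    """Split surviving cluster vertices along atlas labels into ROIs.

    The union of all clusters' vertices is taken first (two clusters inside
    one label yield one ROI), then a label is kept iff its significant-vertex
    fraction reaches ``min_fraction`` (a label at exactly the boundary is
    kept: only labels with *fewer* significant vertices are discarded).
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size != r.n_vertices:
        raise InvalidArgumentError("need one atlas label per vertex")
    if r.clusters:
        union = np.unique(np.concatenate([cl.vertex_set for cl in r.clusters]))
    else:
        union = np.empty(0, dtype=int)
    bad = [int(v) for v in union if labels[v] is None or labels[v] == ""]
    if bad:
        raise UnlabeledVertexError(f"vertices without atlas label: {bad[:5]}")

    rois = []
    for lab in sorted({str(labels[v]) for v in union}):
        in_label = np.flatnonzero(labels == lab)
        sig = np.intersect1d(union, in_label)
        frac = sig.size / in_label.size
        if frac >= min_fraction:
            rois.append(ROISpec(label=lab, member_vertices=sig,
                                significant_fraction=float(frac),
                                label_size=int(in_label.size)))
    return rois
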