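"""Network-level significance: surrogate thresholds, binomial group test,
condition contrast, and node-degree nulls.

Participant-level GPDC values are thresholded against surrogate data: time
samples are permuted independently within every epoch and channel, which
destroys the temporal (phase) structure while keeping the amplitude
distribution; the full MVAR + GPDC procedure is re-run per surrogate, the
maximum GPDC over all ordered channel pairs is recorded per frequency bin,
and a band's threshold is the mean over its bins of the chosen percentile
(99.99 by default) across surrogates.

Group significance treats each participant as a coin flip: under the null a
binary connection is carried by Binomial(n, 0.5) participants, and an edge is
significant when the exact upper tail of the observed carrier count falls
below alpha (0.001 by default).  Hubs are detected against a null that
redistributes each band's significant edges uniformly over all ordered
off-diagonal pairs and records the maximum node degree per randomization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from ._seeding import substream
from .errors import InvalidArgumentError
from .mvar_gpdc import (BANDS, CausalityMatrix, _band_indices, _fit_gram,
                        band_average, gpdc_values, spectral_radius)
from .roitc import ROIEpochSet

__all__ = [
    "GroupNetwork",
    "DegreeReport",
    "ContrastResult",
    "surrogate_threshold",
    "threshold_matrix",
    "group_binomial",
    "binomial_tail",
    "expand_and_contrast",
    "node_degree_test",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# surrogate thresholds
# ---------------------------------------------------------------------------

def surrogate_threshold(e: ROIEpochSet, order: int, n_surrogates: int = 200,
                        percentile: float = 99.99,
                        bands: Mapping[str, tuple[int, int]] | None = None,
                        freqs: np.ndarray | None = None, seed: int = 0,
                        pipeline: Callable[[np.ndarray], np.ndarray] | None = None,
                        ) -> dict[str, float]:
    """Per-band GPDC significance thresholds from time-shuffled surrogates.

    ``pipeline`` maps a surrogate (epochs, channels, samples) array to
    per-bin GPDC values (F, N, N); the default refits an MVAR of the given
    ``order`` (float32 Gram accumulation — the surrogate loop dominates the
    pipeline's runtime) and evaluates GPDC on the 1-Hz grid.  Surrogates
    whose refitted model is unstable are skipped with a logged count.
    """
    if n_surrogates < 1:
        raise InvalidArgumentError("need at least 1 surrogate")
    bands = dict(bands or BANDS)
    if freqs is None:
        freqs = np.arange(1.0, 41.0)
    data = np.ascontiguousarray(e.data, dtype=np.float32)
    fs = e.sampling_rate

    def default_pipeline(surr: np.ndarray) -> np.ndarray | None:
        A, sigma2 = _fit_gram(surr, order)
        if spectral_radius(A) >= 1.0:
            return None
        return gpdc_values(A, sigma2, freqs, fs)

    run = pipeline or default_pipeline
    rng = substream(seed, "surrogates")
    off_diag = ~np.eye(e.n_channels, dtype=bool)
    bin_max = []
    n_skipped = 0
    buf = np.empty_like(data)
    for _ in range(n_surrogates):
        rng.permuted(data, axis=2, out=buf)
        values = run(buf)
        if values is None:
            n_skipped += 1
            continue
        bin_max.append(values[:, off_diag].max(axis=1))
    if n_skipped:
        log.info("surrogate_threshold: skipped %d unstable surrogate(s)", n_skipped)
    if not bin_max:
        raise InvalidArgumentError("all surrogates were unstable")
    bin_max_arr = np.asarray(bin_max)                       # (S, F)
    per_bin = np.percentile(bin_max_arr, percentile, axis=0)
    return {name: float(per_bin[_band_indices(freqs, band)].mean())
            for name, band in bands.items()}


def threshold_matrix(c: CausalityMatrix, thresholds: Mapping[str, float]) -> np.ndarray:
    """Boolean (bands, N, N) edge matrix: value >= band threshold, diagonal off."""
    if c.bands is None:
        raise InvalidArgumentError("threshold_matrix needs a band-averaged matrix")
    if set(c.band_names) - set(thresholds):
        raise InvalidArgumentError("missing thresholds for some bands")
    thr = np.array([thresholds[b] for b in c.band_names])
    mask = c.values >= thr[:, None, None]
    for b in range(mask.shape[0]):
        np.fill_diagonal(mask[b], False)
    return mask


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def binomial_tail(k: int, n: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, 1/2), by integer summation."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    return sum(comb(n, j) for j in range(k, n + 1)) / float(2 ** n)


@dataclass
class GroupNetwork:
    """Group-level directed network for one condition."""

    roi_names: list[str]
    bands: dict[str, tuple[int, int]]
    counts: np.ndarray            # (B, N, N) participants carrying each edge
    p_values: np.ndarray          # (B, N, N) exact binomial upper tails
    significant: np.ndarray       # (B, N, N) bool, p < alpha
    mean_strength: np.ndarray     # (B, N, N) mean thresholded GPDC across participants
    n_participants: int
    alpha: float
    condition: str = ""

    def degree(self) -> np.ndarray:
        """In+out significant-edge count per (band, node)."""
        return self.significant.sum(axis=1) + self.significant.sum(axis=2)


def group_binomial(edges: np.ndarray, n_participants: int | None = None,
                   alpha: float = 0.001, strengths: np.ndarray | None = None,
                   roi_names: list[str] | None = None,
                   bands: Mapping[str, tuple[int, int]] | None = None,
                   condition: str = "") -> GroupNetwork:
    """Exact binomial group test on per-participant boolean edge matrices.

    ``edges`` is (participants, bands, N, N).  An edge carried by k of n
    participants gets p = P(Binomial(n, 0.5) >= k); it is significant when
    p < alpha (strict).  ``strengths`` (same shape, thresholded GPDC values)
    feeds the group-mean strength used by the condition contrast.
    """
    edges = np.asarray(edges, dtype=bool)
    if edges.ndim != 4 or edges.shape[2] != edges.shape[3]:
        raise InvalidArgumentError("edges must be (participants, bands, N, N)")
    n = n_participants or edges.shape[0]
    counts = edges.sum(axis=0)
    tails = np.array([binomial_tail(k, n) for k in range(n + 1)])
    p_values = tails[counts]
    significant = p_values < alpha
    if strengths is None:
        mean_strength = counts / float(n)
    else:
        mean_strength = np.asarray(strengths, dtype=float).mean(axis=0)
    bands = dict(bands or BANDS)
    names = roi_names or [f"roi{i}" for i in range(edges.shape[2])]
    return GroupNetwork(roi_names=list(names), bands=bands, counts=counts,
                        p_values=p_values, significant=significant,
                        mean_strength=mean_strength, n_participants=n,
                        alpha=alpha, condition=condition)


@dataclass
class ContrastResult:
    """FV - VS comparison on the union ROI set."""

    roi_names: list[str]
    contrast: np.ndarray          # (B, U, U) FV mean strength - VS mean strength
    fv_significant: np.ndarray    # (B, U, U) bool
    vs_significant: np.ndarray
    shared: np.ndarray
    fv_only: np.ndarray
    vs_only: np.ndarray


def _embed(values: np.ndarray, names: list[str], union: list[str]) -> np.ndarray:
    idx = np.array([union.index(n) for n in names])
    out = np.zeros(values.shape[:1] + (len(union), len(union)), dtype=values.dtype)
    out[np.ix_(range(values.shape[0]), idx, idx)] = values
    return out


def expand_and_contrast(g_fv: GroupNetwork, g_vs: GroupNetwork) -> ContrastResult:
    """Embed both networks into the union ROI set and subtract VS from FV.

    A ROI absent from one condition contributes zero rows/columns for that
    condition.  Restricting the embedded matrices back to the original ROI
    set recovers them exactly.
    """
    for g in (g_fv, g_vs):
        if len(set(g.roi_names)) != len(g.roi_names):
            raise InvalidArgumentError("duplicate ROI names")
    if list(g_fv.bands) != list(g_vs.bands):
        raise InvalidArgumentError("conditions must share the band definition")
    union = list(g_fv.roi_names) + [n for n in g_vs.roi_names
                                    if n not in g_fv.roi_names]
    fv_s = _embed(g_fv.mean_strength, g_fv.roi_names, union)
    vs_s = _embed(g_vs.mean_strength, g_vs.roi_names, union)
    fv_sig = _embed(g_fv.significant, g_fv.roi_names, union)
    vs_sig = _embed(g_vs.significant, g_vs.roi_names, union)
    return ContrastResult(roi_names=union, contrast=fv_s - vs_s,
                          fv_significant=fv_sig, vs_significant=vs_sig,
                          shared=fv_sig & vs_sig,
                          fv_only=fv_sig & ~vs_sig,
                          vs_only=vs_sig & ~fv_sig)


# ---------------------------------------------------------------------------
# node degree
# ---------------------------------------------------------------------------

@dataclass
class DegreeReport:
    """Observed node degrees against a uniform-redistribution null."""

    roi_names: list[str]
    band_names: list[str]
    degrees: np.ndarray           # (B, N) in+out counts
    percentile_thresholds: np.ndarray   # (B,) null max-degree percentile
    high_degree: np.ndarray       # (N,) bool: >= threshold in >= 1 band
    percentile: float
    n_randomizations: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b, band in enumerate(self.band_names):
            for i, roi in enumerate(self.roi_names):
                rows.append({"roi": roi, "band": band,
                             "degree": int(self.degrees[b, i]),
                             "threshold": float(self.percentile_thresholds[b]),
                             "high_degree": bool(self.degrees[b, i] > 0
                                                 and self.degrees[b, i]
                                                 >= self.percentile_thresholds[b])})
        return pd.DataFrame(rows)


def _null_max_degree(n_nodes: int, n_edges: int, n_rand: int,
                     rng: np.random.Generator, chunk: int = 20000) -> np.ndarray:
    """Max node degree per randomization when edges land uniformly on ordered pairs."""
    n_pairs = n_nodes * (n_nodes - 1)
    if n_edges == 0:
        return np.zeros(n_rand)
    out = np.empty(n_rand)
    done = 0
    while done < n_rand:
        m = min(chunk, n_rand - done)
        keys = rng.random((m, n_pairs), dtype=np.float32)
        pairs = np.argpartition(keys, n_edges - 1, axis=1)[:, :n_edges]
        i = pairs // (n_nodes - 1)
        j_raw = pairs % (n_nodes - 1)
        j = j_raw + (j_raw >= i)
        base = (np.arange(m) * n_nodes)[:, None]
        counts = np.bincount(np.concatenate([(base + i).ravel(),
                                             (base + j).ravel()]),
                             minlength=m * n_nodes).reshape(m, n_nodes)
        out[done:done + m] = counts.max(axis=1)
        done += m
    return out


def node_degree_test(g: GroupNetwork, n_randomizations: int = 100_000,
                     percentile: float = 95.0, seed: int = 0) -> DegreeReport:
    """Flag hub ROIs whose in+out degree beats the randomized-network null.

    Per band, the observed significant edges are redistributed uniformly at
    random over all ordered off-diagonal pairs (edge count preserved in every
    randomization); the null statistic is the maximum degree over nodes, and
    a ROI is a hub when its observed degree reaches the null's
    ``percentile`` in at least one band.
    """
    if n_randomizations < 1000:
        raise InvalidArgumentError("need at least 1000 randomizations")
    rng = substream(seed, "node-degree-null")
    n_nodes = len(g.roi_names)
    degrees = g.degree()
    thresholds = np.empty(len(g.bands))
    for b in range(len(g.bands)):
        n_edges = int(g.significant[b].sum())
        null = _null_max_degree(n_nodes, n_edges, n_randomizations, rng)
        thresholds[b] = np.percentile(null, percentile)
    # a node with no connections is never a hub, even when a band's edge
    # budget is empty and the null threshold degenerates to zero
    high = np.any((degrees > 0) & (degrees >= thresholds[:, None]), axis=0)
    return DegreeReport(roi_names=list(g.roi_names), band_names=list(g.bands),
                        degrees=degrees, percentile_thresholds=thresholds,
                        high_degree=high, percentile=percentile,
                        n_randomizations=n_randomizations)
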