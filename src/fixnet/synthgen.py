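"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators mirror the three arms of the analysis:

* :func:`simulate_mvar_cohort` draws per-participant epoch cohorts from
  planted multivariate autoregressive processes with sparse directed edges.
  Band-specific edges are realised as a damped-oscillator AR(2) block on the
  source channel — pole radius rho at the band's centre frequency puts a
  spectral peak inside the band — plus one lagged cross-coefficient into the
  target channel.  Each participant carries an edge with a configurable
  prevalence, and coefficients are jittered across participants so the group
  statistics are non-degenerate.
* :func:`simulate_vertex_fra` builds toy source meshes (a 2-D grid with
  6.2 mm spacing, standing in for a template cortical surface at desk scale)
  with a planted spatiotemporally connected activation cluster in the "image"
  condition and pure noise in the "fixation-cross" condition.
* :func:`simulate_target_trials` emits trial behaviour tables with a planted
  correlation between response amplitude and response time, plus a
  configurable fraction of trials that violate the correctness filters.

All generators are driven by per-stage substreams of one integer seed and are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph

from ._seeding import substream
from ._windows import analysis_slice
from .epochs import EpochSet
from .errors import InvalidArgumentError, StabilityError
from .mvar_gpdc import BANDS, simulate_var, spectral_radius
from .roitc import ROIEpochSet

__all__ = [
    "ExperimentDesign",
    "Edge",
    "CohortSpec",
    "CohortResult",
    "Mesh",
    "VertexData",
    "PlantedCluster",
    "make_design",
    "grid_mesh",
    "simulate_mvar_cohort",
    "simulate_vertex_fra",
    "simulate_target_trials",
    "trials_to_roi_epochs",
]


# ---------------------------------------------------------------------------
# experiment design arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentDesign:
    """Stimulus-set bookkeeping: configurations = backgrounds x objects x positions."""

    backgrounds: int
    object_sets: int
    position_sets: int
    trials_per_task: int
    tasks: tuple[str, ...] = ("FV", "ME", "VS")

    @property
    def n_configurations(self) -> int:
        return self.backgrounds * self.object_sets * self.position_sets

    @property
    def n_trials(self) -> int:
        return self.trials_per_task * len(self.tasks)


def make_design(backgrounds: int, object_sets: int, position_sets: int,
                trials_per_task: int,
                tasks: tuple[str, ...] = ("FV", "ME", "VS")) -> ExperimentDesign:
    """Validated experiment design; all counts must be positive."""
    for name, v in [("backgrounds", backgrounds), ("object_sets", object_sets),
                    ("position_sets", position_sets),
                    ("trials_per_task", trials_per_task)]:
        if int(v) < 1:
            raise InvalidArgumentError(f"{name} must be >= 1, got {v}")
    return ExperimentDesign(int(backgrounds), int(object_sets), int(position_sets),
                            int(trials_per_task), tuple(tasks))


# ---------------------------------------------------------------------------
# MVAR cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edge:
    """A planted directed influence ``source -> target``.

    ``band`` selects which canonical frequency band the source channel's
    oscillator sits in; ``None`` plants a broadband (lag-1 only) influence
    that shows up in every band.
    """

    source: int
    target: int
    band: str | None
    strength: float


@dataclass
class CohortSpec:
    n_participants: int = 31
    n_channels: int = 6
    order: int = 2
    edge_list: tuple[Edge, ...] = ()
    edge_prevalence: float = 0.9
    noise_sd: float = 1.0
    n_epochs_per_participant: int = 200
    epoch_length: int = 300
    sampling_rate: float = 250.0
    seed: int = 0
    jitter_sd: float = 0.10      # multiplicative between-participant coefficient SD
    osc_rho: float = 0.8         # pole radius of band oscillators
    diag_ar1: float = 0.3        # default lag-1 self-coefficient

    def __post_init__(self) -> None:
        if not 0.0 <= self.edge_prevalence <= 1.0:
            raise InvalidArgumentError("edge_prevalence must lie in [0, 1]")
        if self.order < 1 or self.n_channels < 1:
            raise InvalidArgumentError("order and n_channels must be >= 1")
        if any(e.band is not None for e in self.edge_list) and self.order < 2:
            raise InvalidArgumentError("band-specific edges need order >= 2")
        for e in self.edge_list:
            if not (0 <= e.source < self.n_channels and 0 <= e.target < self.n_channels):
                raise InvalidArgumentError(f"edge {e} outside channel range")
            if e.source == e.target:
                raise InvalidArgumentError("self-edges are not allowed")
            if e.band is not None and e.band not in BANDS:
                raise InvalidArgumentError(f"unknown band {e.band!r}")


@dataclass
class CohortResult:
    participants: list[EpochSet]
    truth: dict[str, np.ndarray]        # band -> (P, N, N) bool, [target, source]
    coefficients: list[np.ndarray]      # per-participant (p, N, N)
    carriers: dict[Edge, np.ndarray]    # edge -> (P,) bool
    spec: CohortSpec


def _base_coefficients(spec: CohortSpec) -> np.ndarray:
    A = np.zeros((spec.order, spec.n_channels, spec.n_channels))
    A[0][np.diag_indices(spec.n_channels)] = spec.diag_ar1
    for e in spec.edge_list:
        if e.band is not None:
            lo, hi = BANDS[e.band]
            f0 = 0.5 * (lo + hi)
            theta = 2.0 * np.pi * f0 / spec.sampling_rate
            A[0][e.source, e.source] = 2.0 * spec.osc_rho * np.cos(theta)
            A[1][e.source, e.source] = -spec.osc_rho ** 2
        A[0][e.target, e.source] += e.strength
    return A


def simulate_mvar_cohort(spec: CohortSpec) -> CohortResult:
    """Per-participant epoch sets from planted MVAR processes plus ground truth.

    The planted base model must be stable; each participant's jittered
    coefficient set is re-checked and re-drawn (up to 100 attempts) until
    stable.  Same spec (including seed) gives bit-identical output.
    """
    base = _base_coefficients(spec)
    if spectral_radius(base) >= 1.0:
        raise StabilityError(
            f"planted coefficients are unstable (radius {spectral_radius(base):.3f})")

    rng_carrier = substream(spec.seed, "cohort-carriers")
    carriers = {e: rng_carrier.random(spec.n_participants) < spec.edge_prevalence
                for e in spec.edge_list}

    # A lagged cross-coefficient is a broadband influence: the transfer from
    # source to target is nonzero at every frequency, the edge's band only
    # concentrates the source's spectral power.  Ground truth therefore marks
    # the carried pair in every band; Edge.band records where detection power
    # is highest.
    truth = {b: np.zeros((spec.n_participants, spec.n_channels, spec.n_channels),
                         dtype=bool) for b in BANDS}
    for e in spec.edge_list:
        for b in BANDS:
            truth[b][carriers[e], e.target, e.source] = True

    participants, coeffs = [], []
    sigma2 = np.full(spec.n_channels, spec.noise_sd ** 2)
    for i in range(spec.n_participants):
        rng = substream(spec.seed, f"cohort-participant-{i}")
        A_i = base.copy()
        for e in spec.edge_list:
            if not carriers[e][i]:
                A_i[0][e.target, e.source] -= e.strength
        nz = A_i != 0
        for _ in range(100):
            jit = A_i.copy()
            jit[nz] *= 1.0 + spec.jitter_sd * rng.standard_normal(int(nz.sum()))
            if spectral_radius(jit) < 1.0:
                break
        else:
            raise StabilityError(f"no stable jitter found for participant {i}")
        data = simulate_var(jit, sigma2, spec.n_epochs_per_participant,
                            spec.epoch_length, rng)
        participants.append(EpochSet(data=data, sampling_rate=spec.sampling_rate,
                                     t0_index=0, condition=f"participant{i}"))
        coeffs.append(jit)
    return CohortResult(participants=participants, truth=truth,
                        coefficients=coeffs, carriers=carriers, spec=spec)


# ---------------------------------------------------------------------------
# toy source meshes
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Vertex graph with coordinates (mm) and an atlas label per vertex."""

    adjacency: sparse.spmatrix
    coords: np.ndarray
    labels: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.adjacency.shape[0]


def grid_mesh(nx: int = 20, ny: int = 20, spacing: float = 6.2,
              label_blocks: tuple[int, int] = (4, 4)) -> Mesh:
    """4-connected 2-D grid mesh with rectangular atlas labels.

    The default 6.2 mm spacing mirrors the average vertex-to-vertex distance
    of a downsampled template cortical surface.
    """
    if nx < 1 or ny < 1:
        raise InvalidArgumentError("grid dimensions must be >= 1")
    idx = np.arange(nx * ny).reshape(nx, ny)
    rows, cols = [], []
    rows.append(idx[:-1, :].ravel()); cols.append(idx[1:, :].ravel())
    rows.append(idx[:, :-1].ravel()); cols.append(idx[:, 1:].ravel())
    r = np.concatenate(rows); c = np.concatenate(cols)
    adj = sparse.coo_matrix((np.ones(r.size), (r, c)), shape=(nx * ny, nx * ny))
    adj = ((adj + adj.T) > 0).astype(np.int8).tocsr()

    ix, iy = np.divmod(np.arange(nx * ny), ny)
    coords = np.column_stack([ix, iy]).astype(float) * spacing
    bx = np.minimum(ix * label_blocks[0] // nx, label_blocks[0] - 1)
    by = np.minimum(iy * label_blocks[1] // ny, label_blocks[1] - 1)
    labels = np.array([f"L{a}_{b}" for a, b in zip(bx, by)], dtype=object)
    return Mesh(adjacency=adj, coords=coords, labels=labels)


@dataclass
class VertexData:
    """Runs x vertices x samples of source-space activity on a mesh."""

    data: np.ndarray
    mesh: Mesh
    sampling_rate: float
    t0_index: int = 0
    condition: str = ""

    @property
    def n_runs(self) -> int:
        return self.data.shape[0]


@dataclass
class PlantedCluster:
    """Ground-truth activation: a connected vertex set, a time window (ms),
    a peak amplitude in units of the noise SD, and a temporal profile."""

    vertex_set: np.ndarray
    time_window_ms: tuple[float, float]
    amplitude: float
    waveform: str = "hann"


def _check_connected(mesh: Mesh, vertices: np.ndarray) -> None:
    vertices = np.asarray(vertices, dtype=int)
    if vertices.min() < 0 or vertices.max() >= mesh.n_vertices:
        raise InvalidArgumentError("planted vertices outside the mesh")
    sub = mesh.adjacency[vertices][:, vertices]
    n_comp, _ = csgraph.connected_components(sub, directed=False)
    if n_comp != 1:
        raise InvalidArgumentError("planted vertex set is not connected on the mesh")


def simulate_vertex_fra(mesh: Mesh, planted: PlantedCluster, n_runs: int,
                        noise_sd: float, seed: int = 0,
                        sampling_rate: float = 250.0,
                        n_samples: int = 60) -> tuple[VertexData, VertexData]:
    """("image", "fixation-cross") condition pair with a planted contrast.

    The image condition adds the planted waveform on the planted vertices to
    i.i.d. Gaussian noise; the fixation-cross condition is noise only, so the
    expected contrast equals the planted signal exactly.
    """
    vertices = np.asarray(planted.vertex_set, dtype=int)
    _check_connected(mesh, vertices)
    rng = substream(seed, "vertex-fra")

    signal = np.zeros((mesh.n_vertices, n_samples))
    if planted.amplitude != 0:
        sl = analysis_slice(planted.time_window_ms[0], planted.time_window_ms[1],
                            sampling_rate, 0, n_samples)
        width = sl.stop - sl.start
        if planted.waveform == "hann":
            profile = np.hanning(width + 2)[1:-1]
        elif planted.waveform == "boxcar":
            profile = np.ones(width)
        else:
            raise InvalidArgumentError(f"unknown waveform {planted.waveform!r}")
        signal[np.ix_(vertices, range(sl.start, sl.stop))] = \
            planted.amplitude * noise_sd * profile[None, :]

    image = rng.standard_normal((n_runs, mesh.n_vertices, n_samples)) * noise_sd
    image += signal[None]
    cross = rng.standard_normal((n_runs, mesh.n_vertices, n_samples)) * noise_sd
    return (VertexData(image, mesh, sampling_rate, 0, "image"),
            VertexData(cross, mesh, sampling_rate, 0, "fixation-cross"))


# ---------------------------------------------------------------------------
# behaviour tables
# ---------------------------------------------------------------------------

def simulate_target_trials(n_trials: int, r_target: float, rt_mean: float = 489.0,
                           rt_sd: float = 197.0, seed: int = 0,
                           invalid_fraction: float = 0.1,
                           amp_mean: float = 10.0,
                           amp_sd: float = 1.0) -> pd.DataFrame:
    """Trial table with a planted amplitude-RT Pearson correlation.

    Amplitude and response time are drawn jointly Gaussian with correlation
    ``r_target``; the amplitude mean is kept well above zero so mean-absolute
    amplitudes stay linear in the latent value.  ``invalid_fraction`` of
    trials are marked invalid by exceeding either the fixation-offset (1.7
    deg) or the response-lag (500 ms) correctness bound; valid trials draw
    both inside the bounds.
    """
    if not abs(r_target) < 1:
        raise InvalidArgumentError("|r_target| must be < 1")
    cols = ["trial_id", "amplitude", "rt_ms", "fix_offset_deg", "response_lag_ms"]
    if n_trials == 0:
        return pd.DataFrame(columns=cols)
    rng = substream(seed, "target-trials")
    z = rng.standard_normal((n_trials, 2))
    z[:, 1] = r_target * z[:, 0] + np.sqrt(1.0 - r_target ** 2) * z[:, 1]
    amplitude = amp_mean + amp_sd * z[:, 0]
    rt = np.maximum(rt_mean + rt_sd * z[:, 1], 1.0)

    offset = rng.uniform(0.0, 1.5, n_trials)
    lag = rng.uniform(0.0, 400.0, n_trials)
    n_bad = int(round(invalid_fraction * n_trials))
    bad = rng.choice(n_trials, size=n_bad, replace=False)
    which = rng.random(n_bad) < 0.5
    offset[bad[which]] = rng.uniform(1.8, 5.0, int(which.sum()))
    lag[bad[~which]] = rng.uniform(550.0, 1500.0, int((~which).sum()))

    return pd.DataFrame({"trial_id": np.arange(n_trials), "amplitude": amplitude,
                         "rt_ms": rt, "fix_offset_deg": offset,
                         "response_lag_ms": lag})


def trials_to_roi_epochs(trials: pd.DataFrame, sampling_rate: float = 250.0,
                         n_samples: int = 75, roi_name: str = "roi",
                         peak_ms: float = 120.0, width_ms: float = 25.0,
                         noise_sd: float = 0.0, seed: int = 0) -> ROIEpochSet:
    """One-ROI epoch set whose response scales with each trial's amplitude.

    Every trial's course is its amplitude times a Gaussian bump (peak at
    ``peak_ms``, SD ``width_ms``), so any window average of |activity| is
    linear in the amplitude column and planted correlations survive the
    amplitude-extraction step.
    """
    t_ms = np.arange(n_samples) / sampling_rate * 1000.0
    bump = np.exp(-0.5 * ((t_ms - peak_ms) / width_ms) ** 2)
    amp = trials["amplitude"].to_numpy()
    data = amp[:, None, None] * bump[None, None, :]
    if noise_sd > 0:
        rng = substream(seed, "trial-roi-noise")
        data = data + noise_sd * rng.standard_normal(data.shape)
    return ROIEpochSet(data=data, sampling_rate=sampling_rate, t0_index=0,
                       roi_names=[roi_name], condition="VS")
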