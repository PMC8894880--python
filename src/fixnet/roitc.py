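"""Representative single-epoch ROI time courses.

A region's activity is summarized by the vertices around its activity peak:
the peak vertex is located on the participant's epoch-averaged data within
the main response window (50-180 ms by default), a spherical neighborhood
(radius 12.4 mm, i.e. twice the template vertex spacing) is taken *within the
ROI*, and vertex time courses are averaged after sign alignment.

Sign alignment exists because source orientations on opposite walls of a
sulcus point in opposite directions: identical underlying currents then
appear with flipped polarity and would cancel in a plain average.  A vertex's
epoch-averaged course is correlated with the peak vertex's; a negative
Pearson correlation flips that vertex's single-epoch courses before
averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._windows import analysis_slice
from .errors import InvalidArgumentError, InvalidStateError

__all__ = [
    "ROIEpochSet",
    "find_peak_vertex",
    "neighborhood",
    "align_signs",
    "prepare_roi",
    "extract_roi_timecourses",
]


@dataclass
class ROIEpochSet:
    """Epochs x ROIs x samples, sharing the epoch axis of the source data."""

    data: np.ndarray
    sampling_rate: float
    t0_index: int
    roi_names: list[str] = field(default_factory=list)
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError("ROIEpochSet data must be (epochs, rois, samples)")
        if not self.roi_names:
            self.roi_names = [f"roi{i}" for i in range(self.data.shape[1])]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.n_samples) - self.t0_index) / self.sampling_rate


def find_peak_vertex(roi, avg: np.ndarray, window_ms: tuple[float, float],
                     sampling_rate: float, t0_index: int = 0) -> int:
    """Vertex with the largest absolute epoch-averaged amplitude in the window.

    ``avg`` is vertices x samples (the participant's epoch average).  Ties
    break to the lowest vertex id, which keeps the choice deterministic.
    """
    members = np.asarray(sorted(roi.member_vertices), dtype=int)
    if members.size == 0:
        raise InvalidArgumentError(f"ROI {roi.label!r} has no member vertices")
    sl = analysis_slice(window_ms[0], window_ms[1], sampling_rate, t0_index,
                        avg.shape[1])
    peak_amp = np.max(np.abs(avg[members, sl]), axis=1)
    return int(members[int(np.argmax(peak_amp))])


def neighborhood(peak: int, coords: np.ndarray, roi, radius: float) -> np.ndarray:
    """ROI vertices within Euclidean ``radius`` (mm) of the peak, peak included.

    Only vertices belonging to the ROI are eligible: a nearby vertex outside
    the ROI never enters the average.
    """
    if radius <= 0:
        raise InvalidArgumentError("radius must be positive")
    members = np.asarray(sorted(roi.member_vertices), dtype=int)
    dist = np.linalg.norm(coords[members] - coords[peak], axis=1)
    return members[dist <= radius + 1e-9]


def align_signs(vertex_avgs: np.ndarray, peak: int,
                vertices: np.ndarray) -> np.ndarray:
    """Per-vertex signs (+1/-1) from correlation with the peak's average course.

    ``vertex_avgs`` is vertices x samples of epoch-averaged data.  A vertex
    whose average correlates negatively with the peak's average gets -1; the
    peak itself is +1 by construction.  Zero-variance averages get +1 with a
    warning, since their correlation is undefined.
    """
    vertices = np.asarray(vertices, dtype=int)
    ref = vertex_avgs[peak] - vertex_avgs[peak].mean()
    ref_sd = np.linalg.norm(ref)
    signs = np.ones(vertices.size, dtype=int)
    if ref_sd == 0:
        warnings.warn("peak vertex average has zero variance; no sign flipping")
        return signs
    for i, v in enumerate(vertices):
        if v == peak:
            continue
        x = vertex_avgs[v] - vertex_avgs[v].mean()
        sd = np.linalg.norm(x)
        if sd == 0:
            warnings.warn(f"vertex {v} average has zero variance; sign kept at +1")
            continue
        if float(x @ ref) < 0:
            signs[i] = -1
    return signs


def prepare_roi(roi, avg: np.ndarray, coords: np.ndarray,
                window_ms: tuple[float, float] = (50.0, 180.0),
                radius: float = 12.4, sampling_rate: float = 0.0,
                t0_index: int = 0,
                corr_window_ms: tuple[float, float] | None = None):
    """Fill peak vertex, neighborhood and signs on a ROI spec, in place.

    Peak selection and sign alignment are participant-level decisions: they
    are computed once on the participant's epoch-averaged data and then held
    fixed for all of that participant's single epochs.  Sign-alignment
    correlations use the full epoch unless ``corr_window_ms`` restricts them.
    """
    roi.peak_vertex = find_peak_vertex(roi, avg, window_ms, sampling_rate, t0_index)
    roi.neighborhood = neighborhood(roi.peak_vertex, coords, roi, radius)
    corr_avg = avg
    if corr_window_ms is not None:
        sl = analysis_slice(corr_window_ms[0], corr_window_ms[1], sampling_rate,
                            t0_index, avg.shape[1])
        corr_avg = avg[:, sl]
    roi.signs = align_signs(corr_avg, roi.peak_vertex, roi.neighborhood)
    return roi


def extract_roi_timecourses(vertex_epochs: np.ndarray, rois: list,
                            sampling_rate: float, t0_index: int = 0,
                            condition: str = "") -> ROIEpochSet:
    """Average sign-aligned neighborhood vertices into one course per ROI.

    ``vertex_epochs`` is epochs x vertices x samples; each ROI must have been
    through :func:`prepare_roi`.  The result is linear in the input for fixed
    signs and neighborhoods.
    """
    out = np.empty((vertex_epochs.shape[0], len(rois), vertex_epochs.shape[2]))
    for i, roi in enumerate(rois):
        if getattr(roi, "neighborhood", None) is None or getattr(roi, "signs", None) is None:
            raise InvalidStateError(f"ROI {roi.label!r} lacks neighborhood/signs; "
                                    "run prepare_roi first")
        nb = np.asarray(roi.neighborhood, dtype=int)
        if nb.size == 0:
            raise InvalidStateError(f"ROI {roi.label!r} has an empty neighborhood")
        signs = np.asarray(roi.signs, dtype=float)
        out[:, i, :] = np.einsum("evt,v->et", vertex_epochs[:, nb, :], signs) / nb.size
    return ROIEpochSet(data=out, sampling_rate=sampling_rate, t0_index=t0_index,
                       roi_names=[roi.label for roi in rois], condition=condition)
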