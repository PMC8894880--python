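"""Trial-wise amplitude / response-time correlation with FDR control.

For each ROI, a per-trial amplitude is the mean absolute activity inside the
ROI's full-width-at-half-maximum (FWHM) interval, determined on the grand
average of |activity| across participants and trials within a search window
(30-200 ms by default — later peaks belong to subsequent fixations).  The
amplitudes are Pearson-correlated with search response times over the trials
that survive the validity filters (correct response, RT <= 1 s), and the
per-ROI p-values are corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._windows import analysis_slice
from .errors import InsufficientDataError, InvalidArgumentError, NoPeakError
from .roitc import ROIEpochSet

__all__ = [
    "fwhm_interval",
    "filter_trials",
    "amplitude_rt_correlation",
]

#: Correctness bounds: a response counts as correct when the participant
#: fixated within this angular distance of the target centre within this lag
#: of the button press.
MAX_FIX_OFFSET_DEG = 1.7
MAX_RESPONSE_LAG_MS = 500.0


def fwhm_interval(grand_avg_abs: np.ndarray, sampling_rate: float,
                  t0_index: int = 0,
                  search_window_ms: tuple[float, float] = (30.0, 200.0)
                  ) -> tuple[float, float]:
    """FWHM interval (ms from onset) of a grand-average |activity| curve.

    The peak is the maximum inside the search window; the interval runs from
    the first half-maximum crossing left of the peak to the first crossing
    right of it, with linear interpolation between samples for sub-sample
    resolution, clipped to the search window.  Invariant to positive
    rescaling of the curve.
    """
    curve = np.asarray(grand_avg_abs, dtype=float)
    sl = analysis_slice(search_window_ms[0], search_window_ms[1], sampling_rate,
                        t0_index, curve.size)
    win = curve[sl]
    if np.ptp(win) == 0:
        raise NoPeakError("flat curve: no peak to bracket")
    peak_rel = int(np.argmax(win))
    half = win[peak_rel] / 2.0

    def to_ms(idx_rel: float) -> float:
        return (sl.start + idx_rel - t0_index) / sampling_rate * 1000.0

    left = 0.0
    for j in range(peak_rel - 1, -1, -1):
        if win[j] < half:
            left = j + (half - win[j]) / (win[j + 1] - win[j])
            break
    right = float(win.size - 1)
    for j in range(peak_rel + 1, win.size):
        if win[j] < half:
            right = j - 1 + (win[j - 1] - half) / (win[j - 1] - win[j])
            break
    return to_ms(left), to_ms(right)


def filter_trials(trials: pd.DataFrame, max_rt_ms: float = 1000.0) -> pd.DataFrame:
    """Keep correct trials with RT at or below ``max_rt_ms``.

    Correctness uses an explicit ``correct`` column when present, otherwise
    it is derived from the fixation-offset and response-lag bounds.
    """
    if "correct" in trials.columns:
        correct = trials["correct"].astype(bool)
    else:
        correct = ((trials["fix_offset_deg"] <= MAX_FIX_OFFSET_DEG)
                   & (trials["response_lag_ms"] <= MAX_RESPONSE_LAG_MS))
    return trials[correct & (trials["rt_ms"] <= max_rt_ms)].reset_index(drop=True)


def amplitude_rt_correlation(roi_epochs: ROIEpochSet, trials: pd.DataFrame,
                             fwhm_intervals: dict[str, tuple[float, float]],
                             fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Per-ROI Pearson correlation of FWHM-window amplitude with response time.

    ``roi_epochs`` must hold one first-target-fixation epoch per row of the
    (already filtered) trial table.  Degenerate cases (constant amplitude or
    RT) are reported as r = 0, p = 1 with a flag rather than NaN.  Returns a
    DataFrame with columns roi, r, p, q_significant, fwhm_start_ms,
    fwhm_end_ms, degenerate.
    """
    n = len(trials)
    if roi_epochs.n_epochs != n:
        raise InvalidArgumentError(
            f"{roi_epochs.n_epochs} epochs for {n} trials: need one epoch per kept trial")
    if n < 3:
        raise InsufficientDataError("need at least 3 trials for a correlation")
    rt = trials["rt_ms"].to_numpy(dtype=float)

    rows = []
    for i, roi in enumerate(roi_epochs.roi_names):
        if roi not in fwhm_intervals:
            raise InvalidArgumentError(f"no FWHM interval for ROI {roi!r}")
        lo, hi = fwhm_intervals[roi]
        sl = analysis_slice(lo, hi, roi_epochs.sampling_rate, roi_epochs.t0_index,
                            roi_epochs.n_samples)
        amp = np.abs(roi_epochs.data[:, i, sl]).mean(axis=1)
        degenerate = np.ptp(amp) == 0 or np.ptp(rt) == 0
        if degenerate:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(amp, rt)
        rows.append({"roi": roi, "r": float(r), "p": float(p),
                     "fwhm_start_ms": lo, "fwhm_end_ms": hi,
                     "degenerate": bool(degenerate)})
    report = pd.DataFrame(rows)
    report["q_significant"] = multipletests(report["p"].to_numpy(), alpha=fdr_alpha,
                                            method="fdr_bh")[0]
    return report[["roi", "r", "p", "q_significant", "fwhm_start_ms",
                   "fwhm_end_ms", "degenerate"]]
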