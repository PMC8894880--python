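"""Multivariate autoregressive modelling and generalized partial directed coherence.

An MVAR(p) model represents N simultaneously observed time series as

    X(t) = sum_{k=1..p} A(k) X(t-k) + E(t),

with N x N lag-coefficient matrices A(k) and white innovations E(t) with
per-channel variances sigma_m^2.  Fitting pools epochs as independent
realizations of one process: regression rows never cross an epoch boundary.

In the frequency domain, with f in Hz and sampling rate fs,

    A(f) = sum_k A(k) exp(-2 pi i f k / fs),      Abar(f) = I - A(f),

and the generalized partial directed coherence from channel n to channel m is

    GPDC_mn(f) = (|Abar_mn(f)| / sigma_m) / sqrt(sum_k |Abar_kn(f)|^2 / sigma_k^2),

Baccala's variance-weighted PDC.  The normalization makes every column a unit
vector: sum_m GPDC_mn(f)^2 = 1 at every frequency, so values are comparable
across channels with different innovation scales.  Band-level values are
arithmetic means over the band's inclusive integer frequency bins (alpha
8-13 Hz averages 6 bins).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .errors import InsufficientDataError, InvalidArgumentError, RankDeficiencyError
from .roitc import ROIEpochSet

__all__ = [
    "BANDS",
    "MVARModel",
    "CausalityMatrix",
    "StationarityReport",
    "Diagnostics",
    "companion_matrix",
    "spectral_radius",
    "simulate_var",
    "difference_and_test",
    "select_order",
    "fit_mvar",
    "diagnose",
    "gpdc",
    "band_average",
    "band_bins",
]

#: Canonical frequency bands in Hz.  Shared endpoints belong to both
#: neighbouring bands, so "alpha (8-13)" covers the six 1-Hz bins 8..13.
BANDS: dict[str, tuple[int, int]] = {
    "delta": (1, 4),
    "theta": (4, 8),
    "alpha": (8, 13),
    "beta1": (13, 20),
    "beta2": (20, 30),
    "gamma": (30, 40),
}


def band_bins(band: tuple[int, int]) -> np.ndarray:
    """Inclusive integer frequency bins of a band in Hz."""
    return np.arange(band[0], band[1] + 1)


# ---------------------------------------------------------------------------
# model container and stability
# ---------------------------------------------------------------------------

@dataclass
class MVARModel:
    """Fitted (or planted) MVAR(p) model.

    ``A`` has shape (p, N, N); ``A[k-1][m, n]`` is the influence of channel n
    at lag k on channel m.  ``sigma2`` holds per-channel innovation variances.
    """

    order: int
    A: np.ndarray
    sigma2: np.ndarray
    sampling_rate: float
    n_obs: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.A.ndim != 3 or self.A.shape[0] != self.order or \
                self.A.shape[1] != self.A.shape[2]:
            raise InvalidArgumentError("A must be (order, N, N)")
        if np.any(self.sigma2 <= 0):
            raise InvalidArgumentError("innovation variances must be positive")

    @property
    def n_channels(self) -> int:
        return self.A.shape[1]

    @property
    def stable(self) -> bool:
        return spectral_radius(self.A) < 1.0


def companion_matrix(A: np.ndarray) -> np.ndarray:
    """Companion form of the lag coefficient stack (p, N, N) -> (pN, pN)."""
    A = np.asarray(A, dtype=float)
    p, n, _ = A.shape
    comp = np.zeros((p * n, p * n))
    comp[:n] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[n:, :-n] = np.eye((p - 1) * n)
    return comp


def spectral_radius(A: np.ndarray) -> float:
    """Largest eigenvalue modulus of the companion matrix; < 1 means stable."""
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(A)))))


def simulate_var(A: np.ndarray, sigma2: np.ndarray, n_epochs: int, n_samples: int,
                 rng: np.random.Generator, burnin: int = 100) -> np.ndarray:
    """Draw (n_epochs, N, n_samples) from a stable MVAR process.

    All epochs are advanced in lockstep, so the per-step cost is one small
    einsum regardless of the epoch count.
    """
    A = np.asarray(A, dtype=float)
    p, n, _ = A.shape
    sd = np.sqrt(np.asarray(sigma2, dtype=float))
    total = n_samples + burnin
    innov = rng.standard_normal((n_epochs, n, total)) * sd[None, :, None]
    out = np.zeros((n_epochs, n, total))
    out[:, :, :p] = innov[:, :, :p]
    for t in range(p, total):
        acc = innov[:, :, t].copy()
        for k in range(p):
            acc += out[:, :, t - 1 - k] @ A[k].T
        out[:, :, t] = acc
    return out[:, :, burnin:]


# ---------------------------------------------------------------------------
# stationarity handling
# ---------------------------------------------------------------------------

@dataclass
class StationarityReport:
    """Per-channel ADF / KPSS outcomes before and after differencing.

    A channel counts as stationary when the ADF unit-root null is rejected
    (p < alpha) and the KPSS stationarity null is not (p >= alpha).
    """

    alpha: float
    adf_p_before: np.ndarray
    kpss_p_before: np.ndarray
    adf_p_after: np.ndarray
    kpss_p_after: np.ndarray

    def stationary(self, adf_p: np.ndarray, kpss_p: np.ndarray) -> np.ndarray:
        return (adf_p < self.alpha) & (kpss_p >= self.alpha)

    @property
    def stationary_before(self) -> np.ndarray:
        return self.stationary(self.adf_p_before, self.kpss_p_before)

    @property
    def stationary_after(self) -> np.ndarray:
        return self.stationary(self.adf_p_after, self.kpss_p_after)


def _unit_root_pvalues(series: np.ndarray) -> tuple[float, float]:
    """(ADF p, KPSS p) for one 1-D series; constants count as stationary."""
    from statsmodels.tsa.stattools import adfuller, kpss

    if np.ptp(series) == 0:
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adf_p = adfuller(series, regression="c", autolag="AIC")[1]
        kpss_p = kpss(series, regression="c", nlags="auto")[1]
    return float(adf_p), float(kpss_p)


def difference_and_test(e: ROIEpochSet, alpha: float = 0.05,
                        max_epochs_tested: int = 3) -> tuple[ROIEpochSet, StationarityReport]:
    """First-difference along time and report stationarity before and after.

    Tests run per channel on the first few epochs (median p across epochs) to
    keep the diagnostic cheap; differencing itself is applied to every epoch
    and shortens the time axis by one sample.
    """
    if e.n_samples < 3:
        raise InsufficientDataError("need at least 3 samples to difference and test")
    diffed = replace(e, data=np.diff(e.data, axis=2), t0_index=max(e.t0_index - 1, 0))

    n_test = min(e.n_epochs, max_epochs_tested)
    shape = (e.n_channels,)
    rep = StationarityReport(alpha, np.zeros(shape), np.zeros(shape),
                             np.zeros(shape), np.zeros(shape))
    for c in range(e.n_channels):
        before = [_unit_root_pvalues(e.data[i, c]) for i in range(n_test)]
        after = [_unit_root_pvalues(diffed.data[i, c]) for i in range(n_test)]
        rep.adf_p_before[c] = np.median([b[0] for b in before])
        rep.kpss_p_before[c] = np.median([b[1] for b in before])
        rep.adf_p_after[c] = np.median([a[0] for a in after])
        rep.kpss_p_after[c] = np.median([a[1] for a in after])
    return diffed, rep


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def _design(data: np.ndarray, p: int, dtype=np.float64) -> tuple[np.ndarray, np.ndarray]:
    """Pooled regression design.  Rows never cross epoch boundaries.

    Returns (X, Y): X is (rows, N*p) with lag-1 channels first, Y is (rows, N).
    """
    n_ep, n_ch, n_t = data.shape
    if n_t <= p:
        raise InsufficientDataError(f"epoch length {n_t} <= order {p}")
    Y = np.ascontiguousarray(data[:, :, p:].transpose(0, 2, 1), dtype=dtype)
    Y = Y.reshape(-1, n_ch)
    cols = [np.ascontiguousarray(data[:, :, p - k: n_t - k].transpose(0, 2, 1),
                                 dtype=dtype).reshape(-1, n_ch)
            for k in range(1, p + 1)]
    X = np.concatenate(cols, axis=1)
    return X, Y


def _solve_normal(G: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        cf = sla.cho_factor(G, check_finite=False)
        return sla.cho_solve(cf, b, check_finite=False)
    except (sla.LinAlgError, np.linalg.LinAlgError) as exc:
        raise RankDeficiencyError(f"singular MVAR design: {exc}") from exc


def _coeffs_from_W(W: np.ndarray, n_ch: int, p: int) -> np.ndarray:
    """Reshape the (N*p, N) regression solution into (p, N, N) lag matrices."""
    return np.stack([W[k * n_ch:(k + 1) * n_ch, :].T for k in range(p)])


def fit_mvar(e: ROIEpochSet | np.ndarray, p: int, *,
             sampling_rate: float | None = None) -> MVARModel:
    """Least-squares MVAR(p) fit pooling epochs as independent realizations.

    ``sigma2`` is the per-channel residual variance with ddof = N*p (the
    number of regressors per equation).
    """
    data, fs = _as_array(e, sampling_rate)
    if p < 1:
        raise InvalidArgumentError("order must be >= 1")
    X, Y = _design(data, p)
    n_ch = data.shape[1]
    rows = X.shape[0]
    if rows <= n_ch * p:
        raise InsufficientDataError("fewer regression rows than parameters")
    W = _solve_normal(X.T @ X, X.T @ Y)
    resid = Y - X @ W
    sigma2 = np.sum(resid ** 2, axis=0) / (rows - n_ch * p)
    if np.any(sigma2 <= 0):
        raise RankDeficiencyError("zero residual variance: deterministic channel")
    return MVARModel(order=p, A=_coeffs_from_W(W, n_ch, p), sigma2=sigma2,
                     sampling_rate=fs, n_obs=rows)


def _fit_gram(data: np.ndarray, p: int, dtype=np.float32) -> tuple[np.ndarray, np.ndarray]:
    """Fast (A, sigma2) via normal equations; used by surrogate loops.

    Gram products accumulate in ``dtype`` (float32 by default) and the small
    solve runs in float64.  sigma2 uses the same ddof as :func:`fit_mvar`.
    """
    X, Y = _design(data, p, dtype=dtype)
    n_ch = data.shape[1]
    rows = X.shape[0]
    G = (X.T @ X).astype(np.float64)
    b = (X.T @ Y).astype(np.float64)
    W = _solve_normal(G, b)
    yy = np.einsum("ij,ij->j", Y, Y, dtype=np.float64)
    rss = yy - np.einsum("ij,ij->j", b, W)
    sigma2 = np.maximum(rss, np.finfo(float).tiny) / (rows - n_ch * p)
    return _coeffs_from_W(W, n_ch, p), sigma2


def select_order(e: ROIEpochSet | np.ndarray, p_max: int, *,
                 sampling_rate: float | None = None) -> int:
    """Hannan-Quinn order selection over 1..p_max.

    HQ(p) = ln det(Sigma_p) + 2 p N^2 ln(ln T_eff) / T_eff, where Sigma_p is
    the ML residual covariance and T_eff the pooled row count.  All candidate
    orders are scored on the common sample that discards p_max presample
    points per epoch, so the criterion compares like with like.
    """
    data, _ = _as_array(e, sampling_rate)
    n_ep, n_ch, n_t = data.shape
    if p_max < 1:
        raise InvalidArgumentError("p_max must be >= 1")
    if n_ep * (n_t - p_max) <= p_max * n_ch:
        raise InsufficientDataError("p_max too large for the available samples")
    X, Y = _design(data, p_max)
    rows = X.shape[0]
    G_full = X.T @ X
    b_full = X.T @ Y
    Cyy = Y.T @ Y
    penalty_unit = 2.0 * n_ch * n_ch * math.log(math.log(rows)) / rows
    best_p, best_hq = 1, np.inf
    for p in range(1, p_max + 1):
        m = n_ch * p
        W = _solve_normal(G_full[:m, :m], b_full[:m])
        Sigma = (Cyy - b_full[:m].T @ W) / rows
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            raise RankDeficiencyError("non-positive residual covariance")
        hq = logdet + penalty_unit * p
        if hq < best_hq:
            best_p, best_hq = p, hq
    return best_p


def _as_array(e, sampling_rate):
    if isinstance(e, np.ndarray):
        if sampling_rate is None:
            raise InvalidArgumentError("sampling_rate required for raw arrays")
        return e, float(sampling_rate)
    return e.data, e.sampling_rate


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass
class Diagnostics:
    stable: bool
    whiteness_p: float
    consistency: float
    order: int


def _epoch_autocov(resid: np.ndarray, h: int) -> np.ndarray:
    """Autocovariance matrices C_0..C_h of (E, T, N) residuals, within epochs."""
    n_ep, n_t, n_ch = resid.shape
    total = n_ep * n_t
    C = np.zeros((h + 1, n_ch, n_ch))
    for lag in range(h + 1):
        a = resid[:, lag:, :]
        b = resid[:, : n_t - lag, :]
        C[lag] = np.einsum("eti,etj->ij", a, b) / total
    return C


def residuals(m: MVARModel, e: ROIEpochSet | np.ndarray, *,
              sampling_rate: float | None = None) -> np.ndarray:
    """Model residuals per epoch, shape (epochs, samples - p, channels)."""
    data, _ = _as_array(e, sampling_rate)
    p = m.order
    X, Y = _design(data, p)
    W = np.concatenate([m.A[k].T for k in range(p)], axis=0)
    resid = Y - X @ W
    n_ep = data.shape[0]
    return resid.reshape(n_ep, -1, m.n_channels)


def li_mcleod_portmanteau(resid: np.ndarray, order: int, h: int = 20) -> tuple[float, float]:
    """Li-McLeod portmanteau statistic and p-value for residual whiteness.

    Q = T * sum_{l=1..h} tr(C_l' C_0^-1 C_l C_0^-1) + N^2 h (h+1) / (2T),
    referred to chi-square with N^2 (h - order) degrees of freedom.
    """
    n_ep, n_t, n_ch = resid.shape
    h = max(h, order + 1)
    total = n_ep * n_t
    C = _epoch_autocov(resid, h)
    C0inv = np.linalg.inv(C[0])
    q = 0.0
    for lag in range(1, h + 1):
        M = C[lag].T @ C0inv @ C[lag] @ C0inv
        q += float(np.trace(M))
    q = total * q + n_ch ** 2 * h * (h + 1) / (2.0 * total)
    df = n_ch ** 2 * (h - order)
    return q, float(stats.chi2.sf(q, df))


def consistency(m: MVARModel, e: ROIEpochSet | np.ndarray, *,
                sampling_rate: float | None = None, lags: int = 10,
                seed: int = 0) -> float:
    """Percentage of the data's correlation structure captured by the model.

    Data simulated from the fitted model (same epoch count and length) is
    compared to the real data through the stacked auto/cross-covariance
    matrices at lags 0..``lags``:

        consistency = 100 * (1 - ||R_sim - R_data|| / ||R_data||)

    with the Frobenius norm over all stacked entries.  Values near 100 mean
    the model reproduces the second-order structure; a wrong model scores
    markedly lower.
    """
    data, _ = _as_array(e, sampling_rate)
    n_ep, n_ch, n_t = data.shape
    rng = np.random.default_rng(seed)
    sim = simulate_var(m.A, m.sigma2, n_ep, n_t, rng)
    lags = min(lags, n_t - 2)
    r_data = _epoch_autocov(data.transpose(0, 2, 1), lags).ravel()
    r_sim = _epoch_autocov(sim.transpose(0, 2, 1), lags).ravel()
    denom = np.linalg.norm(r_data)
    if denom == 0:
        return 0.0
    return float(100.0 * (1.0 - np.linalg.norm(r_sim - r_data) / denom))


def diagnose(m: MVARModel, e: ROIEpochSet | np.ndarray, *,
             sampling_rate: float | None = None, h: int = 20,
             seed: int = 0) -> Diagnostics:
    """Stability, residual whiteness (LMLP) and consistency of a fitted model."""
    stable = m.stable
    resid = residuals(m, e, sampling_rate=sampling_rate)
    _, white_p = li_mcleod_portmanteau(resid, m.order, h=h)
    cons = consistency(m, e, sampling_rate=sampling_rate, seed=seed)
    return Diagnostics(stable=stable, whiteness_p=white_p, consistency=cons,
                       order=m.order)


# ---------------------------------------------------------------------------
# GPDC
# ---------------------------------------------------------------------------

@dataclass
class CausalityMatrix:
    """Directed causal strengths; entry (m, n) is the influence of n on m.

    Either per-frequency-bin (``freqs`` set, values (F, N, N)) or band-averaged
    (``bands`` set, values (B, N, N) in band order).
    """

    values: np.ndarray
    freqs: np.ndarray | None = None
    bands: Mapping[str, tuple[int, int]] | None = None
    roi_names: list[str] = field(default_factory=list)
    participant: int | None = None
    condition: str = ""
    diagnostics: Diagnostics | None = None

    @property
    def n_channels(self) -> int:
        return self.values.shape[-1]

    @property
    def band_names(self) -> list[str]:
        return list(self.bands) if self.bands is not None else []


def gpdc_values(A: np.ndarray, sigma2: np.ndarray, freqs: np.ndarray,
                sampling_rate: float) -> np.ndarray:
    """GPDC array (F, N, N) straight from lag coefficients and variances."""
    A = np.asarray(A, dtype=float)
    p, n_ch, _ = A.shape
    freqs = np.asarray(freqs, dtype=float)
    k = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * np.outer(freqs, k) / sampling_rate)   # (F, p)
    Af = np.einsum("fk,kmn->fmn", phase, A)
    Abar = np.eye(n_ch)[None] - Af
    sd = np.sqrt(np.asarray(sigma2, dtype=float))
    num = np.abs(Abar) / sd[None, :, None]
    denom = np.sqrt(np.einsum("fmn->fn", num ** 2))
    denom = np.maximum(denom, np.finfo(float).tiny)
    return num / denom[:, None, :]


def gpdc(m: MVARModel, freqs: np.ndarray | None = None, *,
         participant: int | None = None, condition: str = "",
         roi_names: list[str] | None = None) -> CausalityMatrix:
    """Per-frequency-bin GPDC of a stable MVAR model.

    Defaults to the 1-Hz grid 1..40 Hz that the canonical bands are built on.
    The diagonal is computed like any other entry but ignored by downstream
    network statistics.
    """
    if freqs is None:
        freqs = np.arange(1.0, 41.0)
    if not m.stable:
        raise InvalidArgumentError("GPDC requires a stable model")
    values = gpdc_values(m.A, m.sigma2, freqs, m.sampling_rate)
    return CausalityMatrix(values=values, freqs=np.asarray(freqs, dtype=float),
                           roi_names=roi_names or [], participant=participant,
                           condition=condition)


def band_average(cm: CausalityMatrix,
                 bands: Mapping[str, tuple[int, int]] | None = None) -> CausalityMatrix:
    """Average per-bin GPDC over each band's inclusive integer frequencies."""
    if cm.freqs is None:
        raise InvalidArgumentError("band_average needs a per-bin matrix")
    bands = dict(bands or BANDS)
    out = np.empty((len(bands),) + cm.values.shape[1:])
    for i, (name, band) in enumerate(bands.items()):
        idx = _band_indices(cm.freqs, band)
        out[i] = cm.values[idx].mean(axis=0)
    return CausalityMatrix(values=out, bands=bands, roi_names=cm.roi_names,
                           participant=cm.participant, condition=cm.condition,
                           diagnostics=cm.diagnostics)


def _band_indices(freqs: np.ndarray, band: tuple[int, int]) -> np.ndarray:
    wanted = band_bins(band)
    idx = []
    for f in wanted:
        hits = np.flatnonzero(np.isclose(freqs, f))
        if hits.size == 0:
            raise InvalidArgumentError(f"frequency bin {f} Hz missing from the grid")
        idx.append(hits[0])
    return np.asarray(idx)
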