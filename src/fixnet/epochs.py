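"""Event-aligned epoching, baseline standardization and epoch-count capping.

Epochs are cut around fixation onsets from a continuous multichannel
recording.  Each epoch is baseline-standardized: the per-channel mean over a
pre-onset baseline interval is subtracted from the whole epoch, and the epoch
is then divided by one scalar — the standard deviation pooled across all
channels over the baseline interval.  To equalize signal-to-noise between
conditions, the number of epochs per participant is capped at the cohort-wide
minimum count plus a margin, with deterministic thinning for participants
above the cap.

The filtering split matters downstream: evoked/cluster analyses run on
bandpass-filtered data, while connectivity analyses must only ever see
notch-filtered data, because bandpass filtering biases Granger-causal
estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from ._windows import epoch_window_indices
from .errors import DegenerateEpochError, EmptyEventsError, InvalidArgumentError

__all__ = [
    "EpochSet",
    "BaselineSpec",
    "make_epochs",
    "baseline_standardize",
    "cap_epochs",
    "thin_indices",
    "filter_branch",
]

log = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Epochs x channels x samples, sharing one time axis.

    ``t0_index`` is the sample index of the aligning event (fixation onset)
    within each epoch.
    """

    data: np.ndarray
    sampling_rate: float
    t0_index: int
    channel_names: list[str] = field(default_factory=list)
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidArgumentError("EpochSet data must be (epochs, channels, samples)")
        if self.sampling_rate <= 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        if not 0 <= self.t0_index < self.data.shape[2]:
            raise InvalidArgumentError("t0_index outside the epoch")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]

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
        """Time axis in seconds, 0 at the aligning event."""
        return (np.arange(self.n_samples) - self.t0_index) / self.sampling_rate


@dataclass(frozen=True)
class BaselineSpec:
    """Pre-onset baseline interval in seconds; ``start < end <= 0``."""

    start: float = -0.4
    end: float = 0.0

    def __post_init__(self) -> None:
        if not self.start < self.end <= 0:
            raise InvalidArgumentError(
                f"baseline must satisfy start < end <= 0, got [{self.start}, {self.end}]")


def make_epochs(recording: np.ndarray, events: list[int] | np.ndarray,
                window: tuple[float, float], sampling_rate: float,
                exclude_after: int | None = None,
                channel_names: list[str] | None = None,
                condition: str = "") -> EpochSet:
    """Cut one epoch per retained event from a channels x samples recording.

    Events at or after ``exclude_after`` (a sample index, e.g. the response
    time in a search trial) are ignored.  Events whose window would exceed the
    recording are dropped with a logged count.  Sample values are copied
    verbatim — epoching is pure windowing.
    """
    recording = np.asarray(recording)
    if recording.ndim != 2:
        raise InvalidArgumentError("recording must be (channels, samples)")
    n_samples = recording.shape[1]
    i0, i1 = epoch_window_indices(window[0], window[1], sampling_rate)

    events = np.asarray(events, dtype=int)
    if exclude_after is not None:
        n_late = int(np.sum(events >= exclude_after))
        if n_late:
            log.info("make_epochs: ignoring %d event(s) at/after sample %d",
                     n_late, exclude_after)
        events = events[events < exclude_after]

    fits = (events + i0 >= 0) & (events + i1 < n_samples)
    if np.sum(~fits):
        log.info("make_epochs: dropping %d event(s) whose window exceeds the recording",
                 int(np.sum(~fits)))
    events = events[fits]
    if events.size == 0:
        raise EmptyEventsError("no events retained")

    data = np.stack([recording[:, ev + i0: ev + i1 + 1] for ev in events])
    return EpochSet(data=data, sampling_rate=sampling_rate, t0_index=-i0,
                    channel_names=channel_names or [], condition=condition)


def baseline_standardize(e: EpochSet, b: BaselineSpec | None = None) -> EpochSet:
    """Subtract per-channel baseline means, then divide by the pooled baseline SD.

    Per epoch: the mean of each channel over the baseline interval is
    subtracted from that channel's entire time course; one scalar SD is then
    computed across *all* channels over the baseline interval and the whole
    epoch is divided by it.  Afterwards every channel's baseline mean is 0 and
    the pooled baseline SD is 1, which makes the operation idempotent and
    scale-equivariant.  SDs use the population convention (ddof=0).
    """
    b = b or BaselineSpec()
    j0, j1 = epoch_window_indices(b.start, b.end, e.sampling_rate)
    sl = slice(e.t0_index + j0, e.t0_index + j1 + 1)
    if sl.start < 0:
        raise InvalidArgumentError("baseline interval extends before the epoch")

    x = e.data.astype(float, copy=True)
    means = x[:, :, sl].mean(axis=2, keepdims=True)            # (E, C, 1)
    x -= means
    pooled_sd = x[:, :, sl].std(axis=(1, 2), keepdims=True)    # (E, 1, 1)
    if np.any(pooled_sd == 0):
        bad = int(np.flatnonzero(pooled_sd.ravel() == 0)[0])
        raise DegenerateEpochError(f"epoch {bad} has zero pooled baseline SD")
    x /= pooled_sd
    return replace(e, data=x)


def cap_epochs(counts: list[int], margin: float = 0.1) -> tuple[int, list[np.ndarray]]:
    """Cap epoch counts at floor(min(counts) * (1 + margin)) and thin evenly.

    Returns the cap and, per entry of ``counts``, the epoch indices to keep.
    Thinning drops every k-th epoch with a deterministic stride derived from
    the overshoot ratio (a count 50% over the cap loses every third epoch),
    trimming from the end if the stride alone does not reach the cap.
    """
    if len(counts) == 0:
        raise InvalidArgumentError("counts must be non-empty")
    if margin < 0:
        raise InvalidArgumentError("margin must be >= 0")
    lowest = int(min(counts))
    cap = int(math.floor(round(lowest * (1.0 + margin), 9)))
    keep = [thin_indices(int(c), cap) for c in counts]
    return cap, keep


def thin_indices(count: int, cap: int) -> np.ndarray:
    """Indices of epochs to keep when ``count`` exceeds ``cap``.

    The ``count - cap`` dropped epochs are spread evenly: drop number j
    removes index floor((j+1) * count / n_drop) - 1.  At 50% overshoot this
    removes every third epoch; the result always has exactly ``cap`` entries.
    """
    if count <= cap:
        return np.arange(count)
    n_drop = count - cap
    drops = (np.arange(1, n_drop + 1) * count) // n_drop - 1
    keep = np.ones(count, dtype=bool)
    keep[drops] = False
    return np.flatnonzero(keep)


def filter_branch(e: EpochSet, band: tuple[float, float] | None = None,
                  notches: list[float] | tuple[float, ...] = (),
                  order: int = 4, notch_q: float = 30.0) -> EpochSet:
    """Zero-phase bandpass and/or notch filtering of every epoch.

    The two analysis branches differ only in what they pass here: the evoked /
    cluster branch uses ``band=(1, 45)``; the connectivity branch must use
    ``band=None`` with notches only, since bandpass filtering distorts
    autoregressive causality estimates.  Filters are applied forward-backward
    (zero phase) so evoked latencies are preserved.
    """
    nyq = e.sampling_rate / 2.0
    x = e.data.astype(float, copy=True)
    if band is not None:
        lo, hi = band
        if not 0 < lo < hi < nyq:
            raise InvalidArgumentError(f"band {band} outside (0, {nyq}) Hz")
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=e.sampling_rate,
                            output="sos")
        x = signal.sosfiltfilt(sos, x, axis=2)
    for f0 in notches:
        if not 0 < f0 < nyq:
            raise InvalidArgumentError(f"notch frequency {f0} outside (0, {nyq}) Hz")
        bnum, aden = signal.iirnotch(f0, notch_q, fs=e.sampling_rate)
        x = signal.filtfilt(bnum, aden, x, axis=2)
    return replace(e, data=x)
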