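"""Time-window index conventions.

Two conventions coexist and are used deliberately:

* Epoch construction uses *inclusive* endpoints with nearest-sample rounding:
  a window of [-0.4, 0.3] s at 1000 Hz yields 701 samples.
* Analysis windows (cluster window, peak window, FWHM search window) use a
  floor rule for the sample count: the first 200 ms at 1017.25 Hz cover
  floor(0.2 * 1017.25) = 203 samples.
"""

from __future__ import annotations

import math

from .errors import InvalidArgumentError

__all__ = ["epoch_window_indices", "analysis_slice"]


def epoch_window_indices(start_s: float, end_s: float, rate: float) -> tuple[int, int]:
    """Inclusive sample offsets (relative to the event sample) of an epoch window."""
    if end_s <= start_s:
        raise InvalidArgumentError(f"empty epoch window [{start_s}, {end_s}]")
    i0 = round(start_s * rate)
    i1 = round(end_s * rate)
    return i0, i1


def analysis_slice(start_ms: float, end_ms: float, rate: float, t0_index: int,
                   n_samples: int) -> slice:
    """Map an analysis window in ms (relative to the event) onto sample indices.

    The slice starts at ``t0 + floor(start_ms * rate / 1000)`` and covers
    ``floor((end_ms - start_ms) * rate / 1000)`` samples.
    """
    if end_ms <= start_ms:
        raise InvalidArgumentError(f"empty analysis window [{start_ms}, {end_ms}] ms")
    i0 = t0_index + math.floor(start_ms * rate / 1000.0)
    count = math.floor((end_ms - start_ms) * rate / 1000.0)
    if i0 < 0 or i0 + count > n_samples:
        raise InvalidArgumentError(
            f"analysis window [{start_ms}, {end_ms}] ms falls outside the epoch "
            f"({n_samples} samples, onset at index {t0_index})")
    return slice(i0, i0 + count)
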