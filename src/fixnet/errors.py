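"""Exception types shared across the pipeline stages."""


class FixnetError(Exception):
    """Base class for all fixnet errors."""


class InvalidArgumentError(FixnetError, ValueError):
    """An argument violates a precondition (non-positive count, bad window, ...)."""


class EmptyEventsError(FixnetError, ValueError):
    """No events survived the retention rules when building epochs."""


class DegenerateEpochError(FixnetError, ValueError):
    """An epoch cannot be standardized (zero pooled baseline SD)."""


class NoPeakError(FixnetError, ValueError):
    """A curve has no usable peak (flat input to FWHM extraction)."""


class InsufficientDataError(FixnetError, ValueError):
    """Too few observations for the requested statistic."""


class RankDeficiencyError(FixnetError, ValueError):
    """The autoregressive design matrix is singular or ill-conditioned."""


class StabilityError(FixnetError, ValueError):
    """A planted or fitted MVAR process is unstable (companion radius >= 1)."""


class InvalidStateError(FixnetError, RuntimeError):
    """An object is missing prerequisite fields (e.g. ROI without neighborhood)."""


class UnlabeledVertexError(FixnetError, ValueError):
    """A clustered vertex carries no atlas label."""
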