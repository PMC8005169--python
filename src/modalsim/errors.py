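"""Exception hierarchy.

Everything derives from :class:`ModalSimError` (a ``ValueError``) so callers
that only care about "bad input" can catch one type, while the simulation
engines can distinguish the specific failure.
"""


class ModalSimError(ValueError):
    """Base class for all modalsim input errors."""


class InvalidBoundsError(ModalSimError):
    """low > high for a range or clamp."""


class InvalidCountError(ModalSimError):
    """Negative or otherwise impossible sample/iteration count."""


class InvalidMixtureError(ModalSimError):
    """Mixture weights do not form a probability vector."""


class InvalidStartError(ModalSimError):
    """MCMC chain started at a point of zero target density."""


class InsufficientDataError(ModalSimError):
    """Too few observations for the requested statistic."""


class InvalidTableError(ModalSimError):
    """Contingency table with negative counts or empty margins."""


class UnsupportedSizeError(ModalSimError):
    """Exact enumeration would be too large to be practical."""


class InvalidCountsError(ModalSimError):
    """successes > trials (or similar) in a proportion."""


class InvalidDesignError(ModalSimError):
    """Simulation design parameters are inconsistent (e.g. n_max not a multiple of step)."""


class InvalidComparisonError(ModalSimError):
    """Two traces compared on different sample-size grids."""


class InvalidBandError(ModalSimError):
    """Non-positive stabilization band."""


class InvalidBandwidthError(ModalSimError):
    """Non-positive kernel bandwidth."""


class SchemaError(ModalSimError):
    """Input file is missing required columns or keys."""


class EmptyInputError(ModalSimError):
    """No usable rows after ingestion."""
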