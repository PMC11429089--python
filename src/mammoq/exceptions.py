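"""Exception hierarchy for mammoq.

All domain errors derive from :class:`MammoqError` so callers can catch one
base class at the CLI boundary.
"""


class MammoqError(Exception):
    """Base class for all mammoq domain errors."""


class GeometryError(MammoqError):
    """An insert, ROI or analysis region does not fit the stated geometry."""


class ConfigurationError(MammoqError):
    """Invalid simulator or analysis configuration (unknown material, bad noise parameters...)."""


class DegenerateInputError(MammoqError):
    """Statistic undefined on the given input (zero spread, offset-level signal...)."""


class SaturationError(MammoqError):
    """AEC servo cannot reach the target signal within the mAs cap."""


class EdgeEstimationError(MammoqError):
    """Slanted-edge detection failed (low contrast, edge at region border...)."""


class UnsuitableEdgeError(EdgeEstimationError):
    """Edge angle outside the valid slanted-edge band (1-10 degrees)."""


class BinningError(MammoqError):
    """Empty ESF bins; re-run with a larger bin fraction."""


class RangeError(MammoqError):
    """Value outside the tabulated/supported domain (no extrapolation)."""


class ImageReadError(MammoqError):
    """Input image file rejected (truncated, 8-bit, processed presentation, missing pitch)."""
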