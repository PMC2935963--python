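"""Exception and warning types used across the package.

Every rejection names its cause: the original Image-J plugin "usually
failed" silently on bad scans; this implementation fails loudly instead.
"""


class PQCTShapeError(Exception):
    """Base class for all package errors."""


class ConfigError(PQCTShapeError):
    """Invalid or incomplete analysis configuration."""


class RawFormatError(PQCTShapeError):
    """Raw image file does not match the declared geometry."""


class SegmentationError(PQCTShapeError):
    """Failure while identifying the cortical ring."""

    def __init__(self, message: str, stage: str | None = None):
        self.stage = stage
        super().__init__(f"[{stage}] {message}" if stage else message)


class SeedNotOnBoneError(SegmentationError):
    """The seed pixel fell on background (wrong crosshair placement)."""


class CortexErodedError(SegmentationError):
    """Morphological opening annihilated the cortical component."""


class OpenRingError(SegmentationError):
    """The cortex does not enclose a medullary cavity (open cortical ring)."""


class DegenerateFitError(PQCTShapeError):
    """Point set is degenerate for the requested conic fit."""


class AxisMissError(PQCTShapeError):
    """A directional-thickness ray failed to cross both boundaries."""


class TopologyWarning(UserWarning):
    """Suspicious but non-fatal mask topology (e.g. several large holes)."""
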