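"""Exception hierarchy.

All failures raised by this package derive from :class:`FishSizerError` so
batch drivers can distinguish per-image measurement failures from bugs.
"""


class FishSizerError(Exception):
    """Base class for all errors raised by fishsizer."""


class ValidationError(FishSizerError, ValueError):
    """Invalid argument, parameter, or file content."""


class NoContrastError(FishSizerError):
    """The region of interest is perfectly flat: no gradient to threshold."""


class NoLarvaFoundError(FishSizerError):
    """Segmentation produced no candidate region of sufficient area."""


class MeasurementError(FishSizerError):
    """Morphometric extraction failed on an otherwise valid mask."""


class ArtifactPlacementError(FishSizerError):
    """Synthetic artifact could not be placed without touching the body."""
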