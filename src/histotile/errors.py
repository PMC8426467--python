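"""Exception hierarchy for histotile.

All package errors derive from :class:`HistotileError` so callers (and the
CLI) can distinguish precondition/configuration failures from genuine bugs.
"""


class HistotileError(Exception):
    """Base class for all histotile errors."""


class FormatError(HistotileError):
    """Unreadable, unsupported or malformed raster file."""


class EmptyDatasetError(HistotileError):
    """A directory tree contained no image files."""


class NestingError(HistotileError):
    """Destination root lies inside (or equals) the source root."""


class DegenerateHistogramError(HistotileError):
    """Otsu binarisation requested on a constant image."""


class EighthRuleError(HistotileError):
    """A class holds less than one eighth of the largest class's samples,
    so augmentation-based balancing cannot guarantee duplicate-free output."""


class ConfigurationError(HistotileError):
    """Inconsistent or missing run parameters."""
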