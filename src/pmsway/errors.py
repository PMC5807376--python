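"""Exception hierarchy shared across the package."""


class PmswayError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PmswayError, ValueError):
    """Invalid configuration value."""


class FormatError(PmswayError, ValueError):
    """Unreadable or unsupported marker-file format."""


class LabelingError(PmswayError, ValueError):
    """Marker labels violate the bilateral pairing convention."""


class SelectionError(PmswayError, ValueError):
    """Marker-selection policy names absent labels or selects nothing."""


class UnrecoverableGapError(PmswayError, ValueError):
    """A marker trajectory is too incomplete to reconstruct."""


class IncompatibleSubjectsError(PmswayError, ValueError):
    """Subjects cannot be pooled (mismatched marker sets or column order)."""
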