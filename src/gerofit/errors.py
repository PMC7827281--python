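"""Exception hierarchy shared across the package."""


class GerofitError(Exception):
    """Base class for all package errors."""


class InputError(GerofitError):
    """Invalid user-supplied value or malformed input."""


class DegeneratePoseError(InputError):
    """A geometric primitive was asked of a pose it is undefined for
    (coincident joints, zero-length segment)."""


class CaptureError(InputError):
    """Stream quality too poor to use (e.g. too many out-of-range frames)."""


class CalibrationError(GerofitError):
    """Calibration preconditions violated (e.g. the user was moving)."""


class FormatError(InputError):
    """Malformed file content; message names the offending line or field."""


class CatalogError(InputError):
    """Exercise catalog entry failed validation."""


class AggregationError(GerofitError):
    """Session-level aggregation asked of an empty result set."""


class UndefinedStatisticError(GerofitError):
    """A statistic is undefined for the given sample (constant input,
    all-zero paired differences)."""
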