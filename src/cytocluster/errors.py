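"""Exception hierarchy shared across the pipeline."""


class CytoclusterError(Exception):
    """Base class for all pipeline errors."""


class InputError(CytoclusterError):
    """Missing or unreadable input (file, manifest, record field)."""


class RegistrationError(CytoclusterError):
    """Channel or mask shapes disagree with the co-registration contract."""


class EmptyRegionError(CytoclusterError):
    """An operation that needs a non-empty region received an empty mask."""


class FormatError(CytoclusterError):
    """Malformed label file, polygon, or image payload."""


class ParameterError(CytoclusterError):
    """Out-of-range or inconsistent configuration value."""


class SplitError(CytoclusterError):
    """Cross-validation split cannot be constructed."""


class GenerationError(CytoclusterError):
    """Synthetic scene generation failed (e.g. infeasible packing)."""


class UndefinedMetricError(CytoclusterError):
    """Metric has no defined value (zero denominator, no ground truth)."""
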