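"""Exception hierarchy shared across the package."""


class PulseprotError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PulseprotError):
    """A quantification table does not match the declared dialect."""


class IntegrityError(PulseprotError):
    """Parsed data violates a structural invariant (e.g. duplicate protein IDs)."""


class DesignError(PulseprotError):
    """The sample-design table is invalid or inconsistent with the quant table."""


class SelectionError(PulseprotError):
    """A sample/protein selection is empty or otherwise unusable."""


class NormalizationError(PulseprotError):
    """A sample cannot be median-normalized (no quantified ratios)."""


class EstimationError(PulseprotError):
    """Too little data to estimate a model component (e.g. the variance prior)."""


class GeometryError(PulseprotError):
    """An image ROI/axis/background geometry is degenerate."""


class ConfigError(PulseprotError):
    """A simulation configuration violates its invariants."""


class ValidationError(PulseprotError):
    """An input value is outside its documented domain."""
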