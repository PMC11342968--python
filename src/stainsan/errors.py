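"""Exception hierarchy for stainsan.

All library errors derive from :class:`StainSanError` so callers can catch one
base class; the CLI maps them to non-zero exit codes with readable messages.
"""


class StainSanError(Exception):
    """Base class for all stainsan errors."""


class ShapeError(StainSanError, ValueError):
    """An array has the wrong shape or channel count (e.g. RGBA input)."""


class DomainError(StainSanError, ValueError):
    """A value lies outside its physical domain (e.g. negative optical density)."""


class ParameterError(StainSanError, ValueError):
    """A configuration parameter is outside its allowed range."""


class DegenerateInputError(StainSanError, ValueError):
    """The input carries too little information for the requested estimate
    (no foreground, rank-deficient OD cloud, single-stain image)."""


class ConditioningError(StainSanError, ValueError):
    """A linear system is too ill-conditioned to solve (collinear stain vectors)."""


class EstimationError(StainSanError, ValueError):
    """Distribution estimation is impossible (fewer than two usable matrices)."""


class FormatError(StainSanError, ValueError):
    """A serialized artifact (distribution JSON, manifest) is malformed."""


class ConfigurationError(StainSanError, ValueError):
    """Required companion inputs for a method are missing or inconsistent."""
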