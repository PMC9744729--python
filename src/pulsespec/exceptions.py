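"""Exception hierarchy for the pulse-analysis pipeline."""


class PulseError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(PulseError, ValueError):
    """An input violates a stated precondition."""


class NoBeatsError(PulseError):
    """No cardiac cycles could be located in a recording."""


class InsufficientBeatsError(PulseError):
    """Too few beats survived quality control for stable statistics."""


class ResolutionError(PulseError):
    """A beat carries too few samples to resolve ten harmonics."""


class DegenerateSpectrumError(PulseError):
    """A beat spectrum has no usable harmonic content."""


class NoInformativeIndicesError(PulseError):
    """Index selection or calibration left no usable indices."""
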