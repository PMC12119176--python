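"""Exception hierarchy shared across the package."""


class KelpNicheError(Exception):
    """Base class for all package errors."""


class InputError(KelpNicheError):
    """A required input file is missing or unreadable."""


class SchemaError(KelpNicheError):
    """An input file lacks a required column/field or violates uniqueness."""


class FormatError(KelpNicheError):
    """A raster/vector file is structurally unusable (multi-band, no georeferencing, ...)."""


class ConfigurationError(KelpNicheError):
    """An invalid parameter combination (unknown mode, mismatched codes, empty stack, ...)."""


class DegenerateSpecError(KelpNicheError):
    """A simulation spec that admits no valid sample (all-zero sampling probability)."""
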