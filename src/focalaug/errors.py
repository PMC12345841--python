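"""Exception hierarchy shared across the package."""


class FocalAugError(Exception):
    """Base class for all package-specific errors."""


class LabelParseError(FocalAugError, ValueError):
    """A label or detection text file violates the normalized-label dialect."""


class ValidationError(FocalAugError, ValueError):
    """A domain object violates its invariants."""


class ConfigError(FocalAugError, ValueError):
    """A configuration value is outside its legal range."""


class DegenerateBoxError(FocalAugError, ValueError):
    """A box maps to an empty pixel region."""


class DatasetError(FocalAugError, IOError):
    """A dataset on disk is missing files or structurally inconsistent."""


class EvaluationError(FocalAugError, ValueError):
    """Detector evaluation was asked for an impossible comparison."""
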