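"""Typed exceptions shared across the toolkit."""


class NtkError(Exception):
    """Base class for all toolkit errors."""


# --- mechanics ---------------------------------------------------------------

class FloatingIndenterError(NtkError):
    """Indenter density does not exceed the medium density; no net load."""


class NonPositiveDenominatorError(NtkError):
    """Thin-film correction denominator fell below the positivity floor."""


class NoRootInValidityDomainError(NtkError):
    """The forward model cannot reach the target modulus inside the bracket."""


# --- stack profiling ---------------------------------------------------------

class FlatProfileError(NtkError):
    """Axial profile has no derivative peak above the noise floor."""


class InvertedBoundaryError(NtkError):
    """Detected gel top precedes the detected bottom."""


class EmptySurfaceError(NtkError):
    """Too few columns yielded a surface elevation."""


class EdgeDepressionError(NtkError):
    """Depression minimum touches the field border; depth unreliable."""


# --- membrane potential ------------------------------------------------------

class MissingBackgroundError(NtkError):
    """Plate has no dye-only background wells."""


class NonPositiveBackgroundError(NtkError):
    """Background fluorescence F0 must be positive."""


class LogDomainError(NtkError):
    """dF/F0 <= -1 puts the voltage conversion outside the log domain."""


class ZeroMeanError(NtkError):
    """COV undefined for zero-mean reads."""


class InsufficientPointsError(NtkError):
    """Regression needs more distinct x values."""


class EmptyGroupError(NtkError):
    """A requested group has no wells."""


class DomainError(NtkError):
    """Generic numeric-domain violation."""


# --- IO ----------------------------------------------------------------------

class MissingMetadataError(NtkError):
    """Required voxel metadata absent and no override supplied."""


class ChannelCountError(NtkError):
    """Channel map inconsistent with the file's channel count."""


class PlateSchemaError(NtkError):
    """Plate CSV violates the expected schema."""


class ConfigError(NtkError):
    """Configuration file invalid or contains unknown keys."""
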