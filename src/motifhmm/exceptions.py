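"""Exception hierarchy.

Exit-code mapping used by the CLI: InputError -> 2, ConfigurationError -> 3.
"""


class MotifHMMError(Exception):
    """Base class for all package errors."""


class InputError(MotifHMMError):
    """Malformed or unusable user input (sequences, files)."""


class AlphabetError(InputError):
    """A symbol outside the 20-letter amino-acid alphabet where one is required."""


class NormalizationError(MotifHMMError):
    """A probability vector that should sum to 1 does not."""


class ConfigurationError(MotifHMMError):
    """Invalid configuration: unknown matrix label, zero blocks, bad spec."""


class ProtocolError(MotifHMMError):
    """PD/VD protocol applied to unusable predictions (e.g. empty position list)."""


class LabellingError(MotifHMMError):
    """A predicted sequence id has no truth label."""


class DecodingError(MotifHMMError):
    """A sequence that the model cannot generate (e.g. shorter than the
    minimal emitting path) or an internal trellis inconsistency."""
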