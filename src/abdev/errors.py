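"""Exception hierarchy for abdev."""


class AbdevError(Exception):
    """Base class for all abdev errors."""


class SequenceError(AbdevError):
    """Invalid amino-acid sequence (bad alphabet, empty, etc.)."""


class PairingError(AbdevError):
    """VH/VL chain pairing could not be resolved from the input."""


class JoinError(AbdevError):
    """Measurement table references ids absent from the sequence input."""


class CdrError(AbdevError):
    """A CDR anchor motif could not be located or a rule was violated."""


class DegenerateDataError(AbdevError):
    """Input data is degenerate for the requested operation."""


class TrainingError(AbdevError):
    """A platform cannot be trained (too few rows, all candidates failed...)."""


class SuiteFormatError(AbdevError):
    """A persisted model suite could not be loaded."""
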