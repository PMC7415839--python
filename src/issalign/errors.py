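"""Exception hierarchy for issalign."""


class IssAlignError(Exception):
    """Base class for all issalign errors."""


class ConfigurationError(IssAlignError):
    """Invalid configuration value (unknown matrix, bad cutoff, wrong arity)."""


class InputError(IssAlignError):
    """Invalid user-supplied input (files, sequences, ids)."""


class ParseError(InputError):
    """A text input could not be parsed; message names the offending line."""


class CoordinateError(IssAlignError):
    """An index fell outside the referenced sequence."""


class CompositionError(IssAlignError):
    """Residue maps with mismatched endpoints cannot be composed."""


class InvariantError(IssAlignError):
    """A domain-type invariant was violated."""


class ClassificationError(IssAlignError):
    """Malformed SCOP-style classification code."""


class MetricError(IssAlignError):
    """An evaluation metric is undefined for the given inputs."""


class GenerationError(IssAlignError):
    """Synthetic-family parameters are unsatisfiable."""
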