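"""Exception hierarchy for nummolgen.

Every failure mode named in the module contracts maps to one of these, so
callers (and the CLI) can distinguish user errors from internal bugs.
"""


class NumMolGenError(Exception):
    """Base class for all package errors."""


class SmilesParseError(NumMolGenError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"cannot parse SMILES {smiles!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class VocabularyError(NumMolGenError):
    """A functional-group or token vocabulary is malformed or empty."""


class EncodingError(NumMolGenError):
    """A sequence could not be encoded (e.g. out-of-vocabulary token)."""


class MalformedSequenceError(NumMolGenError):
    """A dual sequence violates the template (missing [BOS]/[EOS], bad header)."""


class TruncationError(NumMolGenError):
    """A sequence exceeds the allowed maximum length; never truncated silently."""


class MoleculeTooLargeError(NumMolGenError):
    """A molecule exceeds the configured maximum atom count."""


class ConfigurationError(NumMolGenError):
    """A run configuration or model configuration is invalid."""


class ContractViolation(NumMolGenError):
    """Mismatched shapes or lengths between paired inputs."""


class NumericDomainError(NumMolGenError):
    """Non-finite numeric input where finite values are required."""


class DegenerateBatchError(NumMolGenError):
    """A training batch has no unmasked positions to compute a loss over."""


class DivergenceError(NumMolGenError):
    """Training produced a non-finite loss."""


class ScoringError(NumMolGenError):
    """A reward component is missing or a scorer failed."""


class UndefinedMetricError(NumMolGenError):
    """A metric is undefined for the given input (e.g. empty set)."""


class CorpusShortfallError(NumMolGenError):
    """A fixture spec cannot yield the requested number of distinct molecules."""
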