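"""Exception hierarchy for the pipeline."""


class G1SNetError(Exception):
    """Base class for all package errors."""


class SchemaError(G1SNetError):
    """A mandatory column is missing or a table does not match its schema."""


class ParseError(G1SNetError):
    """A cell or sequence character could not be parsed."""


class DuplicateGeneError(G1SNetError):
    """The same systematic gene name appears twice where uniqueness is required."""


class ValidationError(G1SNetError):
    """A domain invariant is violated."""


class ParameterError(G1SNetError):
    """Simulation or run parameters are inconsistent."""


class ConfigError(G1SNetError):
    """Run configuration is invalid (e.g. not exactly nine classifiers per TF)."""
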