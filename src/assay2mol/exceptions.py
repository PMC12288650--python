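"""Exception hierarchy shared across the pipeline."""


class Assay2MolError(Exception):
    """Base class for all package-specific errors."""


class ParseError(Assay2MolError):
    """Malformed input document (reports the byte offset when known)."""


class SchemaError(Assay2MolError):
    """Well-formed document that violates the record schema."""


class InvalidSmilesError(Assay2MolError):
    """A SMILES string that RDKit cannot parse."""


class ContractError(Assay2MolError):
    """A precondition of an operation was violated by the caller."""


class DegenerateInputError(Assay2MolError):
    """Mathematically degenerate input, e.g. a zero-norm vector."""


class EmptyCorpusError(Assay2MolError):
    """Query against an index with no records."""


class UndefinedMetricError(Assay2MolError):
    """A metric that is undefined for the given input size."""


class BackendError(Assay2MolError):
    """A text/embedding/scoring backend failed after retries."""
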