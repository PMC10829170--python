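"""Exception hierarchy shared across the package."""


class DDIKitError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DDIKitError):
    """A SMILES string could not be parsed into a molecule."""


class SchemaError(DDIKitError):
    """A tabular input is missing a required column."""


class UnknownTokenError(DDIKitError):
    """A SMILES character has no entry in the tokenizer vocabulary."""


class ShapeError(DDIKitError):
    """Array dimensions do not match what an operation requires."""


class ConfigError(DDIKitError):
    """A configuration value is inconsistent or unusable."""


class DegenerateVectorError(DDIKitError):
    """A similarity is undefined because a vector norm or popcount is zero."""


class DegenerateSplitError(DDIKitError):
    """A requested split leaves one of its buckets empty."""
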