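"""Exception hierarchy.

Configuration errors correspond to misuse of the API or CLI flags (exit
code 2 at the command line); data/schema errors to malformed or
incompatible inputs (exit code 3).
"""


class MediVoteError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MediVoteError):
    """Invalid parameter, missing target column, incompatible options."""


class DataFormatError(MediVoteError):
    """Input file does not parse in the declared format."""


class SchemaError(MediVoteError):
    """Table does not conform to the schema a fitted object expects."""
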