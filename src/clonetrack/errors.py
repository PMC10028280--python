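"""Exception hierarchy shared across the pipeline.

Configuration problems (bad parameters, duplicate barcode tables, invalid
scenario probabilities) are distinguished from data problems (malformed
records, referential breaks) so callers can map them to distinct exit codes.
"""


class ClonetrackError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ClonetrackError):
    """Invalid parameters, tables, or scenario configuration."""


class DataError(ClonetrackError):
    """Malformed or inconsistent input data."""


class SchemaError(DataError):
    """A required column is missing from a tabular input."""
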