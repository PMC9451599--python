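"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataFormatError -> 3.
"""


class EvoTriageError(Exception):
    """Base class for all package errors."""


class ConfigError(EvoTriageError):
    """Invalid configuration: bad thresholds, empty rule sets, missing paths."""


class DataFormatError(EvoTriageError):
    """Malformed input data: missing MAF columns, length mismatches, empty regions."""
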