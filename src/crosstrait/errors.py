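"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
EstimationError -> 4.
"""


class CrosstraitError(Exception):
    """Base class for all package errors."""


class ConfigError(CrosstraitError):
    """Invalid configuration: bad column map, out-of-range threshold, missing path."""


class DataError(CrosstraitError):
    """Invalid or insufficient input data (empty file, zero surviving SNPs...)."""


class EstimationError(CrosstraitError):
    """An estimator could not produce a valid result (degenerate design,
    singular matrix, instrument shortage...)."""
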