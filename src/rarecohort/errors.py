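"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class ConfigError(ValueError):
    """Invalid configuration: bad thresholds, seeds, paths, or schema."""


class DataError(ValueError):
    """Invalid or degenerate input data (counts, dates, taxonomy)."""


class NumericalError(RuntimeError):
    """A fit or root-solve failed to converge or is undefined."""
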