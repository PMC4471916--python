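"""Exception hierarchy shared across the package."""


class SongprovError(Exception):
    """Base class for all package errors."""


class FormatError(SongprovError):
    """Input file is structurally malformed (missing columns, bad timestamp)."""


class IntegrityError(SongprovError):
    """Input parsed but violates a data invariant (position gaps, category drift)."""


class ConfigError(SongprovError):
    """Invalid or infeasible configuration."""


class StatisticsError(SongprovError):
    """A statistic was requested on input that cannot support it."""


class MetricUndefinedError(SongprovError):
    """A network metric is undefined for the given graph (no edges, no triples)."""


class ConvergenceError(SongprovError):
    """An iterative solver failed to converge within its iteration budget."""
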