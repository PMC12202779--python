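"""Typed exceptions raised across the pipeline."""


class NichePartError(Exception):
    """Base class for all package errors."""


class TableParseError(NichePartError):
    """A tabular input file violates the expected layout or cell types."""


class DuplicateIdError(TableParseError):
    """An identifier (OTU or sample) occurs more than once."""


class LineageParseError(NichePartError):
    """A taxonomy lineage string uses an unknown rank prefix."""


class TreeParseError(NichePartError):
    """A Newick file could not be parsed into a valid tree."""


class EmptyResultError(NichePartError):
    """A filtering step removed every row/column."""


class GroupingError(NichePartError):
    """Sample grouping is missing, degenerate, or inconsistent."""


class MetricError(NichePartError):
    """An unknown metric name or an input outside a metric's domain."""
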