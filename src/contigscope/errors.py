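"""Exception hierarchy.

All data-level failures raise :class:`ContigScopeError` subclasses so
callers (and the CLI) can distinguish bad input data from usage errors.
"""


class ContigScopeError(Exception):
    """Base class for all data-level errors raised by contigscope."""


class TableError(ContigScopeError):
    """Malformed or inconsistent contig metadata table."""


class RoleError(ContigScopeError):
    """Invalid column-role assignment."""


class SequenceError(ContigScopeError):
    """Invalid FASTA input or sequence set."""


class AnnotationError(ContigScopeError):
    """Malformed GFF3 input."""


class LinkError(ContigScopeError):
    """Cross-reference failure between table, sequences and annotations."""


class QueryError(ContigScopeError):
    """Invalid search/filter/gate request."""


class ExportError(ContigScopeError):
    """Subset export cannot be satisfied (missing attachment, bad path)."""


class PlotError(ContigScopeError):
    """Plot or track specification cannot be built."""
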