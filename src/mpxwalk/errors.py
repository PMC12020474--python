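"""Exception hierarchy for mpxwalk.

Every user-facing failure mode raises a distinct named error so that both
library callers and the CLI can report precise one-line diagnostics.
"""


class MpxwalkError(Exception):
    """Base class for all mpxwalk errors."""


class FlistError(MpxwalkError):
    """Malformed flist manifest (missing file, too few columns)."""


class DuplicateLayerNameError(FlistError):
    """Two flist rows declare the same layer name."""


class EdgeListError(MpxwalkError):
    """Malformed edge-list file (bad column count, non-numeric weight)."""


class EmptyLayerError(EdgeListError):
    """A layer ends up with no usable edges after cleaning."""


class GeneSetError(MpxwalkError):
    """Malformed gene-set file (empty, negative weight)."""


class NoSeedsError(MpxwalkError):
    """No seed gene carries positive probability mass in the multiplex."""


class MultiplexBuildError(MpxwalkError):
    """Invalid multiplex construction request (no layers, bad delta)."""


class ArchiveError(MpxwalkError):
    """Corrupt or unreadable multiplex archive."""


class ArchiveVersionError(ArchiveError):
    """Archive format version does not match this package."""


class FoldError(MpxwalkError):
    """Invalid cross-validation fold request (K > N, N < 2)."""


class MetricError(MpxwalkError):
    """Rank metrics requested on degenerate input (no positives/negatives)."""
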