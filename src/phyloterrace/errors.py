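"""Exception types shared across the package."""


class PhyloterraceError(Exception):
    """Base class for all package-specific errors."""


class NewickError(PhyloterraceError, ValueError):
    """Malformed Newick input (bad parenthesization, duplicate or empty labels)."""


class LeafSetMismatchError(PhyloterraceError, ValueError):
    """Trees (or a tree and a coverage matrix) do not share the expected leaf set."""

    def __init__(self, message, missing=(), extra=()):
        super().__init__(message)
        self.missing = sorted(missing)
        self.extra = sorted(extra)


class UnknownLabelError(PhyloterraceError, KeyError):
    """A requested leaf label is not present in the tree."""


class NoComprehensiveTaxonError(PhyloterraceError, ValueError):
    """The coverage matrix has no taxon sampled in every locus.

    The terrace machinery roots every locus-induced subtree at one taxon
    common to all loci; without such a taxon the instance is refused.
    """


class IncompatibleSplitsError(PhyloterraceError, ValueError):
    """A split/triplet system is internally inconsistent (cannot form a tree)."""


class CoverageFormatError(PhyloterraceError, ValueError):
    """Bad coverage CSV, alignment, or partition-definition input."""


class ResolutionLimitError(PhyloterraceError, ValueError):
    """Too many binary resolutions of input-tree polytomies to enumerate."""
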