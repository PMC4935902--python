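"""Exception hierarchy for network validation and computation failures."""


class PhyloNetworkError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PhyloNetworkError):
    """A network failed structural validation."""


class CycleError(ValidationError):
    """The edge relation contains a directed cycle."""


class RootError(ValidationError):
    """Zero indegree-0 nodes, or more than one."""


class UnlabeledLeafError(ValidationError):
    """A sink node has no taxon label."""


class DuplicateTaxonError(ValidationError):
    """Two leaves carry the same taxon label (labeling must be bijective)."""


class UnaryTreeNodeError(ValidationError):
    """A tree node (indegree <= 1) has outdegree exactly 1; forbidden in strict mode."""


class MultiEdgeError(ValidationError):
    """The same parent->child pair was supplied twice; edge sets carry no multiplicity."""


class UnknownNodeError(PhyloNetworkError):
    """A node identifier does not belong to the network."""


class TaxonSetMismatchError(PhyloNetworkError):
    """Cross-network operations require identical taxon sets."""


class ReductionError(PhyloNetworkError):
    """A reduction step produced a structurally invalid intermediate."""


class FormatError(PhyloNetworkError):
    """Malformed eNewick or edge-list input."""


class NotPartlyReducedError(PhyloNetworkError):
    """An operation guaranteed only on partly reduced networks was refused."""
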