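"""The d_e distance on rooted phylogenetic networks.

d_e(N1, N2) is half the symmetric difference of two multisets: each network
contributes its equivalence-class multiplicities e_N(v) over the unique nodes
L(N), classes being matched across the pair by cross-equivalence,

    d_e = 1/2 [ sum_{v in L(N1)} max(0, e(v) - e(v'))
              + sum_{u in L(N2)} max(0, e(u) - e(u')) ],

where v' is the (unique, if any) member of L(N2) cross-equivalent to v, with
e(empty) = 0.  d_e is a metric on the space of partly reduced networks: there
d_e = 0 holds exactly for isomorphic pairs.  On arbitrary networks it is a
symmetric, triangle-inequality-satisfying measure that can vanish on
non-isomorphic pairs.  Arithmetic is exact (integer totals, a final division
by two as a Fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .equivalence import ClassingTable, _invert, eq_classes, unique_nodes
from .errors import NotPartlyReducedError
from .network import PhyloNetwork
from .reduction import reduce_network, superconvergent_sets


@dataclass
class DeResult:
    """Outcome of a d_e computation.

    ``value`` is exact (a Fraction with denominator 1 or 2);
    ``contributions`` maps each representative of either network to its
    clipped multiplicity surplus; ``mode`` records any pre-reduction applied.
    """

    value: Fraction
    contributions: dict[tuple[int, str], int]
    mode: str
    n1_size: int
    n2_size: int

    def __float__(self) -> float:  # pragma: no cover - convenience
        return float(self.value)

    def as_decimal(self) -> str:
        """Exact decimal rendering: an integer, or trailing ``.5``."""
        if self.value.denominator == 1:
            return str(self.value.numerator)
        return f"{self.value.numerator // 2}.5"


def de_distance(n1: PhyloNetwork, n2: PhyloNetwork, pre_reduce: str = "none") -> DeResult:
    """Compute d_e between two networks on the same taxon set.

    ``pre_reduce`` applies the same reduction to both inputs first:
    ``"none"`` (default — the measure on the networks as given),
    ``"partial"`` (partly reduced versions; d_e is a metric there) or
    ``"full"`` (reduced versions).
    """
    if pre_reduce not in ("none", "partial", "full"):
        raise ValueError(f"pre_reduce must be none|partial|full, got {pre_reduce!r}")
    if pre_reduce != "none":
        n1, _ = reduce_network(n1, pre_reduce)
        n2, _ = reduce_network(n2, pre_reduce)

    table = eq_classes(n1, n2)
    t1 = unique_nodes(n1, table, 0)
    t2 = unique_nodes(n2, table, 1)
    by_class_2 = {t2.class_of[r]: r for r in t2.representatives}
    by_class_1 = {t1.class_of[r]: r for r in t1.representatives}

    contributions: dict[tuple[int, str], int] = {}
    total = 0
    for rep in t1.representatives:
        other = by_class_2.get(t1.class_of[rep])
        e_other = t2.multiplicity[other] if other is not None else 0
        c = max(0, t1.multiplicity[rep] - e_other)
        contributions[(1, rep)] = c
        total += c
    for rep in t2.representatives:
        other = by_class_1.get(t2.class_of[rep])
        e_other = t1.multiplicity[other] if other is not None else 0
        c = max(0, t2.multiplicity[rep] - e_other)
        contributions[(2, rep)] = c
        total += c

    return DeResult(
        value=Fraction(total, 2),
        contributions=contributions,
        mode=pre_reduce,
        n1_size=len(n1),
        n2_size=len(n2),
    )


def is_isomorphic_partly_reduced(
    n1: PhyloNetwork, n2: PhyloNetwork, *, force: bool = False
) -> tuple[bool, dict[str, str] | None]:
    """Decide isomorphism of two partly reduced networks via d_e = 0.

    Separation (d_e = 0 iff isomorphic) is guaranteed only on the partly
    reduced space, so inputs containing a superconvergent set are refused
    unless ``force`` is set.  On a positive answer the witnessing bijection
    (each node to its unique cross-equivalent partner) is returned.
    """
    if not force:
        for net, name in ((n1, "first"), (n2, "second")):
            if superconvergent_sets(net):
                raise NotPartlyReducedError(
                    f"{name} input contains a superconvergent set; "
                    "d_e = 0 does not imply isomorphism there (pass force=True to override)"
                )
    result = de_distance(n1, n2, pre_reduce="none")
    if result.value != 0:
        return False, None
    table = eq_classes(n1, n2)
    part2 = _invert(table.eq[1])
    mapping: dict[str, str] = {}
    for u in n1.nodes:
        partners = part2.get(table.eq[0][u], frozenset())
        # on partly reduced inputs classes are singletons; pick deterministically
        mapping[u] = min(partners)
    return True, mapping


def oracle_isomorphic(n1: PhyloNetwork, n2: PhyloNetwork, max_nodes: int = 32) -> bool:
    """Exhaustive isomorphism test: search for a bijection preserving edges
    and leaf labels (VF2 over the directed graphs with taxon-matched nodes).

    Independent of the d_e machinery; guarded to small networks.
    """
    if len(n1) > max_nodes or len(n2) > max_nodes:
        raise ValueError(f"oracle_isomorphic is limited to {max_nodes} nodes")
    if len(n1) != len(n2) or len(n1.edges) != len(n2.edges):
        return False
    import networkx as nx

    g1 = nx.DiGraph(n1.edges)
    g1.add_nodes_from(n1.nodes)
    g2 = nx.DiGraph(n2.edges)
    g2.add_nodes_from(n2.nodes)
    for g, net in ((g1, n1), (g2, n2)):
        for n in g:
            g.nodes[n]["taxon"] = net.leaf_labels.get(n)
    matcher = nx.algorithms.isomorphism.DiGraphMatcher(
        g1, g2, node_match=lambda a, b: a["taxon"] == b["taxon"]
    )
    return matcher.is_isomorphic()
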