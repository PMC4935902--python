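"""Node semiequivalence and equivalence for rooted phylogenetic networks.

Two nodes are *semiequivalent* (bottom-up congruence) when they are leaves
with the same taxon, or when their children can be paired off into
semiequivalent pairs.  They are *equivalent* when additionally their parents
pair off into equivalent pairs, with the two roots as the base case.  Both
relations extend across a pair of networks on the same taxon set, yielding
the cross mappings h (semiequivalence) and g (equivalence) from nodes of one
network to node sets of the other.

Because networks carry no child order, pairing is by multiset: a node's
semiequivalence class is the canonically interned fingerprint of its taxon
(leaves) or of the multiset of its children's class ids (internal nodes), and
its equivalence class the fingerprint of (semieq class, multiset of parent
equivalence classes).  Interning is shared across a network pair, so
cross-network comparison is plain identifier equality and the whole
computation is a pair of linear sweeps — well inside the polynomial budget.

A literal recursive oracle (`oracle_semieq`, `oracle_eq`) that tries every
child/parent bijection guards the partition-refinement implementation in the
test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .errors import TaxonSetMismatchError
from .network import PhyloNetwork, height_depth


class _Interner:
    """Canonical fingerprint table shared across one or two networks."""

    def __init__(self) -> None:
        self._table: dict[tuple, int] = {}

    def intern(self, key: tuple) -> int:
        if key not in self._table:
            self._table[key] = len(self._table)
        return self._table[key]


@dataclass
class ClassingTable:
    """Semiequivalence and equivalence class ids for one or two networks.

    ``semieq[i][node]`` / ``eq[i][node]`` give the class id of ``node`` in the
    i-th network of the scope; ids are comparable across the scope (two nodes
    are semi/equivalent iff their ids are equal).
    """

    networks: tuple[PhyloNetwork, ...]
    semieq: tuple[dict[str, int], ...]
    eq: tuple[dict[str, int], ...] = field(default=())

    def semieq_partition(self, i: int = 0) -> dict[int, frozenset[str]]:
        return _invert(self.semieq[i])

    def eq_partition(self, i: int = 0) -> dict[int, frozenset[str]]:
        return _invert(self.eq[i])


def _invert(classing: dict[str, int]) -> dict[int, frozenset[str]]:
    groups: dict[int, set[str]] = {}
    for node, cid in classing.items():
        groups.setdefault(cid, set()).add(node)
    return {cid: frozenset(nodes) for cid, nodes in groups.items()}


def _check_taxa(nets: tuple[PhyloNetwork, ...]) -> None:
    if len(nets) == 2 and nets[0].taxa != nets[1].taxa:
        raise TaxonSetMismatchError(
            f"taxon sets differ: {sorted(nets[0].taxa)} vs {sorted(nets[1].taxa)}"
        )


def _semieq_sweep(net: PhyloNetwork, interner: _Interner) -> dict[str, int]:
    g = net.graph
    out: dict[str, int] = {}
    for n in reversed(list(nx.topological_sort(g))):
        succ = list(g.successors(n))
        if not succ:
            out[n] = interner.intern(("leaf", net.leaf_labels[n]))
        else:
            out[n] = interner.intern(("node", tuple(sorted(out[c] for c in succ))))
    return out


def _eq_sweep(net: PhyloNetwork, semieq: dict[str, int], interner: _Interner) -> dict[str, int]:
    g = net.graph
    out: dict[str, int] = {}
    for n in nx.topological_sort(g):
        pred = list(g.predecessors(n))
        parent_key = tuple(sorted(out[p] for p in pred))  # () exactly at the root
        out[n] = interner.intern(("eq", semieq[n], parent_key))
    return out


def semieq_classes(*nets: PhyloNetwork) -> ClassingTable:
    """Semiequivalence classes for one network or a pair on the same taxa."""
    _check_taxa(nets)
    interner = _Interner()
    return ClassingTable(
        networks=nets,
        semieq=tuple(_semieq_sweep(n, interner) for n in nets),
    )


def eq_classes(*nets: PhyloNetwork) -> ClassingTable:
    """Equivalence (and semiequivalence) classes for one network or a pair."""
    _check_taxa(nets)
    interner = _Interner()
    semieq = tuple(_semieq_sweep(n, interner) for n in nets)
    eq = tuple(_eq_sweep(n, s, interner) for n, s in zip(nets, semieq))
    return ClassingTable(networks=nets, semieq=semieq, eq=eq)


# ---------------------------------------------------------------------------
# cross-network mappings h and g
# ---------------------------------------------------------------------------


@dataclass
class CrossMapping:
    """The mappings h (semiequivalence) and g (equivalence) from nodes of the
    first network to node sets of the second; ``g[u] <= h[u]`` always."""

    h: dict[str, frozenset[str]]
    g: dict[str, frozenset[str]]


def cross_mapping(n1: PhyloNetwork, n2: PhyloNetwork) -> CrossMapping:
    table = eq_classes(n1, n2)
    se2 = _invert(table.semieq[1])
    e2 = _invert(table.eq[1])
    h = {
        u: se2.get(table.semieq[0][u], frozenset())
        for u in n1.nodes
    }
    g = {
        u: e2.get(table.eq[0][u], frozenset())
        for u in n1.nodes
    }
    return CrossMapping(h=h, g=g)


# ---------------------------------------------------------------------------
# unique nodes L(N) and multiplicities e_N
# ---------------------------------------------------------------------------


@dataclass
class UniqueNodeTable:
    """One representative per within-network equivalence class, with the class
    size as multiplicity.  Multiplicities sum to |V|."""

    representatives: list[str]
    multiplicity: dict[str, int]
    class_of: dict[str, int]  # representative -> interned eq class id


def unique_nodes(net: PhyloNetwork, table: ClassingTable | None = None,
                 index: int = 0) -> UniqueNodeTable:
    """Compute L(N): deterministic representatives and class multiplicities.

    Representatives are the smallest member of each class under
    (depth, height, node name) ordering; the table is ordered the same way.
    """
    if table is None:
        table = eq_classes(net)
        index = 0
    eq = table.eq[index]
    hd = height_depth(net)
    partition = _invert(eq)
    reps: list[tuple[tuple, str, int, int]] = []
    for cid, members in partition.items():
        rep = min(members, key=lambda n: (hd.depth[n], hd.height[n], n))
        reps.append(((hd.depth[rep], hd.height[rep], rep), rep, cid, len(members)))
    reps.sort()
    return UniqueNodeTable(
        representatives=[r[1] for r in reps],
        multiplicity={r[1]: r[3] for r in reps},
        class_of={r[1]: r[2] for r in reps},
    )


# ---------------------------------------------------------------------------
# literal recursive oracles (test support)
# ---------------------------------------------------------------------------


def oracle_semieq(n1: PhyloNetwork, n2: PhyloNetwork, u: str, v: str,
                  _memo: dict | None = None) -> bool:
    """Definition-literal semiequivalence test trying every child bijection.

    ``n1`` and ``n2`` may be the same network.  Exponential in outdegree;
    intended for small test networks (outdegree <= ~6).
    """
    memo: dict = {} if _memo is None else _memo
    key = (u, v)
    if key in memo:
        return memo[key]
    cu, cv = n1.children(u), n2.children(v)
    if not cu and not cv:
        result = n1.leaf_labels[u] == n2.leaf_labels[v]
    elif len(cu) != len(cv) or not cu:
        result = False
    else:
        result = any(
            all(oracle_semieq(n1, n2, a, b, memo) for a, b in zip(cu, perm))
            for perm in itertools.permutations(cv)
        )
    memo[key] = result
    return result


def oracle_eq(n1: PhyloNetwork, n2: PhyloNetwork, u: str, v: str,
              _memo: dict | None = None) -> bool:
    """Definition-literal equivalence test trying every parent bijection."""
    if not oracle_semieq(n1, n2, u, v):
        return False
    memo: dict = {} if _memo is None else _memo
    key = (u, v)
    if key in memo:
        return memo[key]
    pu, pv = n1.parents(u), n2.parents(v)
    if not pu and not pv:
        result = True  # both roots (and semiequivalent)
    elif len(pu) != len(pv) or not pu:
        result = False
    else:
        result = any(
            all(oracle_eq(n1, n2, a, b, memo) for a, b in zip(pu, perm))
            for perm in itertools.permutations(pv)
        )
    memo[key] = result
    return result
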