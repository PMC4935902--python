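"""Reduction procedures for rooted phylogenetic networks.

A *convergent set* is a set of >= 2 internal nodes that all reach exactly the
same set of leaves (the set's leaf set).  The *reduced version* of a network is
obtained by (1) collapsing every maximal pendant subtree to a placeholder
leaf, (2) repeatedly deleting maximal convergent sets together with the paths
from their members down to the parents of the affected leaves and suppressing
the unary (indegree 1, outdegree 1) nodes this creates, and (3) re-expanding
the pendant subtrees.  The *partly reduced version* runs the same pipeline but
deletes only *superconvergent* sets: convergent sets whose members share an
identical parent set, that parent set itself being convergent whenever it has
>= 2 elements.

Conventions chosen where the procedure is under-specified:

* a convergent-set member that is itself the parent of an affected leaf is
  kept (the deletion frontier stops just above the leaves);
* parallel edges arising from reconnection or suppression are merged (edge
  sets, not multisets);
* a network with no reticulate node passes through reduction unchanged;
* the root is never deleted as part of a convergent set: sets containing the
  root are left in place (removing the root would disconnect the network).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import ReductionError
from .network import PhyloNetwork, build_network

# ---------------------------------------------------------------------------
# clusters and convergent sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cluster:
    """The set of leaf taxa reachable from a node."""

    node: str
    leaves: frozenset[str]


@dataclass(frozen=True)
class ConvergentSet:
    """A set of >= 2 internal nodes sharing one reachable-leaf set."""

    members: frozenset[str]
    leaf_set: frozenset[str]
    flavor: str  # "maximal" | "super"


def leaf_clusters(net: PhyloNetwork) -> dict[str, Cluster]:
    """Reachable-leaf set of every node, in one reverse-topological sweep."""
    g = net.graph
    clusters: dict[str, frozenset[str]] = {}
    for n in reversed(list(nx.topological_sort(g))):
        succ = list(g.successors(n))
        if not succ:
            clusters[n] = frozenset({net.leaf_labels[n]})
        else:
            acc: set[str] = set()
            for c in succ:
                acc |= clusters[c]
            clusters[n] = frozenset(acc)
    return {n: Cluster(node=n, leaves=cl) for n, cl in clusters.items()}


def _internal_cluster_groups(net: PhyloNetwork) -> dict[frozenset[str], list[str]]:
    clusters = leaf_clusters(net)
    groups: dict[frozenset[str], list[str]] = {}
    for n, cl in clusters.items():
        if net.graph.out_degree(n) >= 1:  # internal nodes only
            groups.setdefault(cl.leaves, []).append(n)
    return groups


def maximal_convergent_sets(net: PhyloNetwork) -> list[ConvergentSet]:
    """Maximal convergent sets: the equivalence classes of internal nodes
    under identical reachable-leaf sets, keeping classes of size >= 2.

    Ordered deterministically by sorted leaf set.
    """
    out = [
        ConvergentSet(members=frozenset(nodes), leaf_set=ls, flavor="maximal")
        for ls, nodes in _internal_cluster_groups(net).items()
        if len(nodes) >= 2
    ]
    out.sort(key=lambda s: (sorted(s.leaf_set), sorted(s.members)))
    return out


def superconvergent_sets(net: PhyloNetwork) -> list[ConvergentSet]:
    """Superconvergent sets, maximal under inclusion.

    Internal nodes are grouped by (reachable-leaf set, parent set); a group of
    size >= 2 qualifies when its shared parent set is empty or a singleton, or
    is itself cluster-homogeneous (i.e. convergent).  Deterministic order:
    sorted leaf set, then sorted members.
    """
    clusters = {n: c.leaves for n, c in leaf_clusters(net).items()}
    g = net.graph
    groups: dict[tuple[frozenset[str], frozenset[str]], list[str]] = {}
    for n in g:
        if g.out_degree(n) < 1:
            continue
        key = (clusters[n], frozenset(g.predecessors(n)))
        groups.setdefault(key, []).append(n)
    out = []
    for (ls, parents), nodes in groups.items():
        if len(nodes) < 2:
            continue
        if len(parents) >= 2 and len({clusters[p] for p in parents}) != 1:
            continue  # parent set must itself be convergent
        out.append(ConvergentSet(members=frozenset(nodes), leaf_set=ls, flavor="super"))
    out.sort(key=lambda s: (sorted(s.leaf_set), sorted(s.members)))
    return out


# ---------------------------------------------------------------------------
# pendant subtrees
# ---------------------------------------------------------------------------


@dataclass
class PendantEntry:
    subtree: PhyloNetwork  # the detached clade, as a (possibly 1-node) tree
    subtree_root: str
    attach_parent: str | None  # original parent p_t


@dataclass
class PendantRegistry:
    """Placeholder leaf -> detached maximal pendant subtree."""

    entries: dict[str, PendantEntry] = field(default_factory=dict)


def _canonical_subtree_label(net: PhyloNetwork, root: str) -> str:
    """Deterministic newick-like serialization used as the placeholder taxon."""
    g = net.graph

    def rec(n: str) -> str:
        succ = list(g.successors(n))
        if not succ:
            return net.leaf_labels[n]
        return "(" + ",".join(sorted(rec(c) for c in succ)) + ")"

    return rec(root)


def collapse_pendant_subtrees(net: PhyloNetwork) -> tuple[PhyloNetwork, PendantRegistry]:
    """Replace every maximal reticulation-free clade by a placeholder leaf.

    The placeholder's taxon is the canonical serialization of the detached
    subtree, so re-expansion is exact.  A network containing no reticulate
    node at all is returned unchanged (collapsing the whole tree would leave
    a parentless placeholder).
    """
    g = net.graph
    registry = PendantRegistry()

    clean: dict[str, bool] = {}
    for n in reversed(list(nx.topological_sort(g))):
        clean[n] = g.in_degree(n) <= 1 and all(clean[c] for c in g.successors(n))
    if clean[net.root]:
        return net, registry  # pure tree: reduction passes it through

    pendant_roots = [
        n
        for n in g
        if clean[n] and all(not clean[p] for p in g.predecessors(n))
    ]
    pendant_roots.sort()

    new_edges = set(net.edges)
    new_labels = dict(net.leaf_labels)
    counter = 0
    for rt in pendant_roots:
        parent = next(iter(g.predecessors(rt)))  # exists: rt is not the root
        clade = {rt} | nx.descendants(g, rt)
        sub_edges = {(u, v) for u, v in net.edges if u in clade}
        sub_labels = {n: t for n, t in net.leaf_labels.items() if n in clade}
        subtree = build_network(sub_edges, sub_labels, strict=True,
                                root=rt if not sub_edges else None)
        counter += 1
        placeholder = f"pend{counter}"
        while placeholder in g or placeholder in new_labels:
            counter += 1
            placeholder = f"pend{counter}"
        label = _canonical_subtree_label(net, rt)
        new_edges -= sub_edges
        new_edges.discard((parent, rt))
        new_edges.add((parent, placeholder))
        for n in clade:
            new_labels.pop(n, None)
        new_labels[placeholder] = label
        registry.entries[placeholder] = PendantEntry(
            subtree=subtree, subtree_root=rt, attach_parent=parent
        )
    collapsed = build_network(new_edges, new_labels, strict=False)
    return collapsed, registry


def expand_pendant_subtrees(net: PhyloNetwork, registry: PendantRegistry) -> PhyloNetwork:
    """Inverse of :func:`collapse_pendant_subtrees` (placeholders still present
    in ``net`` are replaced; placeholders deleted by reduction are dropped)."""
    edges = set(net.edges)
    labels = dict(net.leaf_labels)
    for placeholder, entry in registry.entries.items():
        if placeholder not in net.nodes:
            continue
        parents = [u for u, v in edges if v == placeholder]
        edges = {(u, v) for u, v in edges if v != placeholder}
        labels.pop(placeholder, None)
        edges |= entry.subtree.edges
        labels.update(entry.subtree.leaf_labels)
        for p in parents:
            edges.add((p, entry.subtree_root))
    root = net.root if not edges else None
    return build_network(edges, labels, strict=net.strict, root=root)


# ---------------------------------------------------------------------------
# convergent-path removal and unary suppression
# ---------------------------------------------------------------------------


def remove_convergent_paths(net: PhyloNetwork, conv: ConvergentSet) -> PhyloNetwork:
    """Delete the paths from a convergent set down to the parents of its
    leaves, rewiring boundary edges onto those parents.

    Every node lying on a path from a member of ``conv`` to a parent of a
    leaf labeled in the leaf set is deleted (members included, the leaf
    parents themselves excluded).  Each surviving edge (p, v) into the deleted
    region is replaced by edges from p to every surviving leaf parent.
    """
    g = net.graph
    target_leaves = {n for n, t in net.leaf_labels.items() if t in conv.leaf_set}
    if not target_leaves:
        raise ReductionError("convergent set's leaf set is absent from the network")
    q_nodes: set[str] = set()
    for leaf in target_leaves:
        q_nodes |= set(g.predecessors(leaf))

    reach_from_u: set[str] = set(conv.members)
    for u in conv.members:
        reach_from_u |= nx.descendants(g, u)
    reach_to_q: set[str] = set()
    for q in q_nodes:
        reach_to_q |= nx.ancestors(g, q)
    removed = ((reach_from_u & reach_to_q) | set(conv.members)) - q_nodes

    edges = set(net.edges)
    boundary_parents = {u for u, v in edges if u not in removed and v in removed}
    edges = {(u, v) for u, v in edges if u not in removed and v not in removed}
    for p in sorted(boundary_parents):
        for q in sorted(q_nodes):
            if p != q:
                edges.add((p, q))

    labels = {n: t for n, t in net.leaf_labels.items() if n not in removed}
    surviving = {u for e in edges for u in e}
    indeg0 = surviving - {v for _, v in edges}
    if len(indeg0) != 1:
        raise ReductionError(
            f"removal leaves {len(indeg0)} indegree-0 nodes: {sorted(indeg0)}"
        )
    result = build_network(edges, labels, strict=False)
    reachable = {result.root} | nx.descendants(result.graph, result.root)
    lost = [n for n in result.leaves if n not in reachable]
    if lost:
        raise ReductionError(f"removal disconnected leaves {sorted(lost)} from the root")
    missing = set(net.taxa) - set(result.taxa)
    if missing:
        raise ReductionError(f"removal deleted taxa {sorted(missing)}")
    return result


def suppress_unary_nodes(net: PhyloNetwork) -> PhyloNetwork:
    """Repeatedly splice out nodes with indegree 1 and outdegree 1.

    Parallel edges created by splicing are merged.  A root left with a single
    child (indegree 0, outdegree 1) is also removed, its child becoming the
    new root.
    """
    g = nx.DiGraph(net.graph.edges)
    g.add_nodes_from(net.graph.nodes)
    changed = True
    while changed:
        changed = False
        for w in sorted(g.nodes):
            if g.in_degree(w) == 1 and g.out_degree(w) == 1:
                u = next(iter(g.predecessors(w)))
                v = next(iter(g.successors(w)))
                g.remove_node(w)
                g.add_edge(u, v)  # merged if already present
                changed = True
        roots = [n for n in g if g.in_degree(n) == 0]
        if len(roots) == 1 and g.out_degree(roots[0]) == 1 and g.number_of_nodes() > 1:
            g.remove_node(roots[0])
            changed = True
    labels = {n: t for n, t in net.leaf_labels.items() if n in g}
    if g.number_of_edges() == 0 and g.number_of_nodes() == 1:
        return build_network([], labels, strict=False, root=next(iter(g.nodes)))
    return build_network(g.edges, labels, strict=False)


# ---------------------------------------------------------------------------
# full / partial reduction pipeline
# ---------------------------------------------------------------------------


@dataclass
class ReductionTrace:
    """Ordered record of the reduction events applied to a network."""

    mode: str
    events: list[tuple] = field(default_factory=list)  # ("collapse",) etc.


def _sets_for_mode(net: PhyloNetwork, mode: str) -> list[ConvergentSet]:
    sets = maximal_convergent_sets(net) if mode == "full" else superconvergent_sets(net)
    # never delete the root: its removal would disconnect the network
    return [s for s in sets if net.root not in s.members]


def reduce_network(net: PhyloNetwork, mode: str = "full") -> tuple[PhyloNetwork, ReductionTrace]:
    """Compute the (partly) reduced version of a network.

    ``mode="full"`` iterates over maximal convergent sets (reduced version);
    ``mode="partial"`` over superconvergent sets (partly reduced version).
    The output is strict-valid, preserves the taxon set, and is a fixpoint of
    the same reduction (idempotence up to isomorphism).
    """
    if mode not in ("full", "partial"):
        raise ValueError(f"mode must be 'full' or 'partial', got {mode!r}")
    trace = ReductionTrace(mode=mode)

    collapsed, registry = collapse_pendant_subtrees(net)
    if not registry.entries and collapsed is net:
        # reticulation-free network: unchanged by construction
        return net, trace
    trace.events.append(("collapse", tuple(sorted(registry.entries))))

    current = collapsed
    while True:
        sets = _sets_for_mode(current, mode)
        if not sets:
            break
        conv = sets[0]
        current = remove_convergent_paths(current, conv)
        current = suppress_unary_nodes(current)
        trace.events.append(("remove", tuple(sorted(conv.members)), tuple(sorted(conv.leaf_set))))
        trace.events.append(("suppress",))

    expanded = expand_pendant_subtrees(current, registry)
    trace.events.append(("expand",))
    final = build_network(expanded.edges, expanded.leaf_labels, strict=True,
                          root=expanded.root if not expanded.edges else None)
    return final, trace


def replay_trace(net: PhyloNetwork, trace: ReductionTrace) -> PhyloNetwork:
    """Re-apply a recorded trace to its input; reproduces the traced output."""
    current = net
    registry = PendantRegistry()
    for event in trace.events:
        if event[0] == "collapse":
            current, registry = collapse_pendant_subtrees(net)
        elif event[0] == "remove":
            members, leaf_set = event[1], event[2]
            conv = ConvergentSet(
                members=frozenset(members), leaf_set=frozenset(leaf_set), flavor=trace.mode
            )
            current = remove_convergent_paths(current, conv)
        elif event[0] == "suppress":
            current = suppress_unary_nodes(current)
        elif event[0] == "expand":
            current = expand_pendant_subtrees(current, registry)
            current = build_network(
                current.edges, current.leaf_labels, strict=True,
                root=current.root if not current.edges else None,
            )
    return current
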