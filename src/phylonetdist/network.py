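"""Rooted phylogenetic network model.

A rooted phylogenetic network on a taxon set X is a rooted DAG whose leaves
(sinks) are bijectively labeled by X and in which no tree node (indegree <= 1)
has outdegree exactly 1.  Reticulate nodes (indegree >= 2) model hybridization,
horizontal gene transfer and recombination.  Mid-reduction intermediates are
held in a *relaxed* variant that waives only the outdegree-1 condition.

Nodes are opaque strings; names coming from input files are preserved for
reporting but carry no semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .errors import (
    CycleError,
    DuplicateTaxonError,
    MultiEdgeError,
    RootError,
    UnaryTreeNodeError,
    UnknownNodeError,
    UnlabeledLeafError,
)


class PhyloNetwork:
    """A rooted, leaf-labeled DAG.

    Parameters
    ----------
    edges:
        Iterable of ``(parent, child)`` pairs (node ids are strings).
    leaf_labels:
        Mapping from sink nodes to taxon names; must be injective and cover
        every sink.
    strict:
        When True (the default for user-facing networks), reject tree nodes of
        outdegree 1.  Relaxed networks (``strict=False``) arise only as
        intermediate reduction states.
    root:
        Optional explicit root for the degenerate single-node network with no
        edges.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        leaf_labels: Mapping[str, str],
        *,
        strict: bool = True,
        root: str | None = None,
    ) -> None:
        g = nx.DiGraph()
        seen: set[tuple[str, str]] = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if (u, v) in seen:
                raise MultiEdgeError(f"duplicate edge {u!r}->{v!r}")
            seen.add((u, v))
            g.add_edge(u, v)
        if not seen:
            # degenerate one-taxon network: a single labeled isolated node
            if root is None and len(leaf_labels) == 1:
                root = next(iter(leaf_labels))
            if root is None:
                raise RootError("empty edge set and no isolated labeled node supplied")
            g.add_node(str(root))
        self._g = g
        self.leaf_labels: dict[str, str] = {str(k): str(v) for k, v in leaf_labels.items()}
        self.strict = strict
        self.root = self._validate(strict)

    # -- validation -------------------------------------------------------

    def _validate(self, strict: bool) -> str:
        g = self._g
        if not nx.is_directed_acyclic_graph(g):
            raise CycleError("edge relation contains a directed cycle")
        roots = [n for n in g if g.in_degree(n) == 0]
        if len(roots) != 1:
            raise RootError(f"expected exactly one indegree-0 node, found {sorted(roots)}")
        sinks = {n for n in g if g.out_degree(n) == 0}
        for n in sinks:
            if n not in self.leaf_labels:
                raise UnlabeledLeafError(f"sink node {n!r} has no taxon label")
        for n in self.leaf_labels:
            if n not in g:
                raise UnknownNodeError(f"labeled node {n!r} not present in edge set")
            if g.out_degree(n) != 0:
                raise UnlabeledLeafError(f"labeled node {n!r} is not a sink")
        labels = list(self.leaf_labels.values())
        if len(set(labels)) != len(labels):
            dupes = sorted({t for t in labels if labels.count(t) > 1})
            raise DuplicateTaxonError(f"taxon labels used more than once: {dupes}")
        if strict:
            for n in g:
                if g.in_degree(n) <= 1 and g.out_degree(n) == 1:
                    raise UnaryTreeNodeError(
                        f"tree node {n!r} has outdegree 1 (indegree {g.in_degree(n)})"
                    )
        return roots[0]

    # -- basic accessors --------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        """The underlying directed graph (treat as read-only)."""
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._g.edges)

    @property
    def leaves(self) -> set[str]:
        return {n for n in self._g if self._g.out_degree(n) == 0}

    @property
    def taxa(self) -> set[str]:
        return set(self.leaf_labels.values())

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<PhyloNetwork |V|={len(self)} |E|={self._g.number_of_edges()} "
            f"taxa={sorted(self.taxa)}>"
        )

    def children(self, node: str) -> list[str]:
        self._check(node)
        return sorted(self._g.successors(node))

    def parents(self, node: str) -> list[str]:
        self._check(node)
        return sorted(self._g.predecessors(node))

    def indeg(self, node: str) -> int:
        self._check(node)
        return self._g.in_degree(node)

    def outdeg(self, node: str) -> int:
        self._check(node)
        return self._g.out_degree(node)

    def _check(self, node: str) -> None:
        if node not in self._g:
            raise UnknownNodeError(f"unknown node {node!r}")

    def node_role(self, node: str) -> frozenset[str]:
        """Role flags for a node: subset of {root, tree, reticulate, leaf}.

        A node is reticulate iff indegree >= 2, a tree node iff indegree <= 1,
        a leaf iff outdegree 0 and the root iff indegree 0.  Flags combine
        (the root is also a tree node; a leaf is usually a tree node too).
        """
        self._check(node)
        flags = set()
        ind = self._g.in_degree(node)
        if ind == 0:
            flags.add("root")
        flags.add("reticulate" if ind >= 2 else "tree")
        if self._g.out_degree(node) == 0:
            flags.add("leaf")
        return frozenset(flags)

    def topological_order(self) -> list[str]:
        """A deterministic topological order (lexicographic tie-break)."""
        return list(nx.lexicographical_topological_sort(self._g))

    def copy(self, *, strict: bool | None = None) -> "PhyloNetwork":
        return PhyloNetwork(
            self.edges,
            dict(self.leaf_labels),
            strict=self.strict if strict is None else strict,
            root=self.root if not self.edges else None,
        )

    def relabeled(self, mapping: Mapping[str, str]) -> "PhyloNetwork":
        """Return a copy with node ids renamed through ``mapping`` (total map)."""
        edges = {(mapping[u], mapping[v]) for u, v in self.edges}
        labels = {mapping[n]: t for n, t in self.leaf_labels.items()}
        root = mapping[self.root] if not edges else None
        return PhyloNetwork(edges, labels, strict=self.strict, root=root)


@dataclass(frozen=True)
class HeightDepthTable:
    """Longest-path stratification of a network.

    ``height[v]`` is the length of a longest directed path from ``v`` to a
    leaf (0 exactly on leaves); ``depth[v]`` is the length of a longest path
    from the root to ``v`` (0 exactly on the root).
    """

    height: dict[str, int]
    depth: dict[str, int]


def height_depth(net: PhyloNetwork) -> HeightDepthTable:
    """Compute heights and depths in one reverse-topological and one
    topological sweep."""
    g = net.graph
    order = list(nx.topological_sort(g))
    height: dict[str, int] = {}
    for n in reversed(order):
        succ = list(g.successors(n))
        height[n] = 0 if not succ else 1 + max(height[c] for c in succ)
    depth: dict[str, int] = {}
    for n in order:
        pred = list(g.predecessors(n))
        depth[n] = 0 if not pred else 1 + max(depth[p] for p in pred)
    return HeightDepthTable(height=height, depth=depth)


def build_network(
    edges: Iterable[tuple[str, str]],
    leaf_labels: Mapping[str, str],
    strict: bool = True,
    root: str | None = None,
) -> PhyloNetwork:
    """Validate and construct a :class:`PhyloNetwork` (see class docs)."""
    return PhyloNetwork(edges, leaf_labels, strict=strict, root=root)
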