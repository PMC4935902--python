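"""Seeded random rooted phylogenetic networks for tests and experiments.

Networks are grown as a random rooted binary tree on the requested taxa,
after which each reticulation is added by subdividing two tree edges and
joining the subdivision points (keeping the DAG acyclic and every node
degree-legal).  In ``partly_reduced`` mode the partial reduction is applied
before returning, so the output is a fixpoint of superconvergent-set removal
— the space on which the d_e distance is a metric.

All randomness flows through a single ``random.Random(seed)`` stream per
call; identical configurations reproduce identical edge lists.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx

from .errors import PhyloNetworkError
from .network import PhyloNetwork, build_network
from .reduction import reduce_network


class InfeasibleConfigError(PhyloNetworkError):
    """The requested network could not be built within bounded retries."""


@dataclass(frozen=True)
class GeneratorConfig:
    n_leaves: int
    n_reticulations: int = 0
    seed: int = 0
    mode: str = "any"  # "any" | "partly_reduced"


def _random_binary_tree(rng: random.Random, taxa: list[str]) -> tuple[set, dict]:
    """Random rooted binary tree: repeatedly join two random roots."""
    edges: set[tuple[str, str]] = set()
    labels = {f"t{i}": taxon for i, taxon in enumerate(taxa)}
    roots = sorted(labels)
    counter = 0
    while len(roots) > 1:
        i, j = rng.sample(range(len(roots)), 2)
        a, b = roots[i], roots[j]
        counter += 1
        new = f"i{counter}"
        edges.add((new, a))
        edges.add((new, b))
        roots = [r for r in roots if r not in (a, b)] + [new]
    return edges, labels


def _add_reticulation(rng: random.Random, g: nx.DiGraph, tag: int) -> bool:
    """Subdivide two edges and join them; returns False if no acyclic choice
    was found in this attempt."""
    edges = sorted(g.edges)
    (a, b) = rng.choice(edges)
    (c, d) = rng.choice(edges)
    if (a, b) == (c, d):
        return False
    # new edge s -> r with s on (a,b) and r on (c,d); acyclic unless d reaches a
    if d == a or nx.has_path(g, d, a):
        return False
    s, r = f"s{tag}", f"r{tag}"
    g.remove_edge(a, b)
    g.remove_edge(c, d)
    g.add_edge(a, s)
    g.add_edge(s, b)
    g.add_edge(c, r)
    g.add_edge(r, d)
    g.add_edge(s, r)
    return True


def random_network(cfg: GeneratorConfig) -> PhyloNetwork:
    """Generate a seeded, reproducible random network (see module docs)."""
    if cfg.n_leaves < 1:
        raise InfeasibleConfigError("need at least one leaf")
    if cfg.mode not in ("any", "partly_reduced"):
        raise ValueError(f"unknown mode {cfg.mode!r}")
    rng = random.Random(cfg.seed)
    taxa = [f"L{i + 1}" for i in range(cfg.n_leaves)]
    if cfg.n_leaves == 1 and cfg.n_reticulations == 0:
        return build_network([], {"t0": taxa[0]}, root="t0")
    if cfg.n_leaves < 2 and cfg.n_reticulations > 0:
        raise InfeasibleConfigError("reticulations need at least two leaves")
    edges, labels = _random_binary_tree(rng, taxa)
    g = nx.DiGraph(edges)
    added = 0
    attempts = 0
    max_attempts = 50 * max(1, cfg.n_reticulations)
    while added < cfg.n_reticulations:
        attempts += 1
        if attempts > max_attempts:
            raise InfeasibleConfigError(
                f"could not place {cfg.n_reticulations} reticulations "
                f"on a {cfg.n_leaves}-leaf tree after {attempts} attempts"
            )
        if _add_reticulation(rng, g, added + 1):
            added += 1
    net = build_network(g.edges, labels, strict=True)
    if cfg.mode == "partly_reduced":
        net, _ = reduce_network(net, "partial")
    return net


# ---------------------------------------------------------------------------
# perturbations (nonzero-distance partners for metric-axiom tests)
# ---------------------------------------------------------------------------


def perturb_network(net: PhyloNetwork, kind: str, seed: int = 0) -> PhyloNetwork:
    """Return a strict-valid network on the same taxa, modified by ``kind``:

    ``swap-labels`` exchanges the taxa of two leaves; ``regraft-leaf`` moves
    a leaf onto a random other edge; ``add-reticulation`` subdivides two
    edges and joins them.  The result is usually, but not provably, not
    isomorphic to the input.
    """
    rng = random.Random(seed)
    if kind == "swap-labels":
        leaves = sorted(net.leaf_labels)
        if len(leaves) < 2:
            raise InfeasibleConfigError("need two leaves to swap labels")
        a, b = rng.sample(leaves, 2)
        labels = dict(net.leaf_labels)
        labels[a], labels[b] = labels[b], labels[a]
        return build_network(net.edges, labels,
                             root=net.root if not net.edges else None)
    if kind == "add-reticulation":
        g = nx.DiGraph(net.edges)
        for attempt in range(200):
            g2 = g.copy()
            if _add_reticulation(rng, g2, 9000 + attempt):
                return build_network(g2.edges, dict(net.leaf_labels))
        raise InfeasibleConfigError("no acyclic reticulation placement found")
    if kind == "regraft-leaf":
        for _ in range(200):
            g = nx.DiGraph(net.edges)
            leaves = sorted(net.leaf_labels)
            leaf = rng.choice(leaves)
            parents = list(g.predecessors(leaf))
            if len(parents) != 1:
                continue
            p = parents[0]
            g.remove_edge(p, leaf)
            candidates = [e for e in sorted(g.edges) if leaf not in e and p not in e]
            if not candidates:
                continue
            a, b = rng.choice(candidates)
            new = "rg0"
            while new in g:
                new += "_"
            g.remove_edge(a, b)
            g.add_edge(a, new)
            g.add_edge(new, b)
            g.add_edge(new, leaf)
            # splice out p if left unary
            if g.in_degree(p) == 1 and g.out_degree(p) == 1:
                u = next(iter(g.predecessors(p)))
                v = next(iter(g.successors(p)))
                g.remove_node(p)
                g.add_edge(u, v)
            try:
                return build_network(g.edges, dict(net.leaf_labels))
            except PhyloNetworkError:
                continue
        raise InfeasibleConfigError("no feasible leaf regraft found")
    raise ValueError(f"unknown perturbation kind {kind!r}")
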