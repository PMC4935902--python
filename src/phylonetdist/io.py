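"""Reading and writing rooted phylogenetic networks.

Two plain-text formats are supported:

* **eNewick** (``.enwk``) in the Cardona-style dialect: a reticulate node is
  written once per parent under a shared ``#H<k>`` tag, and its children are
  listed at exactly one of those occurrences.  Hybrid leaves are written
  ``taxon#H<k>``.
* **edge list** (``.nel``): tab-separated ``parent<TAB>child`` records plus
  trailing ``#label<TAB>node<TAB>taxon`` records for the leaf labeling.
  Lines starting with ``#`` (other than ``#label``) are comments.

Writers are deterministic: children are serialized in lexicographic order of
their canonical subtree strings, edge-list records are sorted, and reticulate
tags are numbered in first-encounter order of that canonical traversal.
"""

from __future__ import annotations

import re
from pathlib import Path

from .errors import FormatError
from .network import PhyloNetwork, build_network

_LABEL_RE = re.compile(r"[^(),;#\s]+")
_NEEDS_QUOTE_RE = re.compile(r"[(),;#\s']")


def _quote_label(label: str) -> str:
    """Quote a label for newick output when it contains metacharacters."""
    if _NEEDS_QUOTE_RE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# eNewick
# ---------------------------------------------------------------------------

def parse_enewick(text: str, *, strict: bool = True) -> PhyloNetwork:
    """Parse a single rooted eNewick statement into a network.

    All occurrences of one ``#H`` tag are merged into a single node; children
    may be given at only one occurrence.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise FormatError("eNewick statement must end with ';'")
    body = text[:-1].strip()
    if not body:
        raise FormatError("empty eNewick statement")

    pos = 0

    def parse_node() -> dict:
        nonlocal pos
        occ: dict = {"children": [], "name": None, "tag": None}
        if pos < len(body) and body[pos] == "(":
            pos += 1
            while True:
                occ["children"].append(parse_node())
                if pos >= len(body):
                    raise FormatError("unbalanced parentheses")
                if body[pos] == ",":
                    pos += 1
                    continue
                if body[pos] == ")":
                    pos += 1
                    break
                raise FormatError(f"unexpected character {body[pos]!r} at {pos}")
        if pos < len(body) and body[pos] == "'":
            # quoted label: '' is an escaped quote
            pos += 1
            chunks: list[str] = []
            while True:
                end = body.find("'", pos)
                if end == -1:
                    raise FormatError("unterminated quoted label")
                chunks.append(body[pos:end])
                pos = end + 1
                if pos < len(body) and body[pos] == "'":
                    chunks.append("'")
                    pos += 1
                    continue
                break
            occ["name"] = "".join(chunks)
        else:
            m = _LABEL_RE.match(body, pos)
            if m:
                occ["name"] = m.group(0)
                pos = m.end()
        if pos < len(body) and body[pos] == "#":
            pos += 1
            m = _LABEL_RE.match(body, pos)
            if not m:
                raise FormatError("'#' must be followed by a tag name")
            occ["tag"] = m.group(0)
            pos = m.end()
        if not occ["children"] and occ["name"] is None and occ["tag"] is None:
            raise FormatError(f"empty node occurrence at position {pos}")
        return occ

    root_occ = parse_node()
    if pos != len(body):
        raise FormatError(f"trailing characters after position {pos}: {body[pos:]!r}")

    edges: list[tuple[str, str]] = []
    edge_set: set[tuple[str, str]] = set()
    labels: dict[str, str] = {}
    tag_nodes: dict[str, str] = {}
    tag_children_seen: set[str] = set()
    tag_names: dict[str, str] = {}
    name_of: dict[str, str] = {}
    used_ids: set[str] = set()
    counter = [0]

    def fresh_id(hint: str | None) -> str:
        if hint and hint not in used_ids:
            used_ids.add(hint)
            return hint
        while True:
            counter[0] += 1
            cand = f"n{counter[0]}"
            if cand not in used_ids:
                used_ids.add(cand)
                return cand

    def realize(occ: dict) -> str:
        tag = occ["tag"]
        if tag is not None:
            if tag not in tag_nodes:
                tag_nodes[tag] = fresh_id(occ["name"] or tag)
            node = tag_nodes[tag]
            if occ["name"]:
                prev = tag_names.get(tag)
                if prev is not None and prev != occ["name"]:
                    raise FormatError(
                        f"tag #{tag} carries conflicting names {prev!r} and {occ['name']!r}"
                    )
                tag_names[tag] = occ["name"]
                name_of[node] = occ["name"]
            if occ["children"]:
                if tag in tag_children_seen:
                    raise FormatError(f"tag #{tag} lists children at more than one occurrence")
                tag_children_seen.add(tag)
        else:
            node = fresh_id(occ["name"])
            if occ["name"]:
                name_of[node] = occ["name"]
        for child_occ in occ["children"]:
            child = realize(child_occ)
            if (node, child) in edge_set:
                raise FormatError(f"duplicate edge {node!r}->{child!r} in eNewick input")
            edge_set.add((node, child))
            edges.append((node, child))
        return node

    root = realize(root_occ)

    # sinks must carry a taxon name: the occurrence name of an untagged leaf,
    # or the (unique) name attached to a tagged hybrid leaf
    parents_side = {u for u, _ in edges}
    all_nodes = {root} | parents_side | {v for _, v in edges}
    sinks = all_nodes - parents_side
    for s in sinks:
        if s in name_of:
            labels[s] = name_of[s]
    # sinks missing from `labels` fail validation as unlabeled leaves;
    # repeated taxon names fail as duplicate taxa
    return build_network(edges, labels, strict=strict, root=root if not edges else None)


def write_enewick(net: PhyloNetwork) -> str:
    """Serialize a network to a deterministic eNewick string."""
    g = net.graph

    canon: dict[str, str] = {}

    def canon_of(n: str) -> str:
        if n in canon:
            return canon[n]
        succ = list(g.successors(n))
        if not succ:
            s = _quote_label(net.leaf_labels[n])
        else:
            s = "(" + ",".join(sorted(canon_of(c) for c in succ)) + ")"
        canon[n] = s
        return s

    canon_of(net.root)

    tags: dict[str, int] = {}
    next_tag = [0]
    written: set[str] = set()

    def emit(n: str) -> str:
        retic = g.in_degree(n) >= 2
        if retic and n not in tags:
            next_tag[0] += 1
            tags[n] = next_tag[0]
        if retic and n in written:
            return f"#H{tags[n]}"
        written.add(n)
        succ = sorted(g.successors(n), key=canon_of)
        if not succ:
            core = _quote_label(net.leaf_labels[n])
        else:
            core = "(" + ",".join(emit(c) for c in succ) + ")"
        if retic:
            core += f"#H{tags[n]}"
        return core

    return emit(net.root) + ";"


# ---------------------------------------------------------------------------
# edge list (.nel)
# ---------------------------------------------------------------------------

def parse_edgelist(text: str, *, strict: bool = True) -> PhyloNetwork:
    """Parse a tab-separated edge-list document into a network."""
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    labels: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#label\t"):
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"line {lineno}: malformed #label record: {line!r}")
            _, node, taxon = parts
            labels[node] = taxon
            continue
        if line.startswith("#"):
            continue  # comment
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise FormatError(f"line {lineno}: malformed edge record: {line!r}")
        pair = (parts[0], parts[1])
        if pair in seen:
            raise FormatError(f"line {lineno}: duplicate edge record {line!r}")
        seen.add(pair)
        edges.append(pair)
    if not edges and not labels:
        raise FormatError("empty edge-list document (no root)")
    if not edges:
        if len(labels) != 1:
            raise FormatError("edge-less document must contain exactly one #label record")
        node = next(iter(labels))
        return build_network([], labels, strict=strict, root=node)
    nodes = {u for e in edges for u in e}
    for node in labels:
        if node not in nodes:
            raise FormatError(f"#label record references unknown node {node!r}")
    return build_network(edges, labels, strict=strict)


def write_edgelist(net: PhyloNetwork) -> str:
    """Serialize a network to a deterministic edge-list document."""
    lines = ["# phylonetdist rooted-network edge list (parent<TAB>child)"]
    for u, v in sorted(net.edges):
        lines.append(f"{u}\t{v}")
    for node in sorted(net.leaf_labels):
        lines.append(f"#label\t{node}\t{net.leaf_labels[node]}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# file-level helpers
# ---------------------------------------------------------------------------

def read_network(path: str | Path, fmt: str = "auto", *, strict: bool = True) -> PhyloNetwork:
    """Read a network from a file; format from extension unless given."""
    path = Path(path)
    if fmt == "auto":
        fmt = "nel" if path.suffix == ".nel" else "enewick"
    text = path.read_text(encoding="utf-8")
    if fmt == "nel":
        return parse_edgelist(text, strict=strict)
    if fmt == "enewick":
        return parse_enewick(text, strict=strict)
    raise FormatError(f"unknown format {fmt!r}")


def write_network(net: PhyloNetwork, path: str | Path, fmt: str = "auto") -> None:
    path = Path(path)
    if fmt == "auto":
        fmt = "nel" if path.suffix == ".nel" else "enewick"
    if fmt == "nel":
        path.write_text(write_edgelist(net), encoding="utf-8")
    elif fmt == "enewick":
        path.write_text(write_enewick(net) + "\n", encoding="utf-8")
    else:
        raise FormatError(f"unknown format {fmt!r}")
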