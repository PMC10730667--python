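"""Polytomy-capable trees: Newick output, unrooted splits, re-rooting.

Trees produced by the joining engines are conceptually unrooted; the final
join node doubles as the serialization root.  All topology comparisons go
through :func:`splits`, never through the rooted shape.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator

from .errors import InputError

__all__ = [
    "TreeNode",
    "PhyloTree",
    "to_newick",
    "from_newick",
    "splits",
    "same_unrooted_topology",
    "root_at_longest_branch",
]

_NEWICK_SPECIALS = set("()[]{}:;,='\" \t\n")


@dataclass
class TreeNode:
    """A node of a rooted tree; leaves carry a name, internals carry children.

    ``branch_length`` is the length of the branch to the parent; it is
    ``None`` for the serialization root.
    """

    name: str = ""
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        """Pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]


@dataclass
class PhyloTree:
    root: TreeNode

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.name for n in self.root.leaves())

    def nodes(self) -> Iterator[TreeNode]:
        return self.root.walk()

    def total_branch_length(self) -> float:
        return sum(
            n.branch_length for n in self.nodes() if n.branch_length is not None
        )


def _quote_label(name: str) -> str:
    if any(c in _NEWICK_SPECIALS for c in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _fmt_node(node: TreeNode, precision: int) -> str:
    if node.is_leaf:
        body = _quote_label(node.name)
    else:
        body = "(" + ",".join(_fmt_node(c, precision) for c in node.children) + ")"
    if node.branch_length is not None:
        body += ":" + format(node.branch_length, f".{precision}g")
    return body


def to_newick(tree: PhyloTree, precision: int = 6) -> str:
    """Serialize to standard Newick; children in creation order."""
    return _fmt_node(tree.root, precision) + ";"


def from_newick(text: str) -> PhyloTree:
    """Parse a Newick string (round-trip support; minimal, strict grammar)."""
    s = text.strip()
    if not s.endswith(";"):
        raise InputError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(out)
                out.append(s[pos])
                pos += 1
            raise InputError("unterminated quoted label")
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise InputError("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise InputError(f"unexpected character {s[pos]!r}")
        node.name = parse_label()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            node.branch_length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise InputError(f"trailing characters after tree: {s[pos:]!r}")
    return PhyloTree(root)


def _leafsets(tree: PhyloTree) -> dict[int, frozenset[str]]:
    """Leaf set of the subtree under each node, keyed by id(node)."""
    out: dict[int, frozenset[str]] = {}

    def rec(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            res = frozenset([node.name])
        else:
            res = frozenset(itertools.chain.from_iterable(rec(c) for c in node.children))
        out[id(node)] = res
        return res

    rec(tree.root)
    return out


def splits(tree: PhyloTree) -> frozenset[frozenset[str]]:
    """Non-trivial bipartitions induced by internal edges of the unrooted tree.

    Each split is represented canonically by the side *not* containing the
    lexicographically smallest leaf label.  Degree-2 serialization roots are
    suppressed automatically by the canonicalization.
    """
    all_leaves = tree.leaf_labels
    anchor = min(all_leaves)
    leafsets = _leafsets(tree)
    n = len(all_leaves)
    result = set()
    for node in tree.nodes():
        if node is tree.root:
            continue
        side = leafsets[id(node)]
        if len(side) < 2 or len(side) > n - 2:
            continue
        if anchor in side:
            side = all_leaves - side
        result.add(side)
    return frozenset(result)


def same_unrooted_topology(t1: PhyloTree, t2: PhyloTree) -> bool:
    """True iff the two trees induce equal split sets on equal leaf sets."""
    if t1.leaf_labels != t2.leaf_labels:
        raise InputError("trees have different leaf sets")
    return splits(t1) == splits(t2)


def _unrooted_edges(tree: PhyloTree):
    """Adjacency of the unrooted tree; a degree-2 root is spliced out."""
    adj: dict[int, list[tuple[int, float]]] = {}
    nodes: dict[int, TreeNode] = {}

    def add_edge(a: TreeNode, b: TreeNode, length: float) -> None:
        adj.setdefault(id(a), []).append((id(b), length))
        adj.setdefault(id(b), []).append((id(a), length))

    for node in tree.nodes():
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        for child in node.children:
            add_edge(node, child, child.branch_length or 0.0)

    root = tree.root
    if len(root.children) == 2:
        a, b = root.children
        la = a.branch_length or 0.0
        lb = b.branch_length or 0.0
        adj[id(a)] = [(x, l) for x, l in adj[id(a)] if x != id(root)]
        adj[id(b)] = [(x, l) for x, l in adj[id(b)] if x != id(root)]
        del adj[id(root)], nodes[id(root)]
        add_edge(a, b, la + lb)
    return nodes, adj


def root_at_longest_branch(tree: PhyloTree) -> PhyloTree:
    """Re-root a copy of the tree at the midpoint of its longest branch.

    Ties go to the branch whose subtree contains the lexicographically
    smallest leaf labels.  The unrooted split set and the total branch
    length are preserved.
    """
    if len(tree.root.leaves()) < 2:
        raise InputError("need at least 2 leaves to re-root")
    nodes, adj = _unrooted_edges(tree)

    # Leaf set on the `b` side of each directed edge (a, b).
    side_cache: dict[tuple[int, int], frozenset[str]] = {}

    def side_leaves(a: int, b: int) -> frozenset[str]:
        key = (a, b)
        if key not in side_cache:
            if not nodes[b].children and nodes[b].name:
                side_cache[key] = frozenset([nodes[b].name])
            else:
                acc: set[str] = set()
                if nodes[b].name:
                    acc.add(nodes[b].name)
                for c, _ in adj[b]:
                    if c != a:
                        acc |= side_leaves(b, c)
                side_cache[key] = frozenset(acc)
        return side_cache[key]

    best = None
    for a in adj:
        for b, length in adj[a]:
            if a >= b:  # one direction per edge
                continue
            for x, y in ((a, b), (b, a)):
                key = (length, tuple(sorted(side_leaves(x, y))))
                if best is None or (-key[0], key[1]) < (-best[0][0], best[0][1]):
                    best = (key, x, y)
    assert best is not None
    (length, _), parent_side, child_side = best

    def build(node_id: int, came_from: int, blen: float) -> TreeNode:
        src = nodes[node_id]
        out = TreeNode(name=src.name if src.is_leaf else "", branch_length=blen)
        for nbr, l in adj[node_id]:
            if nbr != came_from:
                out.children.append(build(nbr, node_id, l))
        return out

    root = TreeNode()
    root.children.append(build(child_side, parent_side, length / 2.0))
    root.children.append(build(parent_side, child_side, length / 2.0))
    return PhyloTree(root)
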