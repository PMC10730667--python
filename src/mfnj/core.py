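"""Agglomeration engines: classic neighbor-joining (NJ), the multifurcating
variant (MFNJ) that joins every group of tied nearest OTUs at once, and an
exhaustive tie-break enumerator for NJ.

Selection uses the Studier–Keppler criterion

    S_ij = (N - 2) * D_ij - R_i - R_j,      R_i = sum_k D_ik,

minimized over unordered pairs of active OTUs.  Where classic NJ must pick
one minimal pair, MFNJ collects *all* pairs attaining the minimum (within a
configurable tolerance), merges them into disjoint groups by transitive
closure, and joins each whole group into one new internal node in the same
iteration.  The group generalizations of the pairwise distance-update and
branch-length formulas are:

    node-to-OTU      D_uk = R_Ik/|I| - R_II/(|I|(|I|-1))
    node-to-node     D_uv = R_IJ/(|I||J|) - R_II/(|I|(|I|-1)) - R_JJ/(|J|(|J|-1))
    non-final join   L_iu = R_II/(|I|(|I|-1)) + R_iC/(N-|I|) - R_IC/(|I|(N-|I|))
    final join       L_iu = R_iI/(|I|-2) - R_II/((|I|-1)(|I|-2))

where C is the complement of the join set I among the N active OTUs and the
R terms are the obvious within/cross distance sums.  Every join satisfies
the star-tree conservation law  sum_i L_iu = R_II/(|I|-1), which is asserted
at run time.  With no ties the MFNJ trajectory is identical to NJ.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import InputError
from .matrix_io import DistanceMatrix
from .tree_model import PhyloTree, TreeNode, splits

__all__ = [
    "AlgoConfig",
    "SState",
    "TieGroup",
    "GroupJoin",
    "JoinEvent",
    "JoinLog",
    "EnumerationResult",
    "compute_s_state",
    "find_tied_min_pairs",
    "group_tied_pairs",
    "dist_node_to_otu",
    "dist_node_to_node",
    "branch_lengths_nonfinal",
    "branch_lengths_final",
    "run_nj",
    "run_mfnj",
    "enumerate_nj_trees",
]

#: Relative tolerance for the branch-length conservation assertion.
_CONSERVATION_RTOL = 1e-9

TieGroup = tuple[int, ...]  # sorted active-matrix indices, size >= 2


@dataclass(frozen=True)
class AlgoConfig:
    """Run-time knobs for the joining engines.

    ``tie_rtol``/``tie_atol`` control when two S values count as equal;
    the algorithm's derivation assumes exact arithmetic, which floating
    point cannot deliver.  ``negative_branch_policy`` is applied to the
    finished tree only, so the agglomeration trajectory is unaffected.
    """

    tie_rtol: float = 1e-9
    tie_atol: float = 1e-12
    negative_branch_policy: str = "keep"  # keep | clamp_to_zero
    nj_tie_break: str = "first_scan"  # first_scan | enumerate
    enum_cap: int = 64
    precision: int = 6

    def __post_init__(self) -> None:
        if self.tie_rtol < 0 or self.tie_atol < 0:
            raise ValueError("tie tolerances must be non-negative")
        if self.negative_branch_policy not in ("keep", "clamp_to_zero"):
            raise ValueError(f"unknown policy {self.negative_branch_policy!r}")
        if self.nj_tie_break not in ("first_scan", "enumerate"):
            raise ValueError(f"unknown tie break {self.nj_tie_break!r}")
        if self.enum_cap < 1:
            raise ValueError("enum_cap must be >= 1")


@dataclass(frozen=True)
class SState:
    """Selection state for one iteration: row sums, S matrix, its minimum."""

    row_sums: np.ndarray
    s_values: np.ndarray
    s_min: float


@dataclass(frozen=True)
class GroupJoin:
    """One group joined into one new internal node."""

    members: tuple[str, ...]
    node_id: str
    lengths: dict[str, float]


@dataclass(frozen=True)
class JoinEvent:
    iteration: int  # 1-based loop pass
    groups: tuple[GroupJoin, ...]
    n_before: int
    n_after: int


class JoinLog(list):
    """Sequence of :class:`JoinEvent`, serializable as JSON lines."""

    def to_json_lines(self) -> str:
        out = []
        for ev in self:
            out.append(
                json.dumps(
                    {
                        "iteration": ev.iteration,
                        "groups": [
                            {
                                "members": list(g.members),
                                "node": g.node_id,
                                "lengths": {k: g.lengths[k] for k in g.members},
                            }
                            for g in ev.groups
                        ],
                        "n_before": ev.n_before,
                        "n_after": ev.n_after,
                    }
                )
            )
        return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# Selection criterion


def _s_state(D: np.ndarray) -> SState:
    n = D.shape[0]
    R = D.sum(axis=1)
    S = (n - 2) * D - R[:, None] - R[None, :]
    iu = np.triu_indices(n, k=1)
    s_min = float(S[iu].min())
    return SState(row_sums=R, s_values=S, s_min=s_min)


def compute_s_state(dm: DistanceMatrix) -> SState:
    """Row sums R_i and pair criterion S_ij for an active matrix (N >= 3)."""
    if len(dm) < 3:
        raise InputError("S criterion needs at least 3 active OTUs")
    return _s_state(dm.values)


def _tied_pairs(state: SState, cfg: AlgoConfig) -> list[tuple[int, int]]:
    thresh = state.s_min + cfg.tie_atol + cfg.tie_rtol * abs(state.s_min)
    n = state.s_values.shape[0]
    return [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if state.s_values[i, j] <= thresh
    ]


def find_tied_min_pairs(state: SState, cfg: AlgoConfig) -> set[tuple[int, int]]:
    """All unordered pairs attaining the minimal S within tolerance."""
    return set(_tied_pairs(state, cfg))


def group_tied_pairs(pairs: Iterable[tuple[int, int]]) -> list[TieGroup]:
    """Merge tied pairs into disjoint join groups by transitive closure.

    Groups are the connected components of the graph whose edges are the
    tied pairs, listed in order of their smallest member.
    """
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = list(pairs)
    if not pairs:
        raise InputError("no tied pairs to group")
    for i, j in pairs:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    comps: dict[int, list[int]] = {}
    for x in parent:
        comps.setdefault(find(x), []).append(x)
    return [tuple(sorted(members)) for _, members in sorted(comps.items())]


# ---------------------------------------------------------------------------
# Distance sums and update formulas (array level)


def _r_within(D: np.ndarray, I: Sequence[int]) -> float:
    idx = np.asarray(I)
    sub = D[np.ix_(idx, idx)]
    return float(sub.sum() / 2.0)


def _r_cross(D: np.ndarray, I: Sequence[int], J: Sequence[int]) -> float:
    return float(D[np.ix_(np.asarray(I), np.asarray(J))].sum())


def _dist_node_to_otu(D: np.ndarray, I: Sequence[int], k: int) -> float:
    p = len(I)
    r_Ik = float(D[np.asarray(I), k].sum())
    return r_Ik / p - _r_within(D, I) / (p * (p - 1))


def _dist_node_to_node(D: np.ndarray, I: Sequence[int], J: Sequence[int]) -> float:
    p, q = len(I), len(J)
    return (
        _r_cross(D, I, J) / (p * q)
        - _r_within(D, I) / (p * (p - 1))
        - _r_within(D, J) / (q * (q - 1))
    )


def _branch_lengths_nonfinal(D: np.ndarray, I: Sequence[int]) -> dict[int, float]:
    n = D.shape[0]
    p = len(I)
    comp = [k for k in range(n) if k not in set(I)]
    r_II = _r_within(D, I)
    r_IC = _r_cross(D, I, comp)
    lengths = {}
    for i in I:
        r_iC = float(D[i, np.asarray(comp)].sum())
        lengths[i] = r_II / (p * (p - 1)) + r_iC / (n - p) - r_IC / (p * (n - p))
    _check_conservation(lengths, r_II, p)
    return lengths


def _branch_lengths_final(D: np.ndarray, I: Sequence[int]) -> dict[int, float]:
    p = len(I)
    r_II = _r_within(D, I)
    idx = np.asarray(I)
    lengths = {}
    for i in I:
        r_iI = float(D[i, idx].sum())  # D[i, i] = 0
        lengths[i] = r_iI / (p - 2) - r_II / ((p - 1) * (p - 2))
    _check_conservation(lengths, r_II, p)
    return lengths


def _check_conservation(lengths: dict[int, float], r_II: float, p: int) -> None:
    # Star-tree conservation law: sum_i L_iu = R_II / (|I| - 1).
    total = sum(lengths.values())
    expect = r_II / (p - 1)
    scale = max(abs(expect), 1.0)
    if abs(total - expect) > _CONSERVATION_RTOL * scale:
        raise AssertionError(
            f"branch-length conservation violated: sum={total!r} expected={expect!r}"
        )


# ---------------------------------------------------------------------------
# Public single-step operations (validated wrappers)


def _as_group(dm: DistanceMatrix, group: Iterable[int]) -> TieGroup:
    members = tuple(sorted(set(int(i) for i in group)))
    if any(i < 0 or i >= len(dm) for i in members):
        raise InputError("group member index out of range")
    if len(members) < 2:
        raise InputError("a join group needs at least 2 members")
    return members


def dist_node_to_otu(dm: DistanceMatrix, group: Iterable[int], k: int) -> float:
    """Distance from the node replacing ``group`` to an outside OTU ``k``."""
    members = _as_group(dm, group)
    if k in members:
        raise InputError("k must not belong to the group")
    return _dist_node_to_otu(dm.values, members, k)


def dist_node_to_node(
    dm: DistanceMatrix, group_i: Iterable[int], group_j: Iterable[int]
) -> float:
    """Distance between two nodes replacing disjoint groups of one iteration."""
    gi = _as_group(dm, group_i)
    gj = _as_group(dm, group_j)
    if set(gi) & set(gj):
        raise InputError("groups must be disjoint")
    return _dist_node_to_node(dm.values, gi, gj)


def branch_lengths_nonfinal(
    dm: DistanceMatrix, group: Iterable[int], n_active: int | None = None
) -> dict[int, float]:
    """Branch lengths from group members to their new node (complement non-empty).

    The complement is taken with respect to all ``n_active`` OTUs of the
    iteration, including members of any sibling group joined at the same time.
    """
    members = _as_group(dm, group)
    n = len(dm) if n_active is None else n_active
    if n != len(dm):
        raise InputError("n_active must equal the active matrix size")
    if n - len(members) < 1:
        raise InputError("empty complement: use branch_lengths_final")
    return _branch_lengths_nonfinal(dm.values, members)


def branch_lengths_final(dm: DistanceMatrix, group: Iterable[int]) -> dict[int, float]:
    """Branch lengths when the group contains every remaining OTU (|I| >= 3)."""
    members = _as_group(dm, group)
    if len(members) != len(dm):
        raise InputError("final join must cover all remaining OTUs")
    if len(members) < 3:
        raise InputError("final formula needs at least 3 members")
    return _branch_lengths_final(dm.values, members)


# ---------------------------------------------------------------------------
# Drivers


def _clamp_tree(root: TreeNode) -> None:
    for node in root.walk():
        if node.branch_length is not None and node.branch_length < 0:
            node.branch_length = 0.0


def _join_groups(
    names: list[str],
    D: np.ndarray,
    nodes: list[TreeNode],
    groups: list[TieGroup],
    next_id: int,
) -> tuple[list[str], np.ndarray, list[TreeNode], list[GroupJoin], int]:
    """Create one new node per group, rewire the matrix, keep input order.

    The new node takes the slot of its group's smallest member; other
    members vanish.  Survivor-survivor distances are copied, node-survivor
    distances use the node-to-OTU formula, node-node distances use the
    node-to-node formula.
    """
    member_of: dict[int, int] = {}
    for g, group in enumerate(groups):
        for i in group:
            member_of[i] = g

    joins: list[GroupJoin] = []
    new_nodes: list[TreeNode] = []
    for group in groups:
        lengths = _branch_lengths_nonfinal(D, group)
        node = TreeNode()
        for i in group:
            child = nodes[i]
            child.branch_length = lengths[i]
            node.children.append(child)
        node_id = f"node-{next_id}"
        next_id += 1
        joins.append(
            GroupJoin(
                members=tuple(names[i] for i in group),
                node_id=node_id,
                lengths={names[i]: lengths[i] for i in group},
            )
        )
        new_nodes.append(node)

    # New active order: each group collapses onto its smallest member's slot.
    slots: list[tuple[int, int | None]] = []  # (old index, group id or None)
    for i in range(len(names)):
        g = member_of.get(i)
        if g is None:
            slots.append((i, None))
        elif i == groups[g][0]:
            slots.append((i, g))

    m = len(slots)
    new_D = np.zeros((m, m))
    new_names: list[str] = []
    new_entries: list[TreeNode] = []
    for a, (i, gi) in enumerate(slots):
        if gi is None:
            new_names.append(names[i])
            new_entries.append(nodes[i])
        else:
            new_names.append(joins[gi].node_id)
            new_entries.append(new_nodes[gi])
        for b in range(a):
            j, gj = slots[b]
            if gi is None and gj is None:
                d = D[i, j]
            elif gi is None:
                d = _dist_node_to_otu(D, groups[gj], i)
            elif gj is None:
                d = _dist_node_to_otu(D, groups[gi], j)
            else:
                d = _dist_node_to_node(D, groups[gi], groups[gj])
            new_D[a, b] = new_D[b, a] = d
    return new_names, new_D, new_entries, joins, next_id


def _final_event(
    names: list[str],
    D: np.ndarray,
    nodes: list[TreeNode],
    iteration: int,
    node_id: str,
) -> tuple[TreeNode, JoinEvent]:
    n = len(names)
    root = TreeNode()
    if n == 2:
        # Two remaining components: a single edge, serialized as a root
        # with two children carrying half the distance each.
        half = float(D[0, 1]) / 2.0
        lengths = {0: half, 1: half}
    else:
        lengths = _branch_lengths_final(D, list(range(n)))
    for i in range(n):
        child = nodes[i]
        child.branch_length = lengths[i]
        root.children.append(child)
    join = GroupJoin(
        members=tuple(names),
        node_id=node_id,
        lengths={names[i]: lengths[i] for i in range(n)},
    )
    return root, JoinEvent(iteration=iteration, groups=(join,), n_before=n, n_after=1)


Chooser = Callable[[int, list[tuple[int, int]]], int]


def _run(
    dm: DistanceMatrix,
    cfg: AlgoConfig,
    multifurcate: bool,
    chooser: Chooser | None = None,
) -> tuple[PhyloTree, JoinLog, list[int]]:
    """Shared driver.  ``multifurcate`` selects MFNJ grouping; otherwise one
    tied pair per iteration is joined, picked by ``chooser`` (default: the
    lexicographically first pair under the current input-order positions).

    Returns the tree, the join log, and the number of tied options seen at
    each decision point (used by the enumerator).
    """
    if len(dm) < 2:
        raise InputError("need at least 2 taxa")
    names = list(dm.labels)
    D = dm.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    log = JoinLog()
    option_counts: list[int] = []
    next_id = 1
    iteration = 0
    decision = 0
    while True:
        iteration += 1
        n = len(names)
        if n <= 3:
            root, event = _final_event(names, D, nodes, iteration, f"node-{next_id}")
            log.append(event)
            break
        state = _s_state(D)
        pairs = _tied_pairs(state, cfg)
        if multifurcate:
            groups = group_tied_pairs(pairs)
        else:
            option_counts.append(len(pairs))
            pick = 0 if chooser is None else chooser(decision, pairs)
            decision += 1
            groups = [pairs[pick]]
        if len(groups) == 1 and len(groups[0]) == n:
            root, event = _final_event(names, D, nodes, iteration, f"node-{next_id}")
            log.append(event)
            break
        names, D, nodes, joins, next_id = _join_groups(names, D, nodes, groups, next_id)
        log.append(
            JoinEvent(
                iteration=iteration,
                groups=tuple(joins),
                n_before=n,
                n_after=len(names),
            )
        )
    if cfg.negative_branch_policy == "clamp_to_zero":
        _clamp_tree(root)
    return PhyloTree(root), log, option_counts


def run_mfnj(dm: DistanceMatrix, cfg: AlgoConfig | None = None) -> tuple[PhyloTree, JoinLog]:
    """Multifurcating neighbor joining: joins every tied group per iteration.

    The result is independent of taxon input order; iterations with a single
    untied minimal pair behave exactly like classic NJ.
    """
    tree, log, _ = _run(dm, cfg or AlgoConfig(), multifurcate=True)
    return tree, log


def run_nj(dm: DistanceMatrix, cfg: AlgoConfig | None = None) -> tuple[PhyloTree, JoinLog]:
    """Classic neighbor joining: one pair per iteration.

    Ties are broken toward the pair occupying the lexicographically smallest
    (row, column) positions under input order — deterministic, but
    order-sensitive by design.
    """
    tree, log, _ = _run(dm, cfg or AlgoConfig(), multifurcate=False)
    return tree, log


@dataclass(frozen=True)
class EnumerationResult:
    """Distinct NJ trees over all tie-break choices, in lexicographic
    choice-sequence order; ``truncated`` is set when the enumeration cap
    stopped the search early."""

    trees: tuple[PhyloTree, ...]
    truncated: bool

    def __iter__(self):
        return iter(self.trees)

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i):
        return self.trees[i]


def enumerate_nj_trees(dm: DistanceMatrix, cfg: AlgoConfig | None = None) -> EnumerationResult:
    """Depth-first exploration of every tied-pair choice at every iteration.

    Trees are deduplicated by unrooted split set.  The search stops once
    ``cfg.enum_cap`` distinct trees have been found.
    """
    cfg = cfg or AlgoConfig()
    if len(dm) < 3:
        raise InputError("enumeration needs at least 3 taxa")

    seen: set[frozenset] = set()
    trees: list[PhyloTree] = []
    truncated = False

    def replay(prefix: tuple[int, ...]):
        def chooser(decision: int, pairs: list[tuple[int, int]]) -> int:
            return prefix[decision] if decision < len(prefix) else 0

        return _run(dm, cfg, multifurcate=False, chooser=chooser)

    def explore(prefix: tuple[int, ...]) -> bool:
        """DFS over choice sequences; returns False when capped."""
        nonlocal truncated
        tree, _, counts = replay(prefix)
        if len(prefix) >= len(counts):
            key = splits(tree)
            if key not in seen:
                if len(trees) >= cfg.enum_cap:
                    truncated = True
                    return False
                seen.add(key)
                trees.append(tree)
            return True
        for c in range(counts[len(prefix)]):
            if not explore(prefix + (c,)):
                return False
        return True

    explore(())
    return EnumerationResult(trees=tuple(trees), truncated=truncated)
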