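"""Naive pure-Python reference implementation used as an independent oracle.

Deliberately shares no code with the package engine: plain dict/list
arithmetic, label-keyed matrices, formulas transcribed directly, all sums
recomputed from scratch every iteration.  Trees are returned as nested
frozensets of leaf labels with per-clade branch lengths, plus a per-iteration
record of which leaf sets were joined.
"""

from __future__ import annotations

import itertools


def _s_matrix(dist, active):
    n = len(active)
    r = {a: sum(dist[frozenset((a, b))] for b in active if b != a) for a in active}
    s = {}
    for a, b in itertools.combinations(active, 2):
        s[frozenset((a, b))] = (n - 2) * dist[frozenset((a, b))] - r[a] - r[b]
    return s


def _tied_groups(s, atol=1e-12, rtol=1e-9):
    smin = min(s.values())
    thresh = smin + atol + rtol * abs(smin)
    tied = [pair for pair, v in s.items() if v <= thresh]
    groups = []
    for pair in tied:
        hits = [g for g in groups if g & pair]
        merged = set(pair)
        for g in hits:
            merged |= g
            groups.remove(g)
        groups.append(merged)
    return [frozenset(g) for g in groups], tied


def _lengths_nonfinal(dist, active, group):
    n = len(active)
    p = len(group)
    comp = [k for k in active if k not in group]
    r_II = sum(dist[frozenset(pr)] for pr in itertools.combinations(group, 2))
    r_IC = sum(dist[frozenset((i, k))] for i in group for k in comp)
    out = {}
    for i in group:
        r_iC = sum(dist[frozenset((i, k))] for k in comp)
        out[i] = r_II / (p * (p - 1)) + r_iC / (n - p) - r_IC / (p * (n - p))
    return out


def _lengths_final(dist, group):
    p = len(group)
    r_II = sum(dist[frozenset(pr)] for pr in itertools.combinations(group, 2))
    out = {}
    for i in group:
        r_iI = sum(dist[frozenset((i, j))] for j in group if j != i)
        out[i] = r_iI / (p - 2) - r_II / ((p - 1) * (p - 2))
    return out


def _node_to_otu(dist, group, k):
    p = len(group)
    r_Ik = sum(dist[frozenset((i, k))] for i in group)
    r_II = sum(dist[frozenset(pr)] for pr in itertools.combinations(group, 2))
    return r_Ik / p - r_II / (p * (p - 1))


def _node_to_node(dist, gi, gj):
    p, q = len(gi), len(gj)
    r_IJ = sum(dist[frozenset((i, j))] for i in gi for j in gj)
    r_II = sum(dist[frozenset(pr)] for pr in itertools.combinations(gi, 2))
    r_JJ = sum(dist[frozenset(pr)] for pr in itertools.combinations(gj, 2))
    return r_IJ / (p * q) - r_II / (p * (p - 1)) - r_JJ / (q * (q - 1))


def naive_mfnj(labels, matrix, atol=1e-12, rtol=1e-9):
    """Multifurcating join on (labels, square list-of-lists matrix).

    Returns (clades, lengths, history): ``clades`` is the nested-frozenset
    tree; ``lengths`` maps each clade (or leaf label wrapped in a frozenset)
    to its branch length; ``history`` maps 1-based iteration to the multiset
    of leaf sets joined (one frozenset of member-leaf-sets per new node).
    """
# Each active OTU is identified by the frozenset of leaves below it.
    active = [frozenset((l,)) for l in labels]
    dist = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            dist[frozenset((active[i], active[j]))] = matrix[i][j]
    lengths = {}
    history = {}
    iteration = 0
    while True:
        iteration += 1
        if len(active) == 2:
            d = dist[frozenset(active)]
            for a in active:
                lengths[a] = d / 2.0
            history[iteration] = [frozenset(active)]
            root = frozenset(active)
            break
        if len(active) == 3:
            final = _lengths_final(dist, active)
            lengths.update(final)
            history[iteration] = [frozenset(active)]
            root = frozenset(active)
            break
        s = _s_matrix(dist, active)
        groups, _ = _tied_groups(s, atol=atol, rtol=rtol)
        if len(groups) == 1 and len(groups[0]) == len(active):
            final = _lengths_final(dist, active)
            lengths.update(final)
            history[iteration] = [frozenset(active)]
            root = frozenset(active)
            break
        history[iteration] = [g for g in groups]
        new_nodes = []
        for g in groups:
            for i, l in _lengths_nonfinal(dist, active, g).items():
                lengths[i] = l
            new_nodes.append(frozenset(g))
        survivors = [a for a in active if not any(a in g for g in groups)]
        for g, node in zip(groups, new_nodes):
            for k in survivors:
                dist[frozenset((node, k))] = _node_to_otu(dist, g, k)
        for (ga, na), (gb, nb) in itertools.combinations(zip(groups, new_nodes), 2):
            dist[frozenset((na, nb))] = _node_to_node(dist, ga, gb)
        active = survivors + new_nodes
    return root, lengths, history


def flatten(clade):
    """Leaf set of a nested-frozenset clade."""
    if isinstance(clade, frozenset) and all(isinstance(x, str) for x in clade):
        return clade
    out = set()
    for child in clade:
        if isinstance(child, str):
            out.add(child)
        else:
            out |= flatten(child)
    return frozenset(out)


def naive_splits(root, all_leaves):
    """Canonical non-trivial splits of the nested-frozenset tree."""
    anchor = min(all_leaves)
    n = len(all_leaves)
    result = set()

    def rec(clade):
        leaves = flatten(clade)
        if 2 <= len(leaves) <= n - 2:
            side = leaves if anchor not in leaves else frozenset(all_leaves - leaves)
            result.add(side)
        if not all(isinstance(x, str) for x in clade):
            for child in clade:
                if not isinstance(child, str):
                    rec(child)

    for child in root:
        rec(child)
    return frozenset(result)
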