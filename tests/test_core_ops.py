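"""Unit tests for the single-step engine operations, against hand-computed
and brute-force oracles."""

import itertools

import numpy as np
import pytest

from mfnj import AlgoConfig, DistanceMatrix, InputError, star_matrix
from mfnj.core import (
    SState,
    branch_lengths_final,
    branch_lengths_nonfinal,
    compute_s_state,
    dist_node_to_node,
    dist_node_to_otu,
    find_tied_min_pairs,
    group_tied_pairs,
)

from .conftest import random_distance_matrix


def brute_force_s(dm):
    """Direct evaluation of S_ij = (N-2) D_ij - R_i - R_j with plain loops."""
    n = len(dm)
    r = [sum(dm.values[i, k] for k in range(n)) for i in range(n)]
    return {
        (i, j): (n - 2) * dm.values[i, j] - r[i] - r[j]
        for i in range(n)
        for j in range(i + 1, n)
    }


class TestComputeSState:
    def test_equilateral_triple(self):
        dm = DistanceMatrix(("A", "B", "C"), np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float))
        state = compute_s_state(dm)
        for i, j in itertools.combinations(range(3), 2):
            assert state.s_values[i, j] == pytest.approx(-6.0)
        assert state.s_min == pytest.approx(-6.0)
        assert np.allclose(state.row_sums, [4, 4, 4])

    def test_bears_iteration_one_vs_brute_force(self, bears):
        state = compute_s_state(bears)
        oracle = brute_force_s(bears)
        for (i, j), s in oracle.items():
            assert state.s_values[i, j] == pytest.approx(s, abs=1e-12)
        best = min(oracle, key=oracle.get)
        assert state.s_min == pytest.approx(oracle[best], abs=1e-12)
        assert (bears.labels[best[0]], bears.labels[best[1]]) == ("Kodiak", "Captive-3")

    def test_star_matrix_all_pairs_tied(self):
        l = (1.0, 2.0, 3.0, 4.0)
        dm = star_matrix(l)
        state = compute_s_state(dm)
        for i, j in itertools.combinations(range(4), 2):
            assert state.s_values[i, j] == pytest.approx(-2 * sum(l), abs=1e-12)

    def test_symmetry(self, bears):
        state = compute_s_state(bears)
        assert np.allclose(state.s_values, state.s_values.T)

    def test_too_small(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(InputError):
            compute_s_state(dm)


class TestFindTiedMinPairs:
    def _state(self, s_dict, n):
        S = np.zeros((n, n))
        for (i, j), v in s_dict.items():
            S[i, j] = S[j, i] = v
        return SState(row_sums=np.zeros(n), s_values=S,
                      s_min=min(s_dict.values()))

    def test_all_equal(self, cfg):
        state = self._state({(0, 1): -6, (0, 2): -6, (1, 2): -6}, 3)
        assert find_tied_min_pairs(state, cfg) == {(0, 1), (0, 2), (1, 2)}

    def test_unique_minimum(self, cfg):
        state = self._state({(0, 1): -10, (0, 2): -5, (1, 2): -5}, 3)
        assert find_tied_min_pairs(state, cfg) == {(0, 1)}

    def test_bears_fifth_iteration_tie(self, bears, cfg):
        # Replay four pair joins by hand via the public ops: the tie then
        # involves Captive-4/Subtree-4 and Subtree-4/Black.
        from mfnj.core import run_mfnj

        _, log = run_mfnj(bears, cfg)
        tied_event = next(ev for ev in log if any(len(g.members) > 2 for g in ev.groups))
        assert tied_event.iteration == 5
        members = tied_event.groups[0].members
        assert set(members) == {"node-4", "Captive-4", "Black"}

    def test_tolerance_widens_ties(self):
        state = self._state({(0, 1): -10.0, (0, 2): -10.0 + 1e-11, (1, 2): -5.0}, 3)
        tight = AlgoConfig(tie_rtol=0.0, tie_atol=0.0)
        loose = AlgoConfig(tie_rtol=1e-9, tie_atol=0.0)
        assert find_tied_min_pairs(state, tight) == {(0, 1)}
        assert find_tied_min_pairs(state, loose) == {(0, 1), (0, 2)}


class TestGroupTiedPairs:
    def test_shared_member_chains(self):
        assert group_tied_pairs({(0, 1), (1, 2)}) == [(0, 1, 2)]

    def test_disjoint_pairs_stay_separate(self):
        assert group_tied_pairs({(0, 1), (2, 3)}) == [(0, 1), (2, 3)]

    def test_single_pair(self):
        assert group_tied_pairs({(0, 1)}) == [(0, 1)]

    def test_order_by_smallest_member(self):
        groups = group_tied_pairs({(4, 5), (0, 2), (2, 7)})
        assert groups == [(0, 2, 7), (4, 5)]

    def test_scan_order_independent(self):
        pairs = [(1, 3), (3, 5), (0, 2)]
        for perm in itertools.permutations(pairs):
            assert group_tied_pairs(perm) == [(0, 2), (1, 3, 5)]


class TestDistNodeToOtu:
    def test_pair_reduces_to_classic_update(self):
        # I = {i1, i2}: (D_i1k + D_i2k)/2 - D_i1i2/2
        vals = np.array([[0, 4, 5], [4, 0, 7], [5, 7, 0]], float)
        dm = DistanceMatrix(("i1", "i2", "k"), vals)
        assert dist_node_to_otu(dm, (0, 1), 2) == pytest.approx((5 + 7) / 2 - 4 / 2)

    def test_symmetric_triple(self):
        vals = np.full((4, 4), 10.0)
        vals[:3, :3] = 2.0
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix(("a", "b", "c", "k"), vals)
        assert dist_node_to_otu(dm, (0, 1, 2), 3) == pytest.approx(30 / 3 - 6 / 6)

    def test_star_matrix_gives_center_distance(self):
        l = (1.0, 2.0, 3.0, 4.0, 5.0)
        dm = star_matrix(l)
        for group in [(0, 1), (0, 1, 2), (1, 3)]:
            for k in range(5):
                if k in group:
                    continue
                assert dist_node_to_otu(dm, group, k) == pytest.approx(l[k], abs=1e-12)

    def test_member_as_target_rejected(self, bears):
        with pytest.raises(InputError):
            dist_node_to_otu(bears, (0, 1), 1)


class TestDistNodeToNode:
    def test_arithmetic_example(self):
        vals = np.full((4, 4), 10.0)
        vals[0, 1] = vals[1, 0] = 2.0
        vals[2, 3] = vals[3, 2] = 4.0
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix(("a", "b", "c", "d"), vals)
        assert dist_node_to_node(dm, (0, 1), (2, 3)) == pytest.approx(40 / 4 - 1 - 2)

    def test_star_matrix_nodes_coincide(self):
        dm = star_matrix((1.0, 2.0, 3.0, 4.0, 5.0, 6.0))
        assert dist_node_to_node(dm, (0, 1), (2, 3)) == pytest.approx(0.0, abs=1e-12)
        assert dist_node_to_node(dm, (0, 1, 2), (3, 5)) == pytest.approx(0.0, abs=1e-12)

    def test_mean_residual_oracle(self):
        # D_uv must equal the mean over i in I, j in J of
        # (D_ij - L_iu - L_jv) for any lengths satisfying the conservation
        # law; use the engine's non-final lengths, computed independently.
        rng = np.random.default_rng(11)
        dm = random_distance_matrix(rng, 5)
        gi, gj = (0, 1), (2, 3, 4)
        li = branch_lengths_nonfinal(dm, gi)
        lj = branch_lengths_nonfinal(dm, gj)
        residuals = [
            dm.values[i, j] - li[i] - lj[j] for i in gi for j in gj
        ]
        expected = float(np.mean(residuals))
        assert dist_node_to_node(dm, gi, gj) == pytest.approx(expected, abs=1e-12)

    def test_overlap_rejected(self, bears):
        with pytest.raises(InputError):
            dist_node_to_node(bears, (0, 1), (1, 2))


def path_distance_matrix():
    """Additive matrix of ((A:1,B:2):1,(C:3,D:4)) by explicit path sums."""
    d = {
        ("A", "B"): 3.0, ("A", "C"): 5.0, ("A", "D"): 6.0,
        ("B", "C"): 6.0, ("B", "D"): 7.0, ("C", "D"): 7.0,
    }
    labels = ("A", "B", "C", "D")
    vals = np.zeros((4, 4))
    for (a, b), v in d.items():
        i, j = labels.index(a), labels.index(b)
        vals[i, j] = vals[j, i] = v
    return DistanceMatrix(labels, vals)


class TestBranchLengthsNonfinal:
    def test_additive_recovery(self):
        dm = path_distance_matrix()
        lengths = branch_lengths_nonfinal(dm, (0, 1))
        assert lengths[0] == pytest.approx(1.0, abs=1e-12)
        assert lengths[1] == pytest.approx(2.0, abs=1e-12)

    def test_conservation_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(5, 10))
            dm = random_distance_matrix(rng, n)
            size = int(rng.integers(2, n - 1))
            group = tuple(sorted(rng.choice(n, size=size, replace=False).tolist()))
            lengths = branch_lengths_nonfinal(dm, group)
            r_II = sum(
                dm.values[i, j] for i, j in itertools.combinations(group, 2)
            )
            assert sum(lengths.values()) == pytest.approx(
                r_II / (len(group) - 1), rel=1e-9
            )

    def test_bears_first_join_matches_classic_formula(self, bears):
        # Oracle: the pairwise branch-length formula
        # L = D/2 + R_iC/(N-2) - R_IC/(2(N-2)), evaluated directly.
        i, j = bears.index("Kodiak"), bears.index("Captive-3")
        n = len(bears)
        comp = [k for k in range(n) if k not in (i, j)]
        d = bears.values
        r_iC = sum(d[i, k] for k in comp)
        r_jC = sum(d[j, k] for k in comp)
        r_IC = r_iC + r_jC
        expect_i = d[i, j] / 2 + r_iC / (n - 2) - r_IC / (2 * (n - 2))
        expect_j = d[i, j] / 2 + r_jC / (n - 2) - r_IC / (2 * (n - 2))
        lengths = branch_lengths_nonfinal(bears, (i, j))
        assert lengths[i] == pytest.approx(expect_i, abs=1e-12)
        assert lengths[j] == pytest.approx(expect_j, abs=1e-12)

    def test_empty_complement_rejected(self):
        dm = path_distance_matrix()
        with pytest.raises(InputError):
            branch_lengths_nonfinal(dm, (0, 1, 2, 3))


class TestBranchLengthsFinal:
    def test_three_point_formula(self):
        vals = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        dm = DistanceMatrix(("T1", "T2", "T3"), vals)
        lengths = branch_lengths_final(dm, (0, 1, 2))
        assert lengths[0] == pytest.approx(1.0)
        assert lengths[1] == pytest.approx(2.0)
        assert lengths[2] == pytest.approx(3.0)

    def test_equilateral(self):
        vals = np.full((3, 3), 2.0)
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix(("A", "B", "C"), vals)
        assert all(
            v == pytest.approx(1.0) for v in branch_lengths_final(dm, (0, 1, 2)).values()
        )

    def test_star_matrix_recovers_arm_lengths(self):
        l = (1.0, 2.0, 3.0, 4.0, 5.0)
        dm = star_matrix(l)
        lengths = branch_lengths_final(dm, tuple(range(5)))
        for i, li in enumerate(l):
            assert lengths[i] == pytest.approx(li, abs=1e-12)

    def test_partial_group_rejected(self):
        dm = path_distance_matrix()
        with pytest.raises(InputError):
            branch_lengths_final(dm, (0, 1, 2))


class TestAlgoConfig:
    def test_defaults(self):
        cfg = AlgoConfig()
        assert cfg.tie_rtol == 1e-9
        assert cfg.tie_atol == 1e-12
        assert cfg.negative_branch_policy == "keep"
        assert cfg.enum_cap == 64

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tie_rtol": -1.0},
            {"tie_atol": -1.0},
            {"negative_branch_policy": "explode"},
            {"nj_tie_break": "random"},
            {"enum_cap": 0},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            AlgoConfig(**kwargs)
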