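"""Shadow-test assembly: exactness, feasibility and disjoint parallel forms."""

from itertools import combinations

import numpy as np
import pytest

from shadowcat.assembly import (
    AssemblyConstraints,
    AssemblyInfeasibleError,
    assemble,
    assemble_disjoint_pair,
    assemble_multi_theta,
    greedy_exact_assemble,
)
from shadowcat.irt import ModelConstants, _info

from conftest import make_toy_pool

K = ModelConstants()


def brute_force_best(pool, theta, length, cmin, cmax, forced=frozenset()):
    """Exhaustive enumeration of the best feasible subset (tiny pools only)."""
    info = _info(theta, pool.a, pool.b, pool.c, K.D)
    cats = pool.content_category
    labels = np.unique(cats)
    forced_idx = set(pool.index_of(sorted(forced))) if forced else set()
    best, best_set = -np.inf, None
    for combo in combinations(range(len(pool)), length):
        if not forced_idx <= set(combo):
            continue
        counts = [(cats[list(combo)] == g).sum() for g in labels]
        if any(x < cmin or x > cmax for x in counts):
            continue
        val = info[list(combo)].sum()
        if val > best:
            best, best_set = val, combo
    return best, best_set


class TestSingleForm:
    def test_matches_exhaustive_enumeration(self, toy_pool):
        cons = AssemblyConstraints(test_length=4, category_min=2, category_max=2)
        best, _ = brute_force_best(toy_pool, 0.0, 4, 2, 2)
        st = assemble(toy_pool, 0.0, cons)
        assert st.objective_value == pytest.approx(best, abs=1e-9)

    @pytest.mark.parametrize("theta", [-1.5, 0.0, 0.8])
    def test_enumeration_across_thetas_and_seeds(self, theta):
        for seed in range(5):
            pool = make_toy_pool(n=12, n_cats=2, seed=seed)
            cons = AssemblyConstraints(test_length=5, category_min=1, category_max=4)
            best, _ = brute_force_best(pool, theta, 5, 1, 4)
            st = assemble(pool, theta, cons)
            assert st.objective_value == pytest.approx(best, abs=1e-9)

    def test_forced_items_present(self, toy_pool):
        forced = frozenset(["t001", "t005", "t009"])
        cons = AssemblyConstraints(test_length=6, category_min=2, category_max=4, forced_in=forced)
        st = assemble(toy_pool, 0.0, cons)
        assert forced <= st.item_ids
        best, _ = brute_force_best(toy_pool, 0.0, 6, 2, 4, forced=forced)
        assert st.objective_value == pytest.approx(best, abs=1e-9)

    def test_equality_blueprint_forces_exact_counts(self, default_pool):
        cons = AssemblyConstraints(test_length=32, category_min=8, category_max=12)
        st = assemble(default_pool, 0.0, cons)
        idx = default_pool.index_of(sorted(st.item_ids))
        _, counts = np.unique(default_pool.content_category[idx], return_counts=True)
        assert list(counts) == [8, 8, 8, 8]

    def test_excluded_items_absent(self, toy_pool):
        cons = AssemblyConstraints(test_length=4, category_min=1, category_max=3,
                                   excluded=frozenset(["t002", "t007"]))
        st = assemble(toy_pool, 0.0, cons)
        assert not {"t002", "t007"} & st.item_ids

    def test_infeasible_length_diagnosed(self, toy_pool):
        cons = AssemblyConstraints(test_length=11, category_min=1, category_max=5)
        with pytest.raises(AssemblyInfeasibleError, match="maxima"):
            assemble(toy_pool, 0.0, cons)

    def test_forced_exceeding_category_max_infeasible(self, toy_pool):
        # three forced items from category 1 against a cap of 2
        forced = frozenset(["t001", "t002", "t003"])
        cons = AssemblyConstraints(test_length=4, category_min=0, category_max=2, forced_in=forced)
        with pytest.raises(AssemblyInfeasibleError):
            assemble(toy_pool, 0.0, cons)

    def test_objective_continuity_in_theta(self, default_pool):
        cons = AssemblyConstraints(test_length=32)
        v1 = assemble(default_pool, 0.3, cons).objective_value
        v2 = assemble(default_pool, 0.3 + 1e-9, cons).objective_value
        assert abs(v1 - v2) <= 1e-6


class TestGreedyVsMip:
    def test_objective_equality_random_instances(self):
        """Greedy solver attains the MIP optimum across random toy instances."""
        rng = np.random.default_rng(11)
        for trial in range(30):
            pool = make_toy_pool(n=int(rng.integers(10, 25)), n_cats=int(rng.integers(2, 4)),
                                 seed=trial + 100)
            n_cats = len(np.unique(pool.content_category))
            per = min(np.bincount(pool.content_category)[1:])
            cmax = int(rng.integers(1, per + 1))
            cmin = int(rng.integers(0, cmax + 1))
            length_lo, length_hi = n_cats * cmin, n_cats * cmax
            if length_hi < 2:
                continue
            length = int(rng.integers(max(length_lo, 1), length_hi + 1))
            theta = float(rng.normal())
            cons = AssemblyConstraints(test_length=length, category_min=cmin, category_max=cmax)
            g = assemble(pool, theta, cons, solver="greedy")
            m = assemble(pool, theta, cons, solver="mip")
            assert g.objective_value == pytest.approx(m.objective_value, abs=1e-9)

    def test_stratified_with_free_category_counts_routes_to_mip(self, default_pool):
        """Quota-constrained assembly at a length where the category counts
        are not pinned still returns a feasible optimal form (general MIP
        path)."""
        cons = AssemblyConstraints(test_length=40, category_min=8, category_max=12,
                                   stratum_min=(14, 12, 0))
        g = assemble(default_pool, 0.2, cons, solver="greedy")
        m = assemble(default_pool, 0.2, cons, solver="mip")
        assert g.objective_value == pytest.approx(m.objective_value, abs=1e-7)
        idx = default_pool.index_of(sorted(g.item_ids))
        s = default_pool.stratum[idx]
        counts = np.bincount(default_pool.content_category[idx])[1:]
        assert (s == 1).sum() >= 14 and (s == 2).sum() >= 12
        assert np.all(counts >= 8) and np.all(counts <= 12) and len(idx) == 40

    def test_stratified_quotas_match_mip(self, default_pool):
        """The stratified DP attains the MIP optimum when low/middle-stratum
        minima are imposed on top of the content blueprint."""
        rng = np.random.default_rng(4)
        ids = default_pool.item_id
        for trial in range(8):
            n_forced = int(rng.integers(0, 12))
            forced = frozenset(str(i) for i in rng.choice(ids, n_forced, replace=False))
            theta = float(rng.normal())
            cons = AssemblyConstraints(test_length=32, category_min=8, category_max=12,
                                       forced_in=forced, stratum_min=(14, 12, 0))
            g = assemble(default_pool, theta, cons, solver="greedy")
            m = assemble(default_pool, theta, cons, solver="mip")
            assert g.objective_value == pytest.approx(m.objective_value, abs=1e-7)
            idx = default_pool.index_of(sorted(g.item_ids))
            s = default_pool.stratum[idx]
            assert (s == 1).sum() >= 14 and (s == 2).sum() >= 12


def brute_force_best_pair(pool, theta, length, cmin, cmax):
    """Exhaustive search over disjoint feasible pairs; returns max joint sum."""
    info = _info(theta, pool.a, pool.b, pool.c, K.D)
    cats = pool.content_category
    labels = np.unique(cats)
    feas = []
    for combo in combinations(range(len(pool)), length):
        counts = [(cats[list(combo)] == g).sum() for g in labels]
        if all(cmin <= x <= cmax for x in counts):
            feas.append((set(combo), info[list(combo)].sum()))
    best = -np.inf
    for i, (s1, v1) in enumerate(feas):
        for s2, v2 in feas[i + 1:]:
            if not s1 & s2:
                best = max(best, v1 + v2)
    return best


class TestDisjointPair:
    def test_unadministered_portions_disjoint(self, default_pool):
        forced = frozenset(["it001", "it002"])
        cons = AssemblyConstraints(test_length=32, forced_in=forced)
        f1, f2 = assemble_disjoint_pair(default_pool, 0.0, cons)
        assert forced <= f1.item_ids and forced <= f2.item_ids
        assert not (f1.item_ids - forced) & (f2.item_ids - forced)

    def test_joint_objective_matches_pair_enumeration(self):
        pool = make_toy_pool(n=10, n_cats=2, seed=21)
        cons = AssemblyConstraints(test_length=4, category_min=1, category_max=3)
        best = brute_force_best_pair(pool, 0.0, 4, 1, 3)
        f1, f2 = assemble_disjoint_pair(pool, 0.0, cons)
        assert f1.objective_value + f2.objective_value == pytest.approx(best, abs=1e-9)

    def test_matches_joint_mip(self, default_pool):
        rng = np.random.default_rng(9)
        for trial in range(3):
            n_forced = int(rng.integers(0, 10))
            forced = frozenset(
                str(i) for i in rng.choice(default_pool.item_id, n_forced, replace=False)
            )
            cons = AssemblyConstraints(test_length=32, forced_in=forced)
            theta = float(rng.normal())
            g1, g2 = assemble_disjoint_pair(default_pool, theta, cons, solver="greedy")
            m1, m2 = assemble_disjoint_pair(default_pool, theta, cons, solver="mip")
            assert g1.objective_value + g2.objective_value == pytest.approx(
                m1.objective_value + m2.objective_value, abs=1e-7
            )

    def test_stratified_pair_matches_joint_mip(self, default_pool):
        rng = np.random.default_rng(19)
        forced = frozenset(str(i) for i in rng.choice(default_pool.item_id, 5, replace=False))
        cons = AssemblyConstraints(test_length=32, forced_in=forced, stratum_min=(14, 12, 0))
        g1, g2 = assemble_disjoint_pair(default_pool, 0.4, cons, solver="greedy")
        m1, m2 = assemble_disjoint_pair(default_pool, 0.4, cons, solver="mip")
        assert g1.objective_value + g2.objective_value == pytest.approx(
            m1.objective_value + m2.objective_value, abs=1e-7
        )
        for form in (g1, g2):
            idx = default_pool.index_of(sorted(form.item_ids))
            s = default_pool.stratum[idx]
            assert (s == 1).sum() >= 14 and (s == 2).sum() >= 12
            assert not (g1.item_ids - forced) & (g2.item_ids - forced)

    def test_joint_infeasibility_raises(self):
        pool = make_toy_pool(n=10, n_cats=2, seed=3)
        cons = AssemblyConstraints(test_length=6, category_min=3, category_max=3)
        with pytest.raises(AssemblyInfeasibleError):
            assemble_disjoint_pair(pool, 0.0, cons)  # needs 12 distinct items


class TestMultiTheta:
    def test_target_points(self, default_pool):
        forms = assemble_multi_theta(default_pool, 0.0, 0.4, AssemblyConstraints(test_length=32))
        assert [f.theta_target for f in forms] == pytest.approx([-0.2, 0.0, 0.2])

    def test_degenerate_se_collapses_targets(self, default_pool):
        forms = assemble_multi_theta(default_pool, 0.5, 1e-12, AssemblyConstraints(test_length=32))
        objs = [f.objective_value for f in forms]
        assert objs[0] == pytest.approx(objs[1], abs=1e-6)
        assert objs[1] == pytest.approx(objs[2], abs=1e-6)

    def test_each_form_individually_optimal(self):
        pool = make_toy_pool(n=12, n_cats=2, seed=8)
        cons = AssemblyConstraints(test_length=4, category_min=1, category_max=3)
        forms = assemble_multi_theta(pool, 0.2, 0.6, cons)
        for f in forms:
            best, _ = brute_force_best(pool, f.theta_target, 4, 1, 3)
            assert f.objective_value == pytest.approx(best, abs=1e-9)

    def test_nonpositive_se_rejected(self, default_pool):
        with pytest.raises(ValueError):
            assemble_multi_theta(default_pool, 0.0, 0.0, AssemblyConstraints(test_length=32))


def test_greedy_exact_assemble_alias(default_pool):
    cons = AssemblyConstraints(test_length=48)
    a = greedy_exact_assemble(default_pool, 0.1, cons)
    b = assemble(default_pool, 0.1, cons, solver="greedy")
    assert a.item_ids == b.item_ids
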