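"""Shadow-test assembly: optimal constrained selection of full-length tests.

Before every item is administered, a complete blueprint-feasible test (the
"shadow test") is assembled that (i) contains every item already administered,
(ii) satisfies the content blueprint (per-category minimum/maximum counts and
total length), (iii) optionally contains minimum numbers of items from the
low-discrimination strata (so that stratified selection always finds eligible
items inside the form), and (iv) maximizes the summed Fisher information at
the current ability estimate.  The next item is then picked from the form's
unadministered part, which guarantees the finished test can never violate the
blueprint.

Two interchangeable solvers are provided:

* ``greedy`` (default) — exact specialized solvers for the constraint classes
  used here.  With category bounds only, the objective is a sum of fixed
  per-item scores, so optimizing reduces to choosing how many items each
  category contributes; within a category the top-scoring items are always
  best and the marginal value of one more slot is non-increasing, so a
  steepest-ascent fill over category counts attains the global optimum.  With
  stratum minima added (and category counts pinned by the blueprint
  arithmetic, as in the 32 = 4x8 / 48 = 4x12 design) the per-category choice
  of how many items to draw from each constrained stratum is resolved by an
  exhaustive dynamic programme over residual stratum demand, which is likewise
  exact.  Anything outside these classes falls through to the MIP backend.
* ``mip`` — a mixed-integer programme over binary inclusion indicators solved
  with HiGHS branch-and-bound (scipy.optimize.milp); slower but fully general,
  and used throughout the tests as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .irt import DEFAULT_CONSTANTS, ModelConstants, _info
from .pool import ItemPool

__all__ = [
    "AssemblyConstraints",
    "ShadowTest",
    "AssemblyInfeasibleError",
    "assemble",
    "assemble_disjoint_pair",
    "assemble_multi_theta",
    "greedy_exact_assemble",
]

Solver = Literal["greedy", "mip"]


class AssemblyInfeasibleError(RuntimeError):
    """The constraint system admits no feasible shadow test."""


@dataclass(frozen=True)
class AssemblyConstraints:
    """Blueprint for one shadow test.

    ``category_min``/``category_max`` apply to every content category;
    ``forced_in`` lists items (typically those already administered) that must
    appear; ``excluded`` items may not.  ``stratum_min`` optionally gives a
    minimum item count per discrimination stratum (1-based label order),
    counting forced items.
    """

    test_length: int
    category_min: int = 8
    category_max: int = 12
    forced_in: frozenset = frozenset()
    excluded: frozenset = frozenset()
    stratum_min: tuple | None = None

    def __post_init__(self) -> None:
        if self.test_length < 1:
            raise ValueError("test_length must be positive")
        if self.category_min < 0 or self.category_max < self.category_min:
            raise ValueError("need 0 <= category_min <= category_max")
        object.__setattr__(self, "forced_in", frozenset(self.forced_in))
        object.__setattr__(self, "excluded", frozenset(self.excluded))
        if self.forced_in & self.excluded:
            raise ValueError("forced_in and excluded overlap")
        if len(self.forced_in) > self.test_length:
            raise ValueError("more forced items than the test length")
        if self.stratum_min is not None:
            object.__setattr__(self, "stratum_min", tuple(int(x) for x in self.stratum_min))
            if any(x < 0 for x in self.stratum_min):
                raise ValueError("stratum minima must be non-negative")
            if sum(self.stratum_min) > self.test_length:
                raise ValueError("stratum minima exceed the test length")


@dataclass(frozen=True)
class ShadowTest:
    """One assembled full-length form: item ids, target ability and the
    information sum it attains there."""

    item_ids: frozenset
    theta_target: float
    objective_value: float

    def __len__(self) -> int:
        return len(self.item_ids)

    def unadministered(self, administered: Iterable[str]) -> frozenset:
        return self.item_ids - frozenset(administered)


# ---------------------------------------------------------------------------
# shared bookkeeping
# ---------------------------------------------------------------------------

def _category_problem(cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax, n_items):
    """Feasibility bookkeeping shared by all cores.  Returns (availability
    mask, forced per-category counts, needed/capacity per category, free slot
    count)."""
    in_test = np.zeros(n_items, dtype=bool)
    in_test[forced_idx] = True
    if np.count_nonzero(in_test) != len(forced_idx):
        raise ValueError("duplicate forced item indices")
    avail = ~in_test
    avail[excluded_idx] = False
    f = np.bincount(cats0[forced_idx], minlength=n_cats)
    if np.any(f > cmax):
        g = int(np.argmax(f > cmax))
        raise AssemblyInfeasibleError(
            f"forced items give category {g + 1} count {int(f[g])} above its maximum {int(cmax[g])}"
        )
    free = L - len(forced_idx)
    if free < 0:
        raise AssemblyInfeasibleError("more forced items than the test length")
    need = np.maximum(cmin - f, 0)
    cap = cmax - f
    if need.sum() > free:
        raise AssemblyInfeasibleError(
            f"category minima require {int(need.sum())} more items but only {free} slots remain"
        )
    if cap.sum() < free:
        raise AssemblyInfeasibleError(
            f"category maxima cap the test at {int(cap.sum() + len(forced_idx))} items, below length {L}"
        )
    return avail, f, need, cap, free


def _ranked(info, idx):
    """Candidate indices ordered by (-information, index): stable argsort of
    descending info keeps ascending index among ties."""
    return idx[np.argsort(-info[idx], kind="stable")]


# ---------------------------------------------------------------------------
# category-only exact greedy
# ---------------------------------------------------------------------------

def greedy_core(info, cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax):
    """Exact greedy assembly under length + per-category bounds.

    Single descending scan with reserved slots for unmet category minima;
    equivalent to allocating each category its minimum of top items and then
    filling remaining slots with the globally best marginal item.
    Returns selected indices (forced included) in ascending order.
    """
    n_items = info.shape[0]
    avail, f, need, cap, free = _category_problem(
        cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax, n_items
    )
    order = _ranked(info, np.flatnonzero(avail))
    take = np.zeros(n_cats, dtype=int)
    spare = free - int(need.sum())
    chosen = np.empty(free, dtype=int)
    pos = 0
    for j in order:
        if pos == free:
            break
        g = cats0[j]
        if take[g] < need[g]:
            take[g] += 1
        elif take[g] < cap[g] and spare > 0:
            take[g] += 1
            spare -= 1
        else:
            continue
        chosen[pos] = j
        pos += 1
    if pos < free:
        lacking = np.flatnonzero(take < need)
        raise AssemblyInfeasibleError(
            f"pool cannot fill the blueprint: {free - pos} open slots remain"
            + (f"; category {int(lacking[0]) + 1} lacks items" if lacking.size else "")
        )
    return np.sort(np.concatenate([np.asarray(forced_idx, dtype=int), chosen]))


# ---------------------------------------------------------------------------
# stratified exact assembly (category counts pinned, stratum minima)
# ---------------------------------------------------------------------------

try:  # the DP kernel is pure counting loops; JIT-compile when numba is present
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard speedup, soft dependency
    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


@_njit(cache=True)
def _dp_solve(ranked, rinfo, rcats, rcells, n_cats, R, q1, q2):  # pragma: no cover - jitted
    """Exact DP over residual stratum demand, forward pass + deterministic
    backtrack.

    ``ranked``: available item indices in (-info, index) order; ``rcats`` /
    ``rcells`` their category codes and cell classes (0/1 = constrained
    strata, 2 = pooled remainder); ``R``: per-category exact take counts;
    ``q1``/``q2``: residual quotas of the two constrained strata.  Returns
    (ok flag, per-category-cell take counts, per-cell ranked item table,
    per-cell lengths).  See _strat_select for the model.
    """
    maxR = 0
    for g in range(n_cats):
        if R[g] > maxR:
            maxR = R[g]
    cell_items = np.full((n_cats, 3, max(maxR, 1)), -1, dtype=np.int64)
    cell_len = np.zeros((n_cats, 3), dtype=np.int64)
    cum = np.zeros((n_cats, 3, max(maxR, 1) + 1))
    for t in range(ranked.shape[0]):
        g = rcats[t]
        ce = rcells[t]
        k = cell_len[g, ce]
        if k < R[g]:
            cell_items[g, ce, k] = ranked[t]
            cum[g, ce, k + 1] = cum[g, ce, k] + rinfo[t]
            cell_len[g, ce] = k + 1

    F = np.full((n_cats + 1, q1 + 1, q2 + 1), -1e30)
    F[0, 0, 0] = 0.0
    for g in range(n_cats):
        Rg = R[g]
        l0 = cell_len[g, 0]
        l1 = cell_len[g, 1]
        l2 = cell_len[g, 2]
        for u1 in range(q1 + 1):
            for u2 in range(q2 + 1):
                base = F[g, u1, u2]
                if base < -1e29:
                    continue
                x1max = Rg if Rg < l0 else l0
                for x1 in range(x1max + 1):
                    rem = Rg - x1
                    x2max = rem if rem < l1 else l1
                    for x2 in range(x2max + 1):
                        x3 = rem - x2
                        if x3 > l2:
                            continue
                        v = cum[g, 0, x1] + cum[g, 1, x2] + cum[g, 2, x3]
                        t1 = u1 + x1
                        if t1 > q1:
                            t1 = q1
                        t2 = u2 + x2
                        if t2 > q2:
                            t2 = q2
                        nv = base + v
                        if nv > F[g + 1, t1, t2]:
                            F[g + 1, t1, t2] = nv

    take = np.zeros((n_cats, 3), dtype=np.int64)
    if F[n_cats, q1, q2] < -1e29:
        return False, take, cell_items, cell_len

    u1, u2 = q1, q2
    for g in range(n_cats - 1, -1, -1):
        target = F[g + 1, u1, u2]
        Rg = R[g]
        l0 = cell_len[g, 0]
        l1 = cell_len[g, 1]
        l2 = cell_len[g, 2]
        found = False
        x1max = Rg if Rg < l0 else l0
        for x1 in range(x1max + 1):
            if found:
                break
            rem = Rg - x1
            x2max = rem if rem < l1 else l1
            for x2 in range(x2max + 1):
                x3 = rem - x2
                if x3 > l2:
                    continue
                v = cum[g, 0, x1] + cum[g, 1, x2] + cum[g, 2, x3]
                if u1 < q1:
                    p1a = u1 - x1
                    p1b = p1a
                else:
                    p1a = q1 - x1 if q1 - x1 > 0 else 0
                    p1b = q1
                if p1a < 0:
                    continue
                if u2 < q2:
                    p2a = u2 - x2
                    p2b = p2a
                else:
                    p2a = q2 - x2 if q2 - x2 > 0 else 0
                    p2b = q2
                if p2a < 0:
                    continue
                best = -1e30
                bi = -1
                bj = -1
                for p1 in range(p1a, p1b + 1):
                    for p2 in range(p2a, p2b + 1):
                        if F[g, p1, p2] > best:
                            best = F[g, p1, p2]
                            bi = p1
                            bj = p2
                if best > -1e29 and best + v >= target - 1e-9:
                    take[g, 0] = x1
                    take[g, 1] = x2
                    take[g, 2] = x3
                    u1 = bi
                    u2 = bj
                    found = True
                    break
        if not found:
            return False, take, cell_items, cell_len
    return True, take, cell_items, cell_len


def _pinned_targets(cmin, cmax, L):
    """Per-category exact counts when the blueprint arithmetic pins them,
    else None."""
    if int(cmin.sum()) == L:
        return cmin.copy()
    if int(cmax.sum()) == L:
        return cmax.copy()
    if np.array_equal(cmin, cmax):
        return cmin.copy()
    return None


def _strat_select(info, cats0, strata0, n_cats, avail, R, q_by_stratum):
    """Exact selection of R[g] items per category maximizing information,
    subject to minimum total counts per constrained stratum.

    Solved by dynamic programming over residual stratum demand (demand state
    capped at the quota).  Supports up to two constrained strata — the
    low/middle discrimination quotas of the stratified phase schedule; other
    patterns go through the MIP backend instead.

    Returns (selected index array, per-category per-cell take counts (cells
    0/1 = constrained strata, 2 = pooled rest), the per-cell ranked item
    table) for downstream splitting.
    """
    cons_strata = sorted(s for s, qv in q_by_stratum.items() if qv > 0)
    if len(cons_strata) > 2:
        raise NotImplementedError("at most two constrained strata in the exact DP")
    q1 = int(q_by_stratum[cons_strata[0]]) if len(cons_strata) >= 1 else 0
    q2 = int(q_by_stratum[cons_strata[1]]) if len(cons_strata) >= 2 else 0

    avail_idx = np.flatnonzero(avail)
    ranked = _ranked(info, avail_idx)
    rcells = np.full(len(ranked), 2, dtype=np.int64)
    rstrata = strata0[ranked]
    rcells[rstrata == cons_strata[0]] = 0
    if len(cons_strata) >= 2:
        rcells[rstrata == cons_strata[1]] = 1
    ok, take, cell_items, cell_len = _dp_solve(
        ranked.astype(np.int64),
        info[ranked].astype(np.float64),
        cats0[ranked].astype(np.int64),
        rcells,
        int(n_cats),
        np.asarray(R, dtype=np.int64),
        q1,
        q2,
    )
    if not ok:
        raise AssemblyInfeasibleError(
            f"stratum minima {dict(q_by_stratum)} cannot be met within the category blueprint"
        )
    parts = [
        cell_items[g, ce, : take[g, ce]] for g in range(n_cats) for ce in range(3)
    ]
    sel = np.concatenate(parts) if parts else np.empty(0, dtype=int)
    return sel.astype(int), take, cell_items


def _stratum_bookkeeping(strata0, n_strata, forced_idx, strat_min):
    smin = np.zeros(n_strata, dtype=int)
    smin[: len(strat_min)] = np.asarray(strat_min, dtype=int)[:n_strata]
    fs = np.bincount(strata0[np.asarray(forced_idx, dtype=int)] - 1, minlength=n_strata)
    return np.maximum(smin - fs, 0)


def stratified_core(
    info, cats0, n_cats, strata0, forced_idx, excluded_idx, L, cmin, cmax, strat_min
):
    """Exact assembly with per-stratum minima.

    ``strata0`` holds 1-based stratum labels; ``strat_min`` the per-stratum
    minimum counts (forced items included).  Falls back to the category-only
    greedy when the residual quotas vanish, and to the MIP backend when the
    category counts are not pinned by the blueprint arithmetic.
    """
    n_items = info.shape[0]
    n_strata = int(strata0.max()) if len(strata0) else 0
    avail, f, need, cap, free = _category_problem(
        cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax, n_items
    )
    q = _stratum_bookkeeping(strata0, n_strata, forced_idx, strat_min)
    if q.sum() == 0:
        return greedy_core(info, cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax)
    T = _pinned_targets(cmin, cmax, L)
    if T is None or np.count_nonzero(q) > 2:
        return milp_core(
            info, cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax,
            strata0=strata0, strat_min=strat_min,
        )
    if np.any(f > T):
        g = int(np.argmax(f > T))
        raise AssemblyInfeasibleError(
            f"forced items exceed category {g + 1}'s pinned count {int(T[g])}"
        )
    R = T - f
    q_by_stratum = {s + 1: int(q[s]) for s in range(n_strata) if q[s] > 0}
    sel, _, _ = _strat_select(info, cats0, strata0, n_cats, avail, R, q_by_stratum)
    return np.sort(np.concatenate([np.asarray(forced_idx, dtype=int), sel]))


# ---------------------------------------------------------------------------
# disjoint parallel forms
# ---------------------------------------------------------------------------

def _split_alternating(ranked, n1):
    """Deterministic near-balanced split of a ranked cell into (n1, rest)."""
    evens, odds = ranked[0::2], ranked[1::2]
    if n1 <= len(evens):
        return evens[:n1], np.concatenate([odds, evens[n1:]])
    extra = n1 - len(evens)
    return np.concatenate([evens, odds[:extra]]), odds[extra:]


def _single_dispatch(info, cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax,
                     strata0=None, strat_min=None):
    if strat_min is not None and strata0 is not None and any(strat_min):
        return stratified_core(
            info, cats0, n_cats, strata0, forced_idx, excluded_idx, L, cmin, cmax, strat_min
        )
    return greedy_core(info, cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax)


def sequential_pair_core(
    info, cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax,
    strata0=None, strat_min=None,
):
    """Sequentially assembled pair of forms sharing no unadministered items.

    The first form is the single-form optimum; the second is the optimum with
    the first form's unadministered items barred.  The second form therefore
    reaches strictly deeper into the information ranking, which is what makes
    the paired-form candidate pool diversify item usage.
    """
    forced = np.asarray(forced_idx, dtype=int)
    s1 = _single_dispatch(info, cats0, n_cats, forced, excluded_idx, L, cmin, cmax,
                          strata0, strat_min)
    excl2 = np.concatenate([np.asarray(excluded_idx, dtype=int), np.setdiff1d(s1, forced)])
    s2 = _single_dispatch(info, cats0, n_cats, forced, excl2, L, cmin, cmax,
                          strata0, strat_min)
    return s1, s2


def disjoint_pair_core(
    info, cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax,
    strata0=None, strat_min=None,
):
    """Jointly optimal pair of forms sharing no unadministered items.

    Both forms score an item identically, so the joint objective only depends
    on WHICH unadministered items are picked in total: 2(L - |F|) distinct
    items with all per-form count constraints doubled.  The doubled problem is
    solved with the exact single-form machinery; the winners are then split
    into two feasible forms (rank-alternating within each category/stratum
    cell, with cell counts rounded so both forms respect the pinned category
    counts and stratum quotas — such an integral rounding always exists
    because the half-half split is a fractional solution of an integral
    transportation polytope).
    """
    n_items = info.shape[0]
    avail, f, need, cap, free = _category_problem(
        cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax, n_items
    )
    forced_idx = np.asarray(forced_idx, dtype=int)
    excl2 = np.concatenate([np.asarray(excluded_idx, dtype=int), forced_idx])

    n_strata = int(strata0.max()) if strata0 is not None and len(strata0) else 0
    q = (
        _stratum_bookkeeping(strata0, n_strata, forced_idx, strat_min)
        if strat_min is not None
        else np.zeros(0, dtype=int)
    )

    if q.sum() == 0:
        # category-only: doubled greedy, then per-category alternating split
        sel = greedy_core(
            info, cats0, n_cats, np.empty(0, dtype=int), excl2, 2 * free, 2 * need, 2 * cap
        )
        m = np.bincount(cats0[sel], minlength=n_cats)
        n1 = m // 2
        deficit = free - int(n1.sum())
        for g in range(n_cats):
            if deficit <= 0:
                break
            if m[g] % 2 == 1:
                n1[g] += 1
                deficit -= 1
        p1, p2 = [forced_idx], [forced_idx]
        for g in range(n_cats):
            ranked = _ranked(info, sel[cats0[sel] == g])
            a_part, b_part = _split_alternating(ranked, int(n1[g]))
            p1.append(a_part)
            p2.append(b_part)
        return np.sort(np.concatenate(p1)), np.sort(np.concatenate(p2))

    # stratified: doubled DP, then a cell-count rounding that keeps both forms
    # feasible for categories AND stratum quotas
    T = _pinned_targets(cmin, cmax, L)
    if T is None or np.count_nonzero(q) > 2:
        return disjoint_pair_milp(
            info, cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax,
            strata0=strata0, strat_min=strat_min,
        )
    if np.any(f > T):
        raise AssemblyInfeasibleError("forced items exceed a pinned category count")
    R = T - f
    q_by_stratum = {s + 1: int(q[s]) for s in range(n_strata) if q[s] > 0}
    q2_by_stratum = {s: 2 * v for s, v in q_by_stratum.items()}
    avail2 = avail.copy()
    avail2[forced_idx] = False
    sel, take2, cell_items = _strat_select(
        info, cats0, strata0, n_cats, avail2, 2 * R, q2_by_stratum,
    )
    # form-1 cell counts: floor(m/2) everywhere, then bump one odd cell per
    # category (each row has an even number of odd cells: 0 or 2 given 3
    # cells) so row sums hit R[g]; choose bumps so each constrained stratum
    # column lands in [q_s, M_s - q_s] (both forms meet the quota)
    m = take2
    n1 = m // 2
    odd_rows = [g for g in range(n_cats) if int(m[g].sum() - 2 * n1[g].sum()) > 0]
    cons_cols = list(range(len(q_by_stratum)))
    col_lo = np.array([q_by_stratum[s] for s in sorted(q_by_stratum)], dtype=int)
    col_tot = m[:, cons_cols].sum(axis=0)
    chosen_bumps = None
    for combo in range(2 ** len(odd_rows)):
        trial = n1.copy()
        for bit, g in enumerate(odd_rows):
            odd_cells = [ci for ci in range(3) if m[g, ci] % 2 == 1]
            trial[g, odd_cells[(combo >> bit) & 1]] += 1
        csum = trial[:, cons_cols].sum(axis=0)
        if np.all(csum >= col_lo) and np.all(col_tot - csum >= col_lo):
            chosen_bumps = trial
            break
    if chosen_bumps is None:  # pragma: no cover - rounding always feasible
        raise RuntimeError("disjoint split rounding failed")
    n1 = chosen_bumps
    p1, p2 = [forced_idx], [forced_idx]
    for g in range(n_cats):
        for ci in range(3):
            ranked = cell_items[g, ci, : m[g, ci]]
            a_part, b_part = _split_alternating(ranked, int(n1[g, ci]))
            p1.append(a_part)
            p2.append(b_part)
    return np.sort(np.concatenate(p1)), np.sort(np.concatenate(p2))


# ---------------------------------------------------------------------------
# MIP backend (HiGHS branch-and-bound)
# ---------------------------------------------------------------------------

def milp_core(
    info, cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax,
    strata0=None, strat_min=None,
):
    """Binary-programme assembly; fully general within the constraint kinds."""
    from scipy.optimize import Bounds, LinearConstraint, milp
    from scipy.sparse import csr_matrix

    n = info.shape[0]
    lb = np.zeros(n)
    ub = np.ones(n)
    lb[np.asarray(forced_idx, dtype=int)] = 1.0
    ub[np.asarray(excluded_idx, dtype=int)] = 0.0
    rows = [np.ones(n)]
    lo = [float(L)]
    hi = [float(L)]
    for g in range(n_cats):
        rows.append((cats0 == g).astype(float))
        lo.append(float(cmin[g]))
        hi.append(float(cmax[g]))
    if strat_min is not None and strata0 is not None:
        for s, smin in enumerate(strat_min, start=1):
            if smin > 0:
                rows.append((strata0 == s).astype(float))
                lo.append(float(smin))
                hi.append(float(n))
    A = csr_matrix(np.vstack(rows))
    res = milp(
        c=-info,
        constraints=LinearConstraint(A, lo, hi),
        integrality=np.ones(n),
        bounds=Bounds(lb, ub),
    )
    if res.status != 0 or res.x is None:
        raise AssemblyInfeasibleError(f"MIP solver reported infeasibility: {res.message}")
    return np.flatnonzero(res.x > 0.5)


def disjoint_pair_milp(
    info, cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax,
    strata0=None, strat_min=None,
):
    """Joint MIP over 2N binary indicators with pairwise exclusivity on
    unadministered items; independent oracle for disjoint_pair_core."""
    from scipy.optimize import Bounds, LinearConstraint, milp
    from scipy.sparse import csr_matrix, hstack, identity, vstack

    n = info.shape[0]
    forced_idx = np.asarray(forced_idx, dtype=int)
    excluded_idx = np.asarray(excluded_idx, dtype=int)
    lb = np.zeros(2 * n)
    ub = np.ones(2 * n)
    for off in (0, n):
        lb[forced_idx + off] = 1.0
        ub[excluded_idx + off] = 0.0
    rows, lo, hi = [], [], []
    ones = np.ones(n)
    zeros = np.zeros(n)

    def both_forms(row, lo_v, hi_v):
        rows.append(np.concatenate([row, zeros]))
        rows.append(np.concatenate([zeros, row]))
        lo.extend([lo_v, lo_v])
        hi.extend([hi_v, hi_v])

    both_forms(ones, float(L), float(L))
    for g in range(n_cats):
        both_forms((cats0 == g).astype(float), float(cmin[g]), float(cmax[g]))
    if strat_min is not None and strata0 is not None:
        for s, smin in enumerate(strat_min, start=1):
            if smin > 0:
                both_forms((strata0 == s).astype(float), float(smin), float(n))
    A_dense = csr_matrix(np.vstack(rows))
    pair = hstack([identity(n, format="csr"), identity(n, format="csr")], format="csr")
    forced_mask = np.zeros(n, dtype=bool)
    forced_mask[forced_idx] = True
    pair = pair[np.flatnonzero(~forced_mask)]
    A = vstack([A_dense, pair], format="csr")
    lo = np.concatenate([lo, np.zeros(pair.shape[0])])
    hi = np.concatenate([hi, np.ones(pair.shape[0])])
    res = milp(
        c=-np.concatenate([info, info]),
        constraints=LinearConstraint(A, lo, hi),
        integrality=np.ones(2 * n),
        bounds=Bounds(lb, ub),
    )
    if res.status != 0 or res.x is None:
        raise AssemblyInfeasibleError(f"joint MIP reported infeasibility: {res.message}")
    return np.flatnonzero(res.x[:n] > 0.5), np.flatnonzero(res.x[n:] > 0.5)


# ---------------------------------------------------------------------------
# public id-level interface
# ---------------------------------------------------------------------------

def _prepare(pool: ItemPool, theta: float, constraints: AssemblyConstraints, constants: ModelConstants):
    info = _info(theta, pool.a, pool.b, pool.c, constants.D)
    cats = pool.content_category
    cat_labels = np.unique(cats)
    codes = np.searchsorted(cat_labels, cats)
    n_cats = len(cat_labels)
    cmin = np.full(n_cats, constraints.category_min, dtype=int)
    cmax = np.full(n_cats, constraints.category_max, dtype=int)
    forced_idx = pool.index_of(sorted(constraints.forced_in)) if constraints.forced_in else np.empty(0, int)
    excluded_idx = pool.index_of(sorted(constraints.excluded)) if constraints.excluded else np.empty(0, int)
    return info, codes, n_cats, forced_idx, excluded_idx, cmin, cmax


def _to_shadow(pool: ItemPool, sel: np.ndarray, theta: float, info: np.ndarray) -> ShadowTest:
    return ShadowTest(
        item_ids=frozenset(str(i) for i in pool.item_id[sel]),
        theta_target=float(theta),
        objective_value=float(info[sel].sum()),
    )


def assemble(
    pool: ItemPool,
    theta: float,
    constraints: AssemblyConstraints,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    solver: Solver = "greedy",
) -> ShadowTest:
    """Assemble one optimal shadow test at ability ``theta``.

    The returned set contains every ``forced_in`` item, respects the category
    bounds, total length and any stratum minima, and maximizes summed Fisher
    information at ``theta``; ties are broken toward lower item index so the
    result is deterministic.
    """
    info, codes, n_cats, fidx, xidx, cmin, cmax = _prepare(pool, theta, constraints, constants)
    if solver == "mip":
        sel = milp_core(
            info, codes, n_cats, fidx, xidx, constraints.test_length, cmin, cmax,
            strata0=pool.stratum if constraints.stratum_min else None,
            strat_min=constraints.stratum_min,
        )
    elif constraints.stratum_min:
        sel = stratified_core(
            info, codes, n_cats, pool.stratum, fidx, xidx,
            constraints.test_length, cmin, cmax, constraints.stratum_min,
        )
    else:
        sel = greedy_core(info, codes, n_cats, fidx, xidx, constraints.test_length, cmin, cmax)
    return _to_shadow(pool, sel, theta, info)


def greedy_exact_assemble(
    pool: ItemPool,
    theta: float,
    constraints: AssemblyConstraints,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> ShadowTest:
    """Exact greedy assembly (the default fast path of :func:`assemble`)."""
    return assemble(pool, theta, constraints, constants, solver="greedy")


def assemble_disjoint_pair(
    pool: ItemPool,
    theta: float,
    constraints: AssemblyConstraints,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    solver: Solver = "greedy",
    mode: str = "sequential",
) -> tuple[ShadowTest, ShadowTest]:
    """Assemble two parallel shadow tests that share no unadministered items.

    Already-administered (forced) items appear in both forms.  With
    ``mode="sequential"`` (default) the first form is optimal and the second
    optimal among forms disjoint from it, so the second form carries the
    next-best tier of items; ``mode="joint"`` instead maximizes the summed
    information of the two forms.  The MIP solver cross-checks the joint mode.
    """
    info, codes, n_cats, fidx, xidx, cmin, cmax = _prepare(pool, theta, constraints, constants)
    strata0 = pool.stratum if constraints.stratum_min else None
    if mode == "sequential":
        core = sequential_pair_core if solver == "greedy" else _sequential_pair_milp
    elif mode == "joint":
        core = disjoint_pair_core if solver == "greedy" else disjoint_pair_milp
    else:
        raise ValueError(f"unknown pair mode {mode!r}")
    s1, s2 = core(
        info, codes, n_cats, fidx, xidx, constraints.test_length, cmin, cmax,
        strata0=strata0, strat_min=constraints.stratum_min,
    )
    return _to_shadow(pool, s1, theta, info), _to_shadow(pool, s2, theta, info)


def _sequential_pair_milp(info, cats0, n_cats, forced_idx, excluded_idx, L, cmin, cmax,
                          strata0=None, strat_min=None):
    forced = np.asarray(forced_idx, dtype=int)
    s1 = milp_core(info, cats0, n_cats, forced, excluded_idx, L, cmin, cmax,
                   strata0=strata0, strat_min=strat_min)
    excl2 = np.concatenate([np.asarray(excluded_idx, dtype=int), np.setdiff1d(s1, forced)])
    s2 = milp_core(info, cats0, n_cats, forced, excl2, L, cmin, cmax,
                   strata0=strata0, strat_min=strat_min)
    return s1, s2


def assemble_multi_theta(
    pool: ItemPool,
    theta_hat: float,
    se: float,
    constraints: AssemblyConstraints,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    solver: Solver = "greedy",
) -> tuple[ShadowTest, ShadowTest, ShadowTest]:
    """Three independent forms targeting theta_hat - SE/2, theta_hat and
    theta_hat + SE/2; overlap between forms is permitted."""
    if se <= 0:
        raise ValueError("se must be positive")
    targets = (theta_hat - se / 2.0, theta_hat, theta_hat + se / 2.0)
    return tuple(assemble(pool, t, constraints, constants, solver=solver) for t in targets)
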