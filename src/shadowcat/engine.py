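"""Two-stage variable-length shadow-CAT administration for one examinee.

Each cycle estimates ability from the responses so far (Warm's WLE), then
assembles fresh shadow form(s) at the stage-appropriate full length forced to
contain every administered item, selects the next item per the active policy,
draws a Bernoulli response at the examinee's true ability, re-estimates and
applies the stopping rule.

Stage 1 assembles at the minimum length (32) until that many items have been
given, guaranteeing the core blueprint; Stage 2 re-assembles at the maximum
length (48) and stops as soon as the interim standard error reaches the
target (0.2) or the maximum length is hit.  The final reported ability is
the bounded MLE; the final SE is the Fisher SE at that estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .assembly import (
    AssemblyInfeasibleError,
    greedy_core,
    sequential_pair_core,
    stratified_core,
)
from .irt import DEFAULT_CONSTANTS, ModelConstants, _info, mle_theta, wle_theta
from .policies import (
    PolicyConfig,
    argmax_info,
    candidate_indices,
    pooled_topk_candidates,
    randomesque_pick,
)
from .pool import ItemPool

__all__ = ["TestDesign", "TestRecord", "simulate_response", "stopping_check", "administer_test"]


@dataclass(frozen=True)
class TestDesign:
    """Variable-length two-stage design parameters."""

    min_length: int = 32
    max_length: int = 48
    se_target: float = 0.2
    category_min: int = 8
    category_max: int = 12
    initial_theta: float = 0.0
    initial_se: float = 1.0

    def __post_init__(self) -> None:
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("need 1 <= min_length <= max_length")
        if self.se_target <= 0:
            raise ValueError("se_target must be positive")
        if self.initial_se <= 0:
            raise ValueError("initial_se must be positive")


@dataclass(frozen=True)
class TestRecord:
    """One simulated administration."""

    true_theta: float
    item_sequence: tuple
    responses: tuple
    interim_estimates: tuple  # ordered (theta_hat, se) pairs, one per response
    final_theta_hat: float
    final_se: float
    length: int
    reached_max: bool
    termination: str  # "precision" | "max_length"
    policy: str
    rng_seed: int


def simulate_response(true_theta: float, item, rng: np.random.Generator,
                      constants: ModelConstants = DEFAULT_CONSTANTS) -> int:
    """Bernoulli response draw with success probability P(true_theta)."""
    from .irt import prob_3pl

    p = prob_3pl(true_theta, item, constants)
    return int(rng.random() < p)


def stopping_check(n: int, se: float, design: TestDesign) -> str | None:
    """Variable-length stopping rule applied after the n-th response.

    Returns None to continue, "precision" once the SE target is met at or
    beyond the minimum length, or "max_length" at the length cap.
    """
    if n < design.min_length:
        return None
    if se <= design.se_target:
        return "precision"
    if n >= design.max_length:
        return "max_length"
    return None


def _resolve_rngs(rng, policy_config: PolicyConfig):
    """Derive independent response / selection substreams.

    Passing an int seed gives the order-independence contract: record i is
    identical no matter which examinees ran before it, and the response
    substream does not depend on the policy (paired comparisons)."""
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        resp = np.random.default_rng([seed, 11])
        sel = np.random.default_rng([seed, 13, policy_config.rng_seed])
        return resp, sel, seed
    return rng, rng, -1


def administer_test(
    true_theta: float,
    pool: ItemPool,
    policy_config: PolicyConfig,
    design: TestDesign = TestDesign(),
    rng=0,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    solver: str = "greedy",
) -> TestRecord:
    """Run one complete two-stage shadow-CAT administration.

    ``rng`` may be an integer seed (preferred; spawns independent response and
    selection substreams) or a numpy Generator used for both streams.
    """
    if solver not in ("greedy", "mip"):
        raise ValueError(f"unknown solver {solver!r}")
    resp_rng, sel_rng, seed = _resolve_rngs(rng, policy_config)

    n_pool = len(pool)
    a, b, c, D = pool.a, pool.b, pool.c, constants.D
    cat_labels = np.unique(pool.content_category)
    codes = np.searchsorted(cat_labels, pool.content_category)
    n_cats = len(cat_labels)
    cmin = np.full(n_cats, design.category_min, dtype=int)
    cmax = np.full(n_cats, design.category_max, dtype=int)
    strata = pool.stratum
    kind = policy_config.kind
    no_excl = np.empty(0, dtype=int)
    quotas = policy_config.stratum_quotas or None

    if solver == "mip":  # slow cross-validation path
        from .assembly import _sequential_pair_milp, milp_core

        def single(info_v, forced, L):
            return milp_core(info_v, codes, n_cats, forced, no_excl, L, cmin, cmax,
                             strata0=strata if quotas else None, strat_min=quotas)

        def pair(info_v, forced, L):
            return _sequential_pair_milp(info_v, codes, n_cats, forced, no_excl, L, cmin, cmax,
                                         strata0=strata if quotas else None, strat_min=quotas)
    else:
        if quotas:
            def single(info_v, forced, L):
                return stratified_core(info_v, codes, n_cats, strata, forced, no_excl,
                                       L, cmin, cmax, quotas)
        else:
            def single(info_v, forced, L):
                return greedy_core(info_v, codes, n_cats, forced, no_excl, L, cmin, cmax)

        def pair(info_v, forced, L):
            return sequential_pair_core(info_v, codes, n_cats, forced, no_excl, L, cmin, cmax,
                                        strata0=strata if quotas else None, strat_min=quotas)

    admin: list[int] = []
    in_admin = np.zeros(n_pool, dtype=bool)
    responses: list[int] = []
    interim: list[tuple[float, float]] = []
    theta_hat = design.initial_theta
    se = design.initial_se
    # incremental parameter arrays of administered items
    adm_a = np.empty(design.max_length)
    adm_b = np.empty(design.max_length)
    adm_c = np.empty(design.max_length)

    while True:
        n = len(admin)
        L = design.min_length if n < design.min_length else design.max_length
        forced = np.asarray(admin, dtype=int)
        info = _info(theta_hat, a, b, c, D)

        # --- assemble the policy's shadow form(s) --------------------------
        if kind in ("MFI", "ASTR", "MODIF1"):
            forms = [single(info, forced, L)]
            form_infos = [info]
        elif kind == "MODIF2":
            try:
                s1, s2 = pair(info, forced, L)
                forms = [s1, s2]
            except AssemblyInfeasibleError as exc:
                warnings.warn(
                    f"disjoint pair infeasible at step {n + 1} ({exc}); falling back to a single form",
                    RuntimeWarning,
                )
                forms = [single(info, forced, L)]
            form_infos = [info] * len(forms)
        else:  # MODIF3
            offsets = (-se / 2.0, 0.0, se / 2.0)
            forms, form_infos = [], []
            for off in offsets:
                info_t = info if off == 0.0 else _info(theta_hat + off, a, b, c, D)
                forms.append(single(info_t, forced, L))
                form_infos.append(info_t)

        # --- candidate set and pick ----------------------------------------
        step = n + 1
        want_stratum = None
        if policy_config.stratified:
            want_stratum, k = policy_config.phase_for_step(step)
        else:
            _, k = policy_config.phase_for_step(step)
        if len(forms) == 1:
            unadmin = forms[0][~in_admin[forms[0]]]
            cand = candidate_indices(unadmin, strata, want_stratum)
            if kind == "MFI" or kind == "ASTR":
                j = argmax_info(cand, info)
            else:  # MODIF1
                j = randomesque_pick(cand, info, k, sel_rng)
        else:
            # MODIF2 / MODIF3: pool each form's top-k eligible candidates,
            # ranked at the form's own target ability
            per_form = [f[~in_admin[f]] for f in forms]
            cand = pooled_topk_candidates(per_form, strata, want_stratum, form_infos, k)
            j = int(cand[sel_rng.integers(len(cand))])
        p_true = c[j] + (1.0 - c[j]) / (1.0 + np.exp(-D * a[j] * (true_theta - b[j])))
        u = int(resp_rng.random() < p_true)
        adm_a[n], adm_b[n], adm_c[n] = a[j], b[j], c[j]
        admin.append(j)
        in_admin[j] = True
        responses.append(u)
        n += 1

        # --- re-estimate and check the stopping rule -----------------------
        uu = np.asarray(responses, dtype=float)
        theta_hat = wle_theta(uu, adm_a[:n], adm_b[:n], adm_c[:n], constants)
        ti = float(_info(theta_hat, adm_a[:n], adm_b[:n], adm_c[:n], D).sum())
        se = 1.0 / np.sqrt(ti) if ti > 0 else np.inf
        interim.append((theta_hat, se))
        reason = stopping_check(n, se, design)
        if reason is not None:
            break

    final_theta, _ = mle_theta(uu, adm_a[:n], adm_b[:n], adm_c[:n], constants)
    final_info = float(_info(final_theta, adm_a[:n], adm_b[:n], adm_c[:n], D).sum())
    final_se = 1.0 / np.sqrt(final_info) if final_info > 0 else np.inf

    counts = np.bincount(codes[np.asarray(admin)], minlength=n_cats)
    if not (design.min_length <= n <= design.max_length) or np.any(counts < cmin) or np.any(counts > cmax):
        raise RuntimeError(
            f"blueprint violation in finished test: length {n}, category counts {counts.tolist()}"
        )

    return TestRecord(
        true_theta=float(true_theta),
        item_sequence=tuple(str(i) for i in pool.item_id[np.asarray(admin)]),
        responses=tuple(responses),
        interim_estimates=tuple(interim),
        final_theta_hat=final_theta,
        final_se=final_se,
        length=n,
        reached_max=(reason == "max_length"),
        termination=reason,
        policy=kind,
        rng_seed=seed,
    )
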