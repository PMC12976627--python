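"""Item-selection policies over one or more shadow tests.

Five policies are supported:

* ``MFI``    — deterministic maximum-Fisher-information pick from the single
  shadow form; no discrimination stratification.
* ``ASTR``   — alpha-stratified MFI: early items come from the low-a stratum,
  then the middle stratum, then the whole pool, flattening exposure of
  high-discrimination items.
* ``MODIF1`` — ASTR plus randomesque selection: the next item is drawn
  uniformly from the top-k most informative eligible candidates.
* ``MODIF2`` — randomesque over the pooled PER-FORM top-k candidates of TWO
  parallel forms assembled with no overlap in unadministered items; the
  disjointness guarantees up to 2k distinct candidates at every step.
* ``MODIF3`` — randomesque over the pooled per-form top-k candidates of THREE
  forms targeting theta_hat and theta_hat +/- SE/2; overlap between forms is
  allowed, so candidate sets shrink toward k as the forms converge.

The stratum phases and candidate-set sizes follow a fixed schedule over item
position: items 1-14 from stratum 1 with k=4, items 15-26 from stratum 2 with
k=3, and every later item from the entire pool with k=2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .assembly import ShadowTest
from .irt import DEFAULT_CONSTANTS, ModelConstants, _info
from .pool import ItemPool

__all__ = [
    "POLICY_KINDS",
    "PolicyConfig",
    "SelectionContext",
    "eligible_items",
    "select_mfi",
    "select_randomesque",
    "select_next",
]

POLICY_KINDS = ("MFI", "ASTR", "MODIF1", "MODIF2", "MODIF3")

#: (stratum label or None for all, item count) phases covering Stage 1
DEFAULT_STRATUM_SCHEDULE = ((1, 14), (2, 12), (None, 6))
#: randomesque candidate-set size per phase; the last entry also covers Stage 2
DEFAULT_CANDIDATE_K = (4, 3, 2)

_FORMS_REQUIRED = {"MFI": 1, "ASTR": 1, "MODIF1": 1, "MODIF2": 2, "MODIF3": 3}


@dataclass(frozen=True)
class PolicyConfig:
    """Which selection algorithm to run and its schedules."""

    kind: str
    stratum_schedule: tuple = DEFAULT_STRATUM_SCHEDULE
    candidate_k_schedule: tuple = DEFAULT_CANDIDATE_K
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in POLICY_KINDS:
            raise ValueError(f"unknown policy kind {self.kind!r}; expected one of {POLICY_KINDS}")
        if len(self.candidate_k_schedule) != len(self.stratum_schedule):
            raise ValueError("candidate_k_schedule must align with stratum_schedule phases")
        if any(k < 1 for k in self.candidate_k_schedule):
            raise ValueError("candidate set sizes must be >= 1")
        if any(n < 1 for _, n in self.stratum_schedule):
            raise ValueError("phase item counts must be >= 1")

    @property
    def stratified(self) -> bool:
        return self.kind != "MFI"

    @property
    def randomesque(self) -> bool:
        return self.kind in ("MODIF1", "MODIF2", "MODIF3")

    @property
    def n_forms(self) -> int:
        return _FORMS_REQUIRED[self.kind]

    @property
    def stratum_quotas(self) -> tuple:
        """Per-stratum minimum item counts implied by the schedule, as a tuple
        indexed by stratum label - 1 (phases with no stratum restriction
        contribute nothing).  Stratified policies pass these to the assembler
        so every shadow form can supply the scheduled stratified picks."""
        if not self.stratified:
            return ()
        labels = [s for s, _ in self.stratum_schedule if s is not None]
        if not labels:
            return ()
        quotas = [0] * max(labels)
        for s, count in self.stratum_schedule:
            if s is not None:
                quotas[s - 1] += count
        return tuple(quotas)

    def phase_for_step(self, step_index: int) -> tuple[int | None, int]:
        """Return (eligible stratum or None for all, candidate k) for the item
        about to be selected at 1-based position ``step_index``.  Positions
        past the scheduled phases take the last phase's k with no stratum
        restriction (Stage 2)."""
        if step_index < 1:
            raise ValueError("step_index is 1-based")
        upto = 0
        for (stratum, count), k in zip(self.stratum_schedule, self.candidate_k_schedule):
            upto += count
            if step_index <= upto:
                return stratum, k
        return None, self.candidate_k_schedule[-1]


@dataclass(frozen=True)
class SelectionContext:
    """State handed to the selector: position, current ability estimate and
    the freshly assembled shadow form(s)."""

    step_index: int
    theta_hat: float
    se: float
    administered: tuple
    shadow_forms: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "administered", tuple(self.administered))
        object.__setattr__(self, "shadow_forms", tuple(self.shadow_forms))
        if self.step_index != len(self.administered) + 1:
            raise ValueError("step_index must equal |administered| + 1")
        admin = frozenset(self.administered)
        for form in self.shadow_forms:
            if not admin <= form.item_ids:
                raise ValueError("administered items must be contained in every shadow form")


# ---------------------------------------------------------------------------
# index-level cores
# ---------------------------------------------------------------------------

def candidate_indices(unadmin_idx: np.ndarray, strata: np.ndarray, want_stratum: int | None) -> np.ndarray:
    """Stratum filter with fallback: if restricting to ``want_stratum`` leaves
    nothing, the unfiltered set is returned."""
    if want_stratum is None:
        return unadmin_idx
    mask = strata[unadmin_idx] == want_stratum
    if not mask.any():
        return unadmin_idx
    return unadmin_idx[mask]


def argmax_info(cand_idx: np.ndarray, info: np.ndarray) -> int:
    """Max-information index with ties broken toward the lowest item index."""
    vals = info[cand_idx]
    best = cand_idx[vals == vals.max()]
    return int(best.min())


def topk_indices(cand_idx: np.ndarray, info: np.ndarray, k: int) -> np.ndarray:
    """Top-min(k, n) candidates by (-information, index), deterministic."""
    order = np.lexsort((cand_idx, -info[cand_idx]))
    return cand_idx[order[: min(k, len(cand_idx))]]


def randomesque_pick(cand_idx: np.ndarray, info: np.ndarray, k: int, rng: np.random.Generator) -> int:
    top = topk_indices(cand_idx, info, k)
    return int(top[rng.integers(len(top))])


# ---------------------------------------------------------------------------
# public id-level interface
# ---------------------------------------------------------------------------

def _union_unadministered(context: SelectionContext, pool: ItemPool) -> np.ndarray:
    union: set = set()
    admin = set(context.administered)
    for form in context.shadow_forms:
        union |= form.item_ids - admin
    if not union:
        raise ValueError("no unadministered items remain in any shadow form")
    return np.sort(pool.index_of(sorted(union)))


def eligible_items(context: SelectionContext, config: PolicyConfig, pool: ItemPool) -> frozenset:
    """The candidate set for the next pick: union of unadministered shadow
    items, restricted to the active phase's stratum for stratified policies
    (with fallback to the unfiltered union if the restriction empties it)."""
    idx = _union_unadministered(context, pool)
    stratum = None
    if config.stratified:
        stratum, _ = config.phase_for_step(context.step_index)
    cand = candidate_indices(idx, pool.stratum, stratum)
    return frozenset(str(i) for i in pool.item_id[cand])


def _info_vector(theta: float, pool: ItemPool, constants: ModelConstants) -> np.ndarray:
    return _info(theta, pool.a, pool.b, pool.c, constants.D)


def select_mfi(
    context: SelectionContext,
    pool: ItemPool,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    candidates: frozenset | None = None,
) -> str:
    """Deterministic pick: the candidate with maximum information at the
    current ability estimate (lowest item id on ties)."""
    if candidates is None:
        candidates = frozenset(str(i) for i in pool.item_id[_union_unadministered(context, pool)])
    idx = np.sort(pool.index_of(sorted(candidates)))
    info = _info_vector(context.theta_hat, pool, constants)
    return str(pool.item_id[argmax_info(idx, info)])


def select_randomesque(
    context: SelectionContext,
    pool: ItemPool,
    k: int,
    rng: np.random.Generator,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    candidates: frozenset | None = None,
) -> str:
    """Uniform draw among the top-min(k, n) most informative candidates."""
    if candidates is None:
        candidates = frozenset(str(i) for i in pool.item_id[_union_unadministered(context, pool)])
    idx = np.sort(pool.index_of(sorted(candidates)))
    info = _info_vector(context.theta_hat, pool, constants)
    return str(pool.item_id[randomesque_pick(idx, info, k, rng)])


def pooled_topk_candidates(per_form_unadmin, strata, want_stratum, per_form_info, k) -> np.ndarray:
    """Union of each form's top-k most informative eligible items (index
    level).

    Each form is stratum-filtered separately (with the empty-filter fallback)
    and ranked by the information vector supplied for that form — for
    uncertainty-offset forms that is the information at the form's own target
    ability, so the three forms nominate genuinely different candidates until
    their targets converge.  Duplicates across forms collapse.
    """
    parts = [
        topk_indices(candidate_indices(un, strata, want_stratum), info, k)
        for un, info in zip(per_form_unadmin, per_form_info)
    ]
    return np.unique(np.concatenate(parts))


def select_next(
    context: SelectionContext,
    config: PolicyConfig,
    pool: ItemPool,
    rng: np.random.Generator,
    constants: ModelConstants = DEFAULT_CONSTANTS,
) -> str:
    """Dispatch the next-item choice for the configured policy.

    Single-form policies pick from the form's (stratum-filtered)
    unadministered items — deterministically for MFI/ASTR, randomesque top-k
    for Modification 1.  The multi-form modifications draw uniformly from the
    union of the per-form top-k candidate sets.
    """
    expected = config.n_forms
    if len(context.shadow_forms) != expected:
        raise ValueError(
            f"policy {config.kind} requires {expected} shadow form(s), got {len(context.shadow_forms)}"
        )
    if config.kind in ("MFI", "ASTR"):
        return select_mfi(context, pool, constants, candidates=eligible_items(context, config, pool))
    _, k = config.phase_for_step(context.step_index)
    if config.kind == "MODIF1":
        return select_randomesque(
            context, pool, k, rng, constants, candidates=eligible_items(context, config, pool)
        )
    # MODIF2 / MODIF3: per-form top-k pooled across forms, each form ranked
    # at its own target ability
    admin = set(context.administered)
    want_stratum, _ = config.phase_for_step(context.step_index)
    per_form, per_info = [], []
    for form in context.shadow_forms:
        un = form.item_ids - admin
        if not un:
            continue
        per_form.append(np.sort(pool.index_of(sorted(un))))
        per_info.append(_info_vector(form.theta_target, pool, constants))
    if not per_form:
        raise ValueError("no unadministered items remain in any shadow form")
    cand = pooled_topk_candidates(per_form, pool.stratum, want_stratum, per_info, k)
    return str(pool.item_id[int(cand[rng.integers(len(cand))])])
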