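"""Deterministic miniature pools with analytically known answers.

Each fixture is a small ItemPool plus a manifest of oracle facts (computed
once at fixture-build time, e.g. by exhaustive enumeration) so tests can
assert against frozen expectations instead of recomputing oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .irt import DEFAULT_CONSTANTS, _info
from .pool import ItemPool, assign_strata, write_pool

__all__ = ["FixtureSpec", "make_fixture", "SCHEMES"]

SCHEMES = ("uniform_information", "dominant_category", "symmetric_pair", "low_information")


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    pool_size: int = 12
    n_categories: int = 2
    parameter_scheme: str = "uniform_information"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.parameter_scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.parameter_scheme!r}")
        if self.pool_size < self.n_categories * 2:
            raise ValueError("pool_size must be at least 2 items per category")


def _enumerate_best(pool: ItemPool, theta: float, length: int, cmin: int, cmax: int) -> tuple[float, tuple]:
    """Brute-force optimal subset under per-category bounds (tiny pools only)."""
    info = _info(theta, pool.a, pool.b, pool.c, DEFAULT_CONSTANTS.D)
    cats = pool.content_category
    labels = np.unique(cats)
    best_val, best_set = -np.inf, None
    for combo in combinations(range(len(pool)), length):
        counts = np.array([(cats[list(combo)] == g).sum() for g in labels])
        if np.any(counts < cmin) or np.any(counts > cmax):
            continue
        val = float(info[list(combo)].sum())
        if val > best_val + 1e-12:
            best_val, best_set = val, combo
    if best_set is None:
        raise ValueError("fixture instance is infeasible")
    return best_val, tuple(str(pool.item_id[i]) for i in best_set)


def make_fixture(spec: FixtureSpec, out_dir=None) -> tuple[ItemPool, dict]:
    """Build a fixture pool and its oracle manifest.

    When ``out_dir`` is given, the pool is written as CSV next to a key=value
    manifest text file.  Identical specs yield identical files.
    """
    rng = np.random.default_rng(spec.seed)
    n, g = spec.pool_size, spec.n_categories
    per = n // g
    cats = np.repeat(np.arange(1, g + 1), per)
    cats = np.concatenate([cats, np.arange(1, n - per * g + 1)])  # remainder spread
    ids = np.array([f"fx{str(i + 1).zfill(3)}" for i in range(n)], dtype=object)
    manifest: dict[str, object] = {"name": spec.name, "scheme": spec.parameter_scheme}

    if spec.parameter_scheme == "uniform_information":
        a = np.full(n, 1.0)
        b = np.zeros(n)
        c = np.zeros(n)
        manifest["item_info_at_0"] = 0.25  # 2PL maximum a^2/4
    elif spec.parameter_scheme == "dominant_category":
        a = np.where(cats == 1, 2.0, 0.6) + rng.uniform(-0.05, 0.05, size=n)
        b = rng.uniform(-0.5, 0.5, size=n)
        c = np.zeros(n)
    elif spec.parameter_scheme == "symmetric_pair":
        a = np.full(n, 1.0)
        d = 0.8
        b = np.zeros(n)
        b[0], b[1] = -d, d
        b[2:] = rng.uniform(-1.5, 1.5, size=n - 2)
        c = np.zeros(n)
        manifest["symmetric_items"] = f"{ids[0]},{ids[1]}"
        manifest["wle_of_1_0"] = 0.0  # responses (1,0) on the mirrored pair
    else:  # low_information
        a = np.full(n, 0.2)
        b = rng.uniform(-2.0, 2.0, size=n)
        c = np.full(n, 0.2)
        # even 48 copies of the best such item cannot reach SE 0.2
        max_info = float(_info(np.linspace(-4, 4, 401), a[:1], b[:1], c[:1], 1.0).max())
        manifest["max_single_item_info"] = max_info
        manifest["max_48_item_info"] = 48 * max_info

    pool = assign_strata(ItemPool(ids, a, b, c, cats), k=min(3, n))

    if spec.parameter_scheme in ("uniform_information", "dominant_category") and n <= 16:
        length = 2 * g
        best_val, best_ids = _enumerate_best(pool, 0.0, length, cmin=1, cmax=length - 1)
        manifest["enumerated_length"] = length
        manifest["enumerated_objective"] = best_val
        manifest["enumerated_items"] = ",".join(best_ids)
        if spec.parameter_scheme == "dominant_category":
            dom = sum(1 for i in best_ids if int(pool.content_category[pool.index_of([i])[0]]) == 1)
            manifest["dominant_category_count"] = dom

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_pool(pool, out_dir / f"{spec.name}.csv")
        with open(out_dir / f"{spec.name}.manifest.txt", "w", encoding="utf-8") as fh:
            for key, val in manifest.items():
                fh.write(f"{key}={val}\n")
    return pool, manifest
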