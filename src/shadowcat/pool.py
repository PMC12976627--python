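"""Item pool generation, stratification and plain-text persistence.

The default pool emulates a fixed-form health-professions licensure bank:
360 dichotomous 3PL items, discrimination a ~ N(1.0, 0.4) (non-positive
draws resampled), difficulty b ~ N(0.0, 1.0), guessing c ~ Beta(8, 32),
four content categories of 90 items each.  For discrimination-stratified
item selection the pool is split into equal-size strata by ascending a.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ItemParameters",
    "PoolSpec",
    "ItemPool",
    "generate_pool",
    "assign_strata",
    "read_pool",
    "write_pool",
]

POOL_COLUMNS = ["item_id", "a", "b", "c", "content_category", "stratum"]


@dataclass(frozen=True)
class ItemParameters:
    """One pool item: 3PL parameters plus content and stratum labels."""

    item_id: str
    a: float
    b: float
    c: float
    content_category: int
    stratum: int | None = None

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"item {self.item_id}: discrimination a must be positive, got {self.a}")
        if not 0.0 <= self.c < 1.0:
            raise ValueError(f"item {self.item_id}: guessing c must lie in [0, 1), got {self.c}")


@dataclass(frozen=True)
class PoolSpec:
    """Distributional recipe for a simulated item pool."""

    n_items: int = 360
    a_mean: float = 1.0
    a_sd: float = 0.4
    b_mean: float = 0.0
    b_sd: float = 1.0
    c_alpha: float = 8.0
    c_beta: float = 32.0
    n_categories: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items < 1 or self.n_categories < 1:
            raise ValueError("n_items and n_categories must be positive")
        if self.n_items % self.n_categories != 0:
            raise ValueError(
                f"n_items ({self.n_items}) must be divisible by n_categories ({self.n_categories}) "
                "for equal category sizes"
            )
        if self.a_sd <= 0:
            raise ValueError("a_sd must be positive")
        if self.c_alpha <= 0 or self.c_beta <= 0:
            raise ValueError("Beta parameters for c must be positive")


class ItemPool:
    """A collection of 3PL items held as parallel numpy arrays.

    Attributes
    ----------
    item_id : ndarray of str
    a, b, c : ndarray of float
    content_category : ndarray of int (labels 1..G)
    stratum : ndarray of int (labels 1..K; 0 = unassigned)
    strata_boundaries : the a-values at which strata split (empty if unassigned)
    """

    def __init__(self, item_id, a, b, c, content_category, stratum=None, strata_boundaries=()):
        self.item_id = np.asarray(item_id, dtype=object)
        self.a = np.asarray(a, dtype=float)
        self.b = np.asarray(b, dtype=float)
        self.c = np.asarray(c, dtype=float)
        self.content_category = np.asarray(content_category, dtype=int)
        n = len(self.item_id)
        if stratum is None:
            stratum = np.zeros(n, dtype=int)
        self.stratum = np.asarray(stratum, dtype=int)
        self.strata_boundaries = tuple(float(x) for x in strata_boundaries)
        self._validate()
        self._index = {iid: i for i, iid in enumerate(self.item_id)}

    def _validate(self) -> None:
        n = len(self.item_id)
        for name in ("a", "b", "c", "content_category", "stratum"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has wrong length")
        ids, counts = np.unique(self.item_id.astype(str), return_counts=True)
        if np.any(counts > 1):
            dup = ids[counts > 1][0]
            raise ValueError(f"duplicate item_id {dup!r} in pool")
        if np.any(self.a <= 0):
            row = int(np.flatnonzero(self.a <= 0)[0])
            raise ValueError(f"row {row} (item {self.item_id[row]!r}): a must be positive")
        if np.any((self.c < 0) | (self.c >= 1)):
            row = int(np.flatnonzero((self.c < 0) | (self.c >= 1))[0])
            raise ValueError(f"row {row} (item {self.item_id[row]!r}): c must lie in [0, 1)")

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.item_id)

    @property
    def n_items(self) -> int:
        return len(self.item_id)

    @property
    def categories(self) -> np.ndarray:
        return np.unique(self.content_category)

    def index_of(self, item_ids: Iterable[str]) -> np.ndarray:
        return np.array([self._index[i] for i in item_ids], dtype=int)

    def __getitem__(self, i: int) -> ItemParameters:
        return ItemParameters(
            item_id=str(self.item_id[i]),
            a=float(self.a[i]),
            b=float(self.b[i]),
            c=float(self.c[i]),
            content_category=int(self.content_category[i]),
            stratum=int(self.stratum[i]) or None,
        )

    @property
    def items(self) -> list[ItemParameters]:
        return [self[i] for i in range(len(self))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": self.item_id.astype(str),
                "a": self.a,
                "b": self.b,
                "c": self.c,
                "content_category": self.content_category,
                "stratum": self.stratum,
            }
        )

    def __repr__(self) -> str:  # pragma: no cover
        k = int(self.stratum.max()) if len(self) else 0
        return f"<ItemPool n={len(self)} categories={len(self.categories)} strata={k}>"


def generate_pool(spec: PoolSpec) -> ItemPool:
    """Draw a pool from a PoolSpec's parameter distributions.

    Non-positive discrimination draws are resampled so the a-distribution
    keeps its nominal shape on the positive axis (the mass below zero under
    the default N(1.0, 0.4) is ~6e-3).  Content categories are assigned by a
    random equal partition of the items under the same seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_items
    a = rng.normal(spec.a_mean, spec.a_sd, size=n)
    bad = a <= 0
    while np.any(bad):
        a[bad] = rng.normal(spec.a_mean, spec.a_sd, size=int(bad.sum()))
        bad = a <= 0
    b = rng.normal(spec.b_mean, spec.b_sd, size=n)
    c = rng.beta(spec.c_alpha, spec.c_beta, size=n)
    width = len(str(n))
    item_id = np.array([f"it{str(i + 1).zfill(width)}" for i in range(n)], dtype=object)
    per = n // spec.n_categories
    cats = np.empty(n, dtype=int)
    cats[rng.permutation(n)] = np.repeat(np.arange(1, spec.n_categories + 1), per)
    return ItemPool(item_id, a, b, c, cats)


def assign_strata(pool: ItemPool, k: int = 3) -> ItemPool:
    """Split the pool into ``k`` contiguous strata by ascending discrimination.

    Stratum 1 holds the least discriminating items.  Sizes are equal up to the
    divisibility remainder (earlier strata take the extra item).  Ties in a
    are broken by item_id so the split is deterministic.
    """
    n = len(pool)
    if not 1 <= k <= n:
        raise ValueError(f"stratum count k={k} must lie in [1, {n}]")
    order = np.lexsort((pool.item_id.astype(str), pool.a))
    sizes = np.full(k, n // k, dtype=int)
    sizes[: n % k] += 1
    stratum = np.zeros(n, dtype=int)
    boundaries = []
    start = 0
    for s, size in enumerate(sizes, start=1):
        block = order[start : start + size]
        stratum[block] = s
        if s < k and size > 0:
            boundaries.append(float(pool.a[order[start + size - 1]]))
        start += size
    return ItemPool(
        pool.item_id.copy(),
        pool.a.copy(),
        pool.b.copy(),
        pool.c.copy(),
        pool.content_category.copy(),
        stratum,
        strata_boundaries=boundaries,
    )


def write_pool(pool: ItemPool, path) -> None:
    """Write the pool as comma-delimited UTF-8 text with full float precision."""
    df = pool.to_frame()
    df.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_pool(path) -> ItemPool:
    """Read a pool file, validating the schema and parameter ranges.

    Raises ValueError naming the offending row for malformed rows, duplicate
    ids, or out-of-range parameters.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"item_id": str}, float_precision="round_trip")
    missing = [col for col in POOL_COLUMNS[:5] if col not in df.columns]
    if missing:
        raise ValueError(f"pool file {path} is missing required columns: {missing}")
    if df[["a", "b", "c", "content_category"]].isna().any().any():
        row = int(df[["a", "b", "c", "content_category"]].isna().any(axis=1).idxmax())
        raise ValueError(f"pool file {path}: row {row} has missing or non-numeric values")
    stratum = df["stratum"] if "stratum" in df.columns else None
    boundaries: tuple[float, ...] = ()
    if stratum is not None and (stratum > 0).all():
        # recover split points from the stored labels
        k = int(stratum.max())
        boundaries = tuple(
            float(df.loc[stratum == s, "a"].max()) for s in range(1, k)
        )
    return ItemPool(
        df["item_id"].to_numpy(dtype=object),
        df["a"].to_numpy(dtype=float),
        df["b"].to_numpy(dtype=float),
        df["c"].to_numpy(dtype=float),
        df["content_category"].to_numpy(dtype=int),
        stratum.to_numpy(dtype=int) if stratum is not None else None,
        strata_boundaries=boundaries,
    )
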