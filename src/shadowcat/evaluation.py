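"""Evaluation of simulated CAT administrations.

Computes the dependent measures of the simulation study from a set of
TestRecords: measurement precision (bias, RMSE, average final SE), pool
utilization and exposure control (exposure-rate classes, the chi-square
uniformity index, the pairwise test overlap rate), and test efficiency
(average length, unreached-SE percentage, information accumulated per item).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import TestDesign, TestRecord
from .irt import DEFAULT_CONSTANTS, ModelConstants, _info
from .pool import ItemPool

__all__ = [
    "PrecisionReport",
    "ExposureReport",
    "EfficiencyReport",
    "precision",
    "exposure_report",
    "overlap_rate",
    "efficiency_report",
    "conditional_summaries",
]


@dataclass(frozen=True)
class PrecisionReport:
    bias: float
    rmse: float
    mean_final_se: float

    def to_dict(self) -> dict:
        return {"bias": self.bias, "rmse": self.rmse, "mean_final_se": self.mean_final_se}


@dataclass(frozen=True)
class ExposureReport:
    """Pool-level utilization summary.

    ``exposure_rate`` is a pandas Series indexed by item_id (fraction of
    examinees who saw the item).  Percentages are on the 0-100 scale.  The
    chi-square index measures deviation of exposure rates from the uniform
    ideal L/N (L = mean test length, N = pool size); unused items are a
    subset of the under-exposed class.
    """

    exposure_rate: pd.Series
    over_exposed_pct: float
    under_exposed_pct: float
    unused_pct: float
    chi_square_index: float
    overlap_rate: float
    mean_test_length: float
    pool_size: int

    def to_dict(self) -> dict:
        return {
            "over_exposed_pct": self.over_exposed_pct,
            "under_exposed_pct": self.under_exposed_pct,
            "unused_pct": self.unused_pct,
            "chi_square_index": self.chi_square_index,
            "overlap_rate": self.overlap_rate,
            "mean_test_length": self.mean_test_length,
            "pool_size": self.pool_size,
        }


@dataclass(frozen=True)
class EfficiencyReport:
    mean_test_length: float
    unreached_se_pct: float
    efficiency: float

    def to_dict(self) -> dict:
        return {
            "mean_test_length": self.mean_test_length,
            "unreached_se_pct": self.unreached_se_pct,
            "efficiency": self.efficiency,
        }


def precision(records: Sequence[TestRecord], true_thetas: Sequence[float] | None = None) -> PrecisionReport:
    """Bias = mean(theta_hat - theta); RMSE = sqrt(mean squared error);
    plus the average Fisher SE at the final estimates."""
    if len(records) == 0:
        raise ValueError("need at least one record")
    est = np.array([r.final_theta_hat for r in records])
    if true_thetas is None:
        true = np.array([r.true_theta for r in records])
    else:
        true = np.asarray(true_thetas, dtype=float)
        if true.shape[0] != est.shape[0]:
            raise ValueError(f"{est.shape[0]} records but {true.shape[0]} true abilities")
    err = est - true
    ses = np.array([r.final_se for r in records])
    return PrecisionReport(
        bias=float(err.mean()),
        rmse=float(np.sqrt((err**2).mean())),
        mean_final_se=float(ses.mean()),
    )


def _administration_counts(records: Sequence[TestRecord], pool: ItemPool) -> np.ndarray:
    counts = np.zeros(len(pool), dtype=np.int64)
    for r in records:
        counts[pool.index_of(r.item_sequence)] += 1
    return counts


def overlap_rate(records: Sequence[TestRecord]) -> float:
    """Expected proportion of shared items between two random examinees.

    Computed in closed form over all pairs: sum_j C(n_j, 2) / (C(m, 2) * Lbar)
    where n_j counts examinees who saw item j.  This is the exact expectation
    of |A intersect B| / Lbar over uniformly chosen examinee pairs.
    """
    m = len(records)
    if m < 2:
        raise ValueError("overlap rate needs at least two records")
    counts: dict[str, int] = {}
    total_items = 0
    for r in records:
        total_items += r.length
        for iid in r.item_sequence:
            counts[iid] = counts.get(iid, 0) + 1
    lbar = total_items / m
    n = np.array(list(counts.values()), dtype=float)
    shared_pairs = float((n * (n - 1) / 2.0).sum())
    all_pairs = m * (m - 1) / 2.0
    return shared_pairs / (all_pairs * lbar)


def exposure_report(
    records: Sequence[TestRecord],
    pool: ItemPool,
    thresholds: tuple[float, float] = (0.3, 0.02),
) -> ExposureReport:
    """Per-item exposure rates with over/under/unused classification and the
    chi-square uniformity index chi2 = sum_j (er_j - L/N)^2 / (L/N)."""
    if len(records) == 0:
        raise ValueError("need at least one record")
    over_thr, under_thr = thresholds
    m = len(records)
    counts = _administration_counts(records, pool)
    er = counts / m
    lbar = float(np.mean([r.length for r in records]))
    n_pool = len(pool)
    ideal = lbar / n_pool
    chi2 = float((((er - ideal) ** 2) / ideal).sum())
    return ExposureReport(
        exposure_rate=pd.Series(er, index=pool.item_id.astype(str), name="exposure_rate"),
        over_exposed_pct=float((er > over_thr).mean() * 100.0),
        under_exposed_pct=float((er < under_thr).mean() * 100.0),
        unused_pct=float((counts == 0).mean() * 100.0),
        chi_square_index=chi2,
        overlap_rate=overlap_rate(records) if m >= 2 else 1.0,
        mean_test_length=lbar,
        pool_size=n_pool,
    )


def efficiency_report(
    records: Sequence[TestRecord],
    design: TestDesign,
    pool: ItemPool,
    constants: ModelConstants = DEFAULT_CONSTANTS,
    information_at: str = "final",
) -> EfficiencyReport:
    """Efficiency = sum_i TI_i / sum_i L_i, the average test information
    accumulated per administered item, with TI_i evaluated at examinee i's
    final estimate (``information_at="final"``) or true ability ("true")."""
    if len(records) == 0:
        raise ValueError("need at least one record")
    if information_at not in ("final", "true"):
        raise ValueError("information_at must be 'final' or 'true'")
    total_info = 0.0
    total_len = 0
    for r in records:
        idx = pool.index_of(r.item_sequence)
        theta = r.final_theta_hat if information_at == "final" else r.true_theta
        total_info += float(_info(theta, pool.a[idx], pool.b[idx], pool.c[idx], constants.D).sum())
        total_len += r.length
    ses = np.array([r.final_se for r in records])
    return EfficiencyReport(
        mean_test_length=total_len / len(records),
        unreached_se_pct=float((ses > design.se_target).mean() * 100.0),
        efficiency=total_info / total_len,
    )


def conditional_summaries(
    records: Sequence[TestRecord],
    design: TestDesign = TestDesign(),
) -> pd.DataFrame:
    """Per-ability-level summaries for records generated at fixed theta levels.

    Groups records by their true theta and returns one row per level with
    bias, RMSE, mean final SE, mean test length and the percentage reaching
    the maximum length.  Levels with no records are simply absent.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    by_level: dict[float, list[TestRecord]] = {}
    for r in records:
        by_level.setdefault(round(r.true_theta, 10), []).append(r)
    rows = []
    for level in sorted(by_level):
        recs = by_level[level]
        p = precision(recs)
        rows.append(
            {
                "theta_level": level,
                "n": len(recs),
                "bias": p.bias,
                "rmse": p.rmse,
                "mean_final_se": p.mean_final_se,
                "mean_test_length": float(np.mean([r.length for r in recs])),
                "pct_reached_max": float(np.mean([r.reached_max for r in recs]) * 100.0),
            }
        )
    return pd.DataFrame(rows)
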