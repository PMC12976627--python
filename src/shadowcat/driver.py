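"""Study orchestration: overall and conditional simulations.

Runs a set of selection policies over a common examinee sample (identical
true abilities and response substreams across policies, so policy contrasts
are paired), then summarizes precision, pool utilization and efficiency per
policy in the layout of the study's summary tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .engine import TestDesign, TestRecord, administer_test
from .evaluation import (
    conditional_summaries,
    efficiency_report,
    exposure_report,
    precision,
)
from .irt import DEFAULT_CONSTANTS, ModelConstants
from .policies import POLICY_KINDS, PolicyConfig
from .pool import ItemPool, PoolSpec, assign_strata, generate_pool, read_pool

__all__ = ["StudyConfig", "run_overall", "run_conditional", "records_to_frame", "summarize_policy"]

logger = logging.getLogger("shadowcat")

DEFAULT_LEVELS = tuple(np.round(np.arange(-3.0, 3.01, 0.5), 1))


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one simulation study."""

    pool_path: str | None = None
    pool_spec: PoolSpec = field(default_factory=PoolSpec)
    policies: tuple = POLICY_KINDS
    overall_n: int = 50_000
    conditional_levels: tuple = DEFAULT_LEVELS
    per_level_n: int = 500
    design: TestDesign = field(default_factory=TestDesign)
    master_seed: int = 1
    solver: str = "greedy"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.overall_n < 1 or self.per_level_n < 1:
            raise ValueError("sample sizes must be >= 1")
        unknown = set(self.policies) - set(POLICY_KINDS)
        if unknown:
            raise ValueError(f"unknown policies {sorted(unknown)}")
        levels = list(self.conditional_levels)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("conditional levels must be strictly increasing")

    def load_pool(self) -> ItemPool:
        if self.pool_path is not None:
            pool = read_pool(self.pool_path)
            if not (pool.stratum > 0).all():
                pool = assign_strata(pool, k=3)
            return pool
        return assign_strata(generate_pool(self.pool_spec), k=3)


def _examinee_seed(master_seed: int, examinee_index: int) -> int:
    # order-independent substream key, kept below 2**31
    return int(np.random.SeedSequence([master_seed, examinee_index]).generate_state(1)[0] % (2**31))


def _simulate_policy(
    pool: ItemPool,
    policy: str,
    thetas: np.ndarray,
    design: TestDesign,
    master_seed: int,
    solver: str,
    constants: ModelConstants,
) -> list[TestRecord]:
    config = PolicyConfig(kind=policy)
    records: list[TestRecord] = []
    running_len = 0.0
    for i, theta in enumerate(thetas):
        rec = administer_test(
            float(theta), pool, config, design,
            rng=_examinee_seed(master_seed, i),
            constants=constants, solver=solver,
        )
        records.append(rec)
        running_len += rec.length
        if (i + 1) % 1000 == 0:
            seen = {iid for r in records for iid in r.item_sequence}
            logger.info(
                "%s: %d examinees, running mean length %.2f, unused items %d",
                policy, i + 1, running_len / (i + 1), len(pool) - len(seen),
            )
    return records


def records_to_frame(records: Sequence[TestRecord]) -> pd.DataFrame:
    """One row per examinee: the flat results file."""
    return pd.DataFrame(
        {
            "true_theta": [r.true_theta for r in records],
            "final_theta_hat": [r.final_theta_hat for r in records],
            "final_se": [r.final_se for r in records],
            "length": [r.length for r in records],
            "reached_max": [r.reached_max for r in records],
            "termination": [r.termination for r in records],
            "policy": [r.policy for r in records],
            "seed": [r.rng_seed for r in records],
        }
    )


def items_long_frame(records: Sequence[TestRecord]) -> pd.DataFrame:
    """Companion long-format file: one row per administered item."""
    rows = []
    for i, r in enumerate(records):
        for pos, (iid, u) in enumerate(zip(r.item_sequence, r.responses), start=1):
            rows.append((i, pos, iid, u))
    return pd.DataFrame(rows, columns=["examinee", "position", "item_id", "response"])


def summarize_policy(records, pool, design, constants=DEFAULT_CONSTANTS) -> dict:
    """All summary-table quantities for one policy's record set."""
    prec = precision(records)
    expo = exposure_report(records, pool)
    eff = efficiency_report(records, design, pool, constants)
    return {
        "n_examinees": len(records),
        **prec.to_dict(),
        **expo.to_dict(),
        **eff.to_dict(),
    }


def _write_policy_outputs(out_dir: Path, policy: str, records, pool, summary: dict) -> None:
    pdir = out_dir / policy.lower()
    pdir.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(pdir / "records.csv", index=False)
    items_long_frame(records).to_csv(pdir / "items_long.csv", index=False)
    expo = exposure_report(records, pool)
    counts = (expo.exposure_rate * len(records)).round().astype(int)
    klass = np.where(
        counts == 0, "unused",
        np.where(expo.exposure_rate > 0.3, "over",
                 np.where(expo.exposure_rate < 0.02, "under", "ok")),
    )
    pd.DataFrame(
        {"item_id": expo.exposure_rate.index, "count": counts.to_numpy(),
         "rate": expo.exposure_rate.to_numpy(), "class": klass}
    ).to_csv(pdir / "exposure.csv", index=False)
    pd.DataFrame([summary]).to_csv(pdir / "summary.csv", index=False)


def _write_manifest(out_dir: Path, config: StudyConfig, kind: str) -> None:
    manifest = {
        "study": kind,
        "version": __version__,
        "master_seed": config.master_seed,
        "solver": config.solver,
        "policies": list(config.policies),
        "design": asdict(config.design),
        "pool": config.pool_path or asdict(config.pool_spec),
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def run_overall(config: StudyConfig, constants: ModelConstants = DEFAULT_CONSTANTS) -> dict:
    """Simulate the overall N(0, 1) examinee sample under each policy.

    Returns {policy: {"records": [...], "summary": {...}}}; when
    ``config.out_dir`` is set, per-policy CSVs and a run manifest are written.
    """
    pool = config.load_pool()
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 0]))
    thetas = rng.normal(0.0, 1.0, size=config.overall_n)
    out: dict[str, dict] = {}
    out_dir = Path(config.out_dir) if config.out_dir else None
    for policy in config.policies:
        logger.info("overall study: policy %s, n=%d", policy, config.overall_n)
        records = _simulate_policy(
            pool, policy, thetas, config.design, config.master_seed, config.solver, constants
        )
        summary = summarize_policy(records, pool, config.design, constants)
        out[policy] = {"records": records, "summary": summary}
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            _write_policy_outputs(out_dir, policy, records, pool, summary)
    if out_dir is not None:
        _write_manifest(out_dir, config, "overall")
        pd.DataFrame(
            [{"policy": p, **d["summary"]} for p, d in out.items()]
        ).to_csv(out_dir / "summary_by_policy.csv", index=False)
    return out


def run_conditional(config: StudyConfig, constants: ModelConstants = DEFAULT_CONSTANTS) -> dict:
    """Simulate fixed-ability populations at each conditional level.

    Returns {policy: {"records": [...], "summary": DataFrame}} with one
    summary row per level (bias, RMSE, mean length, percent reaching the
    maximum length — the conditional quantities of the study).
    """
    pool = config.load_pool()
    levels = np.asarray(config.conditional_levels, dtype=float)
    thetas = np.repeat(levels, config.per_level_n)
    out: dict[str, dict] = {}
    out_dir = Path(config.out_dir) if config.out_dir else None
    for policy in config.policies:
        logger.info("conditional study: policy %s, %d levels x n=%d",
                    policy, len(levels), config.per_level_n)
        records = _simulate_policy(
            pool, policy, thetas, config.design, config.master_seed, config.solver, constants
        )
        summary = conditional_summaries(records, config.design)
        out[policy] = {"records": records, "summary": summary}
        if out_dir is not None:
            pdir = out_dir / policy.lower()
            pdir.mkdir(parents=True, exist_ok=True)
            records_to_frame(records).to_csv(pdir / "records.csv", index=False)
            summary.to_csv(pdir / "conditional_summary.csv", index=False)
    if out_dir is not None:
        _write_manifest(out_dir, config, "conditional")
    return out
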