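"""Evaluation measures: precision, exposure, overlap, efficiency."""

import numpy as np
import pytest

from shadowcat.engine import TestDesign, TestRecord
from shadowcat.evaluation import (
    conditional_summaries,
    efficiency_report,
    exposure_report,
    overlap_rate,
    precision,
)
from shadowcat.irt import ModelConstants, _info
from shadowcat.pool import ItemPool, assign_strata

K = ModelConstants()


def rec(true_theta=0.0, items=("i1", "i2"), responses=None, final=0.0, se=0.2,
        policy="MFI", reached_max=False):
    items = tuple(items)
    if responses is None:
        responses = tuple(1 for _ in items)
    return TestRecord(
        true_theta=true_theta, item_sequence=items, responses=tuple(responses),
        interim_estimates=(), final_theta_hat=final, final_se=se, length=len(items),
        reached_max=reached_max, termination="max_length" if reached_max else "precision",
        policy=policy, rng_seed=0,
    )


def small_pool(ids=("i1", "i2", "i3", "i4")):
    n = len(ids)
    return ItemPool(
        np.array(ids, dtype=object), np.ones(n), np.zeros(n), np.zeros(n),
        np.arange(n) % 2 + 1,
    )


class TestPrecision:
    def test_perfect_recovery(self):
        records = [rec(true_theta=0.5, final=0.5), rec(true_theta=-1.0, final=-1.0)]
        p = precision(records)
        assert p.bias == 0.0 and p.rmse == 0.0

    def test_hand_arithmetic(self):
        records = [rec(true_theta=0.0, final=0.1), rec(true_theta=0.0, final=-0.1)]
        p = precision(records)
        assert p.bias == pytest.approx(0.0)
        assert p.rmse == pytest.approx(0.1)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(0)
        true = rng.normal(size=1000)
        err = rng.normal(scale=0.2, size=1000)
        records = [rec(true_theta=t, final=t + e) for t, e in zip(true, err)]
        p = precision(records)
        assert p.bias == pytest.approx(err.mean())
        assert p.rmse == pytest.approx(np.sqrt((err**2).mean()))

    def test_rmse_decomposition_identity(self):
        rng = np.random.default_rng(1)
        err = rng.normal(0.05, 0.3, size=500)
        records = [rec(true_theta=0.0, final=e) for e in err]
        p = precision(records)
        assert p.rmse**2 == pytest.approx(p.bias**2 + err.var(), abs=1e-10)

    def test_mismatched_truths_rejected(self):
        with pytest.raises(ValueError):
            precision([rec()], true_thetas=[0.0, 1.0])


class TestExposure:
    def test_hand_example(self):
        """2 examinees on a 4-item pool with tests {i1,i2} and {i1,i3}."""
        pool = small_pool()
        records = [rec(items=("i1", "i2")), rec(items=("i1", "i3"))]
        er = exposure_report(records, pool)
        assert list(er.exposure_rate) == [1.0, 0.5, 0.5, 0.0]
        assert er.unused_pct == pytest.approx(25.0)
        # hand substitution: L=2, N=4, ideal=0.5
        chi2 = ((1.0 - 0.5) ** 2 + 0.0 + 0.0 + (0.0 - 0.5) ** 2) / 0.5
        assert er.chi_square_index == pytest.approx(chi2)

    def test_uniform_exposure_gives_zero_chi2(self):
        pool = small_pool()
        records = [rec(items=("i1", "i2")), rec(items=("i3", "i4"))]
        er = exposure_report(records, pool)
        assert er.chi_square_index == pytest.approx(0.0)

    def test_any_perturbation_increases_chi2(self):
        pool = small_pool()
        uniform = [rec(items=("i1", "i2")), rec(items=("i3", "i4"))]
        perturbed = [rec(items=("i1", "i2")), rec(items=("i1", "i4"))]
        assert (
            exposure_report(perturbed, pool).chi_square_index
            > exposure_report(uniform, pool).chi_square_index
        )

    def test_counting_conservation(self, default_pool):
        """sum_j er_j * m equals the total number of administered items."""
        rng = np.random.default_rng(2)
        records = []
        for _ in range(50):
            n = int(rng.integers(32, 49))
            items = tuple(str(i) for i in rng.choice(default_pool.item_id, n, replace=False))
            records.append(rec(items=items))
        er = exposure_report(records, default_pool)
        total = sum(r.length for r in records)
        assert er.exposure_rate.sum() * len(records) == pytest.approx(total)
        assert er.mean_test_length == pytest.approx(total / len(records))

    def test_thresholds_are_strict(self):
        pool = small_pool(tuple(f"i{k}" for k in range(1, 11)))
        # one examinee: each administered item has rate exactly 1.0 > 0.3;
        # rate-0 items are < 0.02 and unused
        records = [rec(items=("i1", "i2"))]
        er = exposure_report(records, pool)
        assert er.over_exposed_pct == pytest.approx(20.0)
        assert er.under_exposed_pct == pytest.approx(80.0)
        assert er.unused_pct == pytest.approx(80.0)
        assert er.unused_pct <= er.under_exposed_pct  # unused nested in under


class TestOverlap:
    def test_identical_tests_full_overlap(self):
        records = [rec(items=("i1", "i2", "i3"))] * 4
        assert overlap_rate(records) == pytest.approx(1.0)

    def test_disjoint_tests_zero_overlap(self):
        records = [rec(items=("i1", "i2")), rec(items=("i3", "i4"))]
        assert overlap_rate(records) == pytest.approx(0.0)

    def test_closed_form_matches_pair_sampling(self, default_pool):
        """The all-pairs closed form agrees with Monte-Carlo sampling of
        random examinee pairs."""
        rng = np.random.default_rng(3)
        records = []
        for _ in range(50):
            items = tuple(str(i) for i in rng.choice(default_pool.item_id, 40, replace=False))
            records.append(rec(items=items))
        exact = overlap_rate(records)
        lbar = np.mean([r.length for r in records])
        sets = [set(r.item_sequence) for r in records]
        draws = rng.integers(0, 50, size=(100_000, 2))
        draws = draws[draws[:, 0] != draws[:, 1]]
        mc = np.mean([len(sets[i] & sets[j]) / lbar for i, j in draws])
        assert exact == pytest.approx(mc, abs=0.005)

    def test_needs_two_records(self):
        with pytest.raises(ValueError):
            overlap_rate([rec()])


class TestEfficiency:
    def test_ratio_identity(self):
        # two items each contributing 0.25 information at theta=0 (a=1, c=0, D=1)
        pool = small_pool(("i1", "i2"))
        records = [rec(items=("i1", "i2"), final=0.0)]
        eff = efficiency_report(records, TestDesign(), pool, ModelConstants(D=1.0))
        assert eff.efficiency == pytest.approx(0.25)

    def test_se_information_identity(self):
        """Records at exactly the SE target with length 32 give efficiency
        (1/0.2^2)/32."""
        n = 32
        pool = ItemPool(
            np.array([f"x{k}" for k in range(n)], dtype=object),
            np.ones(n), np.zeros(n), np.zeros(n), np.ones(n, dtype=int),
        )
        # scale a so total information at theta=0 is exactly 25
        scale = np.sqrt(25 / (n * 0.25))
        pool = ItemPool(pool.item_id, np.full(n, scale), pool.b, pool.c,
                        pool.content_category)
        records = [rec(items=tuple(pool.item_id), final=0.0, se=0.2)]
        eff = efficiency_report(records, TestDesign(), pool, ModelConstants(D=1.0))
        assert eff.efficiency == pytest.approx(25 / 32, abs=1e-9)

    def test_unreached_classification(self):
        pool = small_pool()
        records = [rec(items=("i1", "i2"), se=0.25), rec(items=("i3", "i4"), se=0.30)]
        eff = efficiency_report(records, TestDesign(), pool)
        assert eff.unreached_se_pct == pytest.approx(100.0)

    def test_information_at_true_theta_option(self, default_pool):
        items = tuple(str(i) for i in default_pool.item_id[:40])
        records = [rec(true_theta=1.0, items=items, final=0.3)]
        e_final = efficiency_report(records, TestDesign(), default_pool, K, "final")
        e_true = efficiency_report(records, TestDesign(), default_pool, K, "true")
        idx = default_pool.index_of(items)
        want_true = _info(1.0, default_pool.a[idx], default_pool.b[idx],
                          default_pool.c[idx], K.D).sum() / 40
        assert e_true.efficiency == pytest.approx(want_true)
        assert e_final.efficiency != e_true.efficiency


class TestConditional:
    def test_thirteen_levels(self):
        levels = np.round(np.arange(-3, 3.01, 0.5), 1)
        records = [rec(true_theta=float(lv), final=float(lv)) for lv in levels for _ in range(3)]
        df = conditional_summaries(records)
        assert len(df) == 13
        assert list(df["n"]) == [3] * 13

    def test_per_level_quantities(self):
        records = (
            [rec(true_theta=0.0, final=0.1, items=("i1", "i2"))] * 2
            + [rec(true_theta=1.0, final=1.0, items=("i1", "i2", "i3"), reached_max=True)]
        )
        df = conditional_summaries(records).set_index("theta_level")
        assert df.loc[0.0, "bias"] == pytest.approx(0.1)
        assert df.loc[0.0, "pct_reached_max"] == 0.0
        assert df.loc[1.0, "pct_reached_max"] == 100.0
        assert df.loc[1.0, "mean_test_length"] == 3.0

    def test_empty_level_absent(self):
        records = [rec(true_theta=0.0)]
        df = conditional_summaries(records)
        assert list(df["theta_level"]) == [0.0]
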