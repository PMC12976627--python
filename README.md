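# shadowcat

A simulator for **variable-length computerized adaptive testing (CAT) under
the shadow-test approach**, built for studying item-pool utilization and
exposure control in high-stakes (e.g. health-professions licensure)
examinations.

In shadow CAT, every item selection is preceded by assembling a complete,
blueprint-feasible test — the *shadow test* — that contains all items already
administered and maximizes Fisher information at the current ability
estimate θ̂ under the content constraints; the next item is then drawn from
its unadministered part.  This guarantees the finished test always satisfies
the blueprint.  In a variable-length design (stop at target SE or maximum
length), the deterministic maximum-information variant leaves a third of a
realistic item bank unused.  `shadowcat` implements five selection policies
spanning that trade-off:

| policy | selection rule |
|---|---|
| `MFI` | deterministic maximum Fisher information |
| `ASTR` | α-stratified MFI (low-discrimination items first: 14 from stratum 1, 12 from stratum 2, rest unrestricted) |
| `MODIF1` | ASTR + randomesque: uniform draw among the top-k candidates (k = 4/3/2 by phase) |
| `MODIF2` | two parallel shadow forms sharing no unadministered items; per-form top-k candidates pooled |
| `MODIF3` | three forms at θ̂ and θ̂ ± SE/2 (overlap allowed); per-form top-k pooled |

Items follow the 3PL model `P(θ) = c + (1−c)/(1+exp(−Da(θ−b)))`; interim
ability is estimated by Warm's weighted likelihood estimator, final ability
by MLE bounded to [−4, 4]; tests run between 32 and 48 items with an SE 0.2
stopping target and 8–12 items per each of 4 content categories.  Shadow
tests are assembled by exact specialized solvers (with a
`scipy.optimize.milp` branch-and-bound backend as cross-check), fast enough
for the ~10⁶ assemblies of a full study.  See `docs/methods.md` for the
model and algorithm details.

## Worked example

```python
import shadowcat as sc

pool = sc.assign_strata(sc.generate_pool(sc.PoolSpec(seed=0)), k=3)
rec = sc.administer_test(0.5, pool, sc.PolicyConfig("MODIF2"), sc.TestDesign(), rng=42)
print(rec.length, round(rec.final_theta_hat, 3), round(rec.final_se, 3), rec.termination)
```

```
40 0.22 0.199 precision
```

One simulated examinee of true ability θ = 0.5 took a 40-item test that
stopped on the precision rule (interim SE reached the 0.2 target) and was
scored 0.22 by bounded MLE, with a final Fisher SE of 0.199.

A small study from the command line:

```bash
shadowcat simulate --policy mfi --n 1000 --seed 1 --out results/mfi
shadowcat simulate --policy modif2 --n 1000 --seed 1 --out results/modif2
```

prints one summary line per policy (`--policy all` runs all five):

```
MFI: bias=+0.008 rmse=0.201 mean_se=0.193 length=34.4 unused=39.2% chi2=79.348 overlap=31.5%
MODIF2: bias=+0.001 rmse=0.225 mean_se=0.209 length=41.6 unused=16.9% chi2=49.271 overlap=25.2%
```

— the exposure-control modification administers ~7 more items on average but
leaves far fewer pool items unused, with more uniform exposure (lower χ²
uniformity index and pairwise test overlap).  Per-policy `records.csv`,
`items_long.csv`, `exposure.csv` and `summary.csv` land under `--out`.
Other verbs: `generate-pool`, `conditional` (fixed ability levels),
`evaluate` (re-summarize saved records).

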