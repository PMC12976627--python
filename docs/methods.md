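# Methods

This note documents the models, algorithms and design choices behind
`shadowcat`, a simulator for variable-length computerized adaptive testing
(CAT) under the shadow-test approach to automated test assembly.

## Measurement model

Items follow the three-parameter logistic (3PL) IRT model

    P_j(θ) = c_j + (1 − c_j) / (1 + exp(−D a_j (θ − b_j)))

with discrimination `a_j > 0`, difficulty `b_j`, lower asymptote
(pseudo-guessing) `c_j ∈ [0, 1)` and scaling constant `D`.  Fisher
information is

    I_j(θ) = D² a_j² (Q_j / P_j) ((P_j − c_j) / (1 − c_j))²,  Q_j = 1 − P_j,

test information is the sum over administered items, and the standard error
of an ability estimate is `SE = 1/√I`.

**Scaling constant.** The package default is `D = 1.7` (normal-ogive
metric).  This is the scale on which the default item pool (below) supports
the design's stopping rule: with `D = 1.7` the maximum-information policy
terminates after 33–34 items on average at the SE 0.2 target, whereas on the
raw logistic scale (`D = 1.0`) the same pool cannot reach SE 0.2 within 48
items for any examinee and every test runs to the cap.  `D` is configurable
through `ModelConstants`.

## Ability estimation

*Interim* estimates use Warm's weighted likelihood estimator (WLE): the root
of

    W(θ) = S(θ) + J(θ) / (2 I(θ)),   S = Σ (u_j − P_j) P'_j/(P_j Q_j),
    J = Σ P'_j P''_j / (P_j Q_j),

which is finite for all-correct and all-incorrect patterns and less biased
than plain ML at CAT-typical test lengths.  *Final* estimates use maximum
likelihood restricted to [−4, 4], with an `at_bound` flag when the optimum
sits on an endpoint.

Numerically, both estimators evaluate their criterion on an 81-point grid
over the bounds, rank all derivative down-crossings by objective height (the
3PL likelihood can be multimodal; for the WLE the objective has no closed
form and is recovered as the trapezoid integral of `W`), and refine the
winning bracket with four rounds of 10-fold batched bisection plus a secant
step (~1e−7 resolution on θ).  Tests verify agreement with independent
dense-grid maximizers to 1e−4.

The interim SE is defined as the Fisher SE at the interim WLE estimate; it
drives both the stopping rule and the uncertainty-offset form targets.  The
final reported SE is the Fisher SE at the final bounded-ML estimate.

## Item pool

The default pool emulates a fixed-form health-professions licensure bank:
360 items, `a ~ N(1.0, 0.4)` (non-positive draws resampled; ~0.6% of mass),
`b ~ N(0, 1)`, `c ~ Beta(8, 32)` (mean 0.2), four content categories of 90
items assigned by a random equal partition.  For stratified selection the
pool is split into three equal strata by ascending `a` (ties broken by item
id).  Pool generation is fully seeded; identical spec + seed give
bit-identical pool files.

## Shadow-test assembly

Before each item is selected, a full-length shadow test is assembled that
contains every already-administered item, satisfies the content blueprint
(8–12 items per category; total length 32 in Stage 1, 48 in Stage 2),
optionally satisfies per-stratum minimum counts, and maximizes summed Fisher
information at the current ability estimate.  The next item is picked from
the form's unadministered part, which structurally guarantees the finished
test meets the blueprint — the defining property of the shadow-test
approach.

Two solver backends produce identical objectives (verified against each
other and against exhaustive enumeration in the tests):

* **Exact greedy / DP (default).**  With category bounds only, optimal
  assembly reduces to choosing per-category counts; since within-category
  marginal gains are non-increasing (items sorted by information), a
  steepest-ascent fill is exact.  With stratum minima added, the default
  blueprint pins per-category counts exactly (4×8 = 32, 4×12 = 48), and the
  per-category split across (constrained stratum × category) cells is solved
  by an exhaustive dynamic programme over residual stratum demand (states
  capped at the quota), which is likewise exact.  The DP kernel is
  JIT-compiled; a full simulation performs ~10⁵–10⁶ assemblies.
  Configurations outside these classes (non-pinned category counts with
  quotas, more than two constrained strata) fall through to the MIP backend.
* **MIP.**  Binary inclusion indicators solved by HiGHS branch-and-bound
  (`scipy.optimize.milp`).  Slow path; retained as the independent oracle
  and for future constraint classes.

**Stratum quotas in the model.**  For the stratified policies the assembly
model carries minimum counts of 14 stratum-1 and 12 stratum-2 items
(matching the selection schedule).  Without them an information-maximal
shadow test contains no low-discrimination items at all, the stratum filter
at selection is always empty, and stratified selection silently degenerates
to maximum-information selection; with them the early selections genuinely
come from the low strata and the characteristic longer tests and flatter
exposure of α-stratification emerge.

**Parallel disjoint forms.**  Modification 2 needs two forms sharing no
unadministered items.  The default is sequential assembly: form 1 is the
single-form optimum; form 2 is the optimum among forms disjoint from it, and
therefore carries the next tier of items — this depth is what diversifies
the candidate pool.  A jointly-optimal mode (`mode="joint"`, maximizing the
summed information; solved exactly by doubling the single-form problem and
splitting per cell, with a rounding that keeps both forms feasible) is also
provided and is the variant cross-checked against a joint 2N-variable MIP.
If the disjoint pair is infeasible the engine falls back to a single form
for that step with a warning.

## Selection policies

Stage 1 phase schedule (stratified policies): items 1–14 from stratum 1 with
randomesque k = 4, items 15–26 from stratum 2 with k = 3, items 27–32 from
the whole pool with k = 2; Stage 2 keeps k = 2.  If the stratum filter
empties a form's candidate set, the unfiltered set is used.

* **MFI** — deterministic maximum-information pick; ignores strata.
* **ASTR** — deterministic maximum-information pick within the phase's
  stratum.
* **MODIF1** — uniform draw among the top-k eligible candidates of the
  single form.
* **MODIF2** — two disjoint forms; candidates are the union of each form's
  own top-k (deduplicated), so up to 2k distinct candidates per step.
* **MODIF3** — three forms at θ̂ and θ̂ ± SE/2 (overlap allowed); candidates
  are the union of each form's top-k ranked at that form's own target, so
  the candidate set shrinks toward k as the targets converge.

The per-form pooling rule matters: ranking a disjoint pair's union by a
single information vector lets form 1's items dominate every top-k and
collapses Modification 2 onto Modification 1.  Per-form pooling is also the
only reading under which the multi-form methods have the larger candidate
sets that motivate them.

Tie-breaks are deterministic everywhere: equal-information items sort by
item index, and randomness enters only through the seeded randomesque draw.

## Administration loop

Each cycle: estimate θ̂ by WLE from the responses so far (θ̂ = 0, SE = 1.0
before the first response — the examinee population's prior SD), assemble
the policy's shadow form(s) at the stage length (32 until 32 items are
administered, then 48), select the next item, draw a Bernoulli response at
the true θ, re-estimate, and apply the stopping rule: continue until 32
items; stop at SE ≤ 0.2 (checked from item 32 onward, inclusive) or at 48
items.  The final estimate is the bounded MLE.

Per-examinee RNG substreams are derived from (master seed, examinee index),
so each record is independent of execution order and the response substream
is shared across policies (paired comparisons).

## Evaluation measures

Over m examinees with per-item administration counts n_j on a pool of N
items and mean test length L̄:

* bias = mean(θ̂ − θ); RMSE = √mean((θ̂ − θ)²); mean final Fisher SE;
* exposure rate er_j = n_j/m; over-exposed er_j > 0.3; under-exposed
  er_j < 0.02 (unused items, er_j = 0, are a subset); χ² =
  Σ_j (er_j − L̄/N)² / (L̄/N);
* overlap rate = Σ_j C(n_j, 2) / (C(m, 2) · L̄), the exact all-pairs
  expectation of the shared-item proportion between two random examinees
  (the zero-variance limit of pair sampling);
* efficiency = Σ_i TI_i / Σ_i L_i with TI_i the test information of examinee
  i's items at their final estimate (evaluation at true θ is available as an
  option); percentage of examinees whose final SE misses the target.

Conditional summaries group fixed-θ populations by level and apply the same
operations per level.

## Study scales

The default overall-study size is 50,000 examinees per policy; the bundled
acceptance script and test suite run a 5,000-examinee scale per policy
(13 ability levels × 500 for the full conditional design; the test suite
exercises the extreme and central levels).  Rate-based measures (χ², overlap,
exposure-class percentages, lengths, RMSE) are stable across these scales;
the unused-item percentage is not — it shrinks as examinees accumulate
(e.g. Modification 2: 22% unused at 1,000 examinees, 15% at 5,000, still
falling), so small-sample runs overstate it relative to a 50,000-examinee
study.

## Known limitations

* The two exposure-control interpretation points that the literature leaves
  open — the randomesque pooling rule across multiple forms and the
  joint-vs-sequential disjoint pair — change pool-utilization metrics by
  tens of percent.  The package commits to per-form pooling and sequential
  pairs (the choices under which the multi-form modifications behave as
  designed) and keeps the alternatives available for sensitivity analysis.
* Item parameters are simulated independently; the positive a–b correlation
  of operational banks, which would affect α-stratification, is not
  modelled.
* No enemy items, testlets, answer keys, timing or review behaviour; the
  blueprint is a single categorical partition with min/max counts.
* Estimation assumes known item parameters (no calibration error).
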