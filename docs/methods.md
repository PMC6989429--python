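# Methods

## Model

Responses are generated and calibrated under the graded response model
(GRM). An item is a slope `a > 0`, a strictly increasing vector of `f`
boundary difficulties `b`, and the logistic scaling constant `D`. The
boundary curves are two-parameter logistics; score probabilities are
differences of adjacent boundary curves, so the `f + 1` observable scores
0..f always sum to one and an item with `f = 1` is exactly a 2PL
dichotomous item. Item information is the standard GRM form
`D²a² Σ_{t=0..f} p_t (1 − P*_t − P*_{t+1})²`, which is algebraically
identical to Samejima's `Σ_t (P*'_t − P*'_{t+1})²/p_t`; the test suite
verifies the identity numerically. A `literal` flag exposes a variant
that drops the `D²` factor and the `t = 0` term, for comparison with
older printed forms of the information function.

### Choice of D

`D` defaults to **1.7** (normal-ogive metric). Two reasons. First, the
polyserial initializer maps the polyserial correlation to a slope via
`a₀ = r_p/√(1 − r_p²)`, which is a normal-ogive relation; seeding a
logistic-metric (D = 1) calibration with it is internally inconsistent.
Second, simulation pools with lognormal(0,1) slopes truncated to
[0.2, 2.5] are conventional for the D = 1.7 metric; under D = 1 the same
pool contains many near-uninformative items and boundary recovery
degrades well beyond what comparable studies report. `D` is configurable
on every item, calibration call and experiment config.

## Study conditions (the synthetic-data generator)

The generator reproduces the conditions of the simulation studies it is
meant to emulate: operational pools of 1000 items with 2–5 boundaries,
slopes lognormal(0,1) truncated to [0.2, 2.5], boundaries independent
standard normal truncated to [−3, 3] and sorted ascending; abilities
standard normal truncated to [−3, 3]; fixed 25-item tests of 20
operational plus 5 new items; per-item calibration quotas of 300–700,
giving exactly `20·quota/5` examinees per replication (the quota
arithmetic is honored exactly rather than approximately). Truncation is
by rejection, not clipping, so the stated distributions are preserved on
their intervals.

What the generator does **not** emulate: content constraints and exposure
control, multidimensionality, misfit of the GRM itself, response styles,
speededness, or drift in the operational parameters (which are treated as
exactly known during calibration). Passing recovery tests therefore
demonstrates the estimators' statistical behavior under a correctly
specified model, not robustness to the messiness of operational data.

## CAT engine

- Quadrature: 61 equally spaced nodes on [−4, 4], weights proportional
  to the standard normal density and renormalized. EAP and the E-step
  share this grid; the grid is configurable.
- The provisional ability starts at 0; position 1 is always operational,
  and the 5 seeding positions are drawn per examinee uniformly without
  replacement from positions 2–25.
- New items never enter the ability estimate; re-running EAP on the
  operational records reproduces the logged trajectory bit for bit (a
  tested invariant).
- MFI selection inside replicated studies reads item information from a
  per-replication table on a 0.0025-step θ grid; selection can differ
  from the exact argmax only when two information curves cross within
  one quantization step. The exact `select_mfi` is used directly in the
  single-examinee path unless a table is supplied, and both paths are
  tested to coincide.
- The cohort simulator processes all examinees in lockstep but consumes
  one uniform per administered item from a per-examinee spawned stream,
  so it is reproducible examinee-by-examinee against the reference
  single-examinee path (tested to 1e-12).

## Seeding designs

The random design deals items to examinees by a shuffled deal with swap
repair, meeting every quota exactly with no repeats within an examinee.
The adaptive design spends half of each quota on a random phase,
pre-estimates each item (initializer + the condition's calibration
method), then assigns by match-b among under-quota items the examinee has
not seen, re-estimating an item from all of its accumulated responses
after every 20 fresh ones. When an examinee reaches a seeding location
with no eligible under-quota item, a random unseen item is used and the
event is counted (`fallback_assignments`); quotas are then met
approximately rather than exactly — rare in the studied configurations.

## Starting values

The squeezing average trims `floor(0.05·n)` values from each end of each
score group (the printed rule gives no rounding convention). A boundary
whose straddling group is empty falls back to the polyserial value for
that boundary. The "ability" entering both initializers is the final
operational-test EAP estimate — the only ability information available
at calibration time; the score–ability correlation `r_j` is the Pearson
correlation with that estimate. The inverse-normal step uses the
classical rational approximation
`Z = sign(P−½)·√(y·(2.0611786 − 5.7262204/(y + 11.640595)))`,
`y = −ln(4P(1−P))`, accurate to ~1e-3 over (0.005, 0.995). The
point-polyserial→polyserial factor `σ/Σφ(Zₜ)` is applied once; a
`double_conversion` flag reproduces a double application for audit.
Degenerate pass rates are clamped to `[1/(2N), 1 − 1/(2N)]`; a
non-positive polyserial correlation falls back to a unit slope with
quantile-based boundaries. All initializers return `a₀ > 0` and strictly
increasing `b₀` (exact ties separated by 1e-3).

## Calibration (OEM / MEM)

Operational parameters are fixed. Per-examinee operational log-likelihood
vectors over the grid are computed once and cached; only the new-item
factor is recomputed across MEM cycles. The M-step maximizes
`Q = Σₖ Σₜ r̄ₜₖ log pₜ(Xₖ)` by Newton iteration in
`(log a, b₁, log(b₂−b₁), …)`, which makes positivity and monotonicity
structural. Safeguards: analytic gradient; finite-difference Hessian,
shifted negative definite (Levenberg-style) so the search direction is
always an ascent direction; step-length cap 2; step halving so `Q` never
decreases; convergence at per-observation gradient max-norm < 1e-4 or
100 iterations. Box constraints `a ∈ [0.05, 5]`, `b ∈ [−6, 6]` are
applied in the transformed coordinates (gap floor 1e-3; the total
boundary span is capped by the box width). If a score level receives no
expected mass the gap floor keeps the adjacent boundaries separated and
the item is flagged `degenerate` rather than frozen — adjacent
categories still identify each boundary, and flagged items are included
in the metrics (exclusion would require a modelling argument the studies
do not make).

MEM stops when the maximum absolute parameter change between cycles
falls below 1e-3 or after 50 cycles; these values sit well below the
~0.1–0.2 RMSE scale of the recovery results. From cycle 2 onward MEM is
a proper EM on the joint marginal likelihood, so that likelihood is
non-decreasing (tested). OEM is MEM capped at one cycle.

## Evaluation

RMSE is reported on the root scale (`squared=True` gives the mean square
for audit). The mean(b) aggregates pool squared errors over
replications × items × boundaries and require a rectangular boundary
count. Permuting examinees changes only floating-point accumulation
order (results equal to ~1e-9, not bit-identical, because the expected
counts are accumulated by BLAS matrix products).

## Replication design

Each replication spawns child seed streams per stage (pool, new items,
abilities, design/responses). Two conditions sharing a replication seed
therefore share their item pools exactly and their examinee populations
as a nested prefix — a common-random-numbers pairing that sharpens
sample-size comparisons in the categories × sample-size study, where the
master seed is shared across quotas within each boundary count. Results
are byte-identical across repeated runs of the same configuration.

## Problem sizes

Replicated studies in the test suite and the acceptance script use 20
replications per condition (the original studies used 100); reported
Monte-Carlo standard errors of pooled RMSEs at 20 × 20 item-replicates
are roughly 0.005–0.01, adequate for the tolerance bands checked. The
large-sample consistency check uses 3000 responses per item with
point-mass ability posteriors on a 201-node grid (grid spacing 0.04
contributes negligible quantization noise).

## Known limitations

- The adaptive design's phase-2 loop is sequential by construction
  (provisional parameters evolve between examinees) and is therefore an
  order of magnitude slower than the vectorized random design.
- Slope recovery and bias here are noticeably better than the older
  published reference values for the same nominal conditions; the
  safeguarded, fully converged M-step and the exact quota arithmetic are
  the likely causes. In particular this implementation does not
  reproduce the outward bias of extreme boundaries (negative for b₁,
  positive for b_f at f = 5) that under-converged or unsafeguarded
  estimators exhibit; its extreme-boundary bias is near zero.
- Variable-length (information-targeted) stopping rules are out of
  scope, as are GPCM/nominal models and recalibration of operational
  items.
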