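# grmcal — online calibration of graded-response items in adaptive testing

Computerized adaptive testing (CAT) needs a steady supply of freshly
calibrated items: pretest ("new") items are seeded invisibly into
operational adaptive tests, and their parameters are estimated from the
responses collected on the fly. `grmcal` implements this *online
calibration* workflow for polytomous items under Samejima's graded
response model (GRM), for psychometricians and measurement researchers
studying item-bank replenishment designs.

## The model and the estimators

For an item with slope *a* and ordered boundary difficulties
*b*₁ < … < *b*_f, the probability of scoring at or above category *t* is
the logistic boundary curve

P\*ₜ(θ) = 1 / (1 + exp(−D·a·(θ − bₜ))),  with P\*₀ = 1, P\*_{f+1} = 0,

and score probabilities pₜ = P\*ₜ − P\*ₜ₊₁. The package provides:

- **CAT simulation** — maximum Fisher information (MFI) selection over a
  1000-item operational pool, expected a posteriori (EAP) ability
  updates on a quadrature grid, fixed 25-item tests containing 20
  operational and 5 seeded new items.
- **Seeding designs** — *random* (balanced quotas, each examinee sees 5
  distinct new items) and *adaptive match-b* (two-phase: random
  pre-estimation on half the quota, then assignment minimizing
  |θ̂ − mean(b̂)|, with provisional parameters refreshed every 20
  responses).
- **Starting values** — the *polyserial* method (category pass rates →
  normal deviates → polyserial correlation → a₀, b₀) and the
  *deleting-extremum squeezing average* (boundary t starts at the
  midpoint of the 5%-trimmed mean abilities of the two score groups
  straddling it); `poly-sq-ini` combines the polyserial slope with the
  squeezed boundaries.
- **OEM / MEM calibration** — marginal maximum likelihood EM with the
  operational parameters fixed: expected category counts r̄ₜₖ and
  sample sizes f̄ₖ on the quadrature grid, then a safeguarded Newton
  M-step in (log a, b₁, log-gaps). OEM performs exactly one cycle with
  the operational-only posterior; MEM iterates, folding the new item's
  own responses into the posterior from cycle 2 on.
- **Recovery studies** — RMSE and bias pooled over replications and
  items (and over boundaries for the mean(b) aggregates), over a
  design × initializer × method grid and a sample-size × categories
  grid, plus a leave-one-out harness for complete real-data score
  matrices.

## Worked example

```python
import numpy as np, grmcal as g

cfg = g.ExperimentConfig(design="random", initializer="poly-sq-ini",
                         method="mem", f_new=3, quota=700,
                         replications=5, seed=1)
res = g.run_condition(cfg)
print(res.table[["rmse_a", "rmse_b1", "rmse_b2", "rmse_b3",
                 "rmse_mean_b", "bias_a"]].round(4).to_string(index=False))
```

prints

```
 rmse_a  rmse_b1  rmse_b2  rmse_b3  rmse_mean_b  bias_a
 0.0711   0.1319   0.0952   0.1316       0.1208 -0.0022
```

i.e. with 700 calibration responses per 3-boundary item collected by the
random design inside simulated CATs, MEM recovers slopes to about ±0.07
and boundaries to about ±0.12 (root mean squared error over 5
replications × 20 items); the slope bias is near zero. The same workflow
is available from the shell:

```sh
grmcal run-condition --seed 1 --reps 5 --out-dir results
grmcal run-study2 --seed 1 --reps 20 --out-dir results
```

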