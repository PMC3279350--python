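# burrowmap

Spatially explicit inference for interactions between territorial species
that build mapped, long-lived structures — the motivating system being
banner-tailed kangaroo rat mounds (type `K`) and rough harvester ant colony
discs (type `A`) sharing a rectangular desert plot. The package asks two
questions a field ecologist cannot answer from raw maps alone:

1. **Is there a scale-dependent interspecific interaction?** Beyond the
   strong intraspecific territoriality that spaces mounds and colonies out,
   are colonies attracted to (or repelled from) mounds, at what distances,
   and how strongly?
2. **Is colony mortality spatially structured?** Does proximity to a mound
   change a colony's risk of dying, and does a fitted mortality model
   reproduce the spatial pattern of the surviving colonies?

## The model

Structure maps are treated as realizations of a **multitype Strauss
hard-core (MSHC) Gibbs point process**, specified by its conditional
intensity at location *u* for a point of type *m*:

```
λ(u, m | x) = β_m · exp( Σ_c θ_c z_c(u) ) · Π_p γ_p^{ t_p(u, m | x) }
```

where for each unordered type pair *p* (KK, AA, KA), `t_p` counts points of
the opposing type in the annulus `h_p < d ≤ r_p` around *u*; λ is zero
whenever any such point lies at `d ≤ h_p` (hard core: two structures cannot
physically coexist closer than `h_p`). `γ_p > 1` means attraction at those
scales, `γ_p = 1` no interaction, `0 ≤ γ_p < 1` repulsion; all pair
parameters are symmetric. Spatial covariates `z_c` are
distance-to-nearest-reference fields (e.g. distance to the nearest
unoccupied mound).

The package provides:

* **Fitting** by maximum pseudolikelihood (Berman–Turner quadrature, Newton
  iterations on the equivalent weighted Poisson log-linear score), with grid
  profiling of the irregular parameters (h, r), AICc and Akaike weights
  (`MultiTypeStraussModel` / `MSHCResults`).
* **Model comparison** between a *reduced* model (intraspecific interactions
  only) and a *full* model (plus the interspecific KA term) by a parametric
  Monte-Carlo test with the log-pseudolikelihood ratio
  Δ = 2(logPL_full − logPL_reduced) as test statistic.
* **Simulation** of MSHC models by birth/death/shift Metropolis–Hastings
  (numba-accelerated), unconditional or conditioned on observed counts.
* **Summary statistics** with edge correction: uni/bivariate Ripley K and
  centered L(r) = √(K/π) − r (translation correction), nearest-neighbour
  distance distributions G (Kaplan–Meier boundary-censoring correction).
* **Goodness-of-fit** via pointwise 95% Monte-Carlo critical envelopes and
  the curvewise Cramér–von Mises statistic Σ_r (observed − simulation
  mean)².
* **Mortality analysis**: the neighbourhood influence index
  Σ_n D_n / dist_{n,f} (disc diameter over distance, within a
  cohort-specific radius), logistic regression with all-subsets AIC
  selection and Wald tests (`MortalityModel`), the cohort-mortality
  contingency test, and the random- vs logistic-thinning test of survivor
  spatial patterns.
* **Synthetic data** with known ground truth (`SyntheticConfig`,
  `generate_dataset`) emulating the study system, since the original field
  coordinates are not publicly deposited.

## Worked example

Fit the full interaction model to a synthetic structure map drawn at the
study's scale (48 occupied mounds, ~200 colonies in a 397 × 220 m window,
true cross attraction γ_KA = 3.7 on the annulus (1, 5.1] m):

```python
import numpy as np
from burrowmap import (SyntheticConfig, generate_dataset, ModelSpec,
                       MultiTypeStraussModel, monte_carlo_lr_test,
                       adapt_h_to_pattern)

cfg = SyntheticConfig(seed=1)
pattern, records = generate_dataset(cfg)
analysis = pattern.subset(np.isin(pattern.types.astype(str), ["K", "A"]))

h_r_reduced = {("K", "K"): (10, 30), ("A", "A"): (4, 20)}
h_r_full = {**h_r_reduced, ("A", "K"): (1.0, 5.1)}
model = MultiTypeStraussModel(analysis, ModelSpec.full(("A", "K")),
                              edge_correction="none")
result = model.fit(adapt_h_to_pattern(analysis, h_r_full))
print(result.summary())

test = monte_carlo_lr_test(
    analysis, ModelSpec.reduced(("A", "K")), ModelSpec.full(("A", "K")),
    h_r_reduced, h_r_full, nsim=99, seed=2, edge_correction="none")
print(f"Delta = {test.delta_obs:.1f}, Monte-Carlo p = {test.p_value:.3f}")
```

Output:

```
Multitype Strauss hard-core model (maximum pseudolikelihood)
==============================================================
types: A, K   n = 253   k = 5
log PL = -1748.5   AICc = 3507.3   converged: True (13 iter)
--------------------------------------------------------------
parameter                             estimate
log beta_A                             -4.9649
log beta_K                             -6.0542
gamma_AA                                0.6020   (h = 4 m, r = 20 m)
gamma_KK                                0.1356   (h = 10 m, r = 30 m)
gamma_AK                                2.1485   (h = 1 m, r = 5.1 m)
==============================================================
Delta = 18.6, Monte-Carlo p = 0.010
```

Reading the summary: both intraspecific γ are well below 1 (the territorial
repulsion that makes mounds and colonies near-uniformly spaced), while
γ_AK ≈ 2.1 > 1 says colonies are about twice as likely to sit 1–5.1 m from
a mound than farther away — the Monte-Carlo test rejects the
intraspecific-only model (p = 0.01). The pseudolikelihood estimate of γ_KA
is biased toward 1 at this sample size, so γ̂_AK underestimates the
generating 3.7; the sign and scale of the interaction are what the test is
designed to recover.

The same analysis is available from the shell:

```bash
burrowmap synth --seed 1 --out runs/demo
burrowmap fit runs/demo/pattern.csv --model full
burrowmap test-interaction runs/demo/pattern.csv --nsim 99
burrowmap pipeline --seed 1 --out runs/demo
```

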