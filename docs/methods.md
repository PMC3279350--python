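# Methods

This note documents the statistical machinery implemented in `burrowmap`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real field data.

## The multitype Strauss hard-core model

The joint pattern of mounds (K) and colonies (A) in a rectangular window W
is modelled as a Gibbs point process with conditional (Papangelou) intensity

    λ(u, m | x) = β_m · exp(Σ_c θ_c z_c(u)) · Π_p γ_p^{t_p(u, m | x)},

with λ = 0 whenever a point of the paired type lies at distance d ≤ h_p of
u. Conventions:

* The interaction annulus is **open at h and closed at r**: t_p counts
  opposing points with h_p < d ≤ r_p, and d ≤ h_p is forbidden. Coincident
  same-type points are rejected at pattern construction (default duplicate
  tolerance 10⁻⁶ m) because the hard core makes them physically impossible.
* All pair parameters (h_p, r_p, γ_p) are symmetric in the pair; γ_p = 1
  encodes "no interaction", and γ_p = 0 is treated as the valid
  strong-inhibition limit (λ = 0 where t_p > 0), not an error.
* Interactions are pairwise only; covariates are exact (not gridded)
  nearest-reference distances, hence 1-Lipschitz fields.
* Coordinates are continuous planar meters in an axis-aligned rectangle; no
  projection handling, polygonal windows, or GPS error model.
* Structures are treated as dimensionless points; their physical extent is
  absorbed by the hard-core distances.

## Pseudolikelihood fitting

The Gibbs likelihood is intractable; fitting maximizes the log
pseudolikelihood

    log PL(θ) = Σ_data log λ_θ(x_i) − Σ_nodes w_j λ_θ(u_j)

via the Berman–Turner device. Quadrature nodes are the data points plus a
regular dummy grid per type (default spacing: shorter window side / 20);
weights are counting weights, a tile's area split evenly among the
same-type nodes it contains, so weights sum to |W| per type. For fixed
irregular parameters (h, r) the objective is concave in
(log β, θ, log γ) and is maximized by damped Newton iterations with
backtracking; the Poisson special case reproduces β̂ = n/|W| exactly, which
the tests assert.

Particulars:

* **Hard-core bookkeeping.** A dummy node violating a hard core has λ ≡ 0
  and is dropped from the quadrature (it contributes nothing to the
  integral). A *data* point in violation makes the whole pattern impossible
  under the model: the fit is flagged infeasible with log PL = −∞.
* **Data-driven hard cores.** h is an irregular parameter whose natural
  estimate is just below the smallest observed pair distance.
  `adapt_h_to_pattern` clamps a requested h to 0.999 × d_min per pair; the
  Monte-Carlo test applies it uniformly to the observed and every simulated
  pattern, since a pattern simulated without a cross interaction will
  routinely contain cross pairs closer than a fixed h_KA.
* **Degenerate terms.** An interaction column identically zero on all kept
  nodes (no pairs in range) is dropped with a warning; its γ is reported as
  1 and it is not counted in k.
* **Edge correction.** The pseudolikelihood score can be restricted to
  nodes at least r_max from the boundary (`edge_correction="border"`, the
  default) or use all nodes (`"none"`). Border correction is the
  best-understood analogue for pseudolikelihood of the translation
  correction used for K-functions; on the small windows used in simulation
  studies it discards most of the data, so those studies run with `"none"`.
* **Irregular parameters** (h, r) are profiled by exhaustive grid refits
  (`fit_profile`) and never counted in k for AICc, standard practice for
  non-smooth parameters.
* **AICc** uses the textbook formula −2 logPL + 2k + 2k(k+1)/(n−k−1) with
  n = the number of data points of the modelled types and k = the number of
  regular parameters (log β's, covariate coefficients, log γ's). Both
  conventions are documented here because no universal convention exists
  for pseudolikelihood information criteria; Akaike weights
  w_i ∝ exp(−Δᵢ/2) are computed on whatever criterion values are supplied.

## Monte-Carlo log-pseudolikelihood-ratio test

The cross-interaction hypothesis is tested by parametric bootstrap: fit the
reduced (intraspecific-only) and full models to the data to get
Δ_obs = 2(logPL_full − logPL_reduced); simulate nsim patterns from the
*fitted reduced* model; refit both models to each; report
p = (1 + #{Δ_sim ≥ Δ_obs}) / (nsim + 1). The +1 convention makes p = 0.001
the floor at nsim = 999. Replicates whose fits fail are dropped with a
warning, and more than 10% failures aborts the test. Simulated fits reuse
the same quadrature spacing and edge correction as the data fit.

## Simulation

MSHC models are simulated by birth/death/shift Metropolis–Hastings with
proposal probabilities (0.35, 0.35, 0.30), uniform birth locations and
uniform shift proposals, implemented as a numba kernel (the chain is
inherently sequential). Fixed points (e.g. a mound layer conditioned on
while colonies are simulated) are supported, as is a shift-only chain at
fixed counts (`simulate_conditional_on_n`) whose initial state is placed by
random sequential adsorption (an error is raised if the requested counts
cannot be packed under the hard cores). Defaults: 10⁵ proposals of burn-in
for patterns of a few hundred points; replicate draws come from one chain
thinned every burn-in/4 proposals. A capacity guard (default 20× the
expected Poisson count) aborts divergent chains — mutually attractive
two-type models with weak intraspecific inhibition can pile up without
bound in practice, and the guard surfaces that with a trace of the count
trajectory. Chains are byte-identical under a fixed seed. Correctness
checks: exact hard-core respect in every draw, Poisson count distribution
(mean, dispersion, chi-square GOF) in the γ ≡ 1 case, uniform location
marginals for the fixed-n sampler, and realized attraction (smaller
cross-type nearest-neighbour distances) for γ_KA > 1.

## Summary statistics

* **K / L.** The translation estimator sums, over ordered pairs,
  1 / (λ̂_i λ̂_j (a−|Δx|)(b−|Δy|)) for pairs with d ≤ r, with λ̂ = n/|W|.
  Ordered pairs and the λ̂² denominator (rather than n(n−1)) keep the
  estimator symmetric in the types (K̂_KA ≡ K̂_AK) and simple to interpret
  after centering; the resulting (n−1)/n finite-sample factor is what the
  CSR calibration test asserts against. L(r) = √(K(r)/π) − r is 0 under
  complete spatial randomness, > 0 under aggregation, < 0 under regularity;
  where K = 0 the formula continues to L = −r with no special-casing.
* **G.** The nearest-neighbour distance distribution is estimated by the
  product-limit (Kaplan–Meier) estimator treating the distance to the
  window boundary as a censoring time: d_i is uncensored iff d_i ≤ c_i.
  Ties aggregate deaths at one event distance; censored observations tied
  with deaths stay at risk through that distance. With no censoring the
  estimator reduces exactly to the empirical cdf (asserted), and it agrees
  with a general-purpose survival estimator to 10⁻¹⁰ on fixed data.
* Default distance grid: 0–20 m in 0.1 m steps.

## Envelopes and curvewise CvM

Critical envelopes are **pointwise** rank envelopes: with nsim simulations
the bounds at each r are the k-th smallest and k-th largest simulated
values, k = ⌈0.025 (nsim+1)⌉ (min/max at nsim = 39; 25th from each end at
nsim = 999). Simulations are unconditional draws from the fitted model;
conditioning on observed counts is available through the fixed-n sampler
but is not the default. The curvewise Cramér–von Mises statistic is the raw
grid sum Σ_r (observed − simulation mean)² — no dr weighting, which on a
constant-step grid differs only by a constant factor — and the model with
the lower CvM is declared the better fit. Global (simultaneous) envelopes
are out of scope.

## Mortality analysis

* **Influence index**: Σ over neighbouring colonies with dist < radius of
  D_n / dist_{n,f} (cm/m), radius 10 m for recently founded and 20 m for
  established focal colonies (younger colonies forage over shorter ranges).
  The radius boundary is strict (<), a neighbour at distance 0 is invalid,
  and the index is additive over neighbour sets and linear in diameters.
* **Logistic regression** of death on (disc diameter, influence index,
  nearest-mound distance) by maximum likelihood, with two-sided
  normal-approximation Wald tests and no multiple-testing correction.
  All-subsets AIC enumeration (2^p fits, p ≤ 20) ranks every predictor
  subset including intercept-only. Perfect separation is surfaced as a
  flagged non-convergent fit.
* **Thinning test.** Each replicate deletes exactly n_dead colonies from
  the full pattern by weighted sampling without replacement (successive
  renormalized draws), with equal weights under the random mortality model
  and weights proportional to fitted death probabilities under the logistic
  model, so every simulated survivor set has exactly the observed survivor
  count. Survivor patterns are summarized by univariate L(r) and compared
  with the observed survivors via envelopes and CvM; the two mortality
  models use independent simulation streams. Under equal weights the
  procedure reproduces simple random sampling without replacement
  (hypergeometric inclusion frequencies, asserted).
* The cohort-mortality 2×2 table is tested by Pearson chi-square without
  continuity correction.

## Synthetic data generator

The generator stands in for the undeposited field coordinates and defines
the study conditions the tests run under: a 397 × 220 m window; 48 occupied
mounds simulated at fixed count under a Strauss hard-core
(h = 10 m, r = 30 m, γ = 0.2); 20 unoccupied mounds as an independent pure
hard-core layer used only to build the distance covariate (their effect on
colonies is a covariate, not a fitted γ); colonies as an unconditional MSHC
draw given the mound layers with intraspecific (4, 20, 0.5), cross
attraction (1, 5.1, 3.7) to occupied mounds, a mild covariate repulsion
from unoccupied mounds (0.01 per meter), and log first-order intensity −5.0
(calibrated once so the mean colony count is ≈ 200, the observed survey
scale). Colony cohorts are assigned recent with probability 0.44 (the
observed cohort fraction) and disc diameters drawn lognormal with cohort
means 109.4 cm (established) and 33.3 cm (recent); the published tables
give means ± SE only, so the lognormal shape (sd recovered from SE × √n)
is a declared modelling choice. Mortality is Bernoulli with
logit p = 1.275 − 0.029·D + 0.073·influence + 0.037·mound-distance — the
published recent-cohort coefficients — with covariates computed by the same
operations the analysis uses.

What the generator does *not* emulate: GPS measurement error, multi-year
occupancy turnover of mounds, colony relocation (≤10% per year in related
species — acknowledged, not modelled), and any interspecific asymmetry
(the MSHC interaction is symmetric by construction). Passing tests
therefore demonstrate that the inference machinery recovers known ground
truth under the model's own assumptions, not that those assumptions hold
in the field.

## Problem sizes in tests and the acceptance script

Simulation studies are scaled to run quickly while keeping their
statistical meaning; sizes were fixed when the studies were designed:

* Δ-test calibration: 200 null replicates, nsim = 99, two types of ~25
  points each in an 80 × 80 m window (type-I error asserted within
  0.05 ± 0.02); power: 50 replicates with γ_KA = 3.7 on (1, 5.1] m
  (rejection rate asserted ≥ 0.90).
* Parameter recovery: 25 replicates of ~60–80 points (γ̂_KA > 1 in ≥ 95%,
  median log γ̂ within ±50% of truth). Pseudolikelihood estimates of γ are
  noticeably biased toward 1 at these sizes; the tests assert sign and
  bracket, not unbiasedness.
* Mortality recovery: 10 replicates of 500 colonies for 2-SE coefficient
  coverage; 15 replicates of ~130 colonies for the logistic-vs-random
  thinning discrimination (≥ 80% wins).
* The acceptance script's end-to-end pipeline runs at the full study scale
  (48 mounds, ~200 colonies) with nsim = 99 and 8×10⁴ sampler proposals,
  and its Δ-test operating characteristics use 60 null and 30 attractive
  replicates.

## Known limitations

* Pseudolikelihood is consistent but inefficient for strong interactions;
  γ̂ is shrunk toward 1 at survey-scale sample sizes (no Huang–Ogata
  refinement is implemented), and no standard errors are reported for γ.
* The printed-criterion bookkeeping of information criteria differs across
  software; AICc values are comparable within this package, not across
  packages.
* Pointwise envelopes carry the usual multiple-testing caveat across r;
  exceedance intervals are reported descriptively.
* The MH sampler is approximate (no perfect simulation); burn-in adequacy
  is the user's responsibility for unusually strong interactions, with the
  count trace exposed for diagnostics.
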