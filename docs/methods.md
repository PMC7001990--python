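# Methods

This note documents the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical choices that matter for reproducing
results.

## Scat occurrence indices

A scat record is a presence/absence vector over food items; an item found
twice in one scat counts once, because FO and PO count *scats*, not
fragments. Counts are aggregated per group (study area × season by default),
with the wet season defined as November–April and the dry season as
May–October, the two-season structure of a Mediterranean climate.

* FO_i = 100 · n_i / N. Per-item percentages; the column total exceeds 100%
  whenever scats contain more than one item.
* PO_i = 100 · n_i / Σn_i, summing to exactly 100.
* Levins' B = 1 / Σp_i², computed by default over the nine analysis
  categories (birds, reptiles, invertebrates, trash, ornamental fruit and
  seeds, domestic cats, rabbits, ground squirrels, pocket gophers) — the
  items common enough (>10% of scats) for a stable proportion estimate. Any
  category list can be supplied instead.
* Morisita's overlap C uses the finite-sample corrected form with
  numerator 2 Σ p_ij p_ik. The (n−1)/(N−1) correction takes N as the
  group's scat total, the quantity the index is defined against in diet
  work; `count_basis="occurrences"` switches the basis to Σn for
  sensitivity analysis. The correction can push C for identical finite
  samples slightly above 1; values are deliberately not clipped.

Empty scats (no recognized item) stay in the denominator N — dropping them
silently would change FO semantics. The synthetic generator flags them and
can resample on request.

## Isotope preparation

All values are carried in ‰ δ-notation (δ13C vs VPDB, δ15N vs air N2); raw
isotope ratios appear only in `delta_value`.

* Source summaries use the sample SD (n−1). Single-sample sources report
  SD = 0 with a warning instead of erroring, so toy fixtures run; the
  mixing model floors source SDs at 1e-6 to keep near-delta sources
  numerically valid.
* Trophic discrimination: sources are shifted into consumer-tissue space by
  mean + Δ, with the TDF's own uncertainty added in quadrature
  (SD′ = sqrt(SD² + SD_Δ²)), so correction never shrinks a source.
  Defaults: Δ13C = 1.5‰, Δ15N = 3.5‰, SD 0.5‰ each; the human-food source
  uses Δ13C = 2.5‰ (typical of carnivore keratin on processed food) with
  the same 0.5‰ SD — the SD for that source is not separately established,
  so it is configurable.
* The human-food source is back-calculated from human hair (hair sits one
  trophic step above the human diet): δ13C − 2.0‰, δ15N − 3.5‰, SDs carried
  through. The packaged reference stores the published food values
  (−20.9 ± 0.9, 4.9 ± 0.7): the carbon value equals the exact subtraction;
  the nitrogen value follows the unrounded hair mean (the rounded hair mean
  of 8.5 would give 5.0), so the published value is kept rather than
  re-derived from a rounded intermediate.
* The natural-vs-anthropogenic δ13C threshold is the TDF-corrected mean
  plus k·SD (default k = 1) of the natural prey source with the highest
  mean δ13C — theoretically the maximum tissue δ13C a consumer of purely
  natural (C3-chain) prey can carry. With the packaged reference values
  (ground squirrels, −22.7 ± 0.9‰) this is −20.3‰. Individuals exactly at
  the threshold classify as natural-leaning, since the threshold is a
  maximum attainable natural value.

## Bayesian mixing model

Consumers enter as per-individual whisker means (one observation per
animal), fitted separately per study area: individuals have very unequal
subsample counts, and group-level proportions are the estimand. For diet
proportions p on the K-simplex:

    mean_iso(p) = Σ_k p_k (μ_k + Δ_k)
    var_iso(p)  = Σ_k p_k² (σ_k² + σ_Δk²)
    x_i,iso ~ Normal(mean_iso, sqrt(var_iso + τ_iso²)),  independent isotopes

Priors: p ~ Dirichlet(1, …, 1); residual SD τ_iso ~ half-Normal(scale 2‰).
Both are configurable; the defaults are standard weakly-informative
mixing-model practice. Elemental concentration weighting is not modelled.
The rabbit + gopher pooling is applied before fitting, giving six sources.

**Sampling.** The simplex is parameterised as p = softmax(z₁,…,z_{K−1}, 0)
(reference coordinate fixed), τ as log τ, with the corresponding Jacobian
terms (Π p_k for the softmax; τ for the log). The sampler is random-walk
Metropolis, vectorised across chains (4 × 10,000 iterations, 2,000 burn-in
by default). During burn-in only: a Robbins–Monro scalar step-size
adaptation targets ~30% acceptance, and the proposal covariance is
refreshed at burn-in fractions 1/4, 1/2 and 3/4 from the trailing half of
burn-in draws with per-chain means removed (so unmerged chains do not
inflate the proposal). Kernel parameters are frozen before the first
retained draw, so retained draws come from a fixed Markov kernel. The
2,000-iteration burn-in is the smallest at which the covariance estimate is
stable enough for K = 6 problems (split-R̂ ≈ 1.05 rather than 1.2–1.4 at
1,000).

Convergence is assessed with split-R̂ and ESS (via arviz) on every
proportion and residual SD; any R̂ > 1.1 flags the posterior and emits a
warning — results are returned but marked, never silently accepted.
Identical spec + seed reproduces draws exactly. A fixed residual SD can be
supplied instead of sampling τ; this is how posterior means are checked
against a deterministic grid-integration oracle (K = 2 dense quadrature,
K = 3 triangular grid), which agrees to < 0.03 on toy problems — the
oracle shares no code with the sampler.

K = 1 is a degenerate special case returning p = 1 without sampling.

## Individual specialization (WIC/TNW)

Per group and isotope, with individual as the grouping factor:
TNW = Σ (x − grand mean)² over all subsamples, WIC = Σ_ind Σ (x − ind
mean)², BIC = TNW − WIC (computed directly and verified to add up). The
index WIC/TNW is a *sum-of-squares fraction*, not a mean-squares ratio —
no degrees-of-freedom normalisation — because the variance fraction is the
estimand and raw SS ratios are what reproduce reported percentages in this
system. Individuals with one subsample contribute 0 to WIC but stay in TNW
(warned). All-identical values make the index undefined and raise an
explicit error. Isotopes are decomposed separately; no bivariate pooling.

## Land-use models

Transforms are applied per covariate to meet homogeneity-of-variance
assumptions: sqrt and square for the scat-level models; log and
arcsine-sqrt for the isotope-level models. A log of an exact zero (real
buffer tables contain fully natural buffers with 0 urban cover) is an
error unless an explicit offset is configured — no silent offsets.

OLS fits use treatment contrasts with the alphabetically first factor level
as reference. AIC = 2k − 2·logLik with k = coefficients + 1 (residual
variance counted); because ΔAIC is what enters relative likelihoods
exp(−ΔAIC/2) and Akaike weights, any consistent k convention yields the
same weights, and a published ΔAIC column alone reconstructs the weight and
likelihood columns (`rank_from_delta_aic`). AICc is available behind the
same interface by passing corrected AIC values to `rank_from_aic`. Rank
deficiency raises an error naming aliased terms (pivoted QR). For scat
responses, anthropogenic FO is computed per transect × season (two rows per
buffer): a scat counts once regardless of how many anthropogenic items it
holds.

## Synthetic data: what it does and does not emulate

* **Scat generator** — items are independent Bernoulli draws per scat with
  per-area/per-season probabilities; only marginal occurrence rates are
  consumed downstream, so co-occurrence structure is deliberately not
  modelled. An optional logit-scale slope links altered-open-space
  proportion to anthropogenic-item probability per transect. Empty scats
  are retained (flagged) by default.
* **Whisker generator** — a two-level hierarchy: individual latent means
  drawn around the group forward-model mean (between-individual SD per
  isotope), subsamples around the latent mean (within-individual SD).
  Subsample counts are round(Normal(16, 7)) clipped at 1, the observed
  study scale. Segments are treated as exchangeable: no temporal
  autocorrelation along the whisker, no seasonal drift. Default per-area
  diet proportions are the study-scale estimates (urban diets dominated by
  human food and cats; natural prey and figs increasing toward rural),
  with a 2% cricket share so no true proportion sits exactly on the
  simplex boundary (a zero component can never fall inside a strictly
  positive credible interval).
* **Covariate generator** — uniform marginals over configured ranges
  coupled by a Gaussian copula; by default only the empirically strongest
  pair (roads–humans) is correlated. No spatial structure.

Because items are independent and whisker noise is Gaussian, passing tests
demonstrate correctness of the estimators under the stated models — not
robustness to co-occurrence, digestibility bias, or non-Gaussian isotope
noise in real data.

One master seed spawns independent substreams per generator
(`numpy.random.SeedSequence`), so identical configs reproduce byte-identical
tables and generators can be used in isolation.

## Numerical choices and problem sizes

* Simplex draws are validated to sum to 1 within 1e-9; forward-model inputs
  off the simplex by more than 1e-6 are rejected.
* The WIC + BIC = TNW identity is enforced in tests to 1e-9 relative.
* Posterior summaries require ≥ 100 retained draws.
* The calibration experiment in the test suite uses 20 replicates of 50
  consumers with 4 × 20,000-iteration chains (4,000 burn-in, thinning 2) —
  sizes at which the whole suite completes in well under a minute per
  mixing fit while split-R̂ stays ≈ 1.02; the grid oracles use a 2,001-point
  line (K = 2) and a 0.01-step triangular grid (K = 3).
* Report files round percentages to one decimal and indices to two; a
  `_full` companion file always carries full precision.

## Known limitations

* The mixing model has no hierarchical individual effects and no informative
  priors from scat data; consumers are exchangeable within a group.
* Random-walk Metropolis mixes slowly on strongly under-determined source
  sets (many sources, two isotopes); the diagnostics flag this, and longer
  chains or fewer (pooled) sources are the remedy.
* FO/PO/B/C are occurrence-based and do not approximate biomass; the
  isotope side of the pipeline is the biomass-weighted complement.
* No lipid normalisation, Suess correction, or C:N screening is applied to
  isotope inputs; values are assumed analysis-ready.
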