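# nichemix

Diet analysis for carnivores along an urbanization gradient, built around the
study design used for coyotes (*Canis latrans*) in southern California:
scat-content occurrence indices, two-isotope (δ13C/δ15N) Bayesian diet
mixing from whisker (vibrissa) segments, an individual-specialization index,
and AIC comparison of land-use covariate models. Synthetic-data generators
with known ground truth make every stage testable end to end without any
field data.

## Who it is for

Wildlife and trophic ecologists working with two complementary diet records:

* **scat contents** — presence/absence of food items per scat, collected
  along transects across study areas and seasons;
* **stable isotopes** — δ13C and δ15N measured along whisker segments of
  individual animals, plus tissue samples of candidate food sources.

## What it computes

**Scat indices** (`nichemix.scat_diet`). For per-group occurrence counts
n_i out of N scats:

* frequency of occurrence FO_i = 100 · n_i / N (totals may exceed 100%),
* percentage of occurrence PO_i = 100 · n_i / Σn_i (totals exactly 100%),
* Levins niche breadth B = 1 / Σp_i² with p_i = n_i / Σn_i, from 1
  (monophagy) to the category count (uniform use),
* Morisita's niche overlap
  C = 2 Σ p_ij p_ik / [Σ p_ij (n_ij−1)/(N_j−1) + Σ p_ik (n_ik−1)/(N_k−1)],
  0 for disjoint diets, ≈1 for identical ones.

**Isotope preparation** (`nichemix.isotope_prep`). δ-notation conversion,
per-source mean/SD summaries, trophic-discrimination correction
(mean + Δ, SDs added in quadrature), back-calculation of a human-food
source from human hair, exact two-group source pooling (e.g.
rabbit + pocket gopher → "rabbit_gopher"), and the δ13C threshold
separating natural from anthropogenic (corn-based, C4) food chains:
the TDF-corrected mean + 1 SD of the natural prey source with the highest
δ13C (−22.7 + 1.5 + 0.9 = **−20.3‰** with the packaged reference values).

**Bayesian mixing model** (`nichemix.mixing_model`). Per consumer group,
each individual's mean (δ13C, δ15N) is modelled as

    x_iso ~ Normal( Σ_k p_k (μ_k + Δ_k),  sqrt(Σ_k p_k² (σ_k² + σ_Δk²) + τ_iso²) )

with a Dirichlet prior on the diet proportions p and a half-Normal prior on
the residual SD τ. Sampling is adaptive random-walk Metropolis on a
softmax/log transform (4 chains × 10,000 iterations by default), with
split-R̂ and effective-sample-size diagnostics; non-convergence is flagged,
never silent.

**Individual specialization** (`nichemix.specialization`). The one-way
sum-of-squares identity WIC + BIC = TNW per isotope; the index WIC/TNW runs
from 0 (strong individual specialization) to 1 (no individual variation).

**Land-use models** (`nichemix.landuse_models`). Variance-stabilising
covariate transforms (sqrt, square, log, arcsine-sqrt), OLS with factors and
interactions, AIC ranking with relative likelihoods exp(−ΔAIC/2) and Akaike
weights, and a Pearson correlation screen for collinear covariates.

**Synthetic data** (`nichemix.synthetic_data`) and a pipeline driver plus
CLI (`nichemix.cli_io`, `nichemix` command) tie the stages together.

## Worked example

```python
import numpy as np, pandas as pd
import nichemix as nm
from nichemix.reference import (DEFAULT_TDF, NATURAL_PREY_SOURCES,
                                DEFAULT_DIET_PROPORTIONS, mixing_tdfs,
                                pooled_sources)

# scat indices from a toy occurrence table: 8 scats
t = nm.DietTable("urban", pd.Series({"rabbit": 6, "trash": 3, "birds": 1}), 8)
nm.frequency_of_occurrence(t).round(1)   # rabbit 75.0, trash 37.5, birds 12.5
nm.levins_niche_breadth(t, ["rabbit", "trash", "birds"])  # 2.174

# the natural-vs-anthropogenic d13C threshold from the reference sources
nm.anthropogenic_threshold(NATURAL_PREY_SOURCES, DEFAULT_TDF, k_sd=1.0)  # -20.3

# mixing model: 29 synthetic urban consumers from the default diet truth
six = pooled_sources()
tdfs = mixing_tdfs([s.name for s in six])
p = np.array([DEFAULT_DIET_PROPORTIONS["urban"][s.name] for s in six])
mean, sd = nm.forward_model(p, six, tdfs)
obs = np.random.default_rng(0).normal(mean, sd, size=(29, 2))
post = nm.fit_mixing_model(nm.MixingSpec(sources=six, consumers=obs, tdf=tdfs, seed=1))
print(nm.summarize_posterior(post)[["source", "mean", "sd", "q2.5", "q97.5"]].round(1))
```

The mixing summary printed by that snippet (percent of diet):

```
           source  mean  sd  q2.5  q97.5
     domestic_cat  41.7 5.8  30.9   53.6
              fig   3.5 2.5   0.1    9.4
  ground_squirrel  15.7 5.6   4.3   26.3
       human_food  26.6 8.5   8.7   42.6
jerusalem_cricket   5.4 3.9   0.3   14.2
    rabbit_gopher   7.2 5.2   0.3   19.2
```

Every 95% interval contains its generating truth (cat 38.7, fig 5.5,
squirrel 8.1, human food 36.8, cricket 2.0, rabbit-gopher 8.8) — with only
29 consumers and two isotopes the anthropogenic pair (cat vs. human food)
is only weakly separable, which the wide human-food interval reflects.

A full synthetic run from the shell:

```bash
nichemix generate --seed 3 --outdir demo
nichemix run-all --config demo/run.yaml --seed 11 --outdir demo/out
```

writes diet tables, the overlap matrix, source summaries and threshold,
per-area mixing summaries with diagnostics, the specialization table, the
model-comparison table, and a machine-readable `manifest.json`.

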