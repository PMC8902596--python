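# Methods

This note documents the models, conventions and numerical choices behind
`mucoswab`, in the order the pipeline uses them.

## The mucosity factor

A rectal swab collects a blend of luminal digesta and mucus-layer material.
Writing a swab's expected composition as `m·A + (1 − m)·L`, where `L` is the
animal's luminal profile, `A` its mucosa-adhered profile and `m ∈ [0, 1]`
the (unobserved) fraction of adhered material, the swab's Bray-Curtis
dissimilarity to the paired colon sample (≈ `L`) increases monotonically in
`m`. That paired dissimilarity is the *measured mucosity factor*. It is a
proxy, not an estimate of `m` itself: its scale depends on how different
`A` and `L` are, and its floor on technical noise, which is why downstream
validation uses rank (Spearman) correlation throughout.

**Squared vs plain.** The package defaults to elementwise-squared
Bray-Curtis for the mucosity factor and for PCoA input, with a single
global `squared` flag to switch to the plain dissimilarity. Squaring is a
monotone transform on [0, 1], so every rank-based result is identical under
either choice; only the linear-model scale changes.

## Ordination

`rda(Y, X)` centers the response columns (relative abundances,
unstandardised — the usual default for linear ordination of proportions;
per-taxon standardisation is available but off), centers X, computes the
multivariate least-squares fit `Ŷ`, and eigendecomposes `Ŷ` by SVD.
Eigenvalues are `s²/(n − 1)`; explained variation is `SS(Ŷ)/SS(Y)`;
adjusted variation uses Ezekiel's formula (the convention constrained-
ordination software reports), falling back to the raw fraction for
saturated fits where the adjustment is undefined. `prda(Y, X, W)`
residualises both Y and X on the centered covariates first and reports
explained variation as a fraction of the covariate-free variance, with the
effective sample size reduced by the number of covariate columns in the
adjustment.

Score conventions are frozen as follows and matter only up to rank:

- **CaseR scores** (sample positions derived from the responses) are
  projections of the centered response matrix onto the constrained axes,
  rescaled to unit variance per axis over the training samples. In pRDA the
  *centered, non-residualised* responses are projected, so that passive
  projection of a training sample always reproduces its stored score —
  supplementary samples have no covariate values, so residualised scores
  could never be reproduced for them.
- **CaseE scores** are the projections of the fitted values, same scaling.
- **Response scores** are Pearson correlations between each (residualised,
  for pRDA) response column and the fitted axis scores. They live in
  [−1, 1]; the default discriminant-taxon threshold of 0.60 therefore reads
  as "|correlation with the constraint axis| > 0.60". A constraint that
  explains nothing produces uniformly small response scores, which is what
  makes shuffled-label negative controls come out empty. Constant response
  columns get a zero loading rather than an error.
- **Axis orientation**: each constrained axis is flipped, if necessary, to
  correlate non-negatively with its dominant constraint; factor constraints
  enter as centered 0/1 indicators with the lexicographically first level
  as reference. For the mucosity RDA this pins "higher score = higher
  mucosity"; for the sample-type RDA, "positive = swab side".

`pca` is plain SVD of the centered table with a largest-loading-positive
sign convention. `pcoa` is classical scaling: Gower double-centering of
−½ D∘D followed by a symmetric eigendecomposition; coordinates come from
the positive eigenvalues and negative eigenvalues are reported, never
silently dropped. Group dispersion (used for the "swabs are more variable"
comparison) is each sample's Euclidean distance to its group centroid over
the positive-eigenvalue axes, PERMDISP-style, compared between groups by a
two-sided Mann-Whitney test.

**Permutation test.** pseudo-F = `[SS_fit/p] / [SS_res/(n − p − q − 1)]`
with q covariate columns; permutations are unrestricted row shuffles of the
residualised constraints with a seeded generator, and
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`. Default 999 permutations; the
CLI requires an explicit seed. Under the null the test holds its level
(rejection 0.0375 at α = 0.05, KS distance to uniform 0.03 over 400 null
datasets in the shipped checks).

## Prediction and cross-experiment projection

`predict_mucosity` projects swabs passively: align genera to the training
taxa (absent genera → 0, extra genera dropped with a warning), renormalise,
subtract the *training* means, project onto the training axes with the
training scaling. The predicted mucosity factor is the axis-1 CaseR score,
reported in ordination units, not rescaled to [0, 1] — an optional linear
calibration against the measured values on the training subset can be
applied by the user for interpretability, but all shipped validation is
rank-based. Only axis 1 exists for a single continuous constraint.
Cross-experiment projection harmonises genera by label intersection, warns
when more than 25% of training taxa are lost and refuses below 50% overlap.

## The synthetic cohort generator

The generator emulates the study design the pipeline targets, and its
defaults are the package's reference conditions:

| parameter | default | meaning |
|---|---|---|
| studies / arms | exp1: 14 EF + 14 CON; exp2: 8 + 8 | paired animals per treatment per study |
| g_taxa | 60 | genera, 8 mucosa-adhered, one dominant |
| mucosity_range | [0, 0.6] | per-animal `m ~ Uniform` |
| depth | 20 000 | reads per sample |
| overdispersion | 200 | Dirichlet concentration scale |
| batch_sigma | 0.25 | log-sd of the per-taxon study effect |
| ef_suppression | 0.5 | multiplier on the dominant adhered genus in EF |

Base profiles put ~1% of luminal mass on the mucosal block (the dominant
genus at 0.2% — virtually but not literally absent from colon content) and
65% of adhered mass on it (dominant genus 35%, giving a mean dominant-genus
swab abundance near 10% at mean mixing 0.3 in control animals). Non-mucosal
mass follows a rank-decayed lognormal profile shared between the two
communities, the realistic "few dominant genera plus a long tail" shape of
genus tables. The mixture acts on proportions *before* count noise — the
physical picture of blending material — and each sample's counts are
Dirichlet-multinomial, the simplest overdispersion model consistent with
16S data. `m ~ Uniform(range)` because the enrichment is known only to be
"variable"; uniform is the least-informative bounded choice and
configurable. The study effect multiplies both profiles by the same
per-taxon log-normal factors, shifting overall composition while preserving
the swab–colon contrast direction, which is what makes cross-experiment
projection work and lets the generator reproduce the between-study
congruency of sample-type response scores.

Two deliberate extensions beyond the minimal design: (i) in EF animals the
dominant-genus suppression factor is modulated by a per-animal eating
propensity (uniform on [0.6, 1.4], mean factor = `ef_suppression`, inert
when it equals 1), so eating scores carry a negative correlation with the
genus's swab abundance, as observed behaviourally; (ii) an
`ef_mucosity_shift` parameter can move only the mixing coefficient of EF
animals, expressing the pure-confounding scenario where treatment changes
*how much* adhered material swabs collect but not the adhered community
itself.

What the generator does **not** emulate: litter effects (litter ids are
carried in metadata but unused — no quantitative basis was available for a
between-litter variance), read-level artefacts (chimeras, PCR bias),
taxonomic misassignment, or a phylogeny. Passing tests therefore show that
the pipeline recovers known structure under realistic compositional count
noise and batch effects — not that real swab data are this well-behaved.

## Univariate statistics and clustering

Mann-Whitney U uses exact enumeration up to combined n = 12 without ties
(cheap there, and the approximation's continuity/tie corrections take over
exactly where the study's group sizes live), the normal approximation with
tie and continuity corrections otherwise. Significance labels: P < 0.05
significant, 0.1 > P ≥ 0.05 trend, else ns — boundaries included/excluded
exactly as written. Per-taxon contrast tables report raw p-values (no
multiple-testing correction, matching the analysis convention the pipeline
reproduces) plus a clearly separate Benjamini–Hochberg q column.
Correlations are Pearson when both variables pass Shapiro–Wilk at α = 0.05,
Spearman otherwise. Heat-map support is data-only UPGMA (Euclidean,
average linkage) with scipy's smallest-index tie-break; rendering is left
to the user.

## Known limitations and numerical notes

- Correcting the diet test for *measured* mucosity is an errors-in-covariate
  correction: when treatment acts purely through the mixing coefficient,
  the corrected test is calibrated where the measurement is precise
  (demonstrated at concentration 500 / depth 50 000: corrected rejection
  0.05 vs uncorrected 0.95), but retains residual inflation under very
  noisy measurement. This mirrors what the real analysis can and cannot
  promise.
- Held-out recovery of the true mixing coefficient (mean Spearman ≈ 0.87 at
  defaults) is capped by compositional noise at overdispersion 200, and
  degrades monotonically as the Dirichlet concentration drops.
- Rank decisions use a relative singular-value tolerance of 1e-9;
  distances/symmetry are validated at 1e-12; projection self-consistency
  holds to 1e-10.
- Problem sizes in the shipped checks (cohorts of 44–88 samples × 60
  genera, 199–999 permutations, tens to hundreds of replicate cohorts) were
  chosen so that every property is measured with comfortable Monte-Carlo
  margins while the whole suite runs in well under half an hour on a single
  core.
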