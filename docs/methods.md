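# Methods

## The model

Each trait is analyzed at the level of species-by-garden means.  On its
(possibly transformed) scale the trait is modelled as

    z = b0 + b_site·ln(site P/E_p) + b_species·ln(species P/E_p)
        [+ c·ln(site P/E_p)·ln(species P/E_p)]
        + u_garden + u_species + u_phylo + u_phylo_in_garden + ε

with Gaussian random effects:

* `u_garden` — iid garden effect (shared conditions within a site);
* `u_species` — iid species effect, absorbing species differences not
  explained by phylogeny;
* `u_phylo` — species effect with covariance σ²_phylo·C, where C is the
  Brownian-motion covariance of the time-calibrated phylogeny (shared
  branch length to the most recent common ancestor), normalized by tree
  height so σ²_phylo is the tip-level variance and is comparable across
  trees of different depth;
* `u_phylo_in_garden` — an independent Brownian draw within each garden
  ("phylogenetic attraction": related species resemble each other in how
  they respond to a particular site);
* ε — iid residual.

Log moisture supply is used for both predictors because trait–climate
relationships along this kind of gradient are closer to linear on a log
scale, and because the gradient itself is multiplicative (an eightfold
span of P/E_p).

### Estimation

The likelihood is profiled analytically over the fixed effects and the
residual variance, leaving a bounded quasi-Newton (L-BFGS-B) search over
the log variance ratios, run from three deterministic starts to reduce
the risk of local optima.  Maximum likelihood (not REML) is the default
so that AIC comparisons across fixed-effect forms are valid.  A `reml`
flag switches to restricted maximum likelihood, which removes the
downward bias of the variance components in this small design (40
observations, 4 gardens) and is used for interval estimation.

Degenerate inputs: data lying exactly on the fixed-effect plane drive the
profiled residual variance to a floor of 1e-10 (the GLS coefficients are
then exact regardless of the covariance); a covariance matrix that loses
positive definiteness numerically receives a ridge of 1e-8·trace/n, and
this is recorded.

### Model selection

1. **Fixed form and transform.**  Additive vs. interaction forms, crossed
   with none/log/sqrt response transforms (log and sqrt only for strictly
   positive traits), are compared by OLS AIC.  Because likelihoods of
   transformed responses live on different scales, each candidate's
   log-likelihood carries the Jacobian of its transform
   (−Σ ln y for log, −Σ ln 2√y for sqrt), putting all AICs on the
   original-data scale.  Candidates within 2 AIC units of the best are
   resolved by parsimony (fewest parameters, then lowest AIC).
2. **Random effects.**  Starting from all four components, the component
   with the largest likelihood-ratio p-value is dropped while that
   p-value is ≥ 0.5 — a deliberately generous retention cutoff, keeping
   anything with even weak support.  The iid species term is not eligible
   for removal while either phylogenetic term remains, so that
   non-phylogenetic species differences cannot masquerade as phylogenetic
   signal.  LRT p-values use a χ²(1) reference; the boundary-corrected
   ½χ²(0)+½χ²(1) mixture would halve them, and with a 0.5 cutoff the
   plain χ²(1) reference is the more conservative choice (it retains
   more components).
3. **Inference.**  Fixed-effect p-values are two-sided Wald z.  Total R²
   is the likelihood-ratio form 1 − exp(−(2/N)(ℓ_full − ℓ_null)) against
   the intercept-only model; partial R² for a predictor is the drop in
   total R² when it is removed from the final model.

### Confidence intervals

Wald-z intervals undercover here: the slope on ln(site P/E_p) is
effectively estimated from 4 garden-level means, so its denominator
degrees of freedom are near 2, not n − p.  The package therefore provides
Satterthwaite-t intervals from the REML fit: the df for a contrast c is
2(c'Σc)²/Var(c'Σc), with the variance of the coefficient variance
obtained by the delta method over the log variance components (numerical
gradient, and covariance from the numerical Hessian of the restricted
likelihood).  Measured over 200 replicate synthetic studies at the
design dimensions, 95% intervals cover the true slopes 92–95% of the
time, against 83–88% for plain Wald z.  Significance tallies still use
Wald z p-values (with FDR adjustment), matching mixed-model practice in
this literature.

### Multiple testing and tallies

With ~53 traits and two predictors each, the family is 2×53 = 106 tests.
The Benjamini–Yekutieli step-up procedure with harmonic penalty
c(m) = Σ 1/i controls the FDR under arbitrary or positive dependence;
`m_total` fixes the family size even when fewer p-values are supplied
(the missing tests are treated as unobserved at p = 1 in the top ranks).

Agreement of each trait×predictor with its theoretically predicted
direction is tallied with weights: full sign agreement scores 1;
agreement except for the one (two) species with the driest native range
scores 0.9 (0.8); agreement except for the one (two) driest gardens
scores 0.75 (0.5); disagreement scores 0.  Exceptions may be supplied
explicitly or detected by refitting without the driest species/gardens
and checking whether the coefficient sign then matches.

## Ordination

The trait matrix (complete cases; sporadically missing cells
mean-imputed with a count logged — a simple policy, flagged prominently
because imputation shrinks that trait's variance) is centered, scaled to
unit variance, and decomposed by SVD (correlation-matrix PCA).  The two
moisture gradients are projected as supplementary variables: each
gradient's direction in the PC1–PC2 plane is its vector of correlations
with the scores, scaled to unit length.  Raw regression coefficients on
the scores were rejected for this purpose: their 1/var(PC_k) weighting
distorts angles, so two exactly orthogonal gradients can project as
strongly correlated.  The correlation weighting preserves the angle
whenever the gradients lie in the plane.  PC signs are fixed so the
projected site-gradient vector has positive coordinates.

Trait loading vectors are classified into eight descriptive sectors
defined by the two gradient directions, their opposites, and the four
bisectors; each trait joins the angularly nearest half-axis.  When the
gradients are exactly perpendicular this is identical to ±22.5° bands
about each half-axis; nearest-axis assignment keeps the classification
exhaustive and exclusive when they are not.

Reaction norms of the PC1 score: within each garden, the OLS slope of
PC1 against species P/E_p measures multivariate fixed differences; within
each species, the slope against site P/E_p measures multivariate
plasticity.  Parallelism is tested with the ANCOVA interaction F-test,
and the plastic:fixed ratio is reported both as the ratio of mean slopes
and as the mean of per-species ratios (the two can differ; both are
emitted).

## Performance statistics

H* = p̂·m treats dead plants as having zero height.  Its standard error
combines binomial survival uncertainty (n′ planted) with the sampling
error of the mean (n measured, sd s):

    se² = (p̂² + p̂(1−p̂)/n′)·s²/n + m²·p̂(1−p̂)/n′

This is the exact variance of the product of an independent binomial
fraction and a sample mean (not merely a first-order delta
approximation), which is why the Monte-Carlo validation in the test
suite agrees to well under 1%.  With p̂ = 1 it reduces to s²/n; with
p̂ = 0, H* = 0 exactly.  The mass analogue M* shares all code paths and
differs only through `n_measured` (mass is measured on a subset).

Within-garden species comparisons: pairwise z-tests on H* with
Benjamini–Hochberg correction within the garden and a compact letter
display built by insert-and-absorb over the significance graph; 2×2
chi-square with Yates continuity correction for survival; Tukey HSD for
raw means (singleton groups excluded — no letters where no comparison is
possible).

Survival against species P/E_p is fitted both linearly and as the
sigmoid s = s_max/(1 + exp[β(a − P/E_p)]) (β of either sign; a is the
P/E_p at half-maximum), with AIC deciding which is reported.
Counterfactual survival replacement refits the survival–species-P/E_p
regression excluding a target species and substitutes the predicted
survival (clipped to [0,1]) before recomputing H* — used when one
species' survival is anomalous relative to the within-garden trend.

**Cross-over rule.**  Adaptive cross-over is operationalized as a sign
flip of the Spearman correlation between species P/E_p and H* from the
driest garden (negative: dry-adapted species lead) to the wettest
(positive).  The per-garden report also ranks species by H* and checks
whether the top species' native P/E_p is closer to the garden's P/E_p
than the median competitor's.

## The synthetic-data generator

Defaults mirror the target study design: 10 species × 4 gardens, site
P/E_p = {0.16, 0.39, 1.03, 1.25}, species P/E_p evenly spanning
0.19–0.98, 81–254 plants per species per garden, and a pure-birth
ultrametric tree of height 52 My.  Traits are generated from the same
mixed model the analysis fits (Gaussian noise on the transformed scale;
σ²_phylo = 0.09, σ²_site = 0.01, σ²_e = 0.04 by default, i.e. moderate
phylogenetic signal and a residual sd of 0.2 against fixed-effect spans
of order 1–4).  The default trait panel spreads a per-trait response
magnitude (U(1.5, 3.5)) across site and species according to a
plasticity share U(0.15, 0.85), emulating the observed continuum from
strongly plastic traits (gas exchange) to strongly fixed ones (wood
anatomy); with a homogeneous panel the site-vs-species contrast carries
so little multivariate variance that it can drop below a phylogenetic
noise axis and out of the PC1–PC2 plane.

Survival follows per-garden sigmoids whose slope parameter runs from
−10 (steep decline with species P/E_p) at the driest garden to +8 at the
wettest; heights of survivors are lognormal with means increasing in
species P/E_p, more steeply at wetter gardens.  Jointly these plant a
rank reversal in expected H* between the driest and wettest gardens — the
cross-over the detector must find.  Within-cell sample sizes per trait
are a parameter, not a constant, since real designs vary widely (single
plants to everything that survived).

What the generator does **not** emulate: non-Gaussian residuals,
trait–trait correlation beyond the shared gradients and phylogeny,
missing-data mechanisms correlated with trait values, weather time
series, fire, herbivory, or pathogen pressure.  Tests passing on this
generator therefore certify the statistical machinery — estimator
correctness, error control, detection power under the planted structure —
not robustness to every failure mode of field data.

## Numerical choices

* Saturation vapor pressure: Tetens equation over liquid water (standard
  for 15–30 °C chambers); molar mass of water 18.015 g mol⁻¹; water
  density 998.2 kg m⁻³ and dynamic viscosity 1.002 mPa·s at 20 °C; the
  temperature standardization of K_stem multiplies by the viscosity ratio
  η(T)/η(20 °C) from the standard log₁₀ correlation for liquid water.
* g_min "quasi-linear phase": the longest suffix of valid intervals whose
  conductance stays within 20% of its own median; the reported value is
  the mean of the lowest consecutive interval pair inside the phase whose
  bracketing F_v/F_m readings exceed 0.7 (threshold configurable).
  Intervals with mass gain are excluded with a warning.
* k_leaf exclusion threshold 0.3 MPa, configurable.
* K_stem can be expressed per xylem area (default) or per leaf area, and
  rescaled to the median xylem area through the per-species regression
  ln(K/XA) ~ ln(XA) + garden; the median is per-species by default,
  overridable.
* D_h uses the power-mean form ((1/n)ΣD⁴)^(1/4), the standard
  hydraulically weighted mean (lies between min and max and is ≥ the
  arithmetic mean).
* Root-mass imputation fits ln(mass) ~ ln(proximal diameter) on complete
  segments and predicts missing masses smallest-to-largest, refitting as
  imputed segments accumulate; complete segments are never altered; ≥ 3
  complete segments required.
* All CSV I/O uses one dialect (comma, UTF-8, "." decimal, ""/"NA"
  missing); keys are (species_id, site_id) pairs and row order never
  carries meaning; excluded combinations (e.g. total mortality) are
  flagged, not silently dropped.
* One seed governs every stochastic stage; stages derive independent
  child streams by a counter so any stage can be rerun alone and
  reproduce its outputs byte-for-byte.

## Problem sizes in the test and acceptance runs

Simulation-backed checks use 200 replicate studies for slope recovery and
interval coverage, 500 traits for the global-null FDR check, 10⁶
Monte-Carlo draws per grid point for the H* standard-error validation,
and 10⁴ replicate draws for the Brownian-covariance convergence check —
sizes at which the Monte-Carlo error is several times smaller than the
margins being tested.

## Known limitations

* The packaged/simulated phylogeny is a synthetic pure-birth
  approximation of a real time-calibrated tree, not a published
  topology with node ages.
* The mixed model assumes Gaussian residuals on the chosen transform
  scale for every trait; no non-Gaussian response families.
* PCA is phylogenetically unstructured (no established phylogenetic PCA
  handles multiple species scored at multiple sites); the contrast with
  the phylogenetic regressions is intentional.
* Mortality is analyzed as census fractions; no time-to-event modelling.
* The backward-selection p-values are not corrected for selection; they
  feed a screening rule (retain at p < 0.5), not inference.
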