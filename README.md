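# phytoclines

Trait–environment analysis of reciprocal-transplant common-garden studies
along climatic moisture gradients.

## The problem

When closely related tree species are planted together in common gardens
spanning a climatic moisture gradient — moisture supply measured by
P/E_p, the ratio of mean annual precipitation to pan evaporation — two
questions can be separated that field surveys confound:

* **Fixed genetic differences**: how does a trait vary *across species
  within a garden* as a function of each species' native moisture supply
  (its range-mean "species P/E_p")?
* **Plasticity (reaction norms)**: how does the trait vary *within a
  species across gardens* as a function of "site P/E_p"?

A third, harder question is whether these differences matter for
performance: does each species outgrow the others under conditions like
those it dominates in nature (**adaptive cross-over**)?

`phytoclines` implements the full analysis chain for such a design, for
ecophysiologists analyzing multi-species transplant experiments:

1. **Derived traits** from raw measurements: minimum leaf conductance
   g_min from bench drying curves, leaf hydraulic conductance
   k_leaf = T/(ψ_stem − ψ_leaf) with a 0.3 MPa gradient filter, stem
   conductivity K_stem from flow–pressure slopes standardized to 20 °C,
   hydraulically weighted vessel diameter D_h = ((1/n)ΣD_i⁴)^(1/4),
   Poiseuille theoretical conductivity, relative growth rates, allometric
   root-mass imputation, and common-slope standardized ratios
   ln T₁ − β ln T₂.
2. **Phylogenetic mixed-model regression** of each trait on ln(site
   P/E_p) and ln(species P/E_p), with up to four random effects — garden,
   species, species-with-phylogeny (Brownian covariance from a
   time-calibrated tree), and phylogeny-nested-in-garden ("phylogenetic
   attraction") — AIC + parsimony fixed-form selection, backward
   elimination of random effects at a generous p < 0.5 cutoff,
   likelihood-ratio R², Benjamini–Yekutieli FDR control over the full
   test family, and weighted tallies of agreement with theoretically
   predicted response directions.
3. **Ordination**: standardized PCA of the trait matrix, projection of
   the two moisture gradients into the PC1–PC2 plane, classification of
   trait vectors into eight adaptive/maladaptive × plastic/fixed sectors,
   and PC-score reaction-norm slopes.
4. **Performance**: realized height growth H* = survival × mean height
   (and the mass analogue M*) with its delta-method standard error

       se² = (p̂² + p̂(1−p̂)/n′)·s²/n + m²·p̂(1−p̂)/n′

   pairwise z-tests with within-garden Benjamini–Hochberg correction and
   compact letter displays, Yates-corrected survival comparisons, Tukey
   HSD on raw means, sigmoid survival fits
   s = s_max / (1 + exp[β(a − P/E_p)]), counterfactual survival
   replacement, and the cross-over detector.
5. **Synthetic data**: a generator producing complete studies with the
   same statistical structure (log-linear trait responses with Brownian
   phylogenetic effects; survival falling with species P/E_p at dry
   gardens and rising at wet ones; height reaction norms steepening with
   site moisture), so every stage is testable end to end without field
   data.

## Worked example

```python
import phytoclines as pc

# a synthetic study at the default design: 10 species x 4 gardens,
# site P/E_p = {0.16, 0.39, 1.03, 1.25}, species P/E_p spanning 0.19-0.98
cfg = pc.SimulationConfig(traits=pc.simulate.default_traits(12), seed=42)
tree = pc.simulate_tree(10, 52.0, seed=42, labels=cfg.species_ids)
traits = pc.simulate_traits(cfg, tree)

res = pc.select_model("trait01", traits, tree, cfg.sites(), cfg.species())
c = res.coefficients
print(f"form={res.form} transform={res.transform.value} "
      f"random effects={'+'.join(res.retained_effects)}")
print(f"b_site = {c['ln_site_pe']['estimate']:.3f}, "
      f"b_species = {c['ln_species_pe']['estimate']:.3f}, "
      f"R2_total = {res.r2_total:.3f}")

cells, _ = pc.simulate_performance(cfg)
growth = [pc.realized_growth(x) for x in cells if x.n_survived > 0]
report = pc.detect_crossover(growth, cfg.sites(), cfg.species())
print(f"crossover={report.crossover} rho_driest={report.rho_driest:.2f} "
      f"rho_wettest={report.rho_wettest:.2f}")
```

prints

```
form=additive transform=none random effects=site+species+species_phylo
b_site = 0.642, b_species = 1.589, R2_total = 0.927
crossover=True rho_driest=-1.00 rho_wettest=1.00
```

The fitted slopes are the trait's responses to log site and log species
moisture supply (generative values 0.66 and 1.47 for this seed — both
inside their intervals); `R2_total` is the likelihood-ratio R² of the
final mixed model against the intercept-only model.  The cross-over
report says species ranks in realized height growth reverse between the
driest garden (H* falls with species P/E_p: dry-adapted species lead)
and the wettest (H* rises: wet-adapted species lead) — the signature of
adaptive cross-over.

The same chain is scriptable from a shell:

```bash
phytoclines simulate --seed 1 --input-dir study/
phytoclines regress  --input-dir study/ --output-dir out/
phytoclines ordinate --input-dir study/ --output-dir out/
phytoclines perform  --input-dir study/ --output-dir out/
phytoclines check    --seed 1            # end-to-end self-check
```

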