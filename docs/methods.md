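# Methods

This note documents the models, the numerical choices and the limitations of
`funcarch`, module by module, the way a maintainer would want them written
down.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The stratified regression model

The per-SNP chi-square of a polygenic trait decomposes as

    E[χ²_j] = N Σ_C τ_C ℓ(j, C) + 1 + Na,

where τ_C is the per-SNP variance coefficient of annotation class C (on the
standardized-genotype scale), ℓ(j, C) the partitioned LD score, and the
intercept term 1 + Na absorbs confounding (none is simulated here, so the
intercept's no-confounding value is 1; it is always estimated, never
constrained).  Classes may overlap; a SNP's total per-SNP variance is the
sum of the τ of all classes containing it, and the universal `base` class
gives every SNP a floor term.  Consequences used throughout:

* h²(C) sums per-SNP variances over members, so h² of a disjoint union is
  exactly the sum of the parts, and `base` has prop_h2 = enrichment = 1
  identically (asserted to 1e−10 in the tests);
* estimates are unbiased and may legitimately be negative when a class's
  true contribution is below its sampling noise — proportions are reported
  as undefined (NaN, with a warning) if the total-h² estimate is ≤ 0.

### Weights

Two-pass weighted least squares.  Pass 1 uses 1/max(1, ℓ_base), the
overcounting correction: a SNP in strong LD with many others carries partly
redundant information.  Pass 2 multiplies by 1/(2·fitted²) with the pass-1
fitted means (floored at 0.1 to keep weights finite), because the variance
of a chi-square grows with the square of its mean.  An OLS mode exists for
closed-form checks.  Weights are treated as fixed in the jackknife.

### Winsorisation

GWAS effect sizes are strongly right-skewed, and a handful of huge peaks
can dominate a least-squares fit.  Chi-squares are capped at 22 by default;
a mode deriving the cap from a P-value threshold
(`winsor_cap_from_p`) exists because a fixed chi-square cap and a fixed
P-value threshold cannot both be honoured exactly (the 1-df chi-square
quantile at P = 1e−7 is 28.37, and χ² = 22 corresponds to P ≈ 2.7e−6); the
fixed cap of 22 is the default.  Winsorisation is applied after the SNP
intersection with the LD scores.  High-LD leverage regions (MHC-like,
yin-yang haplotypes) are excluded by configured BED intervals in
`annotate.filter_snps` — their coordinates are inputs, not constants.

### Block jackknife

SEs for every reported quantity (τ, intercept, h², proportions,
enrichments) come from a delete-one-block jackknife over `n_blocks`
(default 200) contiguous equal-count SNP blocks, computed from per-block
sufficient statistics of the weighted normal equations.  Ratio quantities
are jackknifed directly (the ratio recomputed on each delete-one fit), not
via the delta method, so the same machinery serves everything.  The
jackknife measures GWAS sampling variability *conditional on the reference
panel*: LD scores are data, not parameters.  Calibration therefore holds
when the panel (and its LD scores) is fixed across replicates — the
regime in which the regression is used — and the null-calibration studies
are designed that way.  Two residual caveats, both genuine properties of
the method rather than of this implementation: (i) all SNPs share one GWAS
cohort, which induces a weak global correlation among chi-squares
(O(M/N) variance inflation of averages) that a SNP-block jackknife cannot
see, and (ii) LD scores estimated from a finite panel are noisy regressors,
which attenuates τ toward zero and pushes the surplus into the intercept.
Both effects shrink as n_ref and N grow and are visible at desk scale; the
parameter-recovery acceptance study quantifies total error as
mean-vs-truth within replicate SDs rather than assuming exact unbiasedness.

## LD scores

ℓ(j, C) sums the adjusted squared correlation adj_r² = r² − (1−r²)/(n_ref−2)
over class-C SNPs within a fixed physical window (default ±1 Mb,
configurable) on the same chromosome, self term included (pinned to exactly
1).  The adjustment makes each null cross-term mean-zero, so an isolated
SNP scores exactly 1 on `base`.  Genotypes are standardized on the panel;
windows are symmetric; chromosomes are independent.  cM windows and
MAF-stratified scores are out of scope (the synthetic data has no genetic
map).  In analyses of the synthetic panels the window is set to about twice
the LD-block span (200 kb for the default geometry): beyond the LD range a
wider window only accumulates estimation noise in the regressors.

## Synthetic data

The generators define the study conditions for every validation:

* **Panel.**  Gaussian-copula threshold model: per haplotype, a latent
  AR(1) Gaussian within blocks of `block_len` SNPs (adjacent correlation
  `rho`, independence across blocks), dichotomised at the allele-frequency
  quantile and summed over two haplotypes.  MAFs uniform on [0.05, 0.5];
  SNPs evenly spaced (10 kb default) on one chromosome.  This is the
  simplest model with tunable, analytically checkable LD: genotype r²
  decays monotonically within blocks and is pure noise across them.
* **Sumstats.**  β_j ~ N(0, Σ_{C∋j} τ_C); an explicit cohort of `n_gwas`
  individuals is drawn from the same LD process (never the panel
  individuals); phenotype = standardized-genotype score + Gaussian noise
  scaled to unit phenotypic variance; χ²_j = N·r²(g_j, y) marginal score
  tests.  LD-induced chi-square inflation therefore arises mechanistically
  rather than being injected, and two closed forms hold: mean χ² = 1 under
  the global null, and 1 + N·h²/M without LD.
* **Annotations.**  Interval classes grown from random runs of consecutive
  SNPs until realized coverage is within tolerance of target, plus a
  random scored conservation track for the derivation operations.
* **Architecture profiles.**  Group mean + iid Gaussian noise, for the
  comparison stage.

Default study sizes (M = 10,000, n_ref = 500, N = 20,000, 500 blocks of 20,
rho = 0.8 for recovery; M = 2,000 with N = 20,000 for the 50-replicate null
study) were chosen as the largest configuration that keeps the full
validation suite in the minutes range on a single CPU while leaving the
estimator's asymptotics visibly in force.  What the generator does *not*
emulate: realistic allele-frequency spectra, genetic maps, imputation
noise, population structure or confounding (the intercept is retained to
absorb such effects but none is simulated), cross-chromosome structure, or
the million-SNP scale of real GWAS.  Passing tests demonstrate correctness
of the machinery and calibration under the model's assumptions — not
robustness to the violations real data bring.

## Annotation derivation

Coordinates follow BED: intervals 0-based half-open, SNP positions 1-based,
and a SNP at position p is inside [s, e) iff s < p ≤ e.  All set operations
are validated against per-base boolean-array oracles.

* **Splice flanks.**  Donor = first `flank_nt` (default 70) bases of each
  intron in transcription direction, acceptor = last; introns shorter than
  the flank contribute their whole extent to both.  "Conserved" means mean
  track score over the flank ≥ 0.5 by default — the aggregation over a
  flank is a genuine free choice, so a per-base intersect mode is provided
  (`mode="intersect"`).  Unstranded introns are treated as forward with a
  warning; the flank is exactly `flank_nt` bases (inclusive boundary
  questions resolved toward the plain reading).
* **Conserved enhancer proxies.**  Bases scoring ≥ 0.5, minus every
  already-annotated class (subtraction is order-independent so "other
  annotations" needs no enumeration); the primate-depth class additionally
  excludes the mammal-depth class, making the two disjoint by
  construction, and the pre-subtraction overlap fraction is reported.
* **Subtraction classes** (e.g. brain promoters = tissue promoters minus
  generic promoters) are plain normalized set differences.

## Empirical Bayes

Per class across phenotypes: h ~ Exp(λ), est|h ~ N(h, se²) with the
reported jackknife SE taken as known.  The marginal likelihood per
observation is λ·exp(λ²se²/2 − λ·est)·Φ((est − λse²)/se), maximized over
log λ ∈ [log 1e−3, log 1e4] by bounded scalar search (tolerance 1e−8,
deterministic; hitting a bound sets a warning flag).  The posterior is
N(est − λse², se²) truncated to (0, ∞) and its mean μ′ + se·φ(μ′/se)/Φ(μ′/se)
is evaluated through log-space Mills ratios, so deeply negative estimates
remain stable and map to small positive values.  Negative estimates are
never truncated before fitting — the noise model owns them.  Shrinkage is
applied to per-class proportions of h² by default (the quantity whose
negative estimates motivate the procedure), with absolute h² as the
alternative; phenotypes whose total-h² estimate is non-positive have
undefined proportions and are dropped from the proportion-scale fit with a
warning (both choices the configuration surfaces).  The procedure is
deliberately biased toward the cross-phenotype prior mean 1/λ_C; that bias
cancels in between-phenotype comparisons, which is the use case.

## Architecture comparison

* **Distance.**  L1 between profile rows — a true metric (checked
  exhaustively on small instances).
* **MDS.**  Kruskal non-metric scaling in 2-D: initialize from classical
  Torgerson scaling, then alternate monotone regression of embedded
  distances on dissimilarity ranks (pool-adjacent-violators via
  scikit-learn's isotonic regression; ties handled by the primary
  approach — within tied dissimilarities the current distances set the
  order, so ties impose no constraint) with Guttman majorization updates.
  Stress-1 is tracked, the best configuration kept, max 300 iterations,
  tolerance 1e−6.  An all-zero distance matrix returns coincident points
  with stress 0 and a warning rather than failing.
* **Discriminant.**  Fisher LDA, w ∝ (Σ_pooled + ridge·I)⁻¹(μ₁ − μ₂),
  threshold at the projected midpoint, oriented so the
  psychiatric/behavioral group scores positive.  Default ridge
  1e−3·trace(Σ)/C: with ~20 phenotypes and ~14 classes the pooled
  covariance is near-singular, and an explicit ridge is more transparent
  than a pseudoinverse.  With ridge 0 a singular design raises an error
  naming the collinear classes.  MDS consumes proportions of h²,
  the discriminant consumes enrichment ratios (proportions span three
  orders of magnitude across classes; enrichments are comparable) — both
  switchable.
* **LOO CV.**  Each phenotype held out in turn (each group needs ≥ 3
  members so folds keep ≥ 2); predictions provably independent of the
  held-out label.  Accuracy is reported as-is; no separate "robustness"
  verdict is computed, and the control/other group simply isn't passed to
  the discriminant unless the caller includes it.

## Known limitations

* Finite-panel attenuation and shared-cohort correlation, as discussed
  under the jackknife: τ point estimates at desk scale are accurate to the
  replicate spread, not to arbitrary precision.
* The empirical-Bayes noise model takes jackknife SEs as exact and
  independent across phenotypes; cross-phenotype sample overlap (common in
  real GWAS consortia) is not modeled.
* The CLI writes genotype matrices as plain text, which is fine for
  synthetic panels but not intended for million-SNP datasets.
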