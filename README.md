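# funcarch

Partitioned SNP-heritability and the *functional genetic architecture* of
complex traits.

Complex-trait GWAS signal is spread over thousands of variants, and because
of linkage disequilibrium (LD) individual associations cannot be assigned to
individual functional elements.  Stratified LD-score regression sidesteps
this: SNPs in high LD with a functionally important class of SNPs show
systematically elevated chi-square statistics, so regressing per-SNP
chi-squares on per-class LD scores apportions heritability among annotation
classes (coding, promoters, splice-regulatory flanks, conserved putative
enhancers, ...).  The profile of per-class heritability — a trait's
functional genetic architecture — can then be compared across phenotypes:
psychiatric and behavioral traits load on regulatory and conserved classes,
neurological disorders on coding and splicing classes.

`funcarch` is a tested implementation of that full pipeline for
statistical-genetics practitioners and methodologists, with a synthetic-data
module that generates LD-structured panels, annotations and GWAS summary
statistics under a *known* architecture, so every stage can be validated
against ground truth.

## The model

For SNP j with GWAS sample size N and annotation classes C (possibly
overlapping, always including a universal `base` class),

    E[χ²_j] = N Σ_C τ_C ℓ(j, C) + intercept,

where ℓ(j,C) = Σ_{k∈C, |pos_k−pos_j| ≤ window} adj_r²(r²_jk, n_ref) is the
partitioned LD score from a reference panel (with the unbiased adjustment
adj_r² = r² − (1−r²)/(n_ref−2)) and τ_C is the per-SNP variance contributed
by membership in class C.  From fitted τ:

    h²(C) = Σ_{j∈C} Σ_{C′∋j} τ_C′ ,   prop_h2(C) = h²(C)/h²(base),
    enrichment(C) = prop_h2(C) / proportion_of_snps(C).

Standard errors for every quantity come from a delete-one-block jackknife
over contiguous SNP blocks.  Two data-hygiene steps precede the regression:
configured high-LD regions (e.g. MHC, the GPHN yin-yang region) are
excluded, and chi-squares are winsorised at 22 to limit the leverage of
extreme association peaks.

Because unbiased per-class estimates are noisy and sometimes negative,
estimates are stabilized across a collection of phenotypes by empirical
Bayes: per class, h² values follow an Exponential(λ) prior fitted by
marginal maximum likelihood, and each estimate is replaced by its posterior
mean (a truncated-normal expectation, strictly positive).  Phenotypes are
then compared through the L1 distance between architecture profiles,
embedded in 2-D by Kruskal's non-metric MDS, and classified
(psychiatric/behavioral vs neurological) by a ridge-regularized Fisher
linear discriminant with leave-one-out cross-validation.

## Worked example

Simulate one phenotype with a known architecture — total h² = 0.20 with a
strongly concentrated 2 % "coding" class (true enrichment ≈ 10.8) and a
mildly concentrated 20 % "conserved" class (true enrichment 2.6) — then
recover the partition:

```python
from funcarch import simdata as sim, ldscore as ld, sldsr as sl

spec = (sim.ClassSpec("base", 1.0, 0.08 / 10_000),
        sim.ClassSpec("coding", 0.02, 2.0 / 10_000),
        sim.ClassSpec("conserved", 0.20, 0.4 / 10_000))
cfg = sim.SimConfig(M=10_000, n_ref=500, n_gwas=20_000, block_len=20,
                    rho=0.8, class_spec=spec, seed=42)
panel = sim.generate_panel(cfg)
bundle = sim.generate_annotations(panel, cfg)
scores = ld.partitioned_ld_scores(panel, bundle.matrix, window_bp=200_000)
stats = sl.winsorise_chisq(sim.simulate_sumstats(panel, bundle.matrix, cfg))
fit = sl.fit_sldsr(stats, scores, bundle.matrix, n_blocks=200)
print(fit.to_frame().to_string(index=False, float_format=lambda x: f"{x:.3g}"))
```

prints

```
    class      tau   se_tau     h2   se_h2  prop_h2  se_prop  prop_snps  enrichment  se_enrich
     base 6.39e-06 4.32e-06  0.171  0.0434        1        0          1           1          0
   coding 0.000188 3.76e-05 0.0402 0.00748    0.235   0.0677       0.02        11.8       3.38
conserved 3.47e-05 3.78e-06 0.0897  0.0111    0.525   0.0859        0.2        2.62       0.43
```

The fitted partition recovers the simulated truth within its jackknife
errors: total h² 0.171 ± 0.043 (truth 0.20), the coding class holds 23.5 %
of it in 2 % of SNPs (enrichment 11.8 ± 3.4; truth ≈ 10.8) and the
conserved class 52 % in 20 % of SNPs (enrichment 2.6 ± 0.4; truth 2.6).  The
`base` row is exact by construction, and the intercept (1.05 ± 0.17 here)
sits at its no-confounding value of 1.

The same stages are scriptable from the shell (`funcarch simulate`,
`annotate`, `ldscore`, `sldsr`, `ebayes`, `compare`); each subcommand
exchanges plain TSV/CSV/BED files.

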