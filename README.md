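# vclasso

Lasso-penalized variance-component selection for microbiome association
analysis.

## The problem

Microbiome studies summarize each sample as counts over thousands of
OTUs (operational taxonomic units) linked by a phylogenetic tree, and a
recurring question is *which taxa are associated with a quantitative
phenotype* — lung function, BMI, an inflammation marker. Per-OTU
regression drowns in sparsity (most OTUs are absent from most samples),
and coefficient-level penalties ignore the phylogeny. `vclasso`
aggregates OTUs into taxon clusters (typically genera), encodes each
cluster's phylogenetic community structure as a sample-similarity
kernel, and casts taxon selection as *variance-component selection* in a
linear mixed model:

    Var(y) = σ_d² ZZ' + Σ_l σ_gl² K_l + σ_e² I

Each cluster *l* contributes a random effect with covariance
`σ_gl² K_l`, where `K_l` is built from a UniFrac distance (weighted,
unweighted, variance-adjusted, or generalized with exponent α) by Gower
double-centering, a positive-semidefiniteness correction, and scaling to
unit Frobenius norm. The subject random intercept `σ_d² ZZ'` handles
repeated visits in longitudinal designs and is never penalized.
Associated clusters are those with `σ_gl² > 0`, found by minimizing the
penalized negative log-likelihood

    -L(β, σ²) + λ Σ_i c_i σ_i        (penalty on standard deviations)

with an MM (majorization-minimization) algorithm whose per-component
update is the unique positive root of a quartic — every iteration
provably decreases the objective. λ is tuned by 5-fold cross-validated
g-Measure (`√(sensitivity × specificity)`, simulations with known truth)
or by AIC/BIC (real data). A full synthetic-data engine (Dirichlet-
multinomial and zero-inflated-beta counts, random coalescent trees,
variance-component and fixed-effect phenotype models) makes the entire
pipeline testable without any external data.

Audience: statistical-genetics / microbiome methods researchers and
analysts with genus-level count tables, a rooted tree, and a
quantitative phenotype, cross-sectional or longitudinal.

## Worked example

Simulate a cross-sectional study (n = 50 samples, 31 genus clusters,
5 true associated clusters at effect strength σ_g² = 100), build
weighted-UniFrac kernels, tune λ by cross-validated g-Measure, and fit:

```sh
vclasso simulate --scenario 1 --n 50 --replicates 2 --seed 11 --out sim
# scenario 1: mean g-Measure 0.772 over 2 replicates

vclasso kernel --table sim/counts.tsv --tree sim/tree.nwk \
        --taxonomy sim/taxonomy.tsv --variant w --out kernels
# wrote 31 kernels to kernels

vclasso cv --pheno sim/phenotypes.csv --kernels kernels \
        --truth sim/truth.json --folds 5 --n-lambda 6 --out cv
# lambda* = 0.015

vclasso fit --pheno sim/phenotypes.csv --kernels kernels \
        --lambda 0.015 --out fit
# selected: Genus01, Genus03, Genus04, Genus05, Genus06, Genus07,
#           Genus10, Genus20, Genus24
```

The ground truth (`sim/truth.json`) is Genus01–Genus05. At λ* the model
recovers four of the five true clusters — it misses Genus02, the rarest
of the five — plus five false positives out of 26 nulls (sensitivity
0.8, specificity 0.81). `fit/fit.json` holds the estimates: the selected
clusters' variance components range from 5.6 to 105 (the residual
variance is absorbed to 0 here — the 31 kernels jointly span the
50-sample space), and β̂ = (0.17, −0.28, 0.38) for intercept and the
two covariates. The first line's mean g-Measure (0.772) is the same
selection accuracy averaged over two full tune-and-fit replicates.

For real data (no ground truth), replace `cv` with
`vclasso ic --criterion bic ...`, and add `--longitudinal` to include
the subject random intercept. `vclasso path ... --plot` writes the
solution path `σ̂²(λ)` whose entry order ranks clusters by evidence.

The same pipeline is available as a library (`vclasso.kernels`,
`vclasso.model`, `vclasso.tuning`, `vclasso.simulate`, `vclasso.io`);
see `docs/methods.md` for the model, algorithm, and design choices.

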