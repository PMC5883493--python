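# Methods

## The model

`vclasso` selects microbiome taxon clusters associated with a
quantitative phenotype by treating each cluster as a random effect in a
Gaussian linear mixed model and penalizing the variance components. For
stacked observations `y` (one row per sample, or per subject-visit in a
longitudinal design):

```
y = X beta + Z b + sum_l h_l + eps,
b   ~ N(0, sigma_d^2 I)        (subject random intercepts, longitudinal)
h_l ~ N(0, sigma_gl^2 K_l)     (one random effect per taxon cluster)
eps ~ N(0, sigma_e^2 I)
```

so that `Var(y) = sigma_d^2 ZZ' + sum_l sigma_gl^2 K_l + sigma_e^2 I`.
`K_l` is a positive semidefinite sample-similarity kernel built from a
UniFrac distance among the samples restricted to cluster `l`, so
phylogenetic structure enters the association model through the
covariance, not through per-OTU coefficients. A cluster is "associated"
exactly when its variance component is nonzero; selection is therefore
estimation of the sparsity pattern of `sigma^2 = (sigma_1^2, ...,
sigma_m^2)`.

Estimation minimizes the lasso-penalized negative log-likelihood

```
pl(beta, sigma^2) = 1/2 ln det V + 1/2 (y - X beta)' V^-1 (y - X beta)
                    + lambda * sum_i c_i sigma_i,      V = sum_i sigma_i^2 V_i,
```

subject to `sigma_i^2 >= 0`. Two conventions matter: the penalty acts on
the standard deviations `sigma_i`, not the variances, and the
`-(n/2) ln 2 pi` constant is omitted from the likelihood (it is restored
inside AIC/BIC, where it cancels across models anyway). The residual
component and, in longitudinal designs, the subject random intercept are
unpenalized (`c_i = 0`); fractional `c_i >= 0` are accepted as weights.

## The MM algorithm

`fit` alternates an exact generalized-least-squares update of `beta`
with a majorization-minimization update of the variance components. The
surrogate combines a convexity bound on the quadratic form with the
supporting-hyperplane bound on `ln det`, separating the components; each
per-component minimization reduces to the quartic

```
tr_i * s^4 + lambda c_i * s^3 - sigma_i^4(t) q_i = 0,
tr_i = tr(V^-1 V_i),   q_i = r' V^-1 V_i V^-1 r,
```

whose coefficient sequence has exactly one sign change, hence exactly
one positive root (Newton from the closed-form upper bracket
`(sigma_i^4 q_i / tr_i)^(1/4)`, monotone because the quartic is
increasing and convex on the positive axis). For unpenalized components
the update has the closed form `sigma_i^2 sqrt(q_i / tr_i)`. A component
at exactly zero has a zero constant term and stays at zero: zeros are
absorbing, which is what makes the path sparse.

Every iteration factorizes `V` once (Cholesky); `V^-1` is obtained by a
single solve against the identity, traces as elementwise-product sums,
and quadratic forms from one solve against the residual. No explicit
matrix inverse is formed outside that factorized solve.

Iterations stop when `|pl(t+1) - pl(t)| < tol * (|pl(t)| + 1)` with
default `tol = 1e-4`, and `max_iter = 1000`.

### Boundary polish

Near the optimum, penalized components heading for zero collapse
superlinearly (the update behaves like `s <- const * s^(4/3)`), but the
relative-objective criterion can fire while they are still at
`~1e-5 Var(y)` — above the selection threshold. After the printed
criterion is met, a bounded polish phase (cap 200 iterations) continues
ordinary MM steps until every component is either below the selection
threshold of `1e-8 Var(y)` or stationary. Components below the threshold
are then set to exactly 0 and `beta` is refreshed by GLS under the
cleaned covariance.

### Non-convexity: multistart and local moves

The penalized objective is non-convex and zero is always a stationary
point in the `sigma_i` parametrization, so a single MM run can miss
basins — in particular the basin where a single kernel carries most of
the phenotypic variance, which is unreachable from a shrinking iterate
because zeros absorb. Two bounded safeguards run by default:

- when at most 10 components are penalized and no explicit start is
  given, one extra MM run per component starts from a state where that
  component dominates at the scale-aware level
  `Var(y) / mean(diag V_i)` (a Frobenius-normalized kernel has diagonal
  far below 1, so `Var(y)` itself is far below the basin); with up to 6
  penalized components, pairwise-dominant starts are added;
- greedy local moves after convergence: tentatively zero each active
  component (including unpenalized components stalled near the
  boundary, whose convergence to zero is only geometric) or re-enter an
  absorbed one at its dominant level, re-run MM, and adopt the move only
  if the objective drops (budget 10 trial solves).

Because only improvements are adopted, the reported objective trace is
non-increasing across the whole procedure. With many penalized
components (the 31-cluster setting) the multistart is skipped and only
the default start plus drop moves run — there the signal is spread over
several kernels and the single-kernel degeneracy is not the failure mode
that matters.

### Numerical safeguards

`V` can drift toward singularity during iteration (kernels are rank
`n-1` at most after centering, and the residual variance may head for
zero). The factorization retries with an escalating ridge
(`1e-12 .. 1e-6` times the mean diagonal); if the computed objective
ever *increases* — impossible for exact MM — the solver treats it as
factorization breakdown, keeps the previous (lower) iterate and stops.
Components whose basis matrix is numerically zero (a cluster absent from
every sample in a fold) are unidentifiable and pinned at zero.

A genuine limitation: when the active kernels jointly span all but at
most `p` directions of the sample space, the maximum-likelihood surface
is unbounded below (the residual variance can collapse while GLS zeroes
the remaining residual directions — the classic variance-collapse
degeneracy). The safeguards stop the solver cleanly in that regime, but
no solver can return "the" optimum of an unbounded problem; with 31
low-rank cluster kernels, a positive residual, and n well above p this
regime is not reached in practice.

## Kernels

For each cluster the tree is pruned to the cluster's OTUs and per-sample
proportions are computed within the cluster slice (per-sample cluster
totals as denominators; a flag-level design choice — whole-community
denominators would mix cluster effects). With branch lengths `b_e` and
descending proportions `p_A, p_B`:

- weighted (normalized): `sum b |p_A - p_B| / sum b (p_A + p_B)`;
- generalized, `alpha` in [0,1]:
  `sum b (p_A+p_B)^(alpha-1) |p_A - p_B| / sum b (p_A+p_B)^alpha`
  (`alpha = 1` recovers the weighted-normalized variant exactly);
- unweighted: shared/union branch-length contrast on presence;
- variance-adjusted: branch weights `b / sqrt((p_A+p_B)(2-p_A-p_B))`.

A sample with zero reads in a cluster has no defined distance; the
matrix flags it (NaN row/column) and the caller chooses a policy:
error, drop the cluster, or impute (empty-empty 0, empty-present 1 —
the convention used by the simulation engine, where rare clusters
routinely miss samples).

Distances become kernels by Gower double-centering of the elementwise
squares, `K = -1/2 (I - 11'/n) D∘2 (I - 11'/n)`, followed by eigenvalue
truncation at zero (clip-and-reconstruct rather than diagonal shifting,
preserving the leading geometry) and scaling to unit Frobenius norm —
in that order, so every fitted kernel sits on the unit sphere and the
penalty acts on comparable scales. Diagnostics (number and mass of
clipped eigenvalues, the scale factor) are kept on the kernel object and
written to the manifest.

When a problem is restricted to a subset of samples (cross-validation
folds, train/test splits), kernels are sliced and re-scaled to unit
Frobenius norm on the subset.

## Tuning

- `lambda_max` is operational: the smallest lambda (doubling plus
  bisection, 5% relative precision) at which a full fit selects nothing.
  No closed form exists because zero is always stationary; a one-step
  shrinkage rule was tried and discarded — it underestimates the sparse
  region by an order of magnitude because one step from a tiny restart
  shrinks at any lambda. Default grids descend geometrically from
  `lambda_max` over 10 points to `lambda_max / 100`.
- Cross-validated g-Measure (simulations, truth known): folds split by
  subject so repeated measures never straddle the boundary; per fold and
  lambda the model is refitted (warm-started along the grid) and
  `g = sqrt(sensitivity * specificity)` of the selected set is averaged;
  lambda* maximizes the fold mean, ties to the larger lambda. The
  geometric mean is the conventional reading of the name; a raw-product
  mode is available and is optimum-equivalent (the square is monotone).
- AIC/BIC (real data, no truth): `-2 L + penalty * df` along a path,
  with `df = p + #{nonzero variance components}` — the standard
  count-of-active-parameters convention, since no reference df rule
  exists for this penalty.
- Selection ROC: components are scored by the largest lambda at which
  they enter the solution path (never entering ranks last); the AUROC of
  that ranking against the ground truth uses the Mann-Whitney form with
  average ranks, so ties contribute 1/2 and an uninformative path scores
  0.5. This is a selection ROC; phenotype-prediction ROC is a different
  quantity and is not computed.

## Synthetic data

The generator emulates a longitudinal pulmonary-microbiome cohort at
reduced scale: 31 genus-level clusters over ~300 OTUs (about one tenth
of the cohort's OTU count, so that replicate sweeps run in minutes on
one CPU), with one dominant cluster, a large catch-all, and a long tail
of rare genera spanning four orders of magnitude in mean abundance.
Within a cluster, OTU mass decays as rank^-1.2. The phylogeny is a
random coalescent-style binary tree with Exponential(0.1) branch
lengths, held fixed across replicates of a run.

- Cross-sectional counts: Dirichlet-multinomial with dispersion 0.02 and
  depth 10,000 per sample (marginal proportion variance
  `p(1-p)(theta + (1-theta)/depth)`).
- Longitudinal counts: zero-inflated beta with subject random intercepts
  on both the zero-probability logit (baseline 0.7) and the beta-mean
  logit (per-OTU means proportional to the profile, precision 50), 2-4
  visits per subject drawn uniformly; abundances are rounded to counts
  at the given depth (per-sample totals are not forced to the depth).
- Phenotypes: either one multivariate-normal draw from the
  variance-component model (`sigma_e^2 = 1`; `sigma_d^2 = 0.6`
  longitudinal, 0 cross-sectional; effect strength `sigma_g^2` in
  {1, 5, 25, 100} with equal strength across the true clusters; two
  standard-normal covariates with coefficients 0.1 each), or a
  fixed-effect model in which per-cluster count matrices scaled by their
  sample maximum multiply coefficient vectors
  `gamma_l ~ N(0, sigma_g^2 I)` drawn once per replicate — a
  deliberately misspecified generator for robustness studies.

Scenario presets sweep sample size (20/50/100, five true clusters),
number of true clusters (2/5/15 at n=50; the size-2 preset plants the
two high-abundance clusters, which makes per-replicate sensitivity take
only the values 0, 1/2, 1), kernel variant (all five), and the
fixed-effect generator. Each replicate: simulate counts and phenotype,
build kernels, hold out 20% of subjects, run 5-fold CV on the training
subjects over an 8-point grid to pick lambda*, refit once on the
training set at lambda* and score its selected set; the solution path
over the same grid yields the selection AUROC. Defaults are 20
replicates per cell (the full-size design would use 1000; the reduction
is a compute choice and widens Monte-Carlo bands accordingly).

What the generator does *not* emulate: real phylogenies (the coalescent
tree has no clustered depth structure), taxon-taxon ecological
interactions, compositional coupling between clusters beyond the shared
multinomial depth, batch effects, or covariate-microbiome dependence.
Passing the simulation suite therefore demonstrates correctness of the
machinery and qualitative selection behavior, not field performance on
any particular cohort.

## Numerical conventions

- Selection threshold `1e-8 Var(y)`; path restarts re-enter zeroed
  components at `1e-4 Var(y)` per grid point (zeros being absorbing,
  re-entry opportunities must be given explicitly).
- Default initialization `sigma_i^2(0) = Var(y)/m`: symmetric,
  scale-aware, strictly positive.
- Ties in lambda* go to the larger lambda (parsimony); ties in AUROC
  ranks use average ranks.
- Degenerate inputs: all-zero distance matrices produce the zero kernel,
  flagged un-normalized; all-zero covariance bases are pinned at zero
  variance; rank-deficient fixed-effect designs raise with an
  actionable message.
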