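"""Synthetic microbiome data and phenotype generators.

Emulates the structure of a longitudinal pulmonary-microbiome cohort
(~30 subjects measured 2-4 times, 31 genus-level clusters, very sparse
OTU counts) so the whole selection pipeline is testable end to end:

- OTU counts: Dirichlet-multinomial (cross-sectional) or a zero-inflated
  beta model with subject random intercepts (longitudinal);
- a random coalescent-style phylogenetic tree over the OTUs with
  exponential branch lengths, so UniFrac kernels are computable;
- quantitative phenotypes from either the variance-component model
  y ~ N(Xb, sigma_d^2 ZZ' + sum_l sigma_gl^2 K_l + sigma_e^2 I) or a
  fixed-effect model with per-cluster coefficient vectors;
- scenario presets sweeping sample size, number of true components,
  kernel variant, and the fixed-effect misspecification, with 5-fold
  cross-validated lambda selection and g-Measure / selection-AUROC
  summaries per replicate.

Default parameter values: within-subject variance sigma_e^2 = 1,
between-subject variance sigma_d^2 = 0.6 for longitudinal designs (0
otherwise), effect strength sigma_g^2 in {1, 5, 25, 100} with equal
strength across true components, covariate effects beta_1 = beta_2 = 0.1,
read depth 10,000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .kernels import OTUTable, group_by_taxonomy, kernels_from_table
from .model import build_problem, default_lambda_grid, fit, fit_path
from .tuning import SelectionTruth, cross_validate, g_measure, selection_roc, \
    sensitivity_specificity, subproblem

__all__ = [
    "ScenarioConfig",
    "FixedEffectConfig",
    "default_cluster_profile",
    "random_coalescent_tree",
    "simulate_dm_counts",
    "simulate_zibr_counts",
    "simulate_phenotype_vc",
    "simulate_phenotype_fixed",
    "run_scenario",
]


# --------------------------------------------------------------------------
# cluster profile
# --------------------------------------------------------------------------

# Synthetic 31-cluster genus profile: one dominant cluster, a large
# catch-all, and a long tail of rare genera. Cluster sizes are scaled to
# ~300 OTUs total so that trees, UniFrac distances, and replicate sweeps
# run comfortably on one CPU; relative mean-read weights span four orders
# of magnitude like real genus-level lung-microbiome tables.
_CLUSTER_SIZES = [
    15, 3, 3, 4, 4, 3, 5, 3, 6, 3, 4, 3, 3, 3, 3, 8,
    3, 3, 5, 30, 3, 5, 3, 3, 3, 7, 6, 6, 40, 3, 60,
]
_CLUSTER_WEIGHTS = [
    230.0, 3.0, 40.0, 50.0, 70.0, 40.0, 12.0, 5.0, 175.0, 70.0, 140.0,
    12.0, 37.0, 3.0, 110.0, 1.0, 75.0, 1.0, 135.0, 835.0, 50.0, 16.0,
    37.0, 1.0, 6.0, 1100.0, 40.0, 50.0, 260.0, 370.0, 1010.0,
]
_CLUSTER_NAMES = [f"Genus{i:02d}" for i in range(1, 31)] + ["Others"]


def default_cluster_profile() -> pd.DataFrame:
    """The built-in 31-cluster OTU profile.

    Returns a frame with one row per OTU: ``otu_id``, ``cluster`` and
    ``proportion`` (mean relative abundance; sums to 1). Within a cluster
    the mass decays as rank^-1.2, producing the heavy-tailed,
    mostly-near-zero abundances typical of genus-aggregated count tables.
    """
    rows = []
    for name, size, weight in zip(_CLUSTER_NAMES, _CLUSTER_SIZES, _CLUSTER_WEIGHTS):
        ranks = np.arange(1, size + 1, dtype=float)
        w = ranks**-1.2
        w = w / w.sum() * weight
        for j, wj in enumerate(w, start=1):
            rows.append((f"{name}_otu{j:03d}", name, wj))
    prof = pd.DataFrame(rows, columns=["otu_id", "cluster", "proportion"])
    prof["proportion"] = prof["proportion"] / prof["proportion"].sum()
    return prof


def cluster_order() -> list[str]:
    """Cluster labels in canonical (sorted) order, as kernels are emitted."""
    return sorted(_CLUSTER_NAMES)


# --------------------------------------------------------------------------
# tree
# --------------------------------------------------------------------------

def random_coalescent_tree(
    otu_ids: list[str],
    rng: np.random.Generator,
    branch_scale: float = 0.1,
) -> TreeNode:
    """Random binary tree over the OTUs with exponential branch lengths.

    Built by iteratively coalescing two uniformly chosen lineages; every
    edge gets an independent Exponential(branch_scale) length. The result
    is rooted, with unique leaf labels, suitable for UniFrac.
    """
    if len(otu_ids) == 0:
        raise ValueError("need at least one OTU")
    nodes = []
    for o in otu_ids:
        tip = TreeNode(name=str(o))
        tip.length = float(rng.exponential(branch_scale))
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = int(i), int(j)
        a, b = nodes[i], nodes[j]
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(branch_scale))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


# --------------------------------------------------------------------------
# count generators
# --------------------------------------------------------------------------

def simulate_dm_counts(
    n_samples: int,
    otu_proportions: np.ndarray,
    dispersion: float,
    depth: int,
    rng: np.random.Generator,
    sample_prefix: str = "S",
) -> np.ndarray:
    """Dirichlet-multinomial OTU counts, one row per sample.

    Per sample, a composition is drawn from Dirichlet(a) with
    ``a = otu_proportions * (1 - dispersion) / dispersion`` and counts
    from Multinomial(depth, composition), so each row sums to ``depth``.
    The marginal variance of an OTU's proportion is
    ``p (1 - p) (theta + (1 - theta) / depth)`` with ``theta`` the
    dispersion.
    """
    p = np.asarray(otu_proportions, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("otu_proportions must sum to 1")
    if np.any(p < 0):
        raise ValueError("otu_proportions must be non-negative")
    if not 0.0 < dispersion < 1.0:
        raise ValueError("dispersion must lie strictly in (0, 1)")
    if depth <= 0:
        raise ValueError("depth must be positive")
    conc = p * (1.0 - dispersion) / dispersion
    counts = np.empty((n_samples, p.size), dtype=np.int64)
    for i in range(n_samples):
        comp = rng.dirichlet(conc)
        counts[i] = rng.multinomial(depth, comp)
    return counts


def simulate_zibr_counts(
    n_subjects: int,
    visits: np.ndarray,
    otu_proportions: np.ndarray,
    rng: np.random.Generator,
    zero_prob: float = 0.7,
    precision: float = 50.0,
    subject_sd: float = 1.0,
    depth: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Longitudinal zero-inflated beta OTU counts with subject effects.

    Per subject-visit-OTU cell, a structural zero occurs with probability
    ``logistic(logit(zero_prob) + a_i)`` where ``a_i`` is a subject random
    intercept with sd ``subject_sd``; otherwise the relative abundance is
    Beta with mean ``logistic(logit(mu_j) + b_i)`` (per-OTU baseline mean
    ``mu_j`` proportional to ``otu_proportions``, subject intercept
    ``b_i``) and the given precision. Abundances become counts by
    rounding ``abundance * depth`` — per-sample totals are therefore not
    forced to ``depth``.

    Returns ``(counts, subject_of)`` with one row per subject-visit.
    """
    if not 0.0 <= zero_prob <= 1.0:
        raise ValueError("zero_prob must lie in [0, 1]")
    if subject_sd < 0:
        raise ValueError("subject_sd must be non-negative")
    if precision <= 0:
        raise ValueError("precision must be positive")
    p = np.asarray(otu_proportions, dtype=float)
    mu = np.clip(p / p.max() * 0.5, 1e-6, 1.0 - 1e-6)  # per-OTU beta means
    visits = np.asarray(visits, dtype=int)
    if visits.size != n_subjects or np.any(visits < 1):
        raise ValueError("visits must give a positive visit count per subject")

    rows = []
    subject_of = []
    logit = lambda x: np.log(x / (1.0 - x))
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))
    for i in range(n_subjects):
        a_i = rng.normal(0.0, subject_sd)
        b_i = rng.normal(0.0, subject_sd)
        p_zero = (
            1.0 if zero_prob == 1.0
            else 0.0 if zero_prob == 0.0
            else expit(logit(zero_prob) + a_i)
        )
        mean_i = expit(logit(mu) + b_i)
        for _ in range(visits[i]):
            zero = rng.random(p.size) < p_zero
            ab = np.zeros(p.size)
            nz = ~zero
            if nz.any():
                shape1 = mean_i[nz] * precision
                shape2 = (1.0 - mean_i[nz]) * precision
                ab[nz] = rng.beta(shape1, shape2)
            rows.append(np.round(ab * depth).astype(np.int64))
            subject_of.append(f"subj{i + 1:03d}")
    return np.asarray(rows), np.asarray(subject_of)


def make_otu_table(counts: np.ndarray, profile: pd.DataFrame,
                   sample_ids: list[str] | None = None) -> OTUTable:
    """Wrap a count matrix as an :class:`OTUTable` using a cluster profile."""
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(counts.shape[0])]
    return OTUTable(
        counts=counts,
        sample_ids=sample_ids,
        otu_ids=profile["otu_id"].tolist(),
        taxon_of=dict(zip(profile["otu_id"], profile["cluster"])),
    )


# --------------------------------------------------------------------------
# phenotype generators
# --------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Parameters of a variance-component phenotype simulation."""

    design: str = "cross_sectional"  # or "longitudinal"
    n_subjects: int = 50
    visit_range: tuple[int, int] = (2, 4)
    true_nonzero: tuple[int, ...] = (0, 1, 2, 3, 4)
    sigma_g2: float = 100.0
    sigma_d2: float = 0.6
    sigma_e2: float = 1.0
    beta: tuple[float, ...] = (0.1, 0.1)
    kernel_variant: str = "weighted"
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.design not in ("cross_sectional", "longitudinal"):
            raise ValueError("design must be 'cross_sectional' or 'longitudinal'")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be positive")


@dataclass
class FixedEffectConfig:
    """Parameters of the fixed-effect (misspecified) phenotype model."""

    true_nonzero: tuple[int, ...] = (0, 1, 2, 3, 4)
    sigma_g2: float = 100.0
    sigma_e2: float = 1.0
    beta: tuple[float, ...] = (0.1, 0.1)


def _subject_Z(subject_of: np.ndarray) -> np.ndarray:
    subject_of = np.asarray(subject_of)
    return (subject_of[:, None] == np.unique(subject_of)[None, :]).astype(float)


def simulate_phenotype_vc(
    config: ScenarioConfig,
    kernels: list[np.ndarray],
    X: np.ndarray,
    rng: np.random.Generator,
    subject_of: np.ndarray | None = None,
) -> np.ndarray:
    """One draw of y ~ N(Xb, sigma_d^2 ZZ' + sum sigma_gl^2 K_l + sigma_e^2 I).

    ``kernels`` lists the kernel matrices of the *true* clusters only
    (each enters with variance ``config.sigma_g2``). Cross-sectional
    designs use sigma_d^2 = 0; longitudinal designs require
    ``subject_of``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    beta = np.asarray(config.beta, dtype=float)
    if beta.size != X.shape[1]:
        raise ValueError("beta length must match X columns")
    cov = config.sigma_e2 * np.eye(n)
    for K in kernels:
        K = np.asarray(K, dtype=float)
        if K.shape != (n, n):
            raise ValueError("kernel shape does not match sample count")
        cov += config.sigma_g2 * K
    if config.design == "longitudinal":
        if subject_of is None:
            raise ValueError("longitudinal design requires subject_of")
        Z = _subject_Z(subject_of)
        cov += config.sigma_d2 * (Z @ Z.T)
    mean = X @ beta
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("phenotype covariance is not positive definite") from exc
    return mean + chol @ rng.standard_normal(n)


def simulate_phenotype_fixed(
    config: FixedEffectConfig,
    cluster_tables: list[np.ndarray],
    X: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One draw of y ~ N(Xb + sum_l G_l* gamma_l, sigma_e^2 I).

    ``cluster_tables`` are the raw per-cluster OTU count matrices of the
    clusters carrying signal; each is scaled by its sample maximum and
    multiplied by a coefficient vector gamma_l ~ N(0, sigma_g^2 I) drawn
    once per call (one replicate). All-zero cluster matrices contribute
    nothing, with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    beta = np.asarray(config.beta, dtype=float)
    mean = X @ beta
    for G in cluster_tables:
        G = np.asarray(G, dtype=float)
        if G.shape[0] != n:
            raise ValueError("cluster table row count does not match X")
        gmax = G.max()
        if gmax == 0:
            warnings.warn("all-zero cluster count matrix contributes no signal",
                          stacklevel=2)
            continue
        gamma = rng.normal(0.0, np.sqrt(config.sigma_g2), size=G.shape[1])
        mean = mean + (G / gmax) @ gamma
    return mean + rng.normal(0.0, np.sqrt(config.sigma_e2), size=n)


# --------------------------------------------------------------------------
# scenario runner
# --------------------------------------------------------------------------

_PRESET_TRUTH_SIZES = {2: (19, 29), 5: tuple(range(5)), 15: tuple(range(15))}


def _one_replicate(
    *,
    design: str,
    n_subjects: int,
    truth_idx: tuple[int, ...],
    sigma_g2: float,
    variant: str,
    alpha: float,
    profile: pd.DataFrame,
    tree: TreeNode,
    rng: np.random.Generator,
    fixed_effect: bool = False,
    depth: int = 10_000,
    dispersion: float = 0.02,
    n_lambda: int = 8,
    k_folds: int = 5,
    tol: float = 1e-4,
    sigma_d2: float = 0.6,
    sigma_e2: float = 1.0,
    beta: tuple[float, float] = (0.1, 0.1),
    train_frac: float = 0.8,
) -> dict:
    proportions = profile["proportion"].to_numpy()

    if design == "cross_sectional":
        counts = simulate_dm_counts(n_subjects, proportions, dispersion, depth, rng)
        subject_of = np.array([f"subj{i + 1:03d}" for i in range(n_subjects)])
    else:
        visits = rng.integers(2, 5, size=n_subjects)
        counts, subject_of = simulate_zibr_counts(
            n_subjects, visits, proportions, rng, depth=depth
        )
    table = make_otu_table(counts, profile)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kernels = kernels_from_table(
            table, tree, variant=variant, alpha=alpha, missing="impute"
        )
    names = sorted(kernels)
    kmats = [kernels[k].values for k in names]
    n_total = table.n_samples

    Xcov = rng.standard_normal((n_total, 2))
    cfg = ScenarioConfig(
        design=design,
        n_subjects=n_subjects,
        true_nonzero=truth_idx,
        sigma_g2=sigma_g2,
        sigma_d2=sigma_d2 if design == "longitudinal" else 0.0,
        sigma_e2=sigma_e2,
        beta=beta,
        kernel_variant=variant,
        alpha=alpha,
    )
    if fixed_effect:
        clusters = {lbl: tbl.counts for lbl, tbl in group_by_taxonomy(table).items()}
        fcfg = FixedEffectConfig(
            true_nonzero=truth_idx, sigma_g2=sigma_g2, sigma_e2=sigma_e2, beta=beta
        )
        y = simulate_phenotype_fixed(
            fcfg, [clusters[names[i]] for i in truth_idx], Xcov, rng
        )
    else:
        y = simulate_phenotype_vc(
            cfg, [kmats[i] for i in truth_idx], Xcov, rng,
            subject_of=subject_of if design == "longitudinal" else None,
        )

    X = np.column_stack([np.ones(n_total), Xcov])
    problem = build_problem(
        y, X, dict(zip(names, kmats)),
        subject_of=subject_of if design == "longitudinal" else None,
    )

    # 80/20 train/test split by subject; tuning and selection use training only
    uniq = np.unique(subject_of)
    n_train = max(int(round(train_frac * uniq.size)), k_folds)
    train_subjects = rng.permutation(uniq)[:n_train]
    train_idx = np.flatnonzero(np.isin(subject_of, train_subjects))
    train = subproblem(problem, train_idx)

    truth = SelectionTruth(truth_idx)
    grid = default_lambda_grid(train, n_lambda=n_lambda, min_ratio=0.01)
    report = cross_validate(train, grid, truth, k_folds=k_folds, seed=rng, tol=tol)
    final = fit(train, lam=report.lambda_star, tol=tol)
    pen = np.flatnonzero(train.penalized)
    sel = np.flatnonzero(final.selected[pen])
    sens, spec = sensitivity_specificity(sel, truth, pen.size)
    gm = g_measure(sel, truth, pen.size)
    path = fit_path(train, lambdas=grid, tol=tol)
    auroc = selection_roc(path, truth)
    return {
        "design": design,
        "n": n_subjects,
        "n_true": len(truth_idx),
        "sigma_g2": sigma_g2,
        "variant": variant if variant != "generalized" else f"generalized({alpha})",
        "lambda_star": report.lambda_star,
        "g_measure": gm,
        "sensitivity": sens,
        "specificity": spec,
        "auroc": auroc,
        "n_selected": int(final.selected.sum()),
    }


def run_scenario(
    preset: int,
    n_replicates: int = 20,
    seed: int = 0,
    sigma_g2: float = 100.0,
    design: str = "cross_sectional",
    n_list: tuple[int, ...] | None = None,
    truth_sizes: tuple[int, ...] | None = None,
    variants: tuple | None = None,
    n_lambda: int = 8,
    k_folds: int = 5,
    depth: int = 10_000,
    dispersion: float = 0.02,
) -> pd.DataFrame:
    """Run a simulation scenario and return one row per replicate.

    Presets:

    1. selection vs. sample size: ``n`` in {20, 50, 100}, 5 true clusters;
    2. selection vs. number of true components: n = 50, truth sizes
       {2, 5, 15} (size 2 uses the two high-abundance clusters);
    3. selection vs. kernel variant: n = 50, 5 true clusters, all five
       UniFrac kernels;
    4. fixed-effect (misspecified) generation: n = 50, cross-sectional,
       truth sizes {2, 5, 15}.

    Effect strength defaults to sigma_g^2 = 100; 20 replicates per cell
    (the full-size study uses 1000 — scaled down so a sweep runs in
    minutes on one CPU). The replicate archive carries per-replicate
    g-Measure, sensitivity/specificity, AUROC, and lambda*.
    """
    if preset not in (1, 2, 3, 4):
        raise ValueError("preset must be 1, 2, 3 or 4")
    profile = default_cluster_profile()
    ss = np.random.SeedSequence(seed)
    tree_rng = np.random.default_rng(ss.spawn(1)[0])
    tree = random_coalescent_tree(profile["otu_id"].tolist(), tree_rng)

    cells: list[dict] = []
    if preset == 1:
        for n in n_list or (20, 50, 100):
            cells.append(dict(n_subjects=n, truth_idx=_truth_for_size(5),
                              variant="weighted", alpha=0.5, fixed_effect=False,
                              design=design))
    elif preset == 2:
        for size in truth_sizes or (2, 5, 15):
            cells.append(dict(n_subjects=50, truth_idx=_truth_for_size(size),
                              variant="weighted", alpha=0.5, fixed_effect=False,
                              design=design))
    elif preset == 3:
        default_variants = (
            ("unweighted", 0.5), ("weighted", 0.5), ("variance_adjusted", 0.5),
            ("generalized", 0.0), ("generalized", 0.5),
        )
        for variant, alpha in variants or default_variants:
            cells.append(dict(n_subjects=50, truth_idx=_truth_for_size(5),
                              variant=variant, alpha=alpha, fixed_effect=False,
                              design=design))
    else:
        for size in truth_sizes or (2, 5, 15):
            cells.append(dict(n_subjects=50, truth_idx=_truth_for_size(size),
                              variant="weighted", alpha=0.5, fixed_effect=True,
                              design="cross_sectional"))

    records = []
    for cell in cells:
        for rep, child in enumerate(ss.spawn(n_replicates)):
            rng = np.random.default_rng(child)
            rec = _one_replicate(
                sigma_g2=sigma_g2, profile=profile, tree=tree, rng=rng,
                depth=depth, dispersion=dispersion, n_lambda=n_lambda,
                k_folds=k_folds, **cell,
            )
            rec["scenario"] = preset
            rec["replicate"] = rep
            records.append(rec)
    return pd.DataFrame.from_records(records)


def _truth_for_size(size: int) -> tuple[int, ...]:
    """True-cluster indices (in sorted-cluster order) for a preset size.

    Size 2 targets the two high-abundance clusters (mirroring the
    Prevotella/Veillonella-style choice); sizes 5 and 15 take the first
    5 / 15 clusters in canonical order.
    """
    order = cluster_order()
    if size == 2:
        heavy = ["Genus20", "Genus30"]
        return tuple(order.index(g) for g in heavy)
    return tuple(range(size))
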