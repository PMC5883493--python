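"""Tuning-parameter selection and selection-performance metrics.

In simulations, lambda is chosen by k-fold cross-validation of the
g-Measure — a combination of selection sensitivity and specificity that
needs ground truth, so it applies only when the true nonzero components
are known. For real data, where no truth exists, AIC/BIC over a lambda
path take its place. The selection ROC ranks components by the lambda at
which they first enter the solution path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    FitResult,
    VCProblem,
    entry_lambdas,
    fit,
    fit_path,
    loglikelihood,
    LOG_2PI,
)

__all__ = [
    "SelectionTruth",
    "TuningReport",
    "g_measure",
    "sensitivity_specificity",
    "cross_validate",
    "information_criteria",
    "selection_roc",
    "subproblem",
    "subject_folds",
]


@dataclass
class SelectionTruth:
    """Ground-truth nonzero penalized components (simulation only)."""

    true_nonzero: frozenset[int]

    def __init__(self, true_nonzero) -> None:
        object.__setattr__(self, "true_nonzero", frozenset(int(i) for i in true_nonzero))


@dataclass
class TuningReport:
    """Criterion values along a lambda grid and the chosen optimum."""

    lambda_grid: np.ndarray
    criterion_values: np.ndarray
    lambda_star: float
    criterion: str
    fold_values: np.ndarray | None = None


def sensitivity_specificity(
    selected, truth: SelectionTruth, n_penalized: int
) -> tuple[float, float]:
    """Selection sensitivity and specificity against a known truth.

    ``selected`` is an index set (or boolean mask over the penalized
    components). Penalized components are indexed 0..n_penalized-1.
    """
    sel = _as_index_set(selected, n_penalized)
    true = truth.true_nonzero
    if not true <= set(range(n_penalized)):
        raise ValueError("truth contains indices outside the penalized components")
    n_null = n_penalized - len(true)
    if len(true) == 0 or n_null == 0:
        raise ValueError(
            "sensitivity/specificity undefined: need at least one true and one "
            "null penalized component"
        )
    sens = len(sel & true) / len(true)
    spec = (n_null - len(sel - true)) / n_null
    return sens, spec


def _as_index_set(selected, n_penalized: int) -> set[int]:
    arr = np.asarray(list(selected) if not isinstance(selected, np.ndarray) else selected)
    if arr.dtype == bool:
        if arr.size != n_penalized:
            raise ValueError("boolean selection mask has wrong length")
        return set(np.flatnonzero(arr).tolist())
    out = {int(i) for i in arr.tolist()} if arr.size else set()
    if not out <= set(range(n_penalized)):
        raise ValueError("selected contains indices outside the penalized components")
    return out


def g_measure(
    selected, truth: SelectionTruth, n_penalized: int, mode: str = "geometric"
) -> float:
    """Combined selection accuracy in [0, 1]; 1 iff selected == truth.

    ``mode='geometric'`` (default) returns sqrt(sensitivity*specificity);
    ``mode='product'`` returns the raw product. The two are monotone
    transforms of each other, so lambda selection is unaffected by the
    choice.
    """
    sens, spec = sensitivity_specificity(selected, truth, n_penalized)
    prod = sens * spec
    if mode == "product":
        return prod
    if mode == "geometric":
        return float(np.sqrt(prod))
    raise ValueError(f"unknown mode {mode!r}")


def subject_folds(
    subjects: np.ndarray, k_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Partition observation indices into folds by subject.

    All visits of a subject land in the same fold, so longitudinal
    correlation never leaks across the train/validation boundary.
    """
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    if uniq.size < k_folds:
        raise ValueError(f"need at least {k_folds} subjects for {k_folds}-fold CV")
    perm = rng.permutation(uniq)
    groups = np.array_split(perm, k_folds)
    folds = []
    for g in groups:
        if g.size < 1:
            raise ValueError("empty CV fold; reduce k_folds")
        folds.append(np.flatnonzero(np.isin(subjects, g)))
    return folds


def subproblem(
    problem: VCProblem, idx: np.ndarray, renormalize: bool = True
) -> VCProblem:
    """Restrict a problem to a subset of observations.

    Covariance basis matrices are sliced to the subset; penalized kernel
    slices are rescaled to unit Frobenius norm (keeping every fitted
    kernel on the unit sphere the penalty scale assumes) unless
    ``renormalize=False``.
    """
    idx = np.asarray(idx)
    V_sub = []
    for i, Vi in enumerate(problem.V):
        S = Vi[np.ix_(idx, idx)]
        if renormalize and problem.c[i] > 0:
            fro = np.linalg.norm(S, "fro")
            if fro > 0:
                S = S / fro
        V_sub.append(S)
    return VCProblem(
        y=problem.y[idx],
        X=problem.X[idx],
        V=V_sub,
        c=problem.c.copy(),
        names=list(problem.names),
        subject_of=None if problem.subject_of is None else problem.subject_of[idx],
    )


def cross_validate(
    problem: VCProblem,
    lambda_grid: np.ndarray,
    truth: SelectionTruth,
    k_folds: int = 5,
    seed: int | np.random.Generator = 0,
    mode: str = "geometric",
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> TuningReport:
    """Choose lambda by k-fold cross-validated g-Measure.

    Folds are split by subject. For each lambda the model is fitted on
    each training fold (warm-started along the grid) and the g-Measure of
    the selected set against ``truth`` is averaged over folds; lambda* is
    the grid maximizer, ties broken toward the larger lambda (parsimony).
    """
    if k_folds < 2:
        raise ValueError("k_folds must be at least 2")
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    order = np.argsort(-lambda_grid)  # fit in descending order for warm starts
    lam_desc = lambda_grid[order]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    subjects = (
        problem.subject_of
        if problem.subject_of is not None
        else np.arange(problem.n)
    )
    folds = subject_folds(subjects, k_folds, rng)
    pen_idx = np.flatnonzero(problem.penalized)
    n_pen = pen_idx.size
    scores = np.empty((k_folds, lam_desc.size))
    for f, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(problem.n), val_idx)
        sub = subproblem(problem, train_idx)
        path = fit_path(sub, lambdas=lam_desc, tol=tol, max_iter=max_iter)
        for j, res in enumerate(path):
            sel = np.flatnonzero(res.selected[pen_idx])
            scores[f, j] = g_measure(sel, truth, n_pen, mode=mode)
    mean_desc = scores.mean(axis=0)
    best = np.flatnonzero(mean_desc == mean_desc.max())[0]  # first = largest lambda
    # report in the caller's grid order
    inv = np.argsort(order)
    return TuningReport(
        lambda_grid=lambda_grid,
        criterion_values=mean_desc[inv],
        lambda_star=float(lam_desc[best]),
        criterion=f"g-measure ({mode})",
        fold_values=scores[:, inv],
    )


def information_criteria(
    result: FitResult, problem: VCProblem, criterion: str = "BIC"
) -> float:
    """AIC or BIC of a converged fit.

    ``-2 L + penalty * df`` with ``df = p + #{nonzero variance
    components}`` and penalty 2 (AIC) or ln(n) (BIC). The likelihood here
    includes the -(n/2) ln 2*pi constant; it is the same for every model
    on the same data, so criterion differences are unaffected.
    """
    crit = criterion.upper()
    if crit not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    n = problem.n
    ll = loglikelihood(problem, result.beta, result.sigma2) - 0.5 * n * LOG_2PI
    df = problem.p + int(np.count_nonzero(result.sigma2))
    penalty = 2.0 if crit == "AIC" else float(np.log(n))
    return -2.0 * ll + penalty * df


def ic_path(
    problem: VCProblem,
    lambda_grid: np.ndarray | None = None,
    criterion: str = "BIC",
    **path_kwargs,
) -> TuningReport:
    """Score a solution path by an information criterion; pick lambda*."""
    from .model import fit_path as _fit_path

    path = _fit_path(problem, lambdas=lambda_grid, **path_kwargs)
    lams = np.array([r.lam for r in path])
    vals = np.array([information_criteria(r, problem, criterion) for r in path])
    best = np.flatnonzero(vals == vals.min())[0]  # descending grid: first = largest
    return TuningReport(
        lambda_grid=lams,
        criterion_values=vals,
        lambda_star=float(lams[best]),
        criterion=criterion.upper(),
    )


def selection_roc(path: list[FitResult], truth: SelectionTruth) -> float:
    """AUROC of the entry-lambda ranking of components against truth.

    Each penalized component is scored by the largest lambda at which it
    appears in the solution path (components that never enter score below
    every lambda). ``truth`` indexes the penalized components in their
    problem order. Computed by the Mann-Whitney formulation with average
    ranks, so exact ties contribute 1/2 — if all components tie the AUROC
    is 0.5.
    """
    if not path:
        raise ValueError("empty path")
    from scipy.stats import rankdata

    if path[0].penalized is None:
        raise ValueError("path results carry no penalized mask")
    pen_idx = np.flatnonzero(path[0].penalized)
    scores = entry_lambdas(path)[pen_idx]
    labels = np.array([i in truth.true_nonzero for i in range(pen_idx.size)])
    if not labels.any() or labels.all():
        raise ValueError("truth must contain some but not all penalized components")
    ranks = rankdata(scores)
    n_t = int(labels.sum())
    n_f = scores.size - n_t
    u = ranks[labels].sum() - n_t * (n_t + 1) / 2.0
    return float(u / (n_t * n_f))
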