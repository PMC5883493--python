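"""Lasso-penalized variance-component estimation via an MM algorithm.

The model is a Gaussian linear mixed model written in variance-component
form: y ~ N(X beta, V(sigma2)) with V(sigma2) = sum_i sigma2_i V_i over
known symmetric PSD basis matrices V_i (a subject random-intercept block
ZZ' for longitudinal designs, one kernel per taxon cluster, and the
identity for residual error). Taxon selection is achieved by an L1
penalty on the standard deviations sigma_i of the penalized components:

    pl(beta, sigma2) = -L(beta, sigma2) + lambda * sum_i c_i * sigma_i,

minimized subject to sigma2 >= 0 by alternating an exact generalized
least squares update of beta with a majorization-minimization (MM) update
of the variance components. The MM surrogate separates the components, so
each sigma_i update reduces to picking the best of {0, the unique positive
root of a quartic}. Every iteration provably decreases the penalized
objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "VCProblem",
    "FitResult",
    "loglikelihood",
    "penalized_objective",
    "update_beta",
    "update_sigma",
    "fit",
    "fit_path",
    "lambda_max",
    "entry_lambdas",
    "build_problem",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class VCProblem:
    """Response, fixed-effect design, and ordered covariance basis.

    Parameters
    ----------
    y
        Response vector, length ``n`` (stacked over subjects for
        longitudinal designs).
    X
        Fixed-effect design, shape ``(n, p)``; include the intercept
        column explicitly.
    V
        Ordered covariance basis matrices, each ``(n, n)`` symmetric PSD.
        The residual identity component must be present (conventionally
        last) and unpenalized.
    c
        Penalty indicator/weight per component, ``c_i >= 0``; ``c_i = 0``
        marks unpenalized components (residual error, and the subject
        random intercept in longitudinal designs).
    names
        Component labels (cluster names); defaults to ``V1..Vm``.
    subject_of
        Per-observation subject label, used for subject-level CV folds.
    """

    y: np.ndarray
    X: np.ndarray
    V: list[np.ndarray]
    c: np.ndarray
    names: list[str] | None = None
    subject_of: np.ndarray | None = None
    _Vstack: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.size
        if self.X.shape[0] != n:
            raise ValueError("X row count does not match y length")
        self.c = np.asarray(self.c, dtype=float).ravel()
        if np.any(self.c < 0):
            raise ValueError("penalty weights c must be non-negative")
        if len(self.V) != self.c.size:
            raise ValueError("one penalty weight per covariance component required")
        Vs = []
        for i, Vi in enumerate(self.V):
            Vi = np.asarray(Vi, dtype=float)
            if Vi.shape != (n, n):
                raise ValueError(f"V[{i}] has shape {Vi.shape}, expected {(n, n)}")
            if not np.allclose(Vi, Vi.T, atol=1e-10):
                raise ValueError(f"V[{i}] is not symmetric")
            Vs.append(0.5 * (Vi + Vi.T))
        self.V = Vs
        self._Vstack = np.stack(Vs)
        if self.names is None:
            self.names = [f"V{i + 1}" for i in range(len(Vs))]
        if len(self.names) != len(Vs):
            raise ValueError("one name per component required")
        has_identity_unpenalized = any(
            self.c[i] == 0 and np.allclose(Vi, np.eye(n)) for i, Vi in enumerate(Vs)
        )
        if not has_identity_unpenalized:
            warnings.warn(
                "no unpenalized identity (residual) component found; "
                "V(sigma2) may become singular",
                stacklevel=2,
            )
        if self.subject_of is not None:
            self.subject_of = np.asarray(self.subject_of)
            if self.subject_of.size != n:
                raise ValueError("subject_of length does not match y")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def m(self) -> int:
        return len(self.V)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def penalized(self) -> np.ndarray:
        """Boolean mask of penalized components."""
        return self.c > 0


@dataclass
class FitResult:
    """Outcome of one penalized fit at a single lambda."""

    beta: np.ndarray
    sigma2: np.ndarray
    lam: float
    objective_trace: np.ndarray
    iterations: int
    converged: bool
    selected: np.ndarray
    names: list[str]
    penalized: np.ndarray | None = None

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    def selected_names(self) -> list[str]:
        return [n for n, s in zip(self.names, self.selected) if s]


def _assemble_V(problem: VCProblem, sigma2: np.ndarray) -> np.ndarray:
    return np.tensordot(sigma2, problem._Vstack, axes=(0, 0))


def _factorize(problem: VCProblem, sigma2: np.ndarray):
    Vmat = _assemble_V(problem, sigma2)
    try:
        return cho_factor(Vmat, lower=True)
    except (np.linalg.LinAlgError, ValueError):
        pass
    # near-singular V (e.g. the residual variance collapsing while the
    # active kernels are low-rank): retry with escalating ridge jitter
    if not np.all(np.isfinite(Vmat)):
        raise np.linalg.LinAlgError(
            "V(sigma2) contains non-finite entries (variance iterate diverged)"
        )
    scale = max(float(np.mean(np.diag(Vmat))), np.finfo(float).tiny)
    for jitter in (1e-12, 1e-10, 1e-8, 1e-6):
        try:
            return cho_factor(Vmat + jitter * scale * np.eye(problem.n),
                              lower=True)
        except (np.linalg.LinAlgError, ValueError):
            continue
    raise np.linalg.LinAlgError(
        "V(sigma2) is numerically singular; ensure the residual variance "
        "component stays positive"
    )


def loglikelihood(problem: VCProblem, beta: np.ndarray, sigma2: np.ndarray) -> float:
    """Gaussian log-likelihood -1/2 ln det V - 1/2 r' V^-1 r.

    The additive -(n/2) ln 2*pi constant is omitted (it cancels in all
    comparisons); :func:`vclasso.tuning.information_criteria` restores it.
    Computed from a Cholesky factorization, never an explicit inverse.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    factor = _factorize(problem, sigma2)
    r = problem.y - problem.X @ np.asarray(beta, dtype=float).ravel()
    logdet = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
    quad = float(r @ cho_solve(factor, r))
    return -0.5 * logdet - 0.5 * quad


def penalized_objective(
    problem: VCProblem, beta: np.ndarray, sigma2: np.ndarray, lam: float
) -> float:
    """Penalized objective: -loglik + lambda * sum_i c_i * sigma_i.

    The lasso penalty acts on standard deviations sigma_i = sqrt(sigma2_i),
    not on the variances.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 < 0):
        raise ValueError("sigma2 must be non-negative")
    pen = float(lam * np.sum(problem.c * np.sqrt(sigma2)))
    return -loglikelihood(problem, beta, sigma2) + pen


def update_beta(problem: VCProblem, sigma2: np.ndarray, factor=None) -> np.ndarray:
    """Generalized least squares update (X' V^-1 X)^-1 X' V^-1 y."""
    if factor is None:
        factor = _factorize(problem, np.asarray(sigma2, dtype=float))
    VinvX = cho_solve(factor, problem.X)
    XtVinvX = problem.X.T @ VinvX
    XtVinvy = VinvX.T @ problem.y
    try:
        beta = np.linalg.solve(XtVinvX, XtVinvy)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "X' V^-1 X is singular: remove collinear covariates from X"
        ) from exc
    if not np.all(np.isfinite(beta)):
        raise np.linalg.LinAlgError(
            "GLS solve produced non-finite coefficients; V(sigma2) is too "
            "ill-conditioned"
        )
    return beta


def _positive_quartic_root(tr_i: float, lam_ci: float, k: float) -> float:
    """Unique positive root of P(s) = tr_i s^4 + lam_ci s^3 - k (k > 0).

    The coefficient sequence has exactly one sign change, so exactly one
    positive root exists. P is increasing and convex on s > 0, so Newton
    from the upper bracket (k / tr_i)^(1/4) converges monotonically.
    """
    s = (k / tr_i) ** 0.25
    if s < 1e-120:
        # root is squeezed into [0, s]; the distinction is far below any
        # selection threshold and s**3 would underflow inside Newton
        return s
    for _ in range(100):
        f = tr_i * s**4 + lam_ci * s**3 - k
        fp = 4.0 * tr_i * s**3 + 3.0 * lam_ci * s**2
        if not np.isfinite(f) or fp <= 0.0:
            break
        step = f / fp
        s_new = s - step
        if s_new <= 0:  # pragma: no cover - bracket guarantees positivity
            s_new = 0.5 * s
        if abs(s_new - s) <= 1e-16 * max(s, 1e-300):
            s = s_new
            break
        s = s_new
    return s


def _trace_and_quad(problem: VCProblem, factor, r: np.ndarray):
    """tr(V^-1 V_i) and q_i = r' V^-1 V_i V^-1 r for every component.

    One Cholesky solve against the identity gives V^-1; traces are then
    elementwise-product sums and quadratic forms use u = V^-1 r.
    """
    n = problem.n
    Vinv = cho_solve(factor, np.eye(n))
    traces = np.einsum("ij,kij->k", Vinv, problem._Vstack)
    u = cho_solve(factor, r)
    quads = np.einsum("i,kij,j->k", u, problem._Vstack, u)
    return traces, quads


def update_sigma(
    problem: VCProblem,
    beta: np.ndarray,
    sigma2: np.ndarray,
    lam: float,
    factor=None,
) -> np.ndarray:
    """One MM update of all variance components.

    For each component the surrogate is minimized in closed form: the
    update is the unique positive root of
    ``tr_i s^4 + lam c_i s^3 - sigma_i^4(t) q_i = 0`` (squared), or 0 when
    the constant term vanishes — zeros are absorbing under MM. For
    unpenalized components (c_i = 0) this reduces to
    ``sigma2_i * sqrt(q_i / tr_i)``.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 < 0):
        raise ValueError("sigma2 must be non-negative")
    if factor is None:
        factor = _factorize(problem, sigma2)
    r = problem.y - problem.X @ np.asarray(beta, dtype=float).ravel()
    traces, quads = _trace_and_quad(problem, factor, r)
    if not (np.all(np.isfinite(traces)) and np.all(np.isfinite(quads))):
        raise np.linalg.LinAlgError(
            "trace/quadratic-form computation degenerated; V(sigma2) is too "
            "ill-conditioned"
        )
    out = np.empty_like(sigma2)
    for i in range(problem.m):
        if traces[i] <= 0.0:
            # V_i is (numerically) the zero matrix — e.g. a taxon cluster
            # absent from every sample — so sigma2_i is unidentifiable
            out[i] = 0.0
            continue
        k = sigma2[i] ** 2 * quads[i]  # sigma_i^4(t) * q_i
        if k <= 0.0:
            out[i] = 0.0
            continue
        lam_ci = lam * problem.c[i]
        if lam_ci == 0.0:
            out[i] = sigma2[i] * np.sqrt(quads[i] / traces[i])
        else:
            out[i] = _positive_quartic_root(traces[i], lam_ci, k) ** 2
    return out


def _default_init(problem: VCProblem) -> np.ndarray:
    v = float(np.var(problem.y))
    if v <= 0:
        v = 1.0
    return np.full(problem.m, v / problem.m)


def _mm_solve(
    problem: VCProblem,
    lam: float,
    sigma2: np.ndarray,
    tol: float,
    max_iter: int,
    selection_threshold: float,
    polish_iter: int,
):
    """Core alternating MM loop from a given starting point.

    Returns ``(beta, sigma2, trace, iterations, converged)``. The trace
    is the penalized objective per iteration (non-increasing by the MM
    descent property).
    """
    var_y = float(np.var(problem.y))
    factor = _factorize(problem, sigma2)
    beta = update_beta(problem, sigma2, factor=factor)
    trace = [penalized_objective(problem, beta, sigma2, lam)]
    converged = False
    iterations = 0
    polishing = False
    polish_left = polish_iter

    while iterations < max_iter and (not polishing or polish_left > 0):
        beta_prev = beta
        sigma2_new = update_sigma(problem, beta, sigma2, lam, factor=factor)
        if not np.all(np.isfinite(sigma2_new)):
            raise np.linalg.LinAlgError(
                "variance-component update diverged (non-finite values); "
                "V(sigma2) is too ill-conditioned"
            )
        factor = _factorize(problem, sigma2_new)
        beta = update_beta(problem, sigma2_new, factor=factor)
        obj = penalized_objective(problem, beta, sigma2_new, lam)
        iterations += 1
        prev = trace[-1]
        if not np.isfinite(obj) or obj > prev + 1e-9 * (1.0 + abs(prev)):
            # MM descent holds in exact arithmetic; a computed ascent means
            # the factorization has broken down (V near-singular at a
            # boundary). Keep the previous, lower iterate and stop.
            beta = beta_prev
            break
        trace.append(obj)

        if polishing:
            polish_left -= 1
            delta = np.abs(sigma2_new - sigma2)
            # every component must be either effectively zero or stationary
            # (components heading for the boundary converge slowly, and the
            # objective criterion can fire long before they arrive)
            settled = (
                (sigma2_new < selection_threshold)
                | (delta < 1e-6 * max(var_y, 1e-300))
            )
            sigma2 = sigma2_new
            if settled.all():
                break
        else:
            sigma2 = sigma2_new
            if abs(obj - prev) < tol * (abs(prev) + 1.0):
                converged = True
                if not problem.penalized.any():
                    break
                polishing = True

    return beta, sigma2, trace, iterations, converged


def fit(
    problem: VCProblem,
    lam: float,
    init: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
    selection_threshold: float | None = None,
    polish_iter: int = 200,
    refine: bool = True,
    refine_budget: int = 10,
    multistart_limit: int = 10,
) -> FitResult:
    """Minimize the penalized objective at one lambda by alternating MM.

    Iterates GLS beta updates and MM sigma updates until the relative
    objective change satisfies ``|pl(t+1) - pl(t)| < tol * (|pl(t)| + 1)``
    (default ``tol=1e-4``). After that criterion fires, a bounded "polish"
    phase keeps iterating until every penalized component has either
    dropped below the selection threshold or become stationary — penalized
    components collapse to zero superlinearly, so without the polish they
    can be caught mid-collapse at small but nonzero values. All polish
    steps are ordinary MM iterations, so descent is preserved.

    The objective is non-convex and zeros are absorbing under MM, so a
    single start can settle on a poor stationary point. Two safeguards
    (both on by default via ``refine=True``) address this:

    - multistart: when no explicit ``init`` is given and at most
      ``multistart_limit`` components are penalized, one extra MM run per
      penalized component starts from a state where that component
      dominates, and the best end point is kept (basins where a single
      kernel carries most of the variance are otherwise unreachable,
      because a shrinking component can never re-grow once absorbed);
    - greedy drop refinement: each active penalized component is
      tentatively zeroed and MM re-run from there, adopting the move when
      it lowers the objective (at most ``refine_budget`` trial solves,
      smallest components first).

    Only improvements are adopted, so the reported objective trace stays
    non-increasing.

    Components below ``selection_threshold`` (default ``1e-8 * Var(y)``)
    are set to exactly 0 on exit and beta is refreshed by GLS under the
    cleaned covariance. Non-convergence returns ``converged=False``, never
    raises.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    var_y = float(np.var(problem.y))
    if selection_threshold is None:
        selection_threshold = 1e-8 * max(var_y, np.finfo(float).tiny)
    sigma2 = _default_init(problem) if init is None else np.asarray(init, dtype=float).copy()
    if sigma2.size != problem.m:
        raise ValueError("init has wrong length")
    if np.any(sigma2 < 0):
        raise ValueError("init must be non-negative")

    try:
        beta, sigma2, trace, iterations, converged = _mm_solve(
            problem, lam, sigma2, tol, max_iter, selection_threshold, polish_iter
        )
    except np.linalg.LinAlgError:
        if init is None:
            raise
        # a pathological warm start (e.g. along a path) can drive V nearly
        # singular; recover from the default initialization instead
        beta, sigma2, trace, iterations, converged = _mm_solve(
            problem, lam, _default_init(problem), tol, max_iter,
            selection_threshold, polish_iter,
        )

    pen_idx = np.flatnonzero(problem.penalized)
    small_m = 0 < pen_idx.size <= multistart_limit
    var_y = float(np.var(problem.y))

    def _dominant_level(i: int) -> float:
        # variance level at which component i alone accounts for Var(y),
        # given its diagonal scale (Frobenius-normalized kernels have
        # diagonals far below 1)
        diag_mean = float(np.mean(np.diag(problem.V[i])))
        return var_y / max(diag_mean, 1e-12)

    if refine and init is None and small_m:
        base = _default_init(problem)
        starts: list[np.ndarray] = []
        for i in pen_idx:
            start = base / 10.0
            start[i] = _dominant_level(i)
            starts.append(start)
        if pen_idx.size <= 6:  # pairwise-dominant basins
            for a in range(pen_idx.size):
                for b in range(a + 1, pen_idx.size):
                    i, j = pen_idx[a], pen_idx[b]
                    start = base / 10.0
                    start[i] = 0.5 * _dominant_level(i)
                    start[j] = 0.5 * _dominant_level(j)
                    starts.append(start)
        for start in starts:
            try:
                sb, ss, strace, siter, sconv = _mm_solve(
                    problem, lam, start, tol, max_iter,
                    selection_threshold, polish_iter,
                )
            except np.linalg.LinAlgError:
                continue
            iterations += siter
            if strace[-1] < trace[-1] - 1e-10 * (1.0 + abs(trace[-1])):
                beta, sigma2, converged = sb, ss, sconv
                trace.append(strace[-1])

    if refine and problem.penalized.any():
        trials = 0
        improved = True
        while improved and trials < refine_budget:
            improved = False
            # drop moves: every active penalized component, plus unpenalized
            # components lingering near the boundary (their convergence to 0
            # is only geometric, so they can stall at small positive values)
            droppable = problem.penalized | (sigma2 < 1e-2 * max(var_y, 1e-300))
            active = np.flatnonzero(droppable & (sigma2 > selection_threshold))
            moves = [("drop", i) for i in active[np.argsort(sigma2[active])]]
            if small_m:
                # add moves: re-enter an absorbed component at its dominant
                # scale (zeros cannot re-grow under MM on their own)
                absorbed = pen_idx[sigma2[pen_idx] <= selection_threshold]
                moves += [("add", i) for i in absorbed]
            for kind, i in moves:
                if trials >= refine_budget:
                    break
                trial_init = sigma2.copy()
                trial_init[i] = 0.0 if kind == "drop" else _dominant_level(i)
                if not np.any(trial_init > 0):
                    continue
                try:
                    tb, ts, ttrace, titer, tconv = _mm_solve(
                        problem, lam, trial_init, tol, max_iter,
                        selection_threshold, polish_iter,
                    )
                except np.linalg.LinAlgError:
                    trials += 1
                    continue
                trials += 1
                iterations += titer
                if ttrace[-1] < trace[-1] - 1e-10 * (1.0 + abs(trace[-1])):
                    beta, sigma2 = tb, ts
                    converged = converged and tconv
                    trace.append(ttrace[-1])
                    improved = True
                    break

    small = sigma2 < selection_threshold
    sigma2 = np.where(small, 0.0, sigma2)
    if np.any(sigma2 > 0):
        factor = _factorize(problem, sigma2)
        beta = update_beta(problem, sigma2, factor=factor)
    selected = problem.penalized & (sigma2 > 0)
    return FitResult(
        beta=beta,
        sigma2=sigma2,
        lam=float(lam),
        objective_trace=np.asarray(trace),
        iterations=iterations,
        converged=converged,
        selected=selected,
        names=list(problem.names),
        penalized=problem.penalized.copy(),
    )


def _null_fit(problem: VCProblem, tol: float, max_iter: int) -> FitResult:
    """Unpenalized-components-only maximum-likelihood fit."""
    init = _default_init(problem)
    init[problem.penalized] = 0.0
    return fit(problem, lam=0.0, init=init, tol=tol, max_iter=max_iter)


def lambda_max(
    problem: VCProblem,
    tol: float = 1e-4,
    max_iter: int = 1000,
    bisect_rel: float = 0.05,
) -> float:
    """Smallest lambda driving every penalized component to zero.

    With the standard-deviation parametrization sigma = 0 is always a
    stationary point, so no closed-form lambda_max exists. The anchor used
    here is operational: the smallest lambda (within ``bisect_rel``
    relative precision, by doubling plus bisection) at which a full fit
    from the default initialization selects no penalized component. Fits
    at large lambda are sparse and converge in few iterations, so the
    search is cheap.
    """
    if not problem.penalized.any():
        raise ValueError("problem has no penalized components")

    def all_zero(lam: float) -> bool:
        res = fit(problem, lam=lam, tol=tol, max_iter=max_iter)
        return not bool(res.selected.any())

    lo, hi = 0.0, 1.0
    for _ in range(60):
        if all_zero(hi):
            break
        lo, hi = hi, hi * 2.0
    else:  # pragma: no cover - pathological scaling
        return hi
    while hi - lo > bisect_rel * hi:
        mid = 0.5 * (lo + hi)
        if all_zero(mid):
            hi = mid
        else:
            lo = mid
    return hi


def default_lambda_grid(
    problem: VCProblem, n_lambda: int = 10, min_ratio: float = 0.01
) -> np.ndarray:
    """Descending geometric grid from lambda_max to lambda_max * min_ratio."""
    lmax = lambda_max(problem)
    return lmax * np.geomspace(1.0, min_ratio, n_lambda)


def fit_path(
    problem: VCProblem,
    lambdas: np.ndarray | None = None,
    n_lambda: int = 10,
    min_ratio: float = 0.01,
    tol: float = 1e-4,
    max_iter: int = 1000,
    restart_frac: float = 1e-4,
) -> list[FitResult]:
    """Warm-started fits along a descending lambda grid.

    Zeros are absorbing under MM, so at each grid point components sitting
    at 0 in the warm start are restarted at ``restart_frac * Var(y)``,
    giving them the opportunity to re-enter at smaller lambda. Entry order
    along the path ranks components by evidence strength.
    """
    if lambdas is None:
        lambdas = default_lambda_grid(problem, n_lambda=n_lambda, min_ratio=min_ratio)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("lambda grid is empty")
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda grid must be sorted in descending order")
    var_y = float(np.var(problem.y))
    restart = restart_frac * max(var_y, np.finfo(float).tiny)
    results: list[FitResult] = []
    warm: np.ndarray | None = None
    for lam in lambdas:
        init = None
        if warm is not None:
            init = warm.copy()
            init[init == 0.0] = restart
        res = fit(problem, lam=lam, init=init, tol=tol, max_iter=max_iter)
        warm = res.sigma2
        results.append(res)
    return results


def entry_lambdas(path: list[FitResult]) -> np.ndarray:
    """Largest lambda at which each component is selected along a path.

    Components never selected score -1 (below any admissible lambda),
    placing them last in the evidence ranking used by the selection ROC.
    """
    if not path:
        raise ValueError("empty path")
    m = path[0].sigma2.size
    entry = np.full(m, -1.0)
    for res in path:
        newly = (entry == -1.0) & res.selected
        entry[newly] = res.lam
    return entry


def build_problem(
    y: np.ndarray,
    X: np.ndarray,
    kernels,
    subject_of: np.ndarray | None = None,
    sigma_d_penalized: bool = False,
) -> VCProblem:
    """Assemble a :class:`VCProblem` from kernels plus standard components.

    Appends the subject random-intercept component ZZ' (when
    ``subject_of`` is given, unpenalized) and the residual identity
    (always, unpenalized) after the penalized kernel components.

    ``kernels`` may be a mapping name -> matrix/KernelMatrix or a
    sequence of matrices.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if hasattr(kernels, "items"):
        items = list(kernels.items())
    else:
        items = [(f"K{i + 1}", K) for i, K in enumerate(kernels)]
    V: list[np.ndarray] = []
    names: list[str] = []
    c: list[float] = []
    for name, K in items:
        mat = K.values if hasattr(K, "values") and not isinstance(K, np.ndarray) else K
        V.append(np.asarray(mat, dtype=float))
        names.append(str(name))
        c.append(1.0)
    if subject_of is not None:
        subject_of = np.asarray(subject_of)
        Z = (subject_of[:, None] == np.unique(subject_of)[None, :]).astype(float)
        V.append(Z @ Z.T)
        names.append("subject")
        c.append(1.0 if sigma_d_penalized else 0.0)
    V.append(np.eye(n))
    names.append("residual")
    c.append(0.0)
    return VCProblem(
        y=y, X=X, V=V, c=np.asarray(c), names=names, subject_of=subject_of
    )
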