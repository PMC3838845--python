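"""Group-penalized least-squares solvers: SCAD, group LASSO, and baselines.

The estimators minimize

    (1/2n) || Y - Z theta ||^2  +  sum_m p(||theta_m||_{K_m})

over the stacked, weight-transformed design, where each factor group m is a
consecutive column block (a covariate's non-diseased/diseased coefficient pair
in the fused ROC regression, or a single column for the separate per-group
baseline).  The penalty p is either the SCAD (nonconvex, shape constant
a = 3.7, unbiased for large effects) or the group-LASSO norm penalty tau * w.

Groups are standardized before penalization: each block is orthonormalized by a
QR factorization so its Gram matrix is n * I, which makes the groupwise
coordinate-descent update an exact closed-form threshold and fixes the penalty
norm to ||theta_m||_{K_m} with K_m = Z_m'Z_m / n.  A user-supplied positive
definite K_m replaces that default, in which case the group update is a
majorize-minimize step.  Coordinate descent sweeps the groups until the
objective is stationary; warm starts carry solutions along a decreasing tuning
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import StackedDesign, TwoGroupSample

__all__ = [
    "PenaltySpec",
    "PenalizedFit",
    "SolutionPath",
    "scad_derivative",
    "scad_penalty",
    "fit_group_scad",
    "group_scad_path",
    "group_lasso_path",
    "fit_separate_scad",
    "separate_scad_path",
    "penalized_objective",
]

ZTOL = 1e-8
MAX_SWEEPS = 2000
COEF_TOL = 1e-8  # relative max coefficient change per sweep


@dataclass(frozen=True)
class PenaltySpec:
    """Tuning parameter, SCAD shape constant, and optional group norm matrices."""

    lam: float
    a: float = 3.7
    norm_matrices: list[np.ndarray] | None = None

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.a <= 2:
            raise ValueError("SCAD shape constant a must exceed 2")
        if self.norm_matrices is not None:
            for K in self.norm_matrices:
                K = np.asarray(K, float)
                if not np.allclose(K, K.T) or np.any(np.linalg.eigvalsh(K) <= 0):
                    raise ValueError("norm matrices must be symmetric positive definite")


@dataclass(frozen=True)
class PenalizedFit:
    """A single penalized fit: coefficients, active factor set, diagnostics."""

    theta: np.ndarray
    active_groups: frozenset[int]
    lam: float
    objective_value: float
    sigma_hat_sq: float
    df: int


@dataclass
class SolutionPath:
    """Fits along a strictly decreasing tuning grid."""

    fits: list[PenalizedFit]
    grid: np.ndarray
    penalty_kind: str

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        if len(self.fits) != len(self.grid):
            raise ValueError("one fit per grid point required")
        if len(self.grid) > 1 and not np.all(np.diff(self.grid) < 0):
            raise ValueError("tuning grid must be strictly decreasing")


# ---------------------------------------------------------------------------
# SCAD penalty primitives


def scad_derivative(w, lam: float, a: float = 3.7):
    """SCAD derivative: lam on [0, lam], linear decay to 0 at a*lam, 0 beyond."""
    w = np.asarray(w, float)
    if np.any(w < 0):
        raise ValueError("SCAD derivative is defined for non-negative w")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    out = np.where(w <= lam, lam, np.maximum(0.0, a * lam - w) / (a - 1))
    return float(out) if out.ndim == 0 else out


def scad_penalty(w, lam: float, a: float = 3.7):
    """SCAD penalty p(w): antiderivative of the derivative with p(0) = 0.

    Equals lam*w on [0, lam], a concave quadratic on [lam, a*lam], and the
    constant (a+1)*lam^2/2 beyond, so large effects are not shrunk.
    """
    w = np.asarray(w, float)
    if np.any(w < 0):
        raise ValueError("SCAD penalty is defined for non-negative w")
    quad = (2 * a * lam * w - w**2 - lam**2) / (2 * (a - 1))
    out = np.where(w <= lam, lam * w, np.where(w <= a * lam, quad, (a + 1) * lam**2 / 2))
    return float(out) if out.ndim == 0 else out


def _scad_penalty_scalar(w: float, lam: float, a: float) -> float:
    if w <= lam:
        return lam * w
    if w <= a * lam:
        return (2 * a * lam * w - w * w - lam * lam) / (2 * (a - 1))
    return (a + 1) * lam * lam / 2


def _prox_norm(b: float, kind: str, lam: float, a: float, h: float) -> float:
    """argmin_{t >= 0}  0.5 * h * (t - b)^2 + p(t)  for the group-norm magnitude.

    ``h`` is the majorization curvature (1 on orthonormalized groups, where the
    solution is exact and the SCAD minimizer is the familiar three-piece rule).
    For h != 1 the piecewise-quadratic objective's clipped stationary points
    are compared directly.
    """
    if kind == "none":
        return b
    if kind == "lasso":
        return max(0.0, b - lam / h)
    if h == 1.0:  # exact SCAD threshold on a standardized group
        if b <= 2 * lam:
            return max(0.0, b - lam)
        if b <= a * lam:
            return ((a - 1) * b - a * lam) / (a - 2)
        return b
    cands = [min(max(b - lam / h, 0.0), lam)]
    den = h * (a - 1) - 1.0
    if den > 0:
        t2 = (h * b * (a - 1) - a * lam) / den
        cands.append(min(max(t2, lam), a * lam))
    else:
        cands.extend([lam, a * lam])
    cands.append(max(a * lam, b))

    def g(t):
        return 0.5 * h * (t - b) ** 2 + _scad_penalty_scalar(t, lam, a)

    return min(cands, key=g)


def _penalty_value(w: float, kind: str, lam: float, a: float) -> float:
    if kind == "none" or w == 0.0:
        return 0.0
    if kind == "lasso":
        return lam * w
    return _scad_penalty_scalar(w, lam, a)


# ---------------------------------------------------------------------------
# core coordinate-descent engine (array-level, group-structured)


class _GroupWorkspace:
    """Standardized design blocks shared across the fits of a path.

    Each group block Z_m is mapped to A_m with A_m'A_m = n I (QR
    standardization) or, under a user norm matrix K_m, to Z_m chol(K_m)^{-T}
    with a majorization curvature h_m.  Coefficients live on the alpha scale
    (alpha_m = ||.||-penalized coordinates); ``back`` maps them to theta.
    """

    def __init__(self, Y, Z, groups, norm_matrices=None):
        self.Y = np.asarray(Y, float)
        self.n = len(self.Y)
        self.groups = [tuple(g) for g in groups]
        self.idx = [np.asarray(g, dtype=int) for g in self.groups]
        self.blocks, self.back, self.h = [], [], []
        for m, cols in enumerate(self.groups):
            Zm = Z[:, list(cols)]
            if norm_matrices is None:
                Q, R = np.linalg.qr(Zm)
                if np.any(np.abs(np.diag(R)) < 1e-12 * max(1.0, np.abs(R).max())):
                    raise ValueError(f"group {m} is rank deficient")
                self.blocks.append(np.sqrt(self.n) * Q)
                self.back.append(np.sqrt(self.n) * np.linalg.inv(R))
                self.h.append(1.0)
            else:
                L = np.linalg.cholesky(np.asarray(norm_matrices[m], float))
                Am = Zm @ np.linalg.inv(L).T
                self.blocks.append(Am)
                self.back.append(np.linalg.inv(L).T)
                self.h.append(float(np.linalg.eigvalsh(Am.T @ Am / self.n).max()))
        # covariance-update quantities: sweeps touch G and c, never the rows
        self.A = np.hstack(self.blocks) if self.blocks else np.empty((self.n, 0))
        self.G = self.A.T @ self.A
        self.c0 = self.A.T @ self.Y

    def theta_from_alpha(self, alpha):
        theta = np.empty(sum(len(g) for g in self.groups))
        for cols, B in zip(self.idx, self.back):
            theta[cols] = B @ alpha[cols]
        return theta

    def alpha_norms(self, alpha):
        return np.array([np.linalg.norm(alpha[c]) for c in self.idx])


def _descend(ws: _GroupWorkspace, kinds, lam, a, alpha0=None):
    """Sweep groups with exact/MM threshold updates until the coefficients
    are stationary.  Uses covariance updates: the gradient vector
    c = A'(Y - A alpha) is maintained through the Gram matrix, so a sweep
    never touches the data rows."""
    n = ws.n
    p = ws.G.shape[0]
    if alpha0 is None:
        alpha = np.zeros(p)
        c = ws.c0.copy()
    else:
        alpha = alpha0.copy()
        c = ws.c0 - ws.G @ alpha
    for _ in range(MAX_SWEEPS):
        max_delta = 0.0
        for idx, h, kind in zip(ws.idx, ws.h, kinds):
            am = alpha[idx]
            b = am + c[idx] / (n * h)
            bnorm = float(np.linalg.norm(b))
            tnorm = _prox_norm(bnorm, kind, lam, a, h)
            new = np.zeros_like(am) if tnorm <= 0 or bnorm == 0 else (tnorm / bnorm) * b
            delta = new - am
            md = float(np.abs(delta).max())
            if md > 0.0:
                c -= ws.G[:, idx] @ delta
                alpha[idx] = new
                if md > max_delta:
                    max_delta = md
        if max_delta <= COEF_TOL * max(1.0, float(np.abs(alpha).max())):
            break
    r = ws.Y - ws.A @ alpha
    obj = 0.5 * float(r @ r) / n + sum(
        _penalty_value(w, kind, lam, a)
        for w, kind in zip(ws.alpha_norms(alpha), kinds)
    )
    return alpha, r, obj


def _finalize(ws, alpha, r, obj, lam, group_sizes):
    norms = ws.alpha_norms(alpha)
    active = frozenset(int(m) for m in np.where(norms > ZTOL)[0])
    alpha = alpha.copy()
    for m, cols in enumerate(ws.groups):
        if m not in active:
            alpha[list(cols)] = 0.0
    theta = ws.theta_from_alpha(alpha)
    df = int(sum(group_sizes[m] for m in active))
    return PenalizedFit(
        theta=theta,
        active_groups=active,
        lam=float(lam),
        objective_value=float(obj),
        sigma_hat_sq=float(r @ r) / ws.n,
        df=df,
    ), alpha


def penalized_objective(
    design: StackedDesign,
    theta: np.ndarray,
    spec: PenaltySpec,
    penalty_kind: str = "scad",
    unpenalized_groups: frozenset = frozenset(),
) -> float:
    """Recompute (1/2n)||Y - Z theta||^2 + sum p(||theta_m||_{K_m}) at theta.

    The group norm uses the same standardization convention as the solver
    (K_m = Z_m'Z_m/n unless ``spec.norm_matrices`` overrides it).
    """
    Y, Z, n = design.response, design.design, design.n
    r = Y - Z @ theta
    total = 0.5 * float(r @ r) / n
    for m, cols in enumerate(design.groups):
        if m in unpenalized_groups:
            continue
        tm = theta[list(cols)]
        if spec.norm_matrices is None:
            K = Z[:, list(cols)].T @ Z[:, list(cols)] / n
        else:
            K = np.asarray(spec.norm_matrices[m], float)
        w = float(np.sqrt(tm @ K @ tm))
        total += _penalty_value(w, penalty_kind, spec.lam, spec.a)
    return total


# ---------------------------------------------------------------------------
# public fitting interfaces


def _require_transformed(design: StackedDesign):
    if not design.transformed:
        raise ValueError("design must be weight-transformed before penalized fitting")
    if design.n == 0:
        raise ValueError("empty design")


def fit_group_scad(
    design: StackedDesign,
    spec: PenaltySpec,
    unpenalized_groups: frozenset = frozenset(),
) -> PenalizedFit:
    """Group-SCAD estimate on the transformed stacked design.

    Every factor group outside ``unpenalized_groups`` is penalized through the
    SCAD on its group norm, so a covariate's non-diseased and diseased
    coefficients enter or leave together.  At lam = 0 this is weighted least
    squares.  Returns a stationary point of the nonconvex objective with
    groupwise exact zeros.
    """
    _require_transformed(design)
    ws = _GroupWorkspace(design.response, design.design, design.groups, spec.norm_matrices)
    kinds = ["none" if m in unpenalized_groups else ("scad" if spec.lam > 0 else "none")
             for m in range(design.d)]
    # two deterministic starts (all-zero and least squares) guard against the
    # nonconvex objective's spurious stationary points on small problems
    A_full = np.hstack(ws.blocks)
    alpha_ls, *_ = np.linalg.lstsq(A_full, ws.Y, rcond=None)
    best = None
    for start in (None, alpha_ls):
        alpha, r, obj = _descend(ws, kinds, spec.lam, spec.a, alpha0=start)
        if best is None or obj < best[2] - 1e-12:
            best = (alpha, r, obj)
    sizes = [len(g) for g in design.groups]
    fit, _ = _finalize(ws, *best, spec.lam, sizes)
    return fit


def _default_grid(bound: float, n_grid: int, ratio: float) -> np.ndarray:
    if bound <= 0:
        bound = 1e-8
    return np.geomspace(bound, bound * ratio, n_grid)


def _run_path(ws, kinds_fn, grid, a, sizes, penalty_kind) -> SolutionPath:
    fits = []
    alpha = None
    for lam in grid:
        kinds = kinds_fn(lam)
        alpha, r, obj = _descend(ws, kinds, lam, a, alpha0=alpha)
        fit, alpha = _finalize(ws, alpha, r, obj, lam, sizes)
        fits.append(fit)
    return SolutionPath(fits=fits, grid=np.asarray(grid, float), penalty_kind=penalty_kind)


def group_scad_path(
    design: StackedDesign,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
    grid_ratio: float = 1e-3,
    a: float = 3.7,
    unpenalized_groups: frozenset = frozenset(),
) -> SolutionPath:
    """Warm-started group-SCAD fits along a decreasing lambda grid.

    The default grid is ``n_grid`` log-spaced points from the KKT bound (the
    smallest lambda with an empty penalized active set) down to
    ``grid_ratio`` times that bound.
    """
    _require_transformed(design)
    ws = _GroupWorkspace(design.response, design.design, design.groups)
    penalized = [m for m in range(design.d) if m not in unpenalized_groups]
    if grid is None:
        # lock penalized groups at zero (infinite lasso penalty) to get the
        # null-fit residual, then read the groupwise KKT bound off it
        null_kinds = ["none" if m in unpenalized_groups else "lasso" for m in range(design.d)]
        alpha, r, _ = _descend(ws, null_kinds, lam=np.inf, a=a)
        bound = max(float(np.linalg.norm(ws.blocks[m].T @ r / ws.n)) for m in penalized)
        grid = _default_grid(bound, n_grid, grid_ratio)
    else:
        grid = np.asarray(grid, float)
        if np.any(grid <= 0) or (len(grid) > 1 and not np.all(np.diff(grid) < 0)):
            raise ValueError("grid must be positive and strictly decreasing")

    def kinds_fn(lam):
        return ["none" if m in unpenalized_groups else "scad" for m in range(design.d)]

    sizes = [len(g) for g in design.groups]
    return _run_path(ws, kinds_fn, grid, a, sizes, "group_scad")


def group_lasso_path(
    design: StackedDesign,
    narrow_groups: frozenset,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
    grid_ratio: float = 1e-3,
) -> SolutionPath:
    """Group-LASSO path over the extension factors, narrow factors unpenalized.

    Used in Stage 2 of the FIC procedure: the Stage-1 narrow factors stay in
    the model at every tau; the recorded active sets are the extension subsets
    that form the FIC search domain.
    """
    _require_transformed(design)
    narrow_groups = frozenset(narrow_groups)
    if not narrow_groups <= set(range(design.d)):
        raise ValueError("narrow_groups must be a subset of the factor indices")
    ws = _GroupWorkspace(design.response, design.design, design.groups)
    penalized = [m for m in range(design.d) if m not in narrow_groups]
    if not penalized:
        raise ValueError("no extension factors to penalize")
    if grid is None:
        null_kinds = ["none" if m in narrow_groups else "lasso" for m in range(design.d)]
        alpha, r, _ = _descend(ws, null_kinds, lam=np.inf, a=3.7)
        bound = max(float(np.linalg.norm(ws.blocks[m].T @ r / ws.n)) for m in penalized)
        grid = _default_grid(bound, n_grid, grid_ratio)
    else:
        grid = np.asarray(grid, float)
        if np.any(grid < 0) or (len(grid) > 1 and not np.all(np.diff(grid) < 0)):
            raise ValueError("grid must be non-negative and strictly decreasing")

    def kinds_fn(tau):
        return ["none" if m in narrow_groups else ("lasso" if tau > 0 else "none")
                for m in range(design.d)]

    sizes = [len(g) for g in design.groups]
    path = _run_path(ws, kinds_fn, grid, 3.7, sizes, "group_lasso")
    return path


def _separate_arrays(sample: TwoGroupSample, group_label: str):
    if group_label == "diseased":
        return sample.y_diseased, sample.z_diseased
    if group_label == "nondiseased":
        return sample.y_nondiseased, sample.z_nondiseased
    raise ValueError("group_label must be 'diseased' or 'nondiseased'")


def fit_separate_scad(
    sample: TwoGroupSample, spec: PenaltySpec, group_label: str
) -> PenalizedFit:
    """Ordinary (non-grouped) SCAD fit of one group's regression alone.

    The baseline that selects variables independently per disease group; the
    comparison convention reports model size as the sum of the two per-group
    selected-variable counts.
    """
    if not sample.centered:
        raise ValueError("center the sample before fitting")
    y, Z = _separate_arrays(sample, group_label)
    groups = [(j,) for j in range(Z.shape[1])]
    ws = _GroupWorkspace(y, Z, groups)
    kinds = ["scad" if spec.lam > 0 else "none"] * Z.shape[1]
    alpha, r, obj = _descend(ws, kinds, spec.lam, spec.a)
    fit, _ = _finalize(ws, alpha, r, obj, spec.lam, [1] * Z.shape[1])
    return fit


def separate_scad_path(
    sample: TwoGroupSample,
    group_label: str,
    grid: np.ndarray | None = None,
    n_grid: int = 100,
    grid_ratio: float = 1e-3,
    a: float = 3.7,
) -> SolutionPath:
    """Warm-started per-variable SCAD path for one group's own regression."""
    if not sample.centered:
        raise ValueError("center the sample before fitting")
    y, Z = _separate_arrays(sample, group_label)
    d = Z.shape[1]
    ws = _GroupWorkspace(y, Z, [(j,) for j in range(d)])
    if grid is None:
        bound = max(float(np.linalg.norm(ws.blocks[j].T @ ws.Y / ws.n)) for j in range(d))
        grid = _default_grid(bound, n_grid, grid_ratio)
    else:
        grid = np.asarray(grid, float)
        if np.any(grid <= 0) or (len(grid) > 1 and not np.all(np.diff(grid) < 0)):
            raise ValueError("grid must be positive and strictly decreasing")

    def kinds_fn(lam):
        return ["scad"] * d

    return _run_path(ws, kinds_fn, grid, a, [1] * d, "separate_scad")
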