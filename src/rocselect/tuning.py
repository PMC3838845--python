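"""Tuning-parameter selection (BIC / AIC / GCV / k-fold CV) and the F-measure.

All criteria operate on a :class:`~rocselect.penalties.SolutionPath` fitted on
the weight-transformed stacked design; the residual variance entering each
score is measured on that same transformed scale so the criteria are
scale-coherent with the fitting objective (`weighted_scale=False` switches BIC
and friends to raw residuals).  Degrees of freedom count the coordinates of the
active factor groups.  Grid ties break toward the larger tuning value, i.e. the
sparser model.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data import StackedDesign
from .penalties import PenalizedFit, SolutionPath, group_scad_path

__all__ = [
    "bic_select",
    "aic_select",
    "gcv_select",
    "cv_select",
    "selection_fmeasure",
    "criterion_scores",
]


def _raw_sigma_sq(design: StackedDesign, fit: PenalizedFit) -> float:
    r = design.response / np.sqrt(design.weights) - (design.design / np.sqrt(design.weights)[:, None]) @ fit.theta
    return float(r @ r) / design.n


def _sigma_sq(path_fit: PenalizedFit, design: StackedDesign | None, weighted_scale: bool) -> float:
    if weighted_scale or design is None:
        return path_fit.sigma_hat_sq
    return _raw_sigma_sq(design, path_fit)


def criterion_scores(
    path: SolutionPath,
    n: int,
    kind: str,
    design: StackedDesign | None = None,
    weighted_scale: bool = True,
) -> np.ndarray:
    """Score every fit on the path under one information criterion.

    BIC: log(sigma^2) + df log(n)/n.  AIC: log(sigma^2) + 2 df / n.
    GCV: sigma^2 / (1 - df/n)^2, with df >= n excluded (NaN, warned).
    """
    scores = np.empty(len(path.fits))
    for i, fit in enumerate(path.fits):
        s2 = _sigma_sq(fit, design, weighted_scale)
        if kind in ("bic", "aic") and s2 <= 0:
            raise ValueError("degenerate saturated fit: zero residual variance")
        if kind == "bic":
            scores[i] = np.log(s2) + fit.df * np.log(n) / n
        elif kind == "aic":
            scores[i] = np.log(s2) + 2.0 * fit.df / n
        elif kind == "gcv":
            if fit.df >= n:
                warnings.warn(f"GCV undefined at df={fit.df} >= n={n}; grid point excluded")
                scores[i] = np.nan
            else:
                scores[i] = s2 / (1.0 - fit.df / n) ** 2
        else:
            raise ValueError(f"unknown criterion {kind!r}")
    return scores


def _argmin_sparse(grid: np.ndarray, scores: np.ndarray) -> int:
    """First (largest tuning value) index attaining the minimal finite score."""
    finite = np.isfinite(scores)
    if not finite.any():
        raise ValueError("no admissible grid point")
    best = np.nanmin(scores[finite])
    return int(np.flatnonzero(finite & (scores <= best))[0])


def _select(path, n, kind, design, weighted_scale):
    if not path.fits:
        raise ValueError("empty solution path")
    scores = criterion_scores(path, n, kind, design, weighted_scale)
    i = _argmin_sparse(path.grid, scores)
    return float(path.grid[i]), path.fits[i]


def bic_select(
    path: SolutionPath, n: int, design: StackedDesign | None = None, weighted_scale: bool = True
) -> tuple[float, PenalizedFit]:
    """Pick the grid point minimizing log(sigma_hat^2) + df log(n)/n.

    Consistent for the narrow model under the group SCAD: as n grows, the
    selected active set converges to the set of always-present factors.
    """
    return _select(path, n, "bic", design, weighted_scale)


def aic_select(
    path: SolutionPath, n: int, design: StackedDesign | None = None, weighted_scale: bool = True
) -> tuple[float, PenalizedFit]:
    """Pick the grid point minimizing log(sigma_hat^2) + 2 df / n."""
    return _select(path, n, "aic", design, weighted_scale)


def gcv_select(
    path: SolutionPath, n: int, design: StackedDesign | None = None, weighted_scale: bool = True
) -> tuple[float, PenalizedFit]:
    """Pick the grid point minimizing generalized cross-validation
    sigma_hat^2 / (1 - df/n)^2."""
    return _select(path, n, "gcv", design, weighted_scale)


def stratified_fold_indices(
    n_nondiseased: int, n_diseased: int, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Row indices per fold, preserving the non-diseased:diseased ratio."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    parts: list[list[int]] = [[] for _ in range(folds)]
    for offset, size in ((0, n_nondiseased), (n_nondiseased, n_diseased)):
        perm = rng.permutation(size) + offset
        for k, chunk in enumerate(np.array_split(perm, folds)):
            parts[k].extend(chunk.tolist())
    return [np.sort(np.array(p, dtype=int)) for p in parts]


def cv_select(
    design: StackedDesign,
    grid: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    unpenalized_groups: frozenset = frozenset(),
    weighted_scale: bool = True,
) -> tuple[float, PenalizedFit]:
    """k-fold cross-validation of the group-SCAD tuning parameter.

    Folds are stratified by disease status.  For each fold the penalized path
    is refitted on the training rows and scored by held-out squared prediction
    error on the transformed (weighted) scale — or the raw scale if
    ``weighted_scale`` is False.  The winning tuning value is refitted on the
    full design.
    """
    if not design.transformed:
        raise ValueError("design must be weight-transformed")
    grid = np.asarray(grid, float)
    rng = np.random.default_rng(seed)
    fold_idx = stratified_fold_indices(design.n_nondiseased, design.n_diseased, folds, rng)
    sse = np.zeros(len(grid))
    all_rows = np.arange(design.n)
    scale = np.ones(design.n) if weighted_scale else 1.0 / np.sqrt(design.weights)
    for test_rows in fold_idx:
        train = np.setdiff1d(all_rows, test_rows)
        sub = StackedDesign(
            response=design.response[train],
            design=design.design[train],
            weights=design.weights[train],
            groups=list(design.groups),
            n_nondiseased=int((train < design.n_nondiseased).sum()),
            n_diseased=int((train >= design.n_nondiseased).sum()),
            transformed=True,
        )
        path = group_scad_path(sub, grid=grid, unpenalized_groups=unpenalized_groups)
        for i, fit in enumerate(path.fits):
            pred = design.design[test_rows] @ fit.theta
            err = (design.response[test_rows] - pred) * scale[test_rows]
            sse[i] += float(err @ err)
    i = _argmin_sparse(grid, sse)
    full_path = group_scad_path(design, grid=grid[i : i + 1], unpenalized_groups=unpenalized_groups)
    return float(grid[i]), full_path.fits[0]


def selection_fmeasure(selected: set, true_narrow: set) -> float:
    """Harmonic mean of selection precision and recall against the narrow set.

    Precision = |selected ∩ truth| / |selected|, recall = |selected ∩ truth| /
    |truth|; defined as 0 when both vanish, and 1 exactly when the selection
    equals the truth.
    """
    truth = set(true_narrow)
    if not truth:
        raise ValueError("true narrow set must be nonempty")
    sel = set(selected)
    if not sel:
        return 0.0
    hits = len(sel & truth)
    precision = hits / len(sel)
    recall = hits / len(truth)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
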