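"""Two-stage focused selection: narrow model by group SCAD + BIC, then FIC.

Under the local-misspecification model the extension coefficients are of order
delta/sqrt(n), so no criterion aiming at consistency or prediction alone is
tailored to the estimand of interest — here the AUC at a covariate profile z0.
The focused information criterion (FIC) scores each candidate extension subset
S by a parametric estimate of the mean squared error of the post-selection
plug-in AUC:

    FIC(S) = [omega' (I - G_S) delta_hat]^2  +  2 omega_S' (pi_S Q^{-1} pi_S')^{-1} omega_S

with G_S = pi_S'(pi_S Q^{-1} pi_S')^{-1} pi_S Q^{-1}, where Q is the extension
block of the inverse information, omega maps extension misspecification into
the focus, and delta_hat = sqrt(n) * gamma_hat_full rescales the full-model
extension estimate to the local-alternative scale.  The first term estimates
the squared bias from omitting extension factors outside S; the second grows
with |S| and accounts for the variance of estimating their coefficients.

The candidate subsets are not all 2^L: Stage 2 searches only the active sets
appearing on a group-LASSO solution path with the narrow factors unpenalized,
which keeps the search stable and linear in the path length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import (
    FocusSpec,
    ModelParameters,
    StackedDesign,
    TwoGroupSample,
    apply_weights,
    auc_from_parameters,
    build_stacked_design,
    center_two_group,
    estimate_group_variances,
    make_focus,
    unstack_coefficients,
)
from .penalties import SolutionPath, group_lasso_path, group_scad_path
from .tuning import bic_select

logger = logging.getLogger(__name__)

__all__ = [
    "FICComponents",
    "FICScore",
    "SelectionResult",
    "stage1_narrow_model",
    "fic_components",
    "fic_score",
    "select_tau_fic",
    "two_stage_fit",
    "wls_refit",
]


@dataclass(frozen=True)
class FICComponents:
    """Information blocks, focus gradient split, and local-effect estimate.

    Coordinates are the stacked ones reordered narrow-block first; extension
    factors are listed in ``extension_factors`` order, two coordinates each.
    """

    info_matrix: np.ndarray
    Q: np.ndarray
    omega: np.ndarray
    delta_hat: np.ndarray
    focus: FocusSpec
    narrow_factors: tuple[int, ...]
    extension_factors: tuple[int, ...]

    def __post_init__(self):
        if len(self.omega) != len(self.delta_hat):
            raise ValueError("omega and delta_hat must share the extension dimension")


@dataclass(frozen=True)
class FICScore:
    """FIC value of one candidate extension subset."""

    candidate_set: frozenset[int]
    squared_bias_term: float
    variance_term: float

    @property
    def total(self) -> float:
        return self.squared_bias_term + self.variance_term


@dataclass
class SelectionResult:
    """Everything the two-stage pipeline decided, for audit and reporting."""

    narrow_set: frozenset[int]
    final_set: frozenset[int]
    lambda_bic: float
    tau_fic: float | None
    theta_nondiseased: np.ndarray
    theta_diseased: np.ndarray
    sigma_nondiseased: float
    sigma_diseased: float
    auc_at_z0: float
    z0: np.ndarray
    stage2_skipped: bool = False
    fic_trace: list[FICScore] = field(default_factory=list)


def stage1_narrow_model(
    design: StackedDesign, n_grid: int = 100, weighted_scale: bool = True
) -> tuple[frozenset[int], float]:
    """Identify the narrow model: BIC-selected active set of the group-SCAD path."""
    path = group_scad_path(design, n_grid=n_grid)
    lam, fit = bic_select(path, design.n, design=design, weighted_scale=weighted_scale)
    if not fit.active_groups:
        logger.info("stage 1 selected an empty narrow model")
    return fit.active_groups, lam


def _coord_indices(factors, groups) -> list[int]:
    idx: list[int] = []
    for m in factors:
        idx.extend(groups[m])
    return idx


def wls_refit(design: StackedDesign, factors) -> np.ndarray:
    """Least squares on the transformed design restricted to ``factors``.

    Returns the full-length stacked coefficient vector with zeros elsewhere.
    """
    theta = np.zeros(design.design.shape[1])
    cols = _coord_indices(sorted(factors), design.groups)
    if cols:
        coef, *_ = np.linalg.lstsq(design.design[:, cols], design.response, rcond=None)
        theta[cols] = coef
    return theta


def fic_components(
    design: StackedDesign,
    narrow: frozenset[int],
    focus: FocusSpec,
    delta_scale: str = "total",
) -> FICComponents:
    """Assemble J, Q, omega, and delta_hat for FIC scoring.

    ``focus.gradient`` must be in stacked coordinates on the same parameter
    scale as the design's coefficients.  ``delta_scale`` chooses the
    local-alternative rescaling of the full-model extension estimate: "total"
    multiplies by sqrt(n) (coherent with J_n = Z~'Z~/n built from the pooled
    weighted design, the default), "per_group" by each coordinate's own group
    size sqrt(n_g).
    """
    if not design.transformed:
        raise ValueError("design must be weight-transformed")
    narrow = frozenset(narrow)
    d = design.d
    if narrow == set(range(d)):
        raise ValueError("narrow model already contains every factor: FIC is degenerate")
    extension = tuple(m for m in range(d) if m not in narrow)
    narrow_t = tuple(sorted(narrow))
    n = design.n
    order = _coord_indices(narrow_t, design.groups) + _coord_indices(extension, design.groups)
    Zo = design.design[:, order]
    if np.linalg.matrix_rank(Zo) < Zo.shape[1]:
        raise ValueError("full stacked design is rank deficient")
    J = Zo.T @ Zo / n
    p_c = 2 * len(narrow_t)
    Jinv = np.linalg.inv(J)
    Q = Jinv[p_c:, p_c:]

    grad = np.asarray(focus.gradient, float)[order]
    dmu_dbeta, dmu_dgamma = grad[:p_c], grad[p_c:]
    if p_c:
        J00 = J[:p_c, :p_c]
        J10 = J[p_c:, :p_c]
        omega = J10 @ np.linalg.solve(J00, dmu_dbeta) - dmu_dgamma
    else:
        omega = -dmu_dgamma

    theta_full = wls_refit(design, range(d))
    gamma_full = theta_full[order][p_c:]
    if delta_scale == "total":
        scale = np.full(len(gamma_full), np.sqrt(n))
    elif delta_scale == "per_group":
        # stacked pairs alternate (non-diseased, diseased) within each factor
        per = np.array([design.n_nondiseased, design.n_diseased], float)
        scale = np.sqrt(np.tile(per, len(extension)))
    else:
        raise ValueError("delta_scale must be 'total' or 'per_group'")
    delta_hat = scale * gamma_full

    return FICComponents(
        info_matrix=J,
        Q=Q,
        omega=omega,
        delta_hat=delta_hat,
        focus=focus,
        narrow_factors=narrow_t,
        extension_factors=extension,
    )


def fic_score(components: FICComponents, candidate_set) -> FICScore:
    """FIC value (squared-bias estimate + twice submodel variance) of a subset.

    The all-extension candidate has zero squared bias; the empty candidate has
    zero variance term and squared bias (omega' delta_hat)^2.
    """
    cand = frozenset(candidate_set)
    if not cand <= set(components.extension_factors):
        raise ValueError("candidate set must contain extension factors only")
    omega, dhat, Q = components.omega, components.delta_hat, components.Q
    if not cand:
        bias = float(omega @ dhat) ** 2
        return FICScore(cand, squared_bias_term=bias, variance_term=0.0)
    pos = {m: i for i, m in enumerate(components.extension_factors)}
    idx = []
    for m in sorted(cand):
        idx.extend([2 * pos[m], 2 * pos[m] + 1])
    Qinv = np.linalg.inv(Q)
    M = Qinv[np.ix_(idx, idx)]
    try:
        Minv = np.linalg.inv(M)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular pi_S Q^{-1} pi_S' block") from exc
    # G_S = pi' Minv pi Qinv has nonzero rows only on idx, so (I - G_S) dhat
    # subtracts the projected part on those coordinates only
    bias_vec = dhat.copy()
    bias_vec[idx] -= Minv @ (Qinv[idx, :] @ dhat)
    bias = float(omega @ bias_vec) ** 2
    w_s = omega[idx]
    var = 2.0 * float(w_s @ Minv @ w_s)
    return FICScore(cand, squared_bias_term=bias, variance_term=var)


def select_tau_fic(
    path: SolutionPath, components: FICComponents
) -> tuple[float, frozenset[int], list[FICScore]]:
    """Minimize the FIC over the distinct extension sets on a Stage-2 path.

    Returns the winning tau, the final model (narrow ∪ winning extension set),
    and the scored trace.  Ties break toward smaller candidate sets (the path
    is scanned from large tau downward, where active sets are sparsest).
    """
    if not path.fits:
        raise ValueError("empty solution path")
    narrow = set(components.narrow_factors)
    seen: dict[frozenset, float] = {}
    order: list[tuple[float, frozenset]] = []
    for tau, fit in zip(path.grid, path.fits):
        cand = frozenset(m for m in fit.active_groups if m not in narrow)
        if cand not in seen:
            seen[cand] = float(tau)
            order.append((float(tau), cand))
    trace = [fic_score(components, cand) for _, cand in order]
    totals = np.array([s.total for s in trace])
    i = int(np.flatnonzero(totals <= totals.min())[0])
    tau_best, cand_best = order[i]
    return tau_best, frozenset(narrow | cand_best), trace


def two_stage_fit(
    sample: TwoGroupSample,
    z0: np.ndarray,
    n_grid: int = 100,
    delta_scale: str = "total",
    add_centers_back: bool = True,
    weighted_scale: bool = True,
) -> SelectionResult:
    """Run the full focused pipeline and return the plug-in AUC at z0.

    Steps: center → estimate per-group variances from the full model → stack
    and weight → Stage 1 (group SCAD + BIC narrow model) → Stage 2 (group-LASSO
    path scored by FIC at z0) → WLS refit of the final model → AUC with the
    removed centers restored.  When Stage 1 already keeps every factor, Stage 2
    is skipped and the full-model fit returned.
    """
    z0 = np.asarray(z0, float).ravel()
    if len(z0) != sample.d:
        raise ValueError(f"z0 has length {len(z0)}, expected {sample.d}")
    work = sample if sample.centered else center_two_group(sample)
    var_nd, var_d = estimate_group_variances(work)
    sig_nd, sig_d = float(np.sqrt(var_nd)), float(np.sqrt(var_d))
    design = apply_weights(build_stacked_design(work, sig_nd, sig_d))

    narrow, lam = stage1_narrow_model(design, n_grid=n_grid, weighted_scale=weighted_scale)

    z0c = z0 - work.covariate_centers
    c_nd, c_d = work.response_centers
    offset = (c_d - c_nd) if add_centers_back else 0.0

    stage2_skipped = False
    tau: float | None = None
    trace: list[FICScore] = []
    if narrow == set(range(sample.d)):
        logger.info("stage 1 retained every factor; stage 2 skipped")
        final = narrow
        stage2_skipped = True
    else:
        theta_full = wls_refit(design, range(sample.d))
        tn_full, td_full = unstack_coefficients(theta_full)
        params_full = ModelParameters(
            theta_diseased=td_full,
            theta_nondiseased=tn_full,
            sigma_diseased=sig_d,
            sigma_nondiseased=sig_nd,
        )
        focus = make_focus(params_full, z0c, offset=offset)
        comps = fic_components(design, narrow, focus, delta_scale=delta_scale)
        path = group_lasso_path(design, narrow, n_grid=n_grid)
        tau, final, trace = select_tau_fic(path, comps)

    theta_hat = wls_refit(design, final)
    tn, td = unstack_coefficients(theta_hat)
    params_hat = ModelParameters(
        theta_diseased=td, theta_nondiseased=tn,
        sigma_diseased=sig_d, sigma_nondiseased=sig_nd,
    )
    auc = auc_from_parameters(params_hat, z0c, offset=offset)
    return SelectionResult(
        narrow_set=frozenset(narrow),
        final_set=frozenset(final),
        lambda_bic=lam,
        tau_fic=tau,
        theta_nondiseased=tn,
        theta_diseased=td,
        sigma_nondiseased=sig_nd,
        sigma_diseased=sig_d,
        auc_at_z0=auc,
        z0=z0,
        stage2_skipped=stage2_skipped,
        fic_trace=trace,
    )
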