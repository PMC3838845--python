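"""Two-group data containers, stacking transforms, and the AUC focus functional.

The induced-methodology ROC regression models the continuous test result of
diseased and non-diseased subjects with separate homoscedastic Gaussian linear
models sharing the same covariates:

    y_D  = z' theta_D  + sigma_D  eps,      y_Dbar = z' theta_Dbar + sigma_Dbar eps,

from which the covariate-specific AUC is the closed form

    AUC(z0) = Phi( z0'(theta_D - theta_Dbar) / sqrt(sigma_Dbar^2 + sigma_D^2) ).

To select each covariate's two coefficients (non-diseased, diseased) jointly,
the two regressions are fused into a single weighted least-squares problem: the
responses are stacked (non-diseased block first), each covariate row is embedded
by a Kronecker product so that covariate m owns a consecutive column pair, and
rows are weighted by the inverse group variances.  Grouped penalties then act on
the 2-vector of each covariate's coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

__all__ = [
    "TwoGroupSample",
    "ModelParameters",
    "StackedDesign",
    "FocusSpec",
    "center_two_group",
    "build_stacked_design",
    "apply_weights",
    "auc_from_parameters",
    "auc_gradient",
    "make_focus",
    "estimate_group_variances",
    "stack_coefficients",
    "unstack_coefficients",
]


@dataclass(frozen=True)
class TwoGroupSample:
    """Raw (or centered) responses and covariates for the two disease groups.

    Attributes
    ----------
    y_nondiseased, y_diseased : ndarray
        Continuous test results per group.
    z_nondiseased, z_diseased : ndarray
        Covariate matrices, one row per subject, same ``d`` columns in both.
    centered : bool
        True once covariates have been centered on the pooled sample and each
        group's response mean removed.
    response_centers : tuple of float
        (non-diseased, diseased) response means that were removed.
    covariate_centers : ndarray
        Pooled covariate means that were removed (zeros when not centered).
    """

    y_nondiseased: np.ndarray
    y_diseased: np.ndarray
    z_nondiseased: np.ndarray
    z_diseased: np.ndarray
    centered: bool = False
    response_centers: tuple[float, float] = (0.0, 0.0)
    covariate_centers: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "y_nondiseased", np.asarray(self.y_nondiseased, float).ravel())
        object.__setattr__(self, "y_diseased", np.asarray(self.y_diseased, float).ravel())
        object.__setattr__(self, "z_nondiseased", np.atleast_2d(np.asarray(self.z_nondiseased, float)))
        object.__setattr__(self, "z_diseased", np.atleast_2d(np.asarray(self.z_diseased, float)))
        if self.z_nondiseased.shape[1] != self.z_diseased.shape[1]:
            raise ValueError(
                "covariate matrices disagree on d: "
                f"{self.z_nondiseased.shape[1]} vs {self.z_diseased.shape[1]}"
            )
        if self.n_nondiseased < 1 or self.n_diseased < 1:
            raise ValueError("each group needs at least one subject")
        if len(self.y_nondiseased) != self.n_nondiseased or len(self.y_diseased) != self.n_diseased:
            raise ValueError("response/covariate row counts disagree")
        if self.covariate_centers is None:
            object.__setattr__(self, "covariate_centers", np.zeros(self.d))

    @property
    def n_nondiseased(self) -> int:
        return self.z_nondiseased.shape[0]

    @property
    def n_diseased(self) -> int:
        return self.z_diseased.shape[0]

    @property
    def n(self) -> int:
        return self.n_nondiseased + self.n_diseased

    @property
    def d(self) -> int:
        return self.z_nondiseased.shape[1]


@dataclass(frozen=True)
class ModelParameters:
    """Per-group regression coefficients and error standard deviations."""

    theta_diseased: np.ndarray
    theta_nondiseased: np.ndarray
    sigma_diseased: float
    sigma_nondiseased: float

    def __post_init__(self):
        object.__setattr__(self, "theta_diseased", np.asarray(self.theta_diseased, float).ravel())
        object.__setattr__(self, "theta_nondiseased", np.asarray(self.theta_nondiseased, float).ravel())
        if len(self.theta_diseased) != len(self.theta_nondiseased):
            raise ValueError("theta vectors must have equal length")
        if self.sigma_diseased <= 0 or self.sigma_nondiseased <= 0:
            raise ValueError("sigma must be strictly positive")

    @property
    def d(self) -> int:
        return len(self.theta_diseased)


@dataclass
class StackedDesign:
    """The fused two-group regression (Y, Z, W) with d two-column factor groups.

    Rows are ordered non-diseased first.  Column pair (2m, 2m+1) holds covariate
    m's (non-diseased, diseased) coefficients: non-diseased rows touch only the
    even-index (first) slot of each pair and diseased rows only the odd-index
    slot.  ``transformed`` flips to True once W^{1/2} has been absorbed into
    (Y, Z), after which ordinary least squares on the stored arrays equals
    weighted least squares on the originals.
    """

    response: np.ndarray
    design: np.ndarray
    weights: np.ndarray
    groups: list[tuple[int, ...]]
    n_nondiseased: int
    n_diseased: int
    transformed: bool = False

    @property
    def n(self) -> int:
        return len(self.response)

    @property
    def d(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class FocusSpec:
    """A covariate profile with the AUC focus value and its stacked gradient."""

    z0: np.ndarray
    focus_value: float
    gradient: np.ndarray

    def __post_init__(self):
        if not 0.0 < self.focus_value < 1.0:
            raise ValueError("focus value must lie strictly inside (0, 1)")


def center_two_group(sample: TwoGroupSample) -> TwoGroupSample:
    """Center covariates on the pooled sample and responses per group.

    Returns a centered copy carrying the removed centers so that AUC
    evaluation can restore the original scale.  A zero-variance covariate
    column is rejected as degenerate.
    """
    if sample.centered:
        raise ValueError("sample is already centered")
    pooled = np.vstack([sample.z_nondiseased, sample.z_diseased])
    if sample.n > 1:
        degenerate = np.where(pooled.std(axis=0) == 0)[0]
        if degenerate.size:
            raise ValueError(f"zero-variance covariate column(s): {degenerate.tolist()}")
    zc = pooled.mean(axis=0)
    c_nd = float(sample.y_nondiseased.mean())
    c_d = float(sample.y_diseased.mean())
    return TwoGroupSample(
        y_nondiseased=sample.y_nondiseased - c_nd,
        y_diseased=sample.y_diseased - c_d,
        z_nondiseased=sample.z_nondiseased - zc,
        z_diseased=sample.z_diseased - zc,
        centered=True,
        response_centers=(c_nd, c_d),
        covariate_centers=zc,
    )


def stack_coefficients(theta_nondiseased: np.ndarray, theta_diseased: np.ndarray) -> np.ndarray:
    """Interleave per-group coefficient vectors into stacked coordinates.

    Covariate m's pair occupies positions (2m, 2m+1) = (non-diseased, diseased).
    """
    tn = np.asarray(theta_nondiseased, float).ravel()
    td = np.asarray(theta_diseased, float).ravel()
    if len(tn) != len(td):
        raise ValueError("coefficient vectors must have equal length")
    out = np.empty(2 * len(tn))
    out[0::2] = tn
    out[1::2] = td
    return out


def unstack_coefficients(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a stacked coefficient vector into (non-diseased, diseased) parts."""
    theta = np.asarray(theta, float).ravel()
    if len(theta) % 2:
        raise ValueError("stacked vector must have even length")
    return theta[0::2].copy(), theta[1::2].copy()


def build_stacked_design(
    sample: TwoGroupSample, sigma_nondiseased: float, sigma_diseased: float
) -> StackedDesign:
    """Build the Kronecker-stacked weighted design from a centered sample.

    Non-diseased covariate rows are embedded as z (x) (1,0)' and diseased rows
    as z (x) (0,1)', giving an n x 2d design whose product with the stacked
    coefficient vector reproduces z'theta_Dbar on non-diseased rows and
    z'theta_D on diseased rows.  Weights are the inverse group variances.
    """
    if sigma_nondiseased <= 0 or sigma_diseased <= 0:
        raise ValueError("sigma must be strictly positive")
    if not sample.centered:
        raise ValueError("center the sample before stacking")
    n0, n1, d = sample.n_nondiseased, sample.n_diseased, sample.d
    Z = np.zeros((n0 + n1, 2 * d))
    Z[:n0, 0::2] = sample.z_nondiseased
    Z[n0:, 1::2] = sample.z_diseased
    Y = np.concatenate([sample.y_nondiseased, sample.y_diseased])
    w = np.concatenate(
        [np.full(n0, sigma_nondiseased**-2), np.full(n1, sigma_diseased**-2)]
    )
    groups = [(2 * m, 2 * m + 1) for m in range(d)]
    return StackedDesign(Y, Z, w, groups, n0, n1, transformed=False)


def apply_weights(design: StackedDesign) -> StackedDesign:
    """Absorb W^{1/2} into (Y, Z) so OLS on the result equals WLS on the input."""
    if design.transformed:
        raise ValueError("design already transformed")
    s = np.sqrt(design.weights)
    return StackedDesign(
        response=design.response * s,
        design=design.design * s[:, None],
        weights=design.weights.copy(),
        groups=list(design.groups),
        n_nondiseased=design.n_nondiseased,
        n_diseased=design.n_diseased,
        transformed=True,
    )


def _auc_argument(params: ModelParameters, z0: np.ndarray, offset: float = 0.0) -> float:
    z0 = np.asarray(z0, float).ravel()
    if len(z0) != params.d:
        raise ValueError(f"z0 has length {len(z0)}, expected {params.d}")
    scale = np.sqrt(params.sigma_nondiseased**2 + params.sigma_diseased**2)
    return (float(z0 @ (params.theta_diseased - params.theta_nondiseased)) + offset) / scale


def auc_from_parameters(params: ModelParameters, z0: np.ndarray, offset: float = 0.0) -> float:
    """Covariate-specific AUC Phi(z0'(theta_D - theta_Dbar)/sqrt(s_Dbar^2+s_D^2)).

    ``offset`` is added inside the Phi argument (before scaling); it carries the
    difference of per-group response centers when evaluating on centered fits.
    """
    return float(norm.cdf(_auc_argument(params, z0, offset)))


def auc_gradient(params: ModelParameters, z0: np.ndarray, offset: float = 0.0) -> np.ndarray:
    """Gradient of the AUC focus in stacked coordinates.

    Equals phi(u) * (z0 (x) (-1, 1)') / sqrt(sigma_Dbar^2 + sigma_D^2) where u
    is the Phi argument of the AUC: each covariate contributes a (-, +) pair
    proportional to its z0 entry.
    """
    u = _auc_argument(params, z0, offset)
    scale = np.sqrt(params.sigma_nondiseased**2 + params.sigma_diseased**2)
    z0 = np.asarray(z0, float).ravel()
    return norm.pdf(u) / scale * np.kron(z0, np.array([-1.0, 1.0]))


def make_focus(params: ModelParameters, z0: np.ndarray, offset: float = 0.0) -> FocusSpec:
    """Bundle a profile with its AUC value and stacked gradient."""
    return FocusSpec(
        z0=np.asarray(z0, float).ravel(),
        focus_value=auc_from_parameters(params, z0, offset),
        gradient=auc_gradient(params, z0, offset),
    )


def estimate_group_variances(sample: TwoGroupSample) -> tuple[float, float]:
    """Full-model residual variances (non-diseased, diseased) per group.

    Each group's response is regressed by ordinary least squares on all d
    covariates plus a group intercept (the full model); the mean squared
    residual estimates that group's error variance and populates the
    stacked-design weights.  The intercept column is kept even on centered
    data: covariates are centered on the pooled sample but responses per
    group, so each group retains a small mean offset that must not inflate
    the variance estimate.  Requires more rows than columns per group and
    full-rank group designs.
    """
    out = []
    for label, y, Z in (
        ("nondiseased", sample.y_nondiseased, sample.z_nondiseased),
        ("diseased", sample.y_diseased, sample.z_diseased),
    ):
        n, d = Z.shape
        if n <= d + 1:
            raise ValueError(f"{label} group has n={n} <= d+1={d + 1}: no residual df")
        X = np.column_stack([np.ones(n), Z])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient full design in {label} group")
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        out.append(float(resid @ resid / (n - X.shape[1])))
    return out[0], out[1]
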