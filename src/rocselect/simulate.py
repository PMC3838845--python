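"""Simulation engine: the three benchmark settings and the method comparison.

Each setting draws two groups of 50 subjects with i.i.d. standard-normal
covariates and Gaussian errors from the per-group linear models.  Settings 1
and 2 are local models: three strong always-in effects plus 5 (resp. 17)
extension effects of size delta/sqrt(50), so the narrow model is {0, 1, 2}.
Setting 3 has harmonically decaying coefficients theta_Dj = 3/(2j),
theta_Dbarj = 2/(2j) with no sharp narrow/extension boundary.  Three constant
test profiles per setting put the true AUC near 0.6, 0.8, and 0.95.

``run_replication`` fits every requested method on one draw — grouped SCAD
with CV/GCV/AIC/BIC tuning, the two-stage FIC (one final model per test
profile), and the separate per-group SCAD baselines — and records selected
sets, model sizes, and plug-in AUC estimates.  ``summarize_study`` aggregates
MSE, MAE, mean size, and the narrow-model F-measure over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    ModelParameters,
    TwoGroupSample,
    apply_weights,
    auc_from_parameters,
    build_stacked_design,
    center_two_group,
    estimate_group_variances,
    make_focus,
    unstack_coefficients,
)
from .fic import fic_components, select_tau_fic, wls_refit
from .penalties import group_lasso_path, group_scad_path, separate_scad_path
from .tuning import criterion_scores, cv_select, selection_fmeasure

__all__ = [
    "SimulationSetting",
    "StudyResult",
    "make_setting",
    "sparse_variant",
    "replicate_seed",
    "generate_setting_data",
    "run_replication",
    "summarize_study",
    "run_study",
    "GROUPED_METHODS",
    "SEPARATE_METHODS",
]

GROUPED_METHODS = ("cv", "gcv", "aic", "bic", "fic")
SEPARATE_METHODS = ("separate_cv", "separate_gcv", "separate_aic", "separate_bic")


@dataclass(frozen=True)
class SimulationSetting:
    """Parameter bundle for one benchmark scenario."""

    setting_id: int
    n_nondiseased: int
    n_diseased: int
    sigma_nondiseased: float
    sigma_diseased: float
    theta_nondiseased: np.ndarray
    theta_diseased: np.ndarray
    test_points: tuple[tuple[np.ndarray, float], ...]
    narrow_truth: frozenset[int] | None

    @property
    def d(self) -> int:
        return len(self.theta_diseased)

    @property
    def params(self) -> ModelParameters:
        return ModelParameters(
            theta_diseased=self.theta_diseased,
            theta_nondiseased=self.theta_nondiseased,
            sigma_diseased=self.sigma_diseased,
            sigma_nondiseased=self.sigma_nondiseased,
        )

    def true_auc(self, z0: np.ndarray) -> float:
        return auc_from_parameters(self.params, z0)


def make_setting(setting_id: int) -> SimulationSetting:
    """The three printed scenarios (extension effects already on the
    delta/sqrt(50) local scale)."""
    root50 = np.sqrt(50.0)
    if setting_id == 1:
        beta_d = [1.5, 2.0, 3.0]
        gam_d = [(3 - 0.5 * (j - 1)) / root50 for j in range(1, 6)]
        beta_n = [0.5, 1.0, 2.0]
        gam_n = [(1 - 0.2 * (j - 1)) / root50 for j in range(1, 6)]
        theta_d = np.array(beta_d + gam_d)
        theta_n = np.array(beta_n + gam_n)
        sig = 2.0
        pts = [(0.2, 0.611), (0.7, 0.838), (1.2, 0.955)]
        truth = frozenset({0, 1, 2})
    elif setting_id == 2:
        beta_d = [1.5, 2.0, 3.0]
        gam_d = [(2 - 0.05 * (j - 1)) / root50 for j in range(1, 18)]
        beta_n = [0.5, 1.0, 2.0]
        gam_n = [(1 - 0.05 * (j - 1)) / root50 for j in range(1, 18)]
        theta_d = np.array(beta_d + gam_d)
        theta_n = np.array(beta_n + gam_n)
        sig = 2.0
        pts = [(0.15, 0.613), (0.45, 0.805), (0.9, 0.957)]
        truth = frozenset({0, 1, 2})
    elif setting_id == 3:
        theta_d = np.array([3.0 / (2 * j) for j in range(1, 9)])
        theta_n = np.array([2.0 / (2 * j) for j in range(1, 9)])
        sig = 1.0
        pts = [(0.3, 0.613), (0.9, 0.806), (1.8, 0.958)]
        truth = None
    else:
        raise ValueError(f"unknown setting id {setting_id!r}")
    d = len(theta_d)
    test_points = tuple((np.full(d, c), auc) for c, auc in pts)
    return SimulationSetting(
        setting_id=setting_id,
        n_nondiseased=50,
        n_diseased=50,
        sigma_nondiseased=sig,
        sigma_diseased=sig,
        theta_nondiseased=theta_n,
        theta_diseased=theta_d,
        test_points=test_points,
        narrow_truth=truth,
    )


def sparse_variant(setting: SimulationSetting, n_per_group: int) -> SimulationSetting:
    """Exactly sparse version of a local-model setting: extension effects set
    to zero, group sizes replaced.  Used to study narrow-model selection
    consistency, where the sparsity assumption (delta = 0) must hold."""
    if setting.narrow_truth is None:
        raise ValueError("setting has no defined narrow truth")
    narrow = sorted(setting.narrow_truth)
    theta_d = np.zeros(setting.d)
    theta_n = np.zeros(setting.d)
    theta_d[narrow] = setting.theta_diseased[narrow]
    theta_n[narrow] = setting.theta_nondiseased[narrow]
    return SimulationSetting(
        setting_id=setting.setting_id,
        n_nondiseased=int(n_per_group),
        n_diseased=int(n_per_group),
        sigma_nondiseased=setting.sigma_nondiseased,
        sigma_diseased=setting.sigma_diseased,
        theta_nondiseased=theta_n,
        theta_diseased=theta_d,
        test_points=setting.test_points,
        narrow_truth=setting.narrow_truth,
    )


def generate_setting_data(setting: SimulationSetting, seed) -> TwoGroupSample:
    """Draw one sample: standard-normal covariates, Gaussian linear responses,
    zero intercepts."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = setting.d
    z_n = rng.standard_normal((setting.n_nondiseased, d))
    z_d = rng.standard_normal((setting.n_diseased, d))
    y_n = z_n @ setting.theta_nondiseased + setting.sigma_nondiseased * rng.standard_normal(
        setting.n_nondiseased
    )
    y_d = z_d @ setting.theta_diseased + setting.sigma_diseased * rng.standard_normal(
        setting.n_diseased
    )
    return TwoGroupSample(y_nondiseased=y_n, y_diseased=y_d, z_nondiseased=z_n, z_diseased=z_d)


def _plugin_auc(design, work, factors, sig_nd, sig_d, z0, add_centers_back=True):
    theta = wls_refit(design, factors)
    tn, td = unstack_coefficients(theta)
    params = ModelParameters(
        theta_diseased=td, theta_nondiseased=tn,
        sigma_diseased=sig_d, sigma_nondiseased=sig_nd,
    )
    z0c = np.asarray(z0, float) - work.covariate_centers
    offset = (work.response_centers[1] - work.response_centers[0]) if add_centers_back else 0.0
    return auc_from_parameters(params, z0c, offset=offset)


def _separate_refit_auc(work, sel_nd, sel_d, sig_nd, sig_d, z0, add_centers_back=True):
    coefs = []
    for Z, y, sel in (
        (work.z_nondiseased, work.y_nondiseased, sel_nd),
        (work.z_diseased, work.y_diseased, sel_d),
    ):
        theta = np.zeros(Z.shape[1])
        cols = sorted(sel)
        if cols:
            c, *_ = np.linalg.lstsq(Z[:, cols], y, rcond=None)
            theta[cols] = c
        coefs.append(theta)
    params = ModelParameters(
        theta_diseased=coefs[1], theta_nondiseased=coefs[0],
        sigma_diseased=sig_d, sigma_nondiseased=sig_nd,
    )
    z0c = np.asarray(z0, float) - work.covariate_centers
    offset = (work.response_centers[1] - work.response_centers[0]) if add_centers_back else 0.0
    return auc_from_parameters(params, z0c, offset=offset)


def _separate_cv_select(work, group_label, grid, folds, seed):
    """Held-out squared-error CV for the per-group (non-grouped) SCAD path."""
    y, Z = (
        (work.y_nondiseased, work.z_nondiseased)
        if group_label == "nondiseased"
        else (work.y_diseased, work.z_diseased)
    )
    n = len(y)
    rng = np.random.default_rng(seed)
    folds_idx = np.array_split(rng.permutation(n), folds)
    sse = np.zeros(len(grid))
    for test_rows in folds_idx:
        train = np.setdiff1d(np.arange(n), test_rows)
        sub = TwoGroupSample(
            y_nondiseased=y[train] if group_label == "nondiseased" else work.y_nondiseased,
            y_diseased=y[train] if group_label == "diseased" else work.y_diseased,
            z_nondiseased=Z[train] if group_label == "nondiseased" else work.z_nondiseased,
            z_diseased=Z[train] if group_label == "diseased" else work.z_diseased,
            centered=True,
            response_centers=work.response_centers,
            covariate_centers=work.covariate_centers,
        )
        path = separate_scad_path(sub, group_label, grid=grid)
        for i, fit in enumerate(path.fits):
            err = y[test_rows] - Z[test_rows] @ fit.theta
            sse[i] += float(err @ err)
    i = int(np.flatnonzero(sse <= sse.min())[0])
    path = separate_scad_path(work, group_label, grid=grid[i : i + 1])
    return float(grid[i]), path.fits[0]


def run_replication(
    sample: TwoGroupSample,
    setting: SimulationSetting,
    methods=GROUPED_METHODS,
    seed: int = 0,
    n_grid: int = 100,
    cv_folds: int = 5,
    add_centers_back: bool = False,
) -> dict[str, dict]:
    """Fit every requested method on one sample.

    Returns per method: ``auc`` (one estimate per test profile), ``size``
    (per profile; constant except for the FIC, whose final model is focus
    dependent), and ``selected`` (grouped methods' factor set, None for the
    separate baselines and the FIC).

    ``add_centers_back`` defaults to False here (unlike the data-analysis
    surface): the benchmark generating models have zero intercepts, so the
    selected-model AUC is evaluated without the estimated-intercept offset.
    """
    unknown = set(methods) - set(GROUPED_METHODS) - set(SEPARATE_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    work = sample if sample.centered else center_two_group(sample)
    var_nd, var_d = estimate_group_variances(work)
    sig_nd, sig_d = float(np.sqrt(var_nd)), float(np.sqrt(var_d))
    design = apply_weights(build_stacked_design(work, sig_nd, sig_d))
    z0s = [z0 for z0, _ in setting.test_points]
    n_pts = len(z0s)
    out: dict[str, dict] = {}

    grouped = [m for m in methods if m in GROUPED_METHODS]
    path = group_scad_path(design, n_grid=n_grid) if grouped else None

    def record_grouped(name, factors):
        auc = [
            _plugin_auc(design, work, factors, sig_nd, sig_d, z0, add_centers_back)
            for z0 in z0s
        ]
        out[name] = {
            "auc": np.array(auc),
            "size": np.full(n_pts, float(len(factors))),
            "selected": frozenset(factors),
        }

    for crit in ("bic", "aic", "gcv"):
        if crit in grouped:
            scores = criterion_scores(path, design.n, crit)
            i = int(np.flatnonzero(scores <= np.nanmin(scores))[0])
            record_grouped(crit, path.fits[i].active_groups)
    if "cv" in grouped:
        _, fit = cv_select(design, path.grid, folds=cv_folds, seed=seed)
        record_grouped("cv", fit.active_groups)

    if "fic" in grouped:
        scores = criterion_scores(path, design.n, "bic")
        i = int(np.flatnonzero(scores <= scores.min())[0])
        narrow = path.fits[i].active_groups
        if narrow == set(range(setting.d)):
            aucs = [
                _plugin_auc(design, work, narrow, sig_nd, sig_d, z0, add_centers_back)
                for z0 in z0s
            ]
            sizes = np.full(n_pts, float(len(narrow)))
        else:
            theta_full = wls_refit(design, range(setting.d))
            tn_f, td_f = unstack_coefficients(theta_full)
            params_full = ModelParameters(
                theta_diseased=td_f, theta_nondiseased=tn_f,
                sigma_diseased=sig_d, sigma_nondiseased=sig_nd,
            )
            lasso = group_lasso_path(design, narrow, n_grid=n_grid)
            offset = (
                work.response_centers[1] - work.response_centers[0]
                if add_centers_back
                else 0.0
            )
            aucs, sizes = [], []
            for z0 in z0s:
                z0c = np.asarray(z0, float) - work.covariate_centers
                focus = make_focus(params_full, z0c, offset=offset)
                comps = fic_components(design, narrow, focus)
                _, final, _ = select_tau_fic(lasso, comps)
                aucs.append(
                    _plugin_auc(design, work, final, sig_nd, sig_d, z0, add_centers_back)
                )
                sizes.append(float(len(final)))
            sizes = np.array(sizes)
        out["fic"] = {"auc": np.array(aucs), "size": np.asarray(sizes, float), "selected": None}

    separate = [m for m in methods if m in SEPARATE_METHODS]
    if separate:
        paths = {
            g: separate_scad_path(work, g, n_grid=n_grid)
            for g in ("nondiseased", "diseased")
        }
        for name in separate:
            crit = name.split("_", 1)[1]
            sels, counts = {}, 0
            for g in ("nondiseased", "diseased"):
                n_g = work.n_nondiseased if g == "nondiseased" else work.n_diseased
                if crit == "cv":
                    _, fit = _separate_cv_select(
                        work, g, paths[g].grid, cv_folds, seed + (1 if g == "diseased" else 0)
                    )
                else:
                    scores = criterion_scores(paths[g], n_g, crit)
                    i = int(np.flatnonzero(scores <= np.nanmin(scores))[0])
                    fit = paths[g].fits[i]
                sels[g] = {int(m) for m in fit.active_groups}
                counts += len(fit.active_groups)
            auc = [
                _separate_refit_auc(
                    work, sels["nondiseased"], sels["diseased"], sig_nd, sig_d, z0,
                    add_centers_back,
                )
                for z0 in z0s
            ]
            out[name] = {
                "auc": np.array(auc),
                "size": np.full(n_pts, float(counts)),
                "selected": None,
            }
    return out


@dataclass
class StudyResult:
    """Aggregated accuracy and selection summaries of a replicated study."""

    setting_id: int
    replicates: int
    seed: int
    table: pd.DataFrame  # rows: (method, test_point); cols: mse, mae, mean_size, true_auc
    fmeasure: pd.Series  # per grouped non-FIC method, NaN when truth undefined


def summarize_study(results: list[dict], setting: SimulationSetting, seed: int = 0) -> StudyResult:
    """Aggregate replicate records into MSE/MAE/size tables and F-measures.

    MSE and MAE are against the closed-form true AUC at each test profile.
    The F-measure compares each grouped criterion's selected factor set with
    the narrow truth; it is undefined (NaN) for Setting 3.
    """
    if not results:
        raise ValueError("need at least one replicate")
    methods = list(results[0].keys())
    true_aucs = np.array([setting.true_auc(z0) for z0, _ in setting.test_points])
    rows = []
    for m in methods:
        est = np.array([r[m]["auc"] for r in results])  # reps x points
        size = np.array([r[m]["size"] for r in results])
        err = est - true_aucs[None, :]
        for k in range(len(true_aucs)):
            rows.append(
                {
                    "method": m,
                    "test_point": k + 1,
                    "true_auc": true_aucs[k],
                    "mse": float(np.mean(err[:, k] ** 2)),
                    "mae": float(np.mean(np.abs(err[:, k]))),
                    "mean_size": float(size[:, k].mean()),
                }
            )
    table = pd.DataFrame(rows).set_index(["method", "test_point"])
    fvals = {}
    for m in methods:
        if m == "fic" or m in SEPARATE_METHODS or setting.narrow_truth is None:
            fvals[m] = np.nan
            continue
        per_rep = [
            selection_fmeasure(r[m]["selected"], setting.narrow_truth) for r in results
        ]
        fvals[m] = float(np.mean(per_rep))
    return StudyResult(
        setting_id=setting.setting_id,
        replicates=len(results),
        seed=seed,
        table=table,
        fmeasure=pd.Series(fvals, name="fmeasure"),
    )


def replicate_seed(master_seed: int, rep: int) -> np.random.SeedSequence:
    """Counter-based child seed so any single replicate reruns in isolation."""
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(rep),))


def run_study(
    setting_id: int,
    reps: int = 500,
    seed: int = 0,
    methods=GROUPED_METHODS,
    n_grid: int = 100,
    cv_folds: int = 5,
) -> StudyResult:
    """Replicate a full setting: generate, fit all methods, summarize."""
    setting = make_setting(setting_id)
    results = []
    for rep in range(reps):
        ss = replicate_seed(seed, rep)
        rng = np.random.default_rng(ss)
        sample = generate_setting_data(setting, rng)
        cv_seed = int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1))
        results.append(
            run_replication(
                sample, setting, methods=methods, seed=cv_seed,
                n_grid=n_grid, cv_folds=cv_folds,
            )
        )
    return summarize_study(results, setting, seed=seed)
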