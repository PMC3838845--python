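"""Independent brute-force oracles used by the solver tests."""

import itertools

import numpy as np
from scipy.optimize import minimize

from rocselect.penalties import penalized_objective


def brute_force_group_scad(design, spec):
    """Exhaustive oracle for the group-SCAD objective.

    Enumerates every active-group zero pattern and minimizes the penalized
    objective over the active coordinates numerically (the SCAD penalty is C^1
    away from the zero patterns, which the enumeration handles).  Returns the
    global minimum objective value.
    """
    n, d = design.n, design.d
    best = 0.5 * float(design.response @ design.response) / n  # all-zero pattern
    for pattern in itertools.product([0, 1], repeat=d):
        active = [m for m in range(d) if pattern[m]]
        if not active:
            continue
        cols = [c for m in active for c in design.groups[m]]

        def obj_fn(t):
            theta = np.zeros(2 * d)
            theta[cols] = t
            return penalized_objective(design, theta, spec)

        ls, *_ = np.linalg.lstsq(design.design[:, cols], design.response, rcond=None)
        for start in (ls, 0.6 * ls, 0.15 * ls):
            res = minimize(obj_fn, start, method="BFGS",
                           options={"gtol": 1e-12, "maxiter": 5000})
            polish = minimize(obj_fn, res.x, method="Nelder-Mead",
                              options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
            best = min(best, res.fun, polish.fun)
    return best
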