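"""Independent oracles the implementation is checked against.

These deliberately avoid the package's vergence algebra: the ray-transfer
oracle tracks a paraxial ray (height, reduced angle) through 2x2 ABCD
matrices and reads the vergence off the ray at the end; the regression
oracle solves the normal equations directly.
"""

import numpy as np


def ray_transfer_vergence(v0, elements):
    """Propagate a vergence through a sequence of optical elements using
    2x2 ray-transfer matrices on a (height, reduced-angle) ray.

    ``elements`` is a list of ("gap", distance_m, n) or ("lens", power_d)
    tuples. A ray at height y heading toward the focus of a vergence V has
    reduced angle nu = -V*y; translation by d in index n maps
    (y, nu) -> (y + (d/n)nu, nu) and a thin lens of power P maps
    (y, nu) -> (y, nu - P*y). The final vergence is -nu/y.
    """
    m = np.eye(2)
    for element in elements:
        if element[0] == "gap":
            _, d, n = element
            step = np.array([[1.0, d / n], [0.0, 1.0]])
        elif element[0] == "lens":
            step = np.array([[1.0, 0.0], [-element[1], 1.0]])
        else:
            raise ValueError(element[0])
        m = step @ m
    ray = m @ np.array([1.0, -v0])
    if ray[0] == 0.0:
        raise ZeroDivisionError("ray crosses the axis at the output plane")
    return -ray[1] / ray[0]


def normal_equations_ols(x, y):
    """Plain normal-equations OLS with intercept: coefficients, SEs,
    adjusted R-squared."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    design = np.hstack([np.ones((n, 1)), x])
    xtx = design.T @ design
    beta = np.linalg.solve(xtx, design.T @ y)
    resid = y - design @ beta
    dof = n - p - 1
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(xtx)))
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - (resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof
    return beta, se, adj_r2
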