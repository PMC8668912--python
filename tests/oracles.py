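"""Independent numerical oracles used to cross-check the closed-form models.

These deliberately avoid the code paths they validate: the exchanger oracle
integrates the two-stream countercurrent boundary-value problem along the
fiber with scipy's collocation solver, and the compartment oracle is a plain
fixed-step RK4 integrator.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_bvp


def bvp_countercurrent_clearance(qb: float, qd: float, a: float, tol: float = 1e-10) -> float:
    """Clearance (ml/min) from the countercurrent two-stream exchange BVP.

    Along the fiber x in [0, 1], blood flows +x and dialysate -x::

        qb * cb'(x) = -a * (cb - cd)
        qd * cd'(x) = -a * (cb - cd)

    with cb(0) = 1 (unit inlet) and cd(1) = 0 (fresh dialysate).  Clearance is
    qb * (1 - cb(1)).  ``a`` is the effective mass-transfer-area coefficient
    in ml/min; all flows in ml/min.
    """
    if a == 0:
        return 0.0

    def rhs(x, y):
        g = y[0] - y[1]
        return np.vstack([-(a / qb) * g, -(a / qd) * g])

    def bc(ya, yb):
        return np.array([ya[0] - 1.0, yb[1]])

    x = np.linspace(0.0, 1.0, 41)
    y0 = np.vstack([np.ones_like(x), np.zeros_like(x)])
    sol = solve_bvp(rhs, bc, x, y0, tol=tol, max_nodes=200000)
    if not sol.success:
        raise RuntimeError(f"BVP oracle failed: {sol.message}")
    return qb * (1.0 - float(sol.sol(1.0)[0]))


def rk4_container(
    c0: float, cd: float, k_ml_min: float, v_l: float, t_min: float, n_steps: int = 100000
) -> float:
    """Container concentration after ``t_min`` by fixed-step RK4.

    Integrates V dC/dt = -(K/1000)(C - cd) with V in L, K in ml/min.
    """
    h = t_min / n_steps
    c = c0

    def f(ci: float) -> float:
        return -(k_ml_min / 1000.0) * (ci - cd) / v_l

    for _ in range(n_steps):
        k1 = f(c)
        k2 = f(c + 0.5 * h * k1)
        k3 = f(c + 0.5 * h * k2)
        k4 = f(c + h * k3)
        c += h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return c
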