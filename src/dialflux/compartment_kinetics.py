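"""Well-mixed compartment kinetics of the open dialysis circuit.

The bench rig is a 25 L glass container recirculated through the filter while
fresh dialysate runs once through the other side and drains to waste (open
circuit: compartment volume is constant, dialysate inflow balances effluent
outflow on the dialysate side only).  The container obeys

.. math:: V \\frac{dC}{dt} = -\\frac{K_{dir}}{1000} (C - c_d)

with ``V`` in L, ``C`` and ``c_d`` in mg/L, clearance ``K_dir`` in ml/min (the
1000 converts ml to L).  Because the trajectory approaches ``c_d``
monotonically and never crosses it, the gradient sign — and hence the
direction-dependent clearance — is fixed along any trajectory, and the
exponential closed form is exact.  A numerical LSODA path is kept for
cross-checks and for the patient mode, whose gradient can change sign on the
way to steady state.

Patient mode is a minimal single-compartment extension: constant distribution
volume, constant protein binding, zero-order infusion and first-order body
clearance.  Only the unbound (free) fraction of the drug crosses the membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dialyzer_transport import DialyzerParams, FlowSetting, clearance
from .exceptions import InvalidInputError

__all__ = [
    "CompartmentState",
    "SolutePK",
    "MEROPENEM",
    "free_concentration",
    "simulate_container",
    "simulate_patient",
    "patient_steady_state",
]


@dataclass(frozen=True)
class CompartmentState:
    """Volume, concentration and clock of a well-mixed compartment."""

    volume_l: float
    concentration: float
    time_min: float = 0.0

    def __post_init__(self) -> None:
        if not self.volume_l > 0:
            raise InvalidInputError(f"volume must be > 0 L, got {self.volume_l}")
        if self.concentration < 0:
            raise InvalidInputError(
                f"concentration must be >= 0 mg/L, got {self.concentration}"
            )


@dataclass(frozen=True)
class SolutePK:
    """Solute constants relevant to dialytic removal.

    Defaults are meropenem: 383.5 Da, 2% protein bound, distribution volume
    21 L, container working concentration 16 mg/L (four-fold the MIC of the
    common ICU flora and the recommended continuous-infusion target).
    """

    molecular_weight: float = 383.5
    protein_binding: float = 0.02
    vd_l: float = 21.0
    container_start_conc: float = 16.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.protein_binding < 1.0):
            raise InvalidInputError(
                f"protein_binding must be in [0, 1), got {self.protein_binding}"
            )
        if not self.vd_l > 0:
            raise InvalidInputError(f"vd_l must be > 0, got {self.vd_l}")
        if self.container_start_conc < 0:
            raise InvalidInputError(
                f"container_start_conc must be >= 0, got {self.container_start_conc}"
            )

    @property
    def free_fraction(self) -> float:
        """Unbound fraction, ``1 - protein_binding``."""
        return 1.0 - self.protein_binding


#: Meropenem constants used throughout the bench scenarios.
MEROPENEM = SolutePK()


def free_concentration(total: float, pk: SolutePK) -> float:
    """Unbound concentration available for membrane transport, mg/L.

    Only unbound drug crosses the filter; bench mode uses binding 0 (the
    "blood" is protein-free dialysate) so free equals total there.
    """
    if total < 0:
        raise InvalidInputError(f"total concentration must be >= 0, got {total}")
    return total * pk.free_fraction


def _directional_clearance(
    gradient_sign: float, flows: FlowSetting, params: DialyzerParams
) -> float:
    """Clearance with the back-filtration asymmetry applied for negative gradients."""
    k = clearance(flows, params)
    if gradient_sign < 0:  # dialysate richer than blood: enrichment direction
        k = min(params.alpha_backfiltration * k, min(flows.qb, flows.qd))
    return k


def simulate_container(
    initial: CompartmentState,
    cd: float,
    flows: FlowSetting,
    params: DialyzerParams,
    duration: float,
    step: float,
    method: str = "auto",
) -> pd.DataFrame:
    """Simulate the open 25 L container under fixed dialysate concentration.

    Parameters
    ----------
    initial : CompartmentState
        Starting volume/concentration; ``time_min`` is taken as t = 0 offset.
    cd : float
        Fresh dialysate concentration, mg/L, held constant.
    flows, params
        Circuit flows and filter parameters.
    duration, step : float
        Horizon and output spacing, min.  ``step > duration`` falls back to a
        single step with a warning.
    method : str
        ``"auto"`` (exact exponential closed form — the gradient sign is fixed
        along the trajectory, so the linear ODE has constant coefficients) or
        ``"numeric"`` (LSODA, for cross-validation).

    Returns
    -------
    pandas.DataFrame
        Columns ``time_min``, ``conc_mg_l``, ``cumulative_effluent_mg``
        (mass exported to waste) and ``cumulative_dialysate_in_mg``
        (mass imported with fresh dialysate).
    """
    if duration < 0:
        raise InvalidInputError(f"duration must be >= 0 min, got {duration}")
    if not step > 0:
        raise InvalidInputError(f"step must be > 0 min, got {step}")
    if cd < 0:
        raise InvalidInputError(f"dialysate concentration must be >= 0, got {cd}")
    if step > duration and duration > 0:
        warnings.warn(
            f"step ({step} min) exceeds duration ({duration} min); "
            "falling back to a single step",
            stacklevel=2,
        )
        step = duration

    v = initial.volume_l
    c0 = initial.concentration
    qd = flows.qd
    if duration == 0:
        t = np.array([0.0])
    else:
        t = np.arange(0.0, duration + 0.5 * step, step)
        if t[-1] < duration:
            t = np.append(t, duration)

    k_dir = _directional_clearance(np.sign(c0 - cd), flows, params)
    k_rate = k_dir / 1000.0 / v  # 1/min

    if method == "numeric":
        def rhs(_t: float, y: np.ndarray) -> list[float]:
            c = y[0]
            kd = _directional_clearance(np.sign(c - cd), flows, params)
            c_el = cd + (kd / qd) * (c - cd) if qd > 0 else cd
            return [
                -(kd / 1000.0) * (c - cd) / v,
                (qd / 1000.0) * c_el,
            ]

        sol = solve_ivp(
            rhs, (0.0, max(duration, 1e-12)), [c0, 0.0], t_eval=t,
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        conc = sol.y[0]
        effluent = sol.y[1]
    else:
        decay = np.exp(-k_rate * t)
        conc = cd + (c0 - cd) * decay
        # integral of (C - cd) dt, analytic
        if k_rate > 0:
            grad_int = (c0 - cd) * (1.0 - decay) / k_rate
        else:
            grad_int = (c0 - cd) * t
        effluent = (qd / 1000.0) * cd * t + (k_dir / 1000.0) * grad_int

    dialysate_in = (qd / 1000.0) * cd * t
    return pd.DataFrame(
        {
            "time_min": t + initial.time_min,
            "conc_mg_l": conc,
            "cumulative_effluent_mg": effluent,
            "cumulative_dialysate_in_mg": dialysate_in,
        }
    )


def patient_steady_state(
    pk: SolutePK,
    infusion_rate_mg_h: float,
    body_clearance_ml_min: float,
    cd: float,
    flows: FlowSetting,
    params: DialyzerParams,
) -> float:
    """Analytic steady-state plasma concentration of the patient compartment, mg/L.

    Solves ``0 = R_inf/60 - (CL_b/1000) C - (K_dir/1000)(f_u C - cd)`` with the
    direction of ``K_dir`` chosen self-consistently with the steady-state
    gradient sign.
    """
    ff = pk.free_fraction
    rate = infusion_rate_mg_h / 60.0  # mg/min
    for sign in (+1.0, -1.0):
        k = _directional_clearance(sign, flows, params)
        denom = (body_clearance_ml_min + k * ff) / 1000.0
        if denom == 0.0:
            if rate == 0.0 and k == 0.0:
                return 0.0
            continue
        css = (rate + k * cd / 1000.0) / denom
        if np.sign(ff * css - cd) == sign or ff * css == cd:
            return css
    # fall back to symmetric clearance (gradient exactly at the switch point)
    k = clearance(flows, params)
    denom = (body_clearance_ml_min + k * ff) / 1000.0
    if denom == 0.0:
        raise InvalidInputError(
            "no elimination pathway: steady state does not exist for a "
            "nonzero infusion with zero clearance"
        )
    return (rate + k * cd / 1000.0) / denom


def simulate_patient(
    pk: SolutePK,
    infusion_rate_mg_h: float,
    body_clearance_ml_min: float,
    cd: float,
    flows: FlowSetting,
    params: DialyzerParams,
    duration: float,
    step: float = 1.0,
    c0: float | None = None,
) -> pd.DataFrame:
    """Single-compartment patient on CVVHD with constant infusion.

    ``V dC/dt = R_inf/60 - (CL_body/1000) C - (K_dir/1000)(f_u C - cd)``
    with ``V = pk.vd_l``.  The trajectory relaxes monotonically toward the
    steady state.  With a symmetric membrane the ODE is linear with constant
    coefficients and the closed form is used; otherwise LSODA integrates the
    piecewise-linear right-hand side.

    Returns a DataFrame with ``time_min`` and ``conc_mg_l``.
    """
    if min(infusion_rate_mg_h, body_clearance_ml_min, duration) < 0 or cd < 0:
        raise InvalidInputError("all rates, concentrations and duration must be >= 0")
    if not step > 0:
        raise InvalidInputError(f"step must be > 0 min, got {step}")
    v = pk.vd_l
    ff = pk.free_fraction
    if c0 is None:
        c0 = pk.container_start_conc
    rate = infusion_rate_mg_h / 60.0

    t = np.arange(0.0, duration + 0.5 * step, step)
    if len(t) == 0 or t[-1] < duration:
        t = np.append(t, duration)

    if params.alpha_backfiltration == 1.0:
        k = clearance(flows, params)
        b = (body_clearance_ml_min + k * ff) / 1000.0 / v  # 1/min
        a = (rate + k * cd / 1000.0) / v  # mg/L/min
        if b > 0:
            css = a / b
            conc = css + (c0 - css) * np.exp(-b * t)
        else:
            conc = c0 + a * t
    else:
        def rhs(_t: float, y: np.ndarray) -> list[float]:
            c = y[0]
            kd = _directional_clearance(np.sign(ff * c - cd), flows, params)
            return [
                (rate - (body_clearance_ml_min / 1000.0) * c
                 - (kd / 1000.0) * (ff * c - cd)) / v
            ]

        sol = solve_ivp(
            rhs, (0.0, max(duration, 1e-12)), [c0], t_eval=t,
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        conc = sol.y[0]

    return pd.DataFrame({"time_min": t, "conc_mg_l": conc})
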