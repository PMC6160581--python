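"""Closed-form diffusive-interaction predictions.

Two damping mechanisms couple hemoglobin saturation heterogeneity (HSH) to
tissue oxygen transport:

* capillary interaction — neighboring capillaries exchange oxygen through
  the shared tissue, damping the saturation difference ΔS between them with
  resistance-like coefficient K_CI;
* RBC interaction — RBCs within one capillary exchange through the local
  tissue, damping the within-vessel standard deviation σ_S with coefficient
  K_RI.

Both obey the same linearized evolution equation: the heterogeneity h(x)
(ΔS or σ_S) decays as Q_O2(S̄) dh/dx = −(h/K) dP_eq/dS|_S̄ alongside the
mean-saturation balance, giving an exponential-type decay along the vessel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy import stats

from .network import Vessel
from .params import OxygenParameters, SolverSettings
from .oxygen import convective_capacity, hill_dpeq_ds

__all__ = [
    "InteractionCoefficients",
    "capillary_interaction_coefficient",
    "predict_heterogeneity_decay",
    "predict_deltaS_decay",
    "predict_sigmaS_decay",
    "fit_decay_rate",
]


@dataclass
class InteractionCoefficients:
    """Resistance-like coefficients, mmHg·s/μm² (flux per unit length = ΔP/K)."""

    K_IV: float
    K_RI: float
    K_CI: float
    r_t_mean: float


def capillary_interaction_coefficient(K_IV: float, D_t: float, alpha_t: float,
                                      r_t_mean: float, r_w: float) -> float:
    """K_CI = K_IV + (log(r_t/r_w) − 1/2)/(2π D_t α_t).

    The tissue term is the radial resistance from the capillary wall to the
    volume-averaged tissue oxygen tension of a Krogh annulus of outer radius
    r_t_mean; it vanishes when r_t_mean = r_w √e.
    """
    if not r_t_mean > r_w > 0:
        raise ValueError("require r_t_mean > r_w > 0")
    return K_IV + (np.log(r_t_mean / r_w) - 0.5) / (2.0 * np.pi * D_t * alpha_t)


def predict_heterogeneity_decay(h0: float, Sbar0: float, vessel: Vessel,
                                K: float, j_t: float,
                                params: OxygenParameters,
                                length: float | None = None,
                                frozen_coefficients: bool = False,
                                n_points: int = 100):
    """Joint integration of the mean saturation and a heterogeneity measure.

    Solves dS̄/dx = −j_t/Q_O2(S̄) and dh/dx = −h dP_eq/dS|_S̄/(K Q_O2(S̄)).
    With ``frozen_coefficients`` the coefficients are evaluated once at the
    inlet mean, which yields the exact exponential
    h(x) = h0 exp(−x dP_eq/dS/(K Q_O2)).

    Returns (x, h(x), S̄(x)).
    """
    if h0 < 0:
        raise ValueError("heterogeneity must be non-negative")
    L = length if length is not None else vessel.length
    x_eval = np.linspace(0.0, L, n_points)
    if frozen_coefficients:
        q0 = convective_capacity(Sbar0, vessel, params)
        dp0 = hill_dpeq_ds(Sbar0, params.P50, params.hill_n)
        rate = dp0 / (K * q0)
        h = h0 * np.exp(-rate * x_eval)
        sol_mean = solve_ivp(lambda x, y: [-j_t / q0], (0, L), [Sbar0],
                             t_eval=x_eval, rtol=1e-10, atol=1e-12)
        return x_eval, h, sol_mean.y[0]

    def rhs(x, y):
        sbar, h = y
        q = convective_capacity(max(sbar, 0.0), vessel, params)
        dp = hill_dpeq_ds(max(sbar, 0.0), params.P50, params.hill_n)
        return [-j_t / q if sbar > 0 else 0.0, -h * dp / (K * q)]

    settings = SolverSettings()
    sol = solve_ivp(rhs, (0.0, L), [Sbar0, h0], t_eval=x_eval,
                    rtol=settings.ode_rtol, atol=settings.ode_atol)
    if not sol.success:
        raise RuntimeError(f"interaction ODE failed: {sol.message}")
    return x_eval, np.clip(sol.y[1], 0.0, None), sol.y[0]


def predict_deltaS_decay(deltaS0: float, Sbar0: float, vessel: Vessel,
                         K_CI: float, j_t: float, params: OxygenParameters,
                         **kwargs):
    """Saturation difference ΔS(x) between paired capillaries (K = K_CI)."""
    return predict_heterogeneity_decay(deltaS0, Sbar0, vessel, K_CI, j_t,
                                       params, **kwargs)


def predict_sigmaS_decay(sigmaS0: float, Sbar0: float, vessel: Vessel,
                         K_RI: float, j_t: float, params: OxygenParameters,
                         **kwargs):
    """Within-capillary saturation SD σ_S(x) (K = K_RI)."""
    return predict_heterogeneity_decay(sigmaS0, Sbar0, vessel, K_RI, j_t,
                                       params, **kwargs)


def fit_decay_rate(x, values) -> dict:
    """Least-squares decay rate of a positive profile: slope of −log(v) vs x.

    Returns {'rate': 1/μm, 'r_squared': float, 'n_used': int, 'flagged': bool}.
    Nonpositive values terminate the fitted prefix (flagged).
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 samples")
    pos = v > 0
    flagged = not np.all(pos)
    if flagged:
        stop = int(np.argmin(pos))  # first nonpositive sample
        x, v = x[:stop], v[:stop]
    if len(x) < 5:
        raise ValueError("fewer than 5 positive samples")
    res = stats.linregress(x, np.log(v))
    return {"rate": -float(res.slope),
            "r_squared": float(res.rvalue**2) if np.std(v) > 0 else 1.0,
            "n_used": len(x), "flagged": flagged}
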