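"""Blood rheology closures for microvascular network hydraulics.

Implements the Pries–Secomb in-vivo apparent viscosity law and the empirical
phase-separation (plasma skimming) law for diverging capillary bifurcations.
Both are standard closures for vessel diameters of a few μm; tube and
discharge hematocrit are identified here because RBC velocity is taken equal
to bulk velocity (no Fåhræus correction) throughout the package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "relative_viscosity_in_vivo",
    "vessel_resistance",
    "phase_separation_fractions",
    "linear_density",
]

MMHG_PER_PA = 1.0 / 133.322
PLASMA_VISCOSITY_MPAS = 1.2


def _mu45(d: np.ndarray) -> np.ndarray:
    return 6.0 * np.exp(-0.085 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)


def _c_shape(d: np.ndarray) -> np.ndarray:
    f = 1.0 / (1.0 + 1e-11 * d**12)
    return (0.8 + np.exp(-0.075 * d)) * (-1.0 + f) + f


def relative_viscosity_in_vivo(diameter, hematocrit):
    """Pries–Secomb in-vivo relative apparent viscosity.

    Parameters
    ----------
    diameter : array_like
        Lumen diameter in μm.
    hematocrit : array_like
        Discharge (= tube, here) hematocrit in [0, 1).
    """
    d = np.asarray(diameter, dtype=float)
    h = np.asarray(hematocrit, dtype=float)
    if np.any(d <= 1.1):
        raise ValueError("viscosity law requires diameter > 1.1 μm")
    mu45 = _mu45(d)
    c = _c_shape(d)
    wall = (d / (d - 1.1)) ** 2
    hfac = ((1.0 - h) ** c - 1.0) / ((1.0 - 0.45) ** c - 1.0)
    return (1.0 + (mu45 - 1.0) * hfac * wall) * wall


def vessel_resistance(diameter, length, hematocrit, plasma_viscosity=PLASMA_VISCOSITY_MPAS):
    """Poiseuille flow resistance R = 128 μ_app L / (π d⁴) in mmHg·s/μm³.

    μ_app = plasma viscosity × in-vivo relative viscosity. Monotone increasing
    in length and hematocrit, decreasing in diameter.
    """
    d = np.asarray(diameter, dtype=float)
    length_ = np.asarray(length, dtype=float)
    if np.any(d <= 0) or np.any(length_ <= 0):
        raise ValueError("diameter and length must be positive")
    mu_app = plasma_viscosity * 1e-3 * relative_viscosity_in_vivo(d, hematocrit)  # Pa·s
    return 128.0 * mu_app * length_ / (np.pi * d**4) * MMHG_PER_PA


def phase_separation_fractions(flow_fractions, diameters, parent_diameter, parent_hematocrit):
    """RBC flux fractions at a diverging bifurcation.

    For a two-child bifurcation the empirical Pries law is used; for more than
    two children (or degenerate inputs) the split is proportional to blood
    flow. Returns RBC-flux fractions summing to 1 over the children.
    """
    fq = np.asarray(flow_fractions, dtype=float)
    if fq.size != 2 or parent_hematocrit <= 0:
        return fq / fq.sum()
    d_a, d_b = float(diameters[0]), float(diameters[1])
    d_f = float(parent_diameter)
    h = float(parent_hematocrit)
    x0 = 0.964 * (1.0 - h) / d_f
    ratio = (d_a / d_b) ** 2
    a = -13.29 * ((ratio - 1.0) / (ratio + 1.0)) * (1.0 - h) / d_f
    b = 1.0 + 6.98 * (1.0 - h) / d_f
    fqb = fq[0] / fq.sum()
    if fqb <= x0:
        fqe = 0.0
    elif fqb >= 1.0 - x0:
        fqe = 1.0
    else:
        logit = a + b * np.log((fqb - x0) / (1.0 - fqb - x0))
        fqe = 1.0 / (1.0 + np.exp(-logit))
    return np.array([fqe, 1.0 - fqe])


def linear_density(H_T, r_p, r_c, warn=None):
    """Linear density μ_LD = H_T (r_p/r_c)² of cylindrical RBCs.

    The RBC column occupies a fraction μ_LD of the vessel length; values above
    1 are unphysical and clipped (optionally reported via ``warn``).
    """
    h = np.asarray(H_T, dtype=float)
    if np.any(h < 0) or np.any(h >= 1):
        raise ValueError("tube hematocrit must lie in [0, 1)")
    mu = h * (np.asarray(r_p, float) / np.asarray(r_c, float)) ** 2
    if np.any(mu > 1.0):
        if warn is not None:
            warn(f"linear density clipped to 1 for {int(np.sum(mu > 1.0))} vessels")
        mu = np.minimum(mu, 1.0)
    return mu
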