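"""Physiological and numerical parameters.

All quantities use the package-wide unit system: lengths in μm, time in s,
pressures in mmHg, oxygen amounts in μm³ O₂ at standard conditions.
Solubilities are therefore (μm³ O₂)/(μm³ · mmHg), i.e. numerically identical
to the usual (mL O₂)/(mL · mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

__all__ = ["OxygenParameters", "SolverSettings", "load_parameters"]


@dataclass
class OxygenParameters:
    """Oxygen-transport parameters for capillary hemoglobin saturation models.

    Attributes
    ----------
    C0 : float
        Oxygen binding capacity of a fully saturated red blood cell,
        N_Hb · V_mol,O2, in (μm³ O₂)/(μm³ RBC). 0.5 corresponds to a heme
        concentration of ~21 mM.
    P50 : float
        Half-saturation oxygen tension of the Hill equilibrium curve, mmHg
        (mouse blood).
    hill_n : float
        Hill exponent (dimensionless, > 1).
    alpha_eff : float
        Effective intravascular oxygen solubility, (μm³ O₂)/(μm³·mmHg).
    alpha_t : float
        Tissue oxygen solubility, same units.
    D_t : float
        Tissue oxygen diffusivity, μm²/s.
    M0 : float
        Metabolic oxygen consumption per unit tissue volume,
        (μm³ O₂)/(μm³·s). 6e-4 ≈ 1.6 μmol·cm⁻³·min⁻¹ (anesthetized mouse
        cortex, mid-range).
    K_IV : float
        Intravascular resistance to radial oxygen transport per unit vessel
        length, mmHg·s/μm² (flux per unit length = ΔP/K).
    K_RI : float
        RBC diffusive-interaction coefficient, same convention.
    V_rbc : float
        Red blood cell volume, μm³ (mouse MCV ≈ 49 fL).
    """

    C0: float = 0.5
    P50: float = 47.9
    hill_n: float = 2.64
    alpha_eff: float = 3.3e-5
    alpha_t: float = 3.89e-5
    D_t: float = 2400.0
    M0: float = 6.0e-4
    K_IV: float = 0.7
    K_RI: float = 2.5
    V_rbc: float = 49.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"OxygenParameters.{name} must be > 0, got {value}")
        if self.hill_n <= 1:
            raise ValueError(f"hill_n must exceed 1, got {self.hill_n}")

    def replace(self, **kwargs) -> "OxygenParameters":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SolverSettings:
    """Numerical settings shared by the ODE and particle stages."""

    ode_rtol: float = 1e-8
    ode_atol: float = 1e-10
    profile_points: int = 50          # dense-output samples per vessel
    atom_cap: int = 32                # max saturation atoms per vessel
    s_clip: float = 1e-9              # Hill-boundary clipping for dP_eq/dS
    dt: float = 1e-3                  # particle time step, s
    t_end: float = 10.0               # particle simulation horizon, s
    averaging_window: float = 2.0     # statistics window at the end of the run, s
    tissue_bin_width: float = 5.0     # axial tissue bin width, μm
    coupling_cutoff: float = 30.0     # inter-vessel tissue coupling cutoff, μm
    spacing_cv: float = 0.5           # CV of RBC inter-arrival times at inflows

    def to_dict(self) -> dict:
        return asdict(self)


def load_parameters(path: str | Path) -> tuple[OxygenParameters, SolverSettings]:
    """Read a YAML file with optional ``oxygen:`` and ``solver:`` sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    oxy = OxygenParameters(**raw.get("oxygen", {}))
    solver = SolverSettings(**raw.get("solver", {}))
    return oxy, solver
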