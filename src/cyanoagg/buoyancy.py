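"""Light-regulated cell density and the modified Stokes buoyant velocity.

*Microcystis* regulates buoyancy through gas vesicles and carbohydrate
ballast: high light increases cell density (sinking), darkness decreases
it (floating).  We model the cell-density rate as a saturating light
response, drho/dt = c1 * I / (I + K_I) - c2, integrated forward in time
and clipped to physiological bounds.  Colony density mixes cell density
with ambient water weighted by the fractal cell-volume fraction, and the
buoyant velocity is the Stokes terminal velocity of the porosity-inflated
equivalent sphere (positive = sinking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ColonyClassTable
from .environment import EnvironmentProfile

__all__ = [
    "CellDensityParams",
    "cell_density_rate",
    "update_cell_density",
    "colony_density",
    "stokes_velocity",
    "velocity_profiles",
    "max_speed_bound",
    "G_GRAVITY",
]

G_GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class CellDensityParams:
    """Parameters of the saturating light response of cell density.

    c1 : maximum density-increase rate under saturating light (kg m^-3 s^-1)
    c2 : density-decrease rate in darkness (kg m^-3 s^-1)
    K_I : half-saturation irradiance (W/m^2)
    rho_min, rho_max : physiological cell-density bounds (kg/m^3)
    """

    c1: float = 2.0e-3
    c2: float = 6.7e-4
    K_I: float = 100.0
    rho_min: float = 985.0
    rho_max: float = 1065.0

    def __post_init__(self) -> None:
        if min(self.c1, self.c2, self.K_I) <= 0.0:
            raise ValueError("c1, c2 and K_I must be positive")
        if not self.rho_min < self.rho_max:
            raise ValueError("require rho_min < rho_max")


def cell_density_rate(I, p: CellDensityParams = CellDensityParams()):
    """Rate of change of cell density (kg m^-3 s^-1) at irradiance I (W/m^2)."""
    Iarr = np.asarray(I, dtype=float)
    if np.any(Iarr < 0.0):
        raise ValueError("irradiance must be non-negative")
    out = p.c1 * Iarr / (Iarr + p.K_I) - p.c2
    return out if out.ndim else float(out)


def update_cell_density(rho_cell, I, dt: float, p: CellDensityParams = CellDensityParams()):
    """One forward-Euler step of the cell-density field, clipped to bounds."""
    if dt <= 0.0:
        raise ValueError("dt must be positive")
    rho = np.asarray(rho_cell, dtype=float)
    out = np.clip(rho + dt * np.asarray(cell_density_rate(I, p)), p.rho_min, p.rho_max)
    return out if out.ndim else float(out)


def colony_density(k, rho_cell, rho_w, table: ColonyClassTable):
    """Density (kg/m^3) of a k-cell colony.

    rho_k = rho_w + vfrac(k) * (rho_cell - rho_w): a single cell is all
    cell; a large tenuous colony is mostly ambient water.
    """
    karr = np.asarray(k)
    if np.any(karr < 1) or np.any(karr > table.k_max):
        raise ValueError(f"size index k outside [1, {table.k_max}]")
    vfrac = table.vfrac[karr - 1]
    out = np.asarray(rho_w, dtype=float) + vfrac * (
        np.asarray(rho_cell, dtype=float) - np.asarray(rho_w, dtype=float)
    )
    return out if out.ndim else float(out)


def stokes_velocity(d, rho_k, rho_w, nu, g: float = G_GRAVITY):
    """Modified Stokes velocity w = g d^2 (rho_k/rho_w - 1) / (18 nu) (m/s).

    Positive w is sinking (z positive downward), negative is floating.
    """
    darr = np.asarray(d, dtype=float)
    nuarr = np.asarray(nu, dtype=float)
    rhow = np.asarray(rho_w, dtype=float)
    if np.any(darr <= 0.0):
        raise ValueError("diameter must be positive")
    if np.any(nuarr <= 0.0):
        raise ValueError("kinematic viscosity must be positive")
    if np.any(rhow <= 0.0):
        raise ValueError("water density must be positive")
    out = g * darr**2 * (np.asarray(rho_k, dtype=float) / rhow - 1.0) / (18.0 * nuarr)
    return out if out.ndim else float(out)


def velocity_profiles(
    rho_cell,
    env: EnvironmentProfile,
    table: ColonyClassTable,
    g: float = G_GRAVITY,
) -> np.ndarray:
    """Buoyant-velocity matrix w[k, z] (m/s) for every class and node.

    Colony density is evaluated from the shared cell-density field and the
    local water density; drag uses the porosity-inflated class diameter.
    """
    rho = np.asarray(rho_cell, dtype=float)
    if rho.shape != env.z_nodes.shape:
        raise ValueError("rho_cell and environment grids do not match")
    rho_w = env.rho_w
    nu = env.nu
    # rho_k[k, z] via the fractal cell-volume fraction
    excess = (rho - rho_w)[None, :] * table.vfrac[:, None]  # rho_k - rho_w
    return g * table.d[:, None] ** 2 * excess / (18.0 * nu[None, :] * rho_w[None, :])


def max_speed_bound(
    env: EnvironmentProfile,
    table: ColonyClassTable,
    p: CellDensityParams = CellDensityParams(),
    g: float = G_GRAVITY,
) -> float:
    """Largest attainable |w| over all classes with cell density at its bounds.

    Used by the stability check to bound the advective Courant number.
    """
    speeds = []
    for rho_bound in (p.rho_min, p.rho_max):
        w = velocity_profiles(np.full(env.z_nodes.shape, rho_bound), env, table, g=g)
        speeds.append(float(np.max(np.abs(w))))
    return max(speeds)
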