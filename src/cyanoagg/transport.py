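"""1D finite-volume advection-dispersion-reaction solver for the water column.

The column is discretized into cells of width dz (z positive downward,
surface at z = 0); concentrations live at cell centers, fluxes at cell
faces.  Each explicit forward-in-time step combines dispersive and
advective (first-order upwind) fluxes with the Smoluchowski reaction term.
The top face of the first cell and the bottom face of the last carry zero
flux at all times, so no cells leave the column and column-integrated cell
mass is conserved to round-off.

When the reaction term would remove more than a configured fraction of any
class within one step (possible at high concentrations), the reaction is
sub-stepped internally to preserve positivity; the transport update stays
on the global time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Optional

import numpy as np

from .geometry import ColonyClassTable
from .environment import (
    EnvironmentProfile,
    LightModel,
    ScenarioSchedule,
    light_at_depth,
    scenario_profile,
    synthetic_profile,
    water_density,
)
from .buoyancy import (
    CellDensityParams,
    max_speed_bound,
    update_cell_density,
    velocity_profiles,
)
from .aggregation import KernelField
from .diagnostics import DiagnosticsSeries, cell_count, mass_audit

__all__ = [
    "NumericalConfig",
    "SimulationState",
    "StabilityReport",
    "ConfigurationError",
    "IntegrationError",
    "initial_condition",
    "face_values",
    "advective_diffusive_flux",
    "stability_check",
    "step",
    "run_simulation",
]


class ConfigurationError(ValueError):
    """A numerical configuration violates a stability bound."""


class IntegrationError(RuntimeError):
    """The explicit scheme produced a non-finite or negative state."""


@dataclass(frozen=True)
class NumericalConfig:
    """Grid, time step and run controls.

    Defaults follow the base numerical setup: dz = 0.2 m, dt = 10 s over a
    10 m column, with single cells seeded uniformly through a 3 m mixed
    layer at 2.3e7 colonies/m^3.
    """

    dz: float = 0.2  # m
    dt: float = 10.0  # s
    z_max: float = 10.0  # m
    t_end: float = 42.0 * 86400.0  # s
    h_ML: float = 3.0  # m, initial seeded mixed-layer width
    n0: float = 2.3e7  # colonies/m^3, initial single-cell concentration
    output_every: float = 3600.0  # s
    rho_cell0: Optional[float] = None  # kg/m^3; None = neutral at surface water
    max_diffusion_number: float = 0.5
    max_courant: float = 1.0
    reaction_guard: float = 0.1  # max loss fraction per (sub)step
    auto_substep: bool = True
    negative_tolerance: float = 1e-9  # relative, before an IntegrationError

    def __post_init__(self) -> None:
        if self.dz <= 0.0 or self.dt <= 0.0:
            raise ValueError("dz and dt must be positive")
        ncells = self.z_max / self.dz
        if abs(ncells - round(ncells)) > 1e-9 or round(ncells) < 2:
            raise ValueError("z_max must be an integer multiple (>= 2) of dz")
        if not (0.0 < self.h_ML <= self.z_max):
            raise ValueError("h_ML must lie in (0, z_max]")
        if self.n0 < 0.0 or self.t_end < 0.0 or self.output_every <= 0.0:
            raise ValueError("n0, t_end must be non-negative; output_every positive")

    @property
    def nz(self) -> int:
        return int(round(self.z_max / self.dz))

    @property
    def z_nodes(self) -> np.ndarray:
        """Cell-center depths (i - 1/2) dz."""
        return (np.arange(self.nz) + 0.5) * self.dz

    @property
    def z_faces(self) -> np.ndarray:
        """Cell-face depths i dz, surface face first."""
        return np.arange(self.nz + 1) * self.dz

    def refined(self, factor: int = 2) -> "NumericalConfig":
        """A grid- and time-refined copy (dz and dt divided by ``factor``)."""
        return replace(self, dz=self.dz / factor, dt=self.dt / factor)


@dataclass
class SimulationState:
    """Colony concentrations n[k, z], shared cell-density field, and clock."""

    t: float
    n: np.ndarray  # (k_max, nz) colonies/m^3
    rho_cell: np.ndarray  # (nz,) kg/m^3

    def copy(self) -> "SimulationState":
        return SimulationState(t=self.t, n=self.n.copy(), rho_cell=self.rho_cell.copy())

    def validate(self, tol_scale: float = 0.0) -> None:
        if not np.all(np.isfinite(self.n)):
            raise IntegrationError(f"non-finite concentration at t = {self.t} s")
        if np.any(self.n < -tol_scale):
            raise IntegrationError(
                f"negative concentration beyond tolerance at t = {self.t} s "
                f"(min {self.n.min():.3e})"
            )


def initial_condition(
    cfg: NumericalConfig,
    table: ColonyClassTable,
    env: Optional[EnvironmentProfile] = None,
) -> SimulationState:
    """Piecewise-uniform start: single cells through the mixed layer, nothing below.

    The cell-density field starts neutrally buoyant at the local water
    density (surface temperature) unless ``cfg.rho_cell0`` overrides it.
    """
    n = np.zeros((table.k_max, cfg.nz))
    n[0, cfg.z_nodes <= cfg.h_ML] = cfg.n0
    if cfg.rho_cell0 is not None:
        rho0 = float(cfg.rho_cell0)
    elif env is not None:
        rho0 = float(np.asarray(env.rho_w)[0])
    else:
        rho0 = float(water_density(20.0))
    return SimulationState(t=0.0, n=n, rho_cell=np.full(cfg.nz, rho0))


def face_values(n: np.ndarray, w_face: np.ndarray) -> np.ndarray:
    """Upwinded concentrations at faces: the node above for w >= 0 (sinking),
    the node below for w < 0.  Boundary faces are returned as zero (their
    fluxes are prescribed to vanish)."""
    n = np.asarray(n, dtype=float)
    w_face = np.asarray(w_face, dtype=float)
    if w_face.shape[-1] != n.shape[-1] + 1:
        raise ValueError("face array must be one longer than the node array")
    out = np.zeros(np.broadcast_shapes(w_face.shape, n.shape[:-1] + (n.shape[-1] + 1,)))
    interior = np.where(w_face[..., 1:-1] >= 0.0, n[..., :-1], n[..., 1:])
    out[..., 1:-1] = interior
    return out


def advective_diffusive_flux(
    n: np.ndarray,
    D_face: np.ndarray,
    w_face: np.ndarray,
    dz: float,
) -> np.ndarray:
    """Total flux (positive downward) at every face, colonies m^-2 s^-1.

    Interior faces carry -D dn/dz + w n_upwind; the surface and bottom
    faces carry exactly zero (no-flux boundaries).
    """
    n = np.asarray(n, dtype=float)
    D_face = np.asarray(D_face, dtype=float)
    w_face = np.asarray(w_face, dtype=float)
    nstar = face_values(n, w_face)
    q = np.zeros_like(nstar)
    grad = (n[..., 1:] - n[..., :-1]) / dz
    q[..., 1:-1] = -D_face[..., 1:-1] * grad + w_face[..., 1:-1] * nstar[..., 1:-1]
    return q


@dataclass(frozen=True)
class StabilityReport:
    """Explicit-scheme stability numbers and the bounds they are held to."""

    diffusion_number: float
    courant_number: float
    reaction_rate_scale: float  # max per-class fractional loss rate x dt (estimate)
    max_diffusion_number: float = 0.5
    max_courant: float = 1.0

    @property
    def ok(self) -> bool:
        return (
            self.diffusion_number <= self.max_diffusion_number
            and self.courant_number <= self.max_courant
        )

    def raise_if_unstable(self) -> None:
        if self.diffusion_number > self.max_diffusion_number:
            raise ConfigurationError(
                f"diffusion number {self.diffusion_number:.3g} exceeds "
                f"{self.max_diffusion_number} (reduce dt or increase dz)"
            )
        if self.courant_number > self.max_courant:
            raise ConfigurationError(
                f"Courant number {self.courant_number:.3g} exceeds "
                f"{self.max_courant} (reduce dt or increase dz)"
            )


def stability_check(
    cfg: NumericalConfig,
    env: EnvironmentProfile,
    w_max: Optional[float] = None,
    table: Optional[ColonyClassTable] = None,
    density: CellDensityParams = CellDensityParams(),
) -> StabilityReport:
    """Report diffusion and Courant numbers for the configured scheme.

    ``w_max`` may be given directly; otherwise it is bounded from the
    class table with cell density at its physiological bounds.
    """
    if w_max is None:
        if table is None:
            raise ValueError("provide either w_max or a colony table")
        w_max = max_speed_bound(env, table, density)
    diff_no = float(np.max(env.Dz)) * cfg.dt / cfg.dz**2
    courant = abs(w_max) * cfg.dt / cfg.dz
    # crude stiffness scale: fastest kernel x the seeded concentration
    reaction_scale = 0.0
    if table is not None:
        kf = KernelField(env, table)
        ab_max = float(kf.ab_static.max()) + float(
            (kf.settling_prefactor.max()) * 2.0 * abs(w_max)
        )
        reaction_scale = ab_max * cfg.n0 * table.k_max * cfg.dt
    return StabilityReport(
        diffusion_number=diff_no,
        courant_number=courant,
        reaction_rate_scale=reaction_scale,
        max_diffusion_number=cfg.max_diffusion_number,
        max_courant=cfg.max_courant,
    )


@lru_cache(maxsize=8)
def _pair_indices(k_max: int):
    """Ordered index pairs (a, b) with (a+1) + (b+1) <= k_max, and the
    destination class index c = a + b + 1 of the product colony."""
    a, b = np.nonzero(np.ones((k_max, k_max), dtype=bool))
    keep = a + b + 2 <= k_max
    a, b = a[keep], b[keep]
    return a, b, a + b + 1


def _reaction_rates(n: np.ndarray, ab: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Smoluchowski gain - loss over the whole column; ab is alpha*beta (K,K,nz)."""
    K = n.shape[0]
    loss = n * np.einsum("ikz,iz->kz", ab * mask[:, :, None], n)
    a, b, c = _pair_indices(K)
    contrib = ab[a, b, :] * n[a, :] * n[b, :]
    gain = np.zeros_like(n)
    np.add.at(gain, c, 0.5 * contrib)
    return gain - loss


def _apply_reaction(
    n: np.ndarray,
    ab: np.ndarray,
    mask: np.ndarray,
    dt: float,
    guard: float,
    auto_substep: bool,
) -> np.ndarray:
    """Advance the reaction term over dt, sub-stepping if the positivity
    guard (max fractional loss per step) would be violated."""
    loss_coeff = np.einsum("ikz,iz->kz", ab * mask[:, :, None], n)
    worst = dt * float(loss_coeff.max()) if loss_coeff.size else 0.0
    if worst <= guard:
        nsub = 1
    elif auto_substep:
        nsub = int(np.ceil(worst / guard))
    else:
        raise ConfigurationError(
            f"reaction would remove a fraction {worst:.3g} > guard {guard} of a "
            "class in one step; enable auto_substep or reduce dt"
        )
    out = n
    sub_dt = dt / nsub
    for _ in range(nsub):
        out = out + sub_dt * _reaction_rates(out, ab, mask)
    return out


def step(
    state: SimulationState,
    env: EnvironmentProfile,
    table: ColonyClassTable,
    cfg: NumericalConfig,
    light: LightModel = LightModel(),
    density: CellDensityParams = CellDensityParams(),
    kernels: Optional[KernelField] = None,
    include_advection: bool = True,
    include_reaction: bool = True,
) -> SimulationState:
    """One explicit step: light -> cell density -> velocities -> kernels ->
    combined transport + reaction update.  All terms are evaluated at the
    current time level."""
    if kernels is None and include_reaction:
        kernels = KernelField(env, table)
    dz, dt = cfg.dz, cfg.dt

    I = np.asarray(light_at_depth(cfg.z_nodes, state.t, light))
    rho_cell = np.asarray(update_cell_density(state.rho_cell, I, dt, density))
    if include_advection:
        w = velocity_profiles(rho_cell, env, table)
    else:
        w = np.zeros((table.k_max, cfg.nz))

    # faces: arithmetic means of adjacent nodes; boundary faces never used
    w_face = np.zeros((table.k_max, cfg.nz + 1))
    w_face[:, 1:-1] = 0.5 * (w[:, :-1] + w[:, 1:])
    D_face = np.zeros(cfg.nz + 1)
    D_face[1:-1] = 0.5 * (env.Dz[:-1] + env.Dz[1:])

    q = advective_diffusive_flux(state.n, D_face[None, :], w_face, dz)
    n_new = state.n + (dt / dz) * (q[:, :-1] - q[:, 1:])  # q_top - q_bot

    if include_reaction:
        ab = kernels.full(w)
        n_react = _apply_reaction(
            state.n, ab, kernels.mask, dt, cfg.reaction_guard, cfg.auto_substep
        )
        n_new = n_new + (n_react - state.n)

    scale = float(n_new.max(initial=0.0))
    out = SimulationState(t=state.t + dt, n=n_new, rho_cell=rho_cell)
    out.validate(tol_scale=cfg.negative_tolerance * scale)
    np.clip(out.n, 0.0, None, out=out.n)  # scrub round-off negatives only
    return out


def run_simulation(
    cfg: NumericalConfig,
    schedule: ScenarioSchedule,
    table: ColonyClassTable,
    profiles: Optional[Mapping[str, EnvironmentProfile]] = None,
    light: LightModel = LightModel(),
    density: CellDensityParams = CellDensityParams(),
    shear_coeff: float = 4.0 / 3.0,
    settling_coeff: float = 1.0,
    include_advection: bool = True,
    include_reaction: bool = True,
    check_stability: bool = True,
    snapshot_every: Optional[float] = 86400.0,
) -> tuple[DiagnosticsSeries, SimulationState]:
    """Advance from t = 0 to cfg.t_end under a wind-regime schedule.

    ``profiles`` maps schedule labels to profiles on the model grid; when
    omitted, synthetic regime profiles are generated on the grid.  The run
    is fully deterministic.  Diagnostics (per-class column cell counts,
    mass audit, periodic total-concentration snapshots) are recorded every
    ``cfg.output_every`` seconds.
    """
    if profiles is None:
        profiles = {
            label: synthetic_profile(cfg.z_nodes, regime=label, h_ML=cfg.h_ML)
            for label in set(schedule.labels)
        }
    for label, prof in profiles.items():
        if prof.z_nodes.shape != cfg.z_nodes.shape or not np.allclose(
            prof.z_nodes, cfg.z_nodes
        ):
            raise ValueError(f"profile {label!r} is not on the model grid")

    kernel_cache = {
        label: KernelField(prof, table, shear_coeff=shear_coeff, settling_coeff=settling_coeff)
        for label, prof in profiles.items()
    }
    if check_stability:
        for prof in profiles.values():
            stability_check(cfg, prof, table=table, density=density).raise_if_unstable()

    env0 = scenario_profile(0.0, schedule, profiles)
    state = initial_condition(cfg, table, env0)

    times = [0.0]
    N = [cell_count(state.n, cfg.dz)]
    mass = [mass_audit(state.n, cfg.dz)]
    snapshots: dict[float, np.ndarray] = {}
    if snapshot_every is not None:
        from .diagnostics import total_concentration

        snapshots[0.0] = total_concentration(state.n)

    nsteps = int(round(cfg.t_end / cfg.dt))
    next_output = cfg.output_every
    next_snapshot = snapshot_every if snapshot_every is not None else np.inf
    for _ in range(nsteps):
        label = schedule.label_at(state.t)
        state = step(
            state,
            profiles[label],
            table,
            cfg,
            light=light,
            density=density,
            kernels=kernel_cache[label] if include_reaction else None,
            include_advection=include_advection,
            include_reaction=include_reaction,
        )
        if state.t >= next_output - 1e-9:
            times.append(state.t)
            N.append(cell_count(state.n, cfg.dz))
            mass.append(mass_audit(state.n, cfg.dz))
            next_output += cfg.output_every
        if state.t >= next_snapshot - 1e-9:
            from .diagnostics import total_concentration

            snapshots[state.t] = total_concentration(state.n)
            next_snapshot += snapshot_every

    series = DiagnosticsSeries(
        times=np.asarray(times),
        N=np.asarray(N).T,
        mass=np.asarray(mass),
        C_snapshots=snapshots,
        dz=cfg.dz,
    )
    return series, state
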