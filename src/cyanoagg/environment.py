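"""Water-column forcing: stratification profiles, wind regimes, light.

The simulator consumes depth profiles of temperature T(z), the combined
molecular + turbulent dispersion coefficient D_Z(z), and the turbulent
kinetic energy dissipation rate eps(z).  Profiles can be read from a
delimited text table (columns ``depth_m,temp_C,Dz_m2s,eps_m2s3``) or
generated synthetically for two canonical regimes anchored at measured
maxima: high wind (eps_max = 4e-4 m^2/s^3) and low wind
(eps_max = 3e-7 m^2/s^3).  A schedule object switches regimes over time
(constant, or stepwise alternating with a 50/50 duty cycle).

Irradiance follows a truncated diel sine at the surface (photoperiod D_L
within a 24 h cycle) attenuated exponentially with depth (Beer-Lambert).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnvironmentProfile",
    "ScenarioSchedule",
    "LightModel",
    "water_density",
    "dynamic_viscosity",
    "kinematic_viscosity",
    "shear_rate",
    "synthetic_profile",
    "read_profile_table",
    "write_profile_table",
    "scenario_profile",
    "surface_light",
    "light_at_depth",
    "REGIME_DEFAULTS",
]

#: Regime anchors: measured dissipation maxima, plus dispersion maxima chosen
#: within the literature range 1e-6..1e-2 m^2/s such that the default
#: dz = 0.2 m, dt = 10 s explicit scheme is diffusively stable.
REGIME_DEFAULTS = {
    "high_wind": {"eps_max": 4e-4, "D_max": 1e-3},
    "low_wind": {"eps_max": 3e-7, "D_max": 1e-5},
}


def _check_temperature(T) -> np.ndarray:
    Tarr = np.asarray(T, dtype=float)
    if np.any(Tarr <= 0.0) or np.any(Tarr >= 40.0):
        raise ValueError("water temperature outside the supported range (0, 40) degC")
    return Tarr


def water_density(T):
    """Fresh-water density (kg/m^3) at temperature T (degC).

    Standard limnological polynomial with the density maximum at 3.986 degC.
    """
    Tarr = _check_temperature(T)
    out = 1000.0 * (
        1.0
        - (Tarr + 288.9414) / (508929.2 * (Tarr + 68.12963)) * (Tarr - 3.9863) ** 2
    )
    return out if out.ndim else float(out)


def dynamic_viscosity(T):
    """Dynamic viscosity of water (Pa s) at temperature T (degC), Vogel form."""
    Tarr = _check_temperature(T)
    out = 2.414e-5 * 10.0 ** (247.8 / (Tarr + 133.15))
    return out if out.ndim else float(out)


def kinematic_viscosity(T):
    """Kinematic viscosity nu = mu / rho_W (m^2/s) at temperature T (degC)."""
    out = np.asarray(dynamic_viscosity(T)) / np.asarray(water_density(T))
    return out if out.ndim else float(out)


def shear_rate(eps, nu):
    """Turbulent shear rate G = sqrt(eps / nu) (1/s)."""
    epsarr = np.asarray(eps, dtype=float)
    nuarr = np.asarray(nu, dtype=float)
    if np.any(nuarr <= 0.0):
        raise ValueError("kinematic viscosity must be positive")
    if np.any(epsarr < 0.0):
        raise ValueError("dissipation rate must be non-negative")
    out = np.sqrt(epsarr / nuarr)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class EnvironmentProfile:
    """Node-centered water-column profiles (z positive downward, surface at 0)."""

    z_nodes: np.ndarray
    T: np.ndarray  # degC
    Dz: np.ndarray  # m^2/s, molecular + turbulent
    eps: np.ndarray  # m^2/s^3
    label: str = "profile"

    def __post_init__(self) -> None:
        for name in ("z_nodes", "T", "Dz", "eps"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.z_nodes.size
        if not (self.T.size == self.Dz.size == self.eps.size == n):
            raise ValueError("profile vectors must share the grid length")
        _check_temperature(self.T)
        if np.any(self.Dz <= 0.0):
            raise ValueError("dispersion coefficient must be positive everywhere")
        if np.any(self.eps < 0.0):
            raise ValueError("dissipation rate must be non-negative everywhere")

    @property
    def T_kelvin(self) -> np.ndarray:
        return self.T + 273.15

    @property
    def rho_w(self) -> np.ndarray:
        """Water density profile (kg/m^3)."""
        return np.asarray(water_density(self.T))

    @property
    def mu(self) -> np.ndarray:
        """Dynamic viscosity profile (Pa s)."""
        return np.asarray(dynamic_viscosity(self.T))

    @property
    def nu(self) -> np.ndarray:
        """Kinematic viscosity profile (m^2/s)."""
        return self.mu / self.rho_w

    @property
    def G(self) -> np.ndarray:
        """Turbulent shear rate profile (1/s)."""
        return np.asarray(shear_rate(self.eps, self.nu))


def synthetic_profile(
    z_nodes,
    regime: str = "high_wind",
    h_ML: float = 3.0,
    T_epi: float = 25.0,
    T_hypo: float = 12.0,
    eps_max: float | None = None,
    D_max: float | None = None,
    D_background: float = 1e-6,
    eps_background: float = 1e-10,
    mixing_rolloff: float = 0.75,
    thermocline_width: float = 1.0,
    label: str | None = None,
) -> EnvironmentProfile:
    """Synthetic stratified-lake profile anchored at the regime maxima.

    Temperature follows a smooth two-layer tanh between ``T_epi`` and
    ``T_hypo`` centered just below the mixed-layer depth ``h_ML``.  Mixing
    quantities (Dz, eps) take their regime maxima in the mixed layer and
    roll off smoothly to small backgrounds below; the profile shape is
    normalized so the stated maxima are attained exactly at the surface.
    """
    z = np.asarray(z_nodes, dtype=float)
    if z.size == 0 or np.any(z < 0.0):
        raise ValueError("grid must be non-empty with non-negative depths")
    if not (0.0 < h_ML < z.max() + 1e-12):
        raise ValueError("mixed-layer depth h_ML must lie inside the column")
    if regime not in REGIME_DEFAULTS:
        raise ValueError(f"unknown regime {regime!r}; options {sorted(REGIME_DEFAULTS)}")
    if eps_max is None:
        eps_max = REGIME_DEFAULTS[regime]["eps_max"]
    if D_max is None:
        D_max = REGIME_DEFAULTS[regime]["D_max"]
    if not (0.0 < D_background <= D_max):
        raise ValueError("require 0 < D_background <= D_max")
    if not (0.0 <= eps_background <= eps_max):
        raise ValueError("require 0 <= eps_background <= eps_max")
    if T_hypo <= 0.0 or T_epi >= 40.0 or T_hypo > T_epi:
        raise ValueError("require 0 < T_hypo <= T_epi < 40 degC")

    # mixed-layer shape in [0, 1], forced to 1 at its maximum (the surface)
    shape = 0.5 * (1.0 - np.tanh((z - h_ML) / mixing_rolloff))
    shape = shape / shape.max()
    # temperature transition centered slightly below the mixed layer
    t_shape = 0.5 * (1.0 - np.tanh((z - (h_ML + thermocline_width / 2.0)) / thermocline_width))
    T = T_hypo + (T_epi - T_hypo) * t_shape
    Dz = D_background + (D_max - D_background) * shape
    eps = eps_background + (eps_max - eps_background) * shape
    return EnvironmentProfile(
        z_nodes=z, T=T, Dz=Dz, eps=eps, label=label if label is not None else regime
    )


_PROFILE_COLUMNS = ("depth_m", "temp_C", "Dz_m2s", "eps_m2s3")


def read_profile_table(path, z_nodes, label: str | None = None) -> EnvironmentProfile:
    """Read a delimited profile table and interpolate onto the model grid.

    The file must contain the header columns ``depth_m,temp_C,Dz_m2s,
    eps_m2s3`` with strictly increasing depths.  Values are interpolated
    linearly onto ``z_nodes`` with constant extrapolation at the ends; a
    file deeper than the grid is silently truncated.
    """
    df = pd.read_csv(path)
    missing = [c for c in _PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile table {path} is missing columns {missing}")
    depth = df["depth_m"].to_numpy(dtype=float)
    if np.any(np.diff(depth) <= 0.0):
        bad = int(np.argmax(np.diff(depth) <= 0.0)) + 2  # 1-based data row
        raise ValueError(f"profile table {path}: depths not strictly increasing at row {bad}")
    for col, lower in (("Dz_m2s", 0.0), ("eps_m2s3", -0.0)):
        vals = df[col].to_numpy(dtype=float)
        bad_rows = np.nonzero(vals < 0.0 if col == "eps_m2s3" else vals <= 0.0)[0]
        if bad_rows.size:
            raise ValueError(
                f"profile table {path}: invalid {col} value at row {int(bad_rows[0]) + 2}"
            )
    z = np.asarray(z_nodes, dtype=float)
    interp = {
        col: np.interp(z, depth, df[col].to_numpy(dtype=float)) for col in _PROFILE_COLUMNS[1:]
    }
    return EnvironmentProfile(
        z_nodes=z,
        T=interp["temp_C"],
        Dz=interp["Dz_m2s"],
        eps=interp["eps_m2s3"],
        label=label if label is not None else str(path),
    )


def write_profile_table(profile: EnvironmentProfile, path) -> None:
    """Write a profile as the delimited text format ``read_profile_table`` accepts."""
    pd.DataFrame(
        {
            "depth_m": profile.z_nodes,
            "temp_C": profile.T,
            "Dz_m2s": profile.Dz,
            "eps_m2s3": profile.eps,
        }
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class ScenarioSchedule:
    """Wind-regime schedule: constant, or stepwise alternating (50/50 duty)."""

    mode: str = "constant"
    labels: Sequence[str] = ("high_wind",)
    period: float = 86400.0  # s, per-regime dwell time when alternating

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "alternating"):
            raise ValueError(f"unknown schedule mode {self.mode!r}")
        if self.mode == "constant" and len(self.labels) != 1:
            raise ValueError("constant schedule takes exactly one profile label")
        if self.mode == "alternating":
            if len(self.labels) != 2:
                raise ValueError("alternating schedule takes exactly two profile labels")
            if self.period <= 0.0:
                raise ValueError("alternating period must be positive")

    def label_at(self, t: float) -> str:
        if self.mode == "constant":
            return self.labels[0]
        return self.labels[int(np.floor(t / self.period)) % 2]


def scenario_profile(
    t: float,
    schedule: ScenarioSchedule,
    profiles: Mapping[str, EnvironmentProfile],
) -> EnvironmentProfile:
    """Profile in force at time t under the given schedule."""
    label = schedule.label_at(t)
    try:
        return profiles[label]
    except KeyError:
        raise KeyError(f"schedule references unknown profile label {label!r}") from None


@dataclass(frozen=True)
class LightModel:
    """Diel surface irradiance and Beer-Lambert attenuation.

    Surface light follows I_max * sin(pi t / D_L) during the photoperiod
    D_L and is zero for the remaining dark fraction of the ``day_length``
    cycle (the sine is only defined on the photoperiod; extending with
    zero keeps irradiance non-negative).
    """

    I_max: float = 800.0  # W/m^2 peak surface irradiance
    D_L: float = 16.0 * 3600.0  # s photoperiod
    day_length: float = 86400.0  # s diel cycle
    k_I: float = 1.3  # 1/m attenuation coefficient

    def __post_init__(self) -> None:
        if not (0.0 < self.D_L <= self.day_length):
            raise ValueError("photoperiod must lie in (0, day_length]")
        if self.k_I <= 0.0:
            raise ValueError("attenuation coefficient must be positive")
        if self.I_max < 0.0:
            raise ValueError("peak irradiance must be non-negative")


def surface_light(t, lm: LightModel = LightModel()):
    """Surface irradiance I_0(t) (W/m^2); zero during the dark phase."""
    tarr = np.asarray(t, dtype=float)
    if np.any(tarr < 0.0):
        raise ValueError("time must be non-negative")
    t_d = np.mod(tarr, lm.day_length)
    out = np.where(t_d <= lm.D_L, lm.I_max * np.sin(np.pi * t_d / lm.D_L), 0.0)
    out = np.maximum(out, 0.0)  # guard the sine endpoint against roundoff
    return out if out.ndim else float(out)


def light_at_depth(z, t, lm: LightModel = LightModel()):
    """Irradiance I(z, t) = I_0(t) exp(-k_I z) (W/m^2)."""
    zarr = np.asarray(z, dtype=float)
    if np.any(zarr < 0.0):
        raise ValueError("depth must be non-negative")
    out = np.asarray(surface_light(t, lm)) * np.exp(-lm.k_I * zarr)
    return out if out.ndim else float(out)
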