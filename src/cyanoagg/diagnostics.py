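"""Run diagnostics: concentrations, appearance times, power-law fits, mass audit.

The key observable is the column-integrated cell count of each size class,
N_k(t) = sum_z k n_k(z, t) dz (cells/m^2).  Because concentrations are
continuous, N_k can be smaller than k; the "appearance time" tau_k is the
first time N_k reaches a threshold (1 cell/m^2 by default) and acts as a
marker for when a colony size becomes present in the column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiagnosticsSeries",
    "total_concentration",
    "cell_count",
    "appearance_time",
    "powerlaw_fit",
    "mass_audit",
    "run_concentration_sweep",
]


def total_concentration(n: np.ndarray) -> np.ndarray:
    """Total cell concentration C(z) = sum_k k n_k(z) (cells/m^3)."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0.0):
        raise ValueError("concentrations must be non-negative")
    k = np.arange(1, n.shape[0] + 1)
    return k @ n


def cell_count(n: np.ndarray, dz: float, k: Optional[int] = None):
    """Column cell count N_k = sum_z k n_k dz (cells/m^2).

    With ``k`` given returns a scalar for that class; otherwise the vector
    over all classes.
    """
    n = np.asarray(n, dtype=float)
    ks = np.arange(1, n.shape[0] + 1)
    N = ks * n.sum(axis=-1) * dz
    if k is None:
        return N
    if not (1 <= k <= n.shape[0]):
        raise ValueError(f"size index k={k} outside [1, {n.shape[0]}]")
    return float(N[k - 1])


def mass_audit(n: np.ndarray, dz: float) -> float:
    """Column-integrated cell mass M = sum_{k,z} k n_k dz (cells/m^2)."""
    return float(np.sum(cell_count(np.asarray(n, dtype=float), dz)))


@dataclass
class DiagnosticsSeries:
    """Time series of per-class column counts, mass audit and C snapshots."""

    times: np.ndarray  # (nt,) s, strictly increasing
    N: np.ndarray  # (k_max, nt) cells/m^2
    mass: np.ndarray  # (nt,) cells/m^2
    C_snapshots: Dict[float, np.ndarray] = field(default_factory=dict)
    dz: float = float("nan")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0.0):
            raise ValueError("diagnostic times must be strictly increasing")
        if self.N.shape[1] != self.times.size or self.mass.size != self.times.size:
            raise ValueError("diagnostics arrays do not share the time axis")

    @property
    def k_max(self) -> int:
        return self.N.shape[0]

    def mass_drift(self) -> float:
        """Largest relative departure of the mass audit from its initial value."""
        return float(np.max(np.abs(self.mass - self.mass[0])) / self.mass[0])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (time_s, k, N_k) for export."""
        nt = self.times.size
        k = np.arange(1, self.k_max + 1)
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.times, self.k_max),
                "k": np.tile(k, nt),
                "N_k": self.N.T.reshape(-1),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def appearance_time(
    series: DiagnosticsSeries,
    k: int,
    threshold: float = 1.0,
) -> Optional[float]:
    """First time N_k reaches ``threshold`` (cells/m^2), or None if never.

    Linearly interpolated between the bracketing recorded outputs; returns
    the first recorded time if the series already starts above threshold.
    The result is never earlier than the first output with N_k > 0 (a class
    cannot appear before any mass was recorded in it).
    """
    if not (1 <= k <= series.k_max):
        raise ValueError(f"size index k={k} outside [1, {series.k_max}]")
    Nk = series.N[k - 1]
    above = np.nonzero(Nk >= threshold)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(series.times[0])
    t0, t1 = series.times[i - 1], series.times[i]
    y0, y1 = Nk[i - 1], Nk[i]
    tau = float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))
    t_first_positive = float(series.times[np.nonzero(Nk > 0.0)[0][0]])
    return max(tau, t_first_positive)


def powerlaw_fit(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Least-squares power law tau = prefactor * n0^slope through (n0, tau) points.

    Ordinary least squares of log10(tau) on log10(n0); returns
    (slope, prefactor).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least two (n0, tau) points")
    if np.any(pts <= 0.0):
        raise ValueError("power-law fit requires strictly positive values")
    slope, intercept = np.polyfit(np.log10(pts[:, 0]), np.log10(pts[:, 1]), 1)
    return float(slope), float(10.0**intercept)


def run_concentration_sweep(
    n0_values: Sequence[float],
    cfg=None,
    schedule=None,
    table=None,
    k_target: Optional[int] = None,
    threshold: float = 1.0,
    **run_kwargs,
) -> dict:
    """Appearance time of the largest class versus initial concentration.

    Reruns the scenario varying only the seeded single-cell concentration
    n0, records tau_{k_target} (default: the largest class) for each, and
    fits a power law through the runs that reached the threshold.  Returns
    a dict with the sampled points, the fit, and any censored runs.
    """
    # imported here: transport builds on diagnostics, not the reverse
    from dataclasses import replace

    from .environment import ScenarioSchedule
    from .geometry import build_colony_table
    from .transport import NumericalConfig, run_simulation

    if cfg is None:
        cfg = NumericalConfig()
    if schedule is None:
        schedule = ScenarioSchedule(mode="constant", labels=("high_wind",))
    if table is None:
        table = build_colony_table()
    if k_target is None:
        k_target = table.k_max

    points: list[tuple[float, float]] = []
    censored: list[float] = []
    for n0 in n0_values:
        series, _ = run_simulation(replace(cfg, n0=float(n0)), schedule, table, **run_kwargs)
        tau = appearance_time(series, k_target, threshold=threshold)
        if tau is None:
            censored.append(float(n0))
        else:
            points.append((float(n0), tau))
    result = {"points": points, "censored": censored, "k_target": int(k_target)}
    if len(points) >= 2:
        slope, prefactor = powerlaw_fit(points)
        result["slope"] = slope
        result["prefactor"] = prefactor
    return result
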