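"""Size-class bookkeeping for fractal cyanobacterial colonies.

A colony of k cells is represented by an equivalent spherical diameter
derived from fractal scaling: the compact fractal size grows as k^(1/Df)
times the single-cell diameter d0, and porosity (the water-filled fraction
of the envelope volume) inflates that size further.  Porosity decreases
linearly with colony size, from 1 for single cells down to ``phi_min`` for
the largest resolved class.  Sticking probability (collision efficiency)
follows the extracellular-polysaccharide content of *Microcystis* colonies,
which peaks at diameters of roughly 100-150 um, and is modelled as a
Gaussian bump in diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StickingParams",
    "ColonyClassTable",
    "porosity",
    "colony_diameter",
    "cell_volume_fraction",
    "sticking_probability",
    "pair_sticking",
    "build_colony_table",
]


@dataclass(frozen=True)
class StickingParams:
    """Gaussian sticking-probability curve alpha(d) = A exp(-((d-d_c)/s)^2).

    Defaults place the peak (A = 0.994) at d_c = 116 um with width
    s = 134 um, which gives alpha ~ 0.5 for a 5 um single cell and
    alpha ~ 1 for colonies near 125 um.

    ``pair_rule`` selects how the per-class values combine for a colliding
    pair: ``"max"`` (the stickier, larger partner dominates; default) or
    ``"product"`` (independent surfaces).
    """

    amplitude: float = 0.994
    center: float = 1.16e-4
    width: float = 1.34e-4
    pair_rule: str = "max"

    def __post_init__(self) -> None:
        if not (0.0 < self.amplitude <= 1.0):
            raise ValueError("sticking amplitude must lie in (0, 1]")
        if self.width <= 0.0:
            raise ValueError("sticking width must be positive")
        if self.pair_rule not in ("max", "product"):
            raise ValueError(f"unknown pair_rule {self.pair_rule!r}")


def porosity(
    k,
    k_max: int,
    phi_max: float = 1.0,
    phi_min: float = 0.2,
):
    """Colony porosity, affine in the cell count k.

    phi(1) = phi_max and phi(k_max) = phi_min; for k_max = 1 the single
    class has porosity phi_max.
    """
    if not (0.0 < phi_min <= phi_max <= 1.0):
        raise ValueError("require 0 < phi_min <= phi_max <= 1")
    karr = np.asarray(k)
    if np.any(karr < 1) or np.any(karr > k_max):
        raise ValueError(f"size index k={k} outside [1, {k_max}]")
    if k_max == 1:
        out = np.full_like(karr, phi_max, dtype=float)
    else:
        out = phi_max + (phi_min - phi_max) * (karr - 1) / (k_max - 1)
    return out if out.ndim else float(out)


def colony_diameter(
    k,
    phi,
    d0: float = 5e-6,
    Df: float = 2.5,
    dialect: str = "phi_outside",
):
    """Equivalent spherical diameter (m) of a k-cell fractal colony.

    Default ``"phi_outside"`` dialect: d_k = k^(1/Df) * d0 / phi, i.e. the
    porosity inflates the compact fractal diameter.  The alternative
    ``"phi_inside"`` dialect places the porosity inside the fractal
    exponent, d_k = (k / phi)^(1/Df) * d0.
    """
    karr = np.asarray(k, dtype=float)
    phiarr = np.asarray(phi, dtype=float)
    if np.any(karr < 1):
        raise ValueError("size index k must be >= 1")
    if np.any(phiarr <= 0.0):
        raise ValueError("porosity must be positive")
    if d0 <= 0.0:
        raise ValueError("single-cell diameter d0 must be positive")
    if not (1.0 < Df <= 3.0):
        raise ValueError("fractal dimension Df must lie in (1, 3]")
    if dialect == "phi_outside":
        out = karr ** (1.0 / Df) * d0 / phiarr
    elif dialect == "phi_inside":
        out = (karr / phiarr) ** (1.0 / Df) * d0
    else:
        raise ValueError(f"unknown diameter dialect {dialect!r}")
    return out if out.ndim else float(out)


def cell_volume_fraction(k, Df: float = 2.5):
    """Ratio of cell volume to compact colony volume, k^(1 - 3/Df).

    Equals 1 for single cells and for space-filling aggregates (Df = 3);
    decreases with k for tenuous fractal colonies (Df < 3).  Used to mix
    cell density with ambient water density when computing colony density.
    """
    karr = np.asarray(k, dtype=float)
    if np.any(karr < 1):
        raise ValueError("size index k must be >= 1")
    out = karr ** (1.0 - 3.0 / Df)
    return out if out.ndim else float(out)


def sticking_probability(d, params: StickingParams = StickingParams()):
    """Sticking probability alpha(d) for a colony of diameter d (m)."""
    darr = np.asarray(d, dtype=float)
    if np.any(darr <= 0.0):
        raise ValueError("diameter must be positive")
    out = params.amplitude * np.exp(
        -(((darr - params.center) / params.width) ** 2)
    )
    return out if out.ndim else float(out)


def pair_sticking(alpha_i, alpha_j, rule: str = "max"):
    """Combine per-class sticking probabilities for a colliding pair.

    ``"max"``: the stickier partner dominates (larger colonies carry more
    adhesive polysaccharide, so pairs involving them aggregate more often).
    ``"product"``: both surfaces must stick independently.
    """
    ai = np.asarray(alpha_i, dtype=float)
    aj = np.asarray(alpha_j, dtype=float)
    if np.any(ai < 0) or np.any(ai > 1) or np.any(aj < 0) or np.any(aj > 1):
        raise ValueError("sticking probabilities must lie in [0, 1]")
    if rule == "max":
        out = np.maximum(ai, aj)
    elif rule == "product":
        out = ai * aj
    else:
        raise ValueError(f"unknown pair rule {rule!r}")
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ColonyClassTable:
    """Per-size-class geometry and adhesion for k = 1 .. k_max.

    Vectors are indexed by class (index 0 is the single cell, index
    ``k_max - 1`` the largest resolved colony).
    """

    k_max: int
    d0: float
    Df: float
    phi: np.ndarray
    d: np.ndarray
    vfrac: np.ndarray
    alpha: np.ndarray
    sticking_params: StickingParams = field(default_factory=StickingParams)

    @property
    def k(self) -> np.ndarray:
        """Cell counts 1..k_max."""
        return np.arange(1, self.k_max + 1)

    def alpha_matrix(self) -> np.ndarray:
        """Symmetric (k_max, k_max) matrix of pairwise sticking probabilities."""
        return pair_sticking(
            self.alpha[:, None], self.alpha[None, :], rule=self.sticking_params.pair_rule
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "d_m": self.d,
                "phi": self.phi,
                "vfrac": self.vfrac,
                "alpha": self.alpha,
            }
        )

    def to_csv(self, path) -> None:
        """Export as a delimited text table for inspection."""
        self.to_frame().to_csv(path, index=False)


def build_colony_table(
    k_max: int = 101,
    d0: float = 5e-6,
    Df: float = 2.5,
    phi_min: float = 0.2,
    phi_max: float = 1.0,
    sticking: StickingParams = StickingParams(),
    diameter_dialect: str = "phi_outside",
) -> ColonyClassTable:
    """Construct and validate the full size-class table."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k = np.arange(1, k_max + 1)
    phi = np.atleast_1d(porosity(k, k_max, phi_max=phi_max, phi_min=phi_min))
    d = np.atleast_1d(colony_diameter(k, phi, d0=d0, Df=Df, dialect=diameter_dialect))
    vfrac = np.atleast_1d(cell_volume_fraction(k, Df=Df))
    alpha = np.atleast_1d(sticking_probability(d, sticking))

    if k_max > 1 and not np.all(np.diff(d) > 0.0):
        raise ValueError(
            "colony diameters are not strictly increasing in k for these "
            "parameters; refuse to build an ill-ordered class table"
        )
    if not (np.all(alpha > 0.0) and np.all(alpha <= sticking.amplitude)):
        raise ValueError("sticking probabilities out of (0, amplitude]")

    return ColonyClassTable(
        k_max=k_max,
        d0=d0,
        Df=Df,
        phi=phi,
        d=d,
        vfrac=vfrac,
        alpha=alpha,
        sticking_params=sticking,
    )
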