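"""Collision kernels and the truncated Smoluchowski reaction term.

Colonies collide through three physical mechanisms whose volumetric rates
(m^3/s) add: Brownian motion, turbulent shear (sub-Kolmogorov particles),
and differential settling.  Collisions aggregate with probability
alpha(i, j).  The population-balance reaction term is the classic discrete
Smoluchowski form, truncated so that no pair whose combined cell count
exceeds k_max ever reacts; this conserves total cell mass exactly.

The analytic solution for a constant kernel with monodisperse initial
conditions is provided as an independent test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import ColonyClassTable
from .environment import EnvironmentProfile

__all__ = [
    "BOLTZMANN",
    "KernelMatrices",
    "brownian_kernel",
    "shear_kernel",
    "settling_kernel",
    "kernel_matrices",
    "smoluchowski_rhs",
    "constant_kernel_solution",
    "truncation_mask",
    "KernelField",
]

BOLTZMANN = 1.380649e-23  # m^2 kg s^-2 K^-1


def brownian_kernel(T, mu, d_i, d_j):
    """Brownian (perikinetic) kernel 2 T k_B (d_i + d_j)^2 / (3 mu d_i d_j).

    T is absolute temperature (K).  For equal sizes this reduces to
    8 k_B T / (3 mu), independent of size.
    """
    Tarr = np.asarray(T, dtype=float)
    muarr = np.asarray(mu, dtype=float)
    di = np.asarray(d_i, dtype=float)
    dj = np.asarray(d_j, dtype=float)
    if np.any(Tarr <= 0.0) or np.any(muarr <= 0.0):
        raise ValueError("temperature and viscosity must be positive")
    if np.any(di <= 0.0) or np.any(dj <= 0.0):
        raise ValueError("diameters must be positive")
    out = 2.0 * Tarr * BOLTZMANN * (di + dj) ** 2 / (3.0 * muarr * di * dj)
    return out if out.ndim else float(out)


def shear_kernel(G, d_i, d_j, coeff: float = 4.0 / 3.0):
    """Turbulent-shear (orthokinetic) kernel coeff * G * (d_i + d_j)^3.

    Default coefficient 4/3 applies the classic constant to the total
    diameter; pass 1/6 for the radius-convention dialect.
    """
    Garr = np.asarray(G, dtype=float)
    if np.any(Garr < 0.0):
        raise ValueError("shear rate must be non-negative")
    out = coeff * Garr * (np.asarray(d_i, dtype=float) + np.asarray(d_j, dtype=float)) ** 3
    return out if out.ndim else float(out)


def settling_kernel(d_i, d_j, w_i, w_j, coeff: float = 1.0):
    """Differential-settling kernel coeff * pi * (d_i + d_j)^2 |w_i - w_j|.

    Vanishes for equal velocities (same-sized colonies at the same depth).
    Pass coeff = 1/4 for the radius-convention dialect.
    """
    di = np.asarray(d_i, dtype=float)
    dj = np.asarray(d_j, dtype=float)
    if np.any(di <= 0.0) or np.any(dj <= 0.0):
        raise ValueError("diameters must be positive")
    out = (
        coeff
        * np.pi
        * (di + dj) ** 2
        * np.abs(np.asarray(w_i, dtype=float) - np.asarray(w_j, dtype=float))
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class KernelMatrices:
    """Pairwise collision kernels and sticking probabilities at one depth."""

    beta: np.ndarray  # (K, K) m^3/s
    alpha: np.ndarray  # (K, K) dimensionless
    components: Optional[dict] = None  # per-mechanism matrices, if kept

    def __post_init__(self) -> None:
        if self.beta.shape != self.alpha.shape or self.beta.ndim != 2:
            raise ValueError("beta and alpha must be square matrices of equal shape")


def kernel_matrices(
    T_K: float,
    mu: float,
    G: float,
    w,
    table: ColonyClassTable,
    shear_coeff: float = 4.0 / 3.0,
    settling_coeff: float = 1.0,
    keep_components: bool = False,
) -> KernelMatrices:
    """Full kernel and sticking matrices at a single depth.

    ``w`` is the per-class buoyant-velocity vector at that depth (m/s).
    beta = Brownian + shear + differential settling, all evaluated with the
    local temperature, viscosity and shear rate.
    """
    w = np.asarray(w, dtype=float)
    if w.shape != (table.k_max,):
        raise ValueError("velocity vector length must equal k_max")
    di = table.d[:, None]
    dj = table.d[None, :]
    br = np.asarray(brownian_kernel(T_K, mu, di, dj))
    ts = np.asarray(shear_kernel(G, di, dj, coeff=shear_coeff))
    ds = np.asarray(settling_kernel(di, dj, w[:, None], w[None, :], coeff=settling_coeff))
    beta = br + ts + ds
    alpha = table.alpha_matrix()
    components = {"brownian": br, "shear": ts, "settling": ds} if keep_components else None
    return KernelMatrices(beta=beta, alpha=alpha, components=components)


def truncation_mask(k_max: int) -> np.ndarray:
    """Boolean matrix of reacting pairs: sizes i + j <= k_max (0-based indices)."""
    idx = np.arange(k_max)
    return (idx[:, None] + idx[None, :] + 2) <= k_max


def smoluchowski_rhs(n, km: KernelMatrices) -> np.ndarray:
    """Truncated Smoluchowski reaction rates dn_k/dt (colonies m^-3 s^-1).

    gain(k) = 1/2 sum_{i+j=k} alpha beta n_i n_j; loss(k) = n_k *
    sum_{i <= k_max - k} alpha beta n_i.  Pairs whose combined size would
    exceed k_max never react, so sum_k k * rhs_k = 0 exactly.
    """
    narr = np.asarray(n, dtype=float)
    if narr.ndim != 1:
        raise ValueError("n must be a vector over size classes")
    if np.any(narr < 0.0):
        raise ValueError("concentrations must be non-negative")
    K = narr.size
    if km.beta.shape != (K, K):
        raise ValueError("kernel matrices do not match the class count")
    q = km.alpha * km.beta
    mask = truncation_mask(K)
    loss = narr * ((q * mask) @ narr)
    gain = np.zeros(K)
    for c in range(1, K):  # class index c holds colonies of size c + 1
        a = np.arange(c)
        gain[c] = 0.5 * np.sum(q[a, c - 1 - a] * narr[a] * narr[c - 1 - a])
    return gain - loss


def constant_kernel_solution(N0: float, beta0: float, t, k):
    """Analytic size spectrum for a constant kernel, monodisperse start.

    n_k(t) = N0 x^(k-1) / (1 + x)^(k+1) with x = beta0 N0 t / 2, for the
    untruncated system with alpha = 1.  Test oracle only.
    """
    if N0 <= 0.0 or beta0 <= 0.0:
        raise ValueError("N0 and beta0 must be positive")
    tarr = np.asarray(t, dtype=float)
    if np.any(tarr < 0.0):
        raise ValueError("time must be non-negative")
    karr = np.asarray(k)
    if np.any(karr < 1):
        raise ValueError("size index k must be >= 1")
    x = beta0 * N0 * tarr / 2.0
    # evaluate in log space: x^(k-1) overflows for deep spectra
    with np.errstate(divide="ignore", invalid="ignore"):
        lognk = (karr - 1) * np.log(x) - (karr + 1) * np.log1p(x)
        out = np.where(karr == 1, N0 / (1.0 + x) ** 2, N0 * np.exp(lognk))
    return out if np.ndim(out) else float(out)


class KernelField:
    """Depth-resolved alpha*beta with the environment-only part precomputed.

    The Brownian and shear components depend only on the (per-regime)
    environment profile and are cached per depth on construction; the
    differential-settling component depends on the instantaneous velocity
    field and is rebuilt on each call to :meth:`full`.
    """

    def __init__(
        self,
        env: EnvironmentProfile,
        table: ColonyClassTable,
        shear_coeff: float = 4.0 / 3.0,
        settling_coeff: float = 1.0,
    ):
        self.table = table
        K = table.k_max
        di = table.d[:, None]
        dj = table.d[None, :]
        alpha = table.alpha_matrix()
        self.alpha = alpha
        # static part: (K, K, nz)
        br = np.asarray(
            brownian_kernel(
                env.T_kelvin[None, None, :], env.mu[None, None, :], di[..., None], dj[..., None]
            )
        )
        ts = np.asarray(
            shear_kernel(env.G[None, None, :], di[..., None], dj[..., None], coeff=shear_coeff)
        )
        self.ab_static = alpha[:, :, None] * (br + ts)
        # settling prefactor alpha * coeff * pi * (d_i + d_j)^2, shape (K, K)
        self.settling_prefactor = alpha * settling_coeff * np.pi * (di + dj) ** 2
        self.mask = truncation_mask(K)

    def full(self, w: np.ndarray) -> np.ndarray:
        """alpha*beta over (i, j, z) for the velocity matrix w[k, z]."""
        dw = np.abs(w[:, None, :] - w[None, :, :])
        return self.ab_static + self.settling_prefactor[:, :, None] * dw
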