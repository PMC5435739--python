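"""Elasticity from interatomic-potential curvature.

At moderate temperature and small strain the entropic contribution to the
free-energy density is negligible, so the elastic modulus reduces to the
curvature of the potential-energy density with respect to strain,

    E = d²u / dε²,   u = U / V₀,

with V₀ the unstrained cell volume (the zero-stress reference; dividing by
the strained volume would leak first-order volume terms into the
curvature).  Two tools implement this picture:

* **Pair stiffness.**  For a generalized Lennard-Jones pair
  U(r) = ε[(r_m/r)ⁿ − 2(r_m/r)ᵐ], the stiffness about equilibrium is the
  closed form K = [n(n−1) − 2m(m−1)] ε / r_m².  Stronger, shorter-ranged
  wells (larger ε, smaller r_m) are stiffer — covalent > hydrogen bond >
  dispersion, which is why hydrogen-bond networks control the modulus of
  amorphous cell-wall polymers.

* **Strain sweep.**  A configuration is affinely expanded along one axis
  (coordinates and box length scaled by 1+ε, no internal relaxation), a
  user-supplied energy function is evaluated at each strain, and the
  modulus is twice the quadratic coefficient of a least-squares parabola
  through the energy-density series.  The default protocol expands to a
  maximum strain amplitude of 0.01 in 10 steps; a symmetric ±ε sweep is
  available and preferred for curvature estimates, since it cancels the
  cubic anharmonicity that biases one-sided fits.

Energies are whatever unit the energy function returns (kcal/mol
throughout this package); moduli in kcal/mol/Å³ convert to GPa via the
factor 6.9477.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .structures import MolecularConfiguration, minimum_image

__all__ = [
    "LJParams",
    "StrainEnergySeries",
    "KCAL_PER_MOL_A3_TO_GPA",
    "lj_energy",
    "lj_stiffness",
    "pairwise_lj_energy",
    "strain_sweep",
    "modulus_from_series",
]

#: 1 kcal/mol/Å³ = 6.9477 GPa  (4184 J/mol / N_A / 1e-30 m³, in Pa).
KCAL_PER_MOL_A3_TO_GPA = 6.9477

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class LJParams:
    """Generalized Lennard-Jones parameters: well depth ε, equilibrium
    distance r_m (Å), repulsive/attractive exponents n > m."""

    epsilon: float
    r_m: float
    n: float = 12.0
    m: float = 6.0

    def __post_init__(self):
        if self.epsilon <= 0 or self.r_m <= 0:
            raise ValueError("epsilon and r_m must be positive")
        if not self.n > self.m > 0:
            raise ValueError("exponents must satisfy n > m > 0")


def lj_energy(r: float | np.ndarray, params: LJParams) -> float | np.ndarray:
    """Pair energy ε[(r_m/r)ⁿ − 2(r_m/r)ᵐ]; minimum −ε at r = r_m."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    x = params.r_m / r
    out = params.epsilon * (x**params.n - 2.0 * x**params.m)
    return float(out) if out.ndim == 0 else out


def lj_stiffness(params: LJParams) -> float:
    """Curvature of the pair potential at equilibrium:
    K = [n(n−1) − 2m(m−1)] ε / r_m²  (72 ε/r_m² for the 12-6 form).

    The "−2" normalization of :func:`lj_energy` places the minimum at r_m
    only when n = 2m; for other exponent pairs r_m is not the equilibrium
    distance and this closed form differs from the curvature at r_m by
    2(n − 2m) ε / r_m².
    """
    n, m = params.n, params.m
    return (n * (n - 1) - 2.0 * m * (m - 1)) * params.epsilon / params.r_m**2


def pairwise_lj_energy(params: LJParams, cutoff: float) -> Callable[[MolecularConfiguration], float]:
    """Energy function summing the LJ pair potential over all unique
    minimum-image pairs within ``cutoff`` (Å).  A toy stand-in for a force
    field, suitable for strain sweeps of generated configurations."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")

    def energy(config: MolecularConfiguration) -> float:
        pos = config.positions
        L = config.box.as_array() if config.box else None
        total = 0.0
        for i in range(config.n_atoms - 1):
            d = minimum_image(pos[i + 1:] - pos[i], L)
            dist = np.linalg.norm(d, axis=1)
            close = dist[dist <= cutoff]
            if close.size:
                total += float(np.sum(lj_energy(close, params)))
        return total

    return energy


@dataclass(frozen=True)
class StrainEnergySeries:
    """Energy density (energy/Å³, reference-volume normalized) vs strain."""

    strains: np.ndarray
    energy_density: np.ndarray
    axis: str

    def __post_init__(self):
        s = np.asarray(self.strains, dtype=float)
        u = np.asarray(self.energy_density, dtype=float)
        if s.shape != u.shape or s.ndim != 1:
            raise ValueError("strains and energy_density must be equal-length 1-D arrays")
        if np.any(np.diff(s) <= 0):
            raise ValueError("strains must be strictly increasing")
        object.__setattr__(self, "strains", s)
        object.__setattr__(self, "energy_density", u)


def strain_sweep(
    config: MolecularConfiguration,
    energy_fn: Callable[[MolecularConfiguration], float],
    max_strain: float = 0.01,
    steps: int = 10,
    axis: str = "x",
    symmetric: bool = False,
) -> StrainEnergySeries:
    """Affine uniaxial strain sweep recording energy density per strain.

    Coordinates and the box length along ``axis`` are scaled by (1+ε) for
    ε ∈ {0, max/steps, …, max} (the default expansion protocol: amplitude
    0.01 in 10 steps → 11 points including ε = 0).  With ``symmetric``
    True the sweep covers −max…+max in the same step size (2·steps + 1
    points), which is the better-conditioned choice for curvature fits.
    Energy densities are U(ε)/V₀ with V₀ the unstrained box volume; no
    internal relaxation is performed between steps.
    """
    if config.box is None:
        raise ValueError("strain sweep requires a periodic box")
    if max_strain <= 0:
        raise ValueError("max_strain must be positive")
    if steps < 2:
        raise ValueError("steps must be >= 2")
    k = _AXES[axis]
    v0 = config.box.volume
    if symmetric:
        strains = np.linspace(-max_strain, max_strain, 2 * steps + 1)
    else:
        strains = np.linspace(0.0, max_strain, steps + 1)
    pos0 = config.positions
    L0 = np.asarray(config.box.lengths)
    densities = []
    for eps in strains:
        pos = pos0.copy()
        pos[:, k] *= 1.0 + eps
        L = L0.copy()
        L[k] *= 1.0 + eps
        strained = config.with_positions(pos, box=type(config.box)(tuple(L)))
        try:
            u = float(energy_fn(strained))
        except Exception as exc:
            raise RuntimeError(f"energy function failed at strain {eps:+.5f}: {exc}") from exc
        densities.append(u / v0)
    return StrainEnergySeries(np.asarray(strains), np.asarray(densities), axis)


def modulus_from_series(series: StrainEnergySeries) -> float:
    """Elastic modulus (energy/Å³) from the strain-energy series.

    Least-squares fit u(ε) = u₀ + bε + aε²; the modulus is E = 2a.  The
    quadratic fit (rather than an endpoint finite difference) averages out
    evaluation noise; adding a constant to the series leaves E unchanged.
    Requires at least three distinct strains.
    """
    s, u = series.strains, series.energy_density
    if len(s) < 3:
        raise ValueError("modulus fit needs at least 3 strain points")
    if np.ptp(s) <= 0:
        raise ValueError("degenerate strain series")
    # centre and scale for conditioning; quadratic coefficient is invariant
    s0 = s - s.mean()
    coeffs = np.polynomial.polynomial.polyfit(s0, u, 2)
    return 2.0 * float(coeffs[2])


def modulus_gpa(series: StrainEnergySeries) -> float:
    """Modulus in GPa, assuming the energy function returned kcal/mol."""
    return modulus_from_series(series) * KCAL_PER_MOL_A3_TO_GPA
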