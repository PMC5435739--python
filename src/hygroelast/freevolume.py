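"""Van der Waals, occupied and free volume of C/H/O configurations.

Two independent routes to the van der Waals volume v_W are provided.

**Group contributions (VABC).**  For organic molecules v_W is well
approximated from composition alone:

    v_W = 14.71 N_O + 20.58 N_C + 7.24 N_H
          - 5.92 N_Bonds - 14.7 N_AR - 3.8 N_NAR      (Å³, "eq8" variant)

with N_Bonds tied to atom and ring counts per molecule by the cyclomatic
identity N_Bonds = N - 1 + N_AR + N_NAR.  Substituting that identity
collapses the formula to a bond-free form; the collapsed form in
circulation prints a carbon coefficient of 14.93 even though the
substitution gives 20.58 - 5.92 = 14.66, and no derivation of the 14.93 is
available.  Both printed forms are implemented verbatim ("eq8", "eq10")
and neither is corrected; :func:`eq10_implied_coefficients` exposes the
exact substitution for comparison.

**Geometry (voxelized Connolly).**  Atoms are hard spheres at their van
der Waals radii (C 1.7, H 1.2, O 1.55 Å); the union volume is integrated
on a voxel grid with periodic wrapping.  Probe radius 0 returns the van
der Waals volume; a positive probe yields the solvent-excluded volume via
dilate / flood-fill / erode morphology.

Occupied volume follows Bondi's packing argument, v_OC = 1.3 v_W, and the
fractional free volume is FFV = 1 - v_OC / v_T with v_T the periodic box
volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage

from .structures import MolecularConfiguration, Ring, ValidationError, perceive_rings

__all__ = [
    "CompositionCount",
    "ElementRadii",
    "VolumeReport",
    "InconsistencyError",
    "ResolutionError",
    "BONDI_FACTOR",
    "VABC_EQ8_COEFFICIENTS",
    "VABC_EQ10_COEFFICIENTS",
    "eq10_implied_coefficients",
    "count_composition",
    "vabc_volume",
    "voxel_volume",
    "fractional_free_volume",
    "volume_report",
]

#: Bondi occupied-volume factor (molecular-crystal packing at 0 K).
BONDI_FACTOR = 1.3

#: Six-term VABC formula coefficients (Å³ per count).
VABC_EQ8_COEFFICIENTS = {
    "N_O": 14.71,
    "N_C": 20.58,
    "N_H": 7.24,
    "N_Bonds": -5.92,
    "N_ARings": -14.7,
    "N_NARings": -3.8,
}

#: Collapsed (bond-free) VABC coefficients as printed; the constant term
#: applies once per molecule.
VABC_EQ10_COEFFICIENTS = {
    "N_O": 8.79,
    "N_C": 14.93,
    "N_H": 1.32,
    "N_ARings": -20.62,
    "N_NARings": -9.72,
    "constant": 5.92,
}


class InconsistencyError(ValidationError):
    """Bond/atom/ring counts violate the cyclomatic identity."""


class ResolutionError(ValueError):
    """Voxel spacing too coarse for the smallest sphere."""


@dataclass(frozen=True)
class ElementRadii:
    """Hard-sphere van der Waals radii (Å)."""

    r_C: float = 1.7
    r_H: float = 1.2
    r_O: float = 1.55

    def __post_init__(self):
        if min(self.r_C, self.r_H, self.r_O) <= 0:
            raise ValueError("radii must be positive")

    def of(self, element: str) -> float:
        return {"C": self.r_C, "H": self.r_H, "O": self.r_O}[element]


@dataclass(frozen=True)
class CompositionCount:
    """Element, bond and ring counts for a whole system.

    ``n_molecules`` is the number of connected components; the cyclomatic
    identity holds per component and therefore system-wide as
    N_Bonds = N - n_molecules + N_ARings + N_NARings.
    """

    N_O: int
    N_C: int
    N_H: int
    N_Bonds: int
    N_ARings: int
    N_NARings: int
    n_molecules: int = 1

    @property
    def N(self) -> int:
        return self.N_O + self.N_C + self.N_H

    def __post_init__(self):
        fields = (self.N_O, self.N_C, self.N_H, self.N_Bonds, self.N_ARings, self.N_NARings, self.n_molecules)
        if any(v < 0 for v in fields):
            raise ValueError("composition counts must be non-negative")


@dataclass(frozen=True)
class VolumeReport:
    """Volumes (Å³) and fractional free volume with the method tag."""

    method: str  # vabc_eq8 | vabc_eq10 | voxel
    v_W: float  # van der Waals volume
    v_OC: float  # occupied volume
    v_T: float  # total (box) volume
    ffv: float
    overpacked: bool = False

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "v_W": self.v_W,
            "v_OC": self.v_OC,
            "v_T": self.v_T,
            "ffv": self.ffv,
            "overpacked": self.overpacked,
        }


def eq10_implied_coefficients() -> dict[str, Fraction]:
    """Collapsed VABC coefficients implied by exact substitution.

    Eliminating N_Bonds = N - 1 + N_AR + N_NAR from the six-term formula
    gives, in exact hundredths arithmetic,

        (14.71-5.92) N_O + (20.58-5.92) N_C + (7.24-5.92) N_H
        - (14.7+5.92) N_AR - (3.8+5.92) N_NAR + 5.92 per molecule.

    All coefficients except carbon match the printed collapsed form.
    """
    c = {k: Fraction(str(v)) for k, v in VABC_EQ8_COEFFICIENTS.items()}
    b = c["N_Bonds"]  # negative
    return {
        "N_O": c["N_O"] + b,
        "N_C": c["N_C"] + b,
        "N_H": c["N_H"] + b,
        "N_ARings": c["N_ARings"] + b,
        "N_NARings": c["N_NARings"] + b,
        "constant": -b,
    }


# ---------------------------------------------------------------------------
# Composition counting
# ---------------------------------------------------------------------------

def count_composition(config: MolecularConfiguration) -> CompositionCount:
    """Count elements, bonds and rings, verifying the cyclomatic identity.

    Ring annotations are taken from the configuration; when absent but the
    bond graph contains cycles, they are derived from a minimum cycle basis
    with the aromatic heuristic of :func:`~hygroelast.structures.perceive_rings`.
    Per connected component the identity bonds = atoms - 1 + rings must
    hold exactly; a violation raises :class:`InconsistencyError` naming the
    component.
    """
    rings: list[Ring] = list(config.rings)
    n_independent_cycles = len(config.bonds) - config.n_atoms + _n_components(config)
    if not rings and n_independent_cycles > 0:
        rings = perceive_rings(config)

    elements = config.elements
    n_o = int(np.sum(elements == "O"))
    n_c = int(np.sum(elements == "C"))
    n_h = int(np.sum(elements == "H"))

    comp_of = {a.id: a.molecule_id for a in config.atoms}
    comp_atoms: dict[int, int] = {}
    for a in config.atoms:
        comp_atoms[a.molecule_id] = comp_atoms.get(a.molecule_id, 0) + 1
    comp_bonds: dict[int, int] = {}
    for i, j in config.bonds:
        ci, cj = comp_of[i], comp_of[j]
        if ci != cj:
            raise InconsistencyError(
                f"bond ({i},{j}) spans molecules {ci} and {cj}; rerun molecule labelling"
            )
        comp_bonds[ci] = comp_bonds.get(ci, 0) + 1
    comp_rings: dict[int, int] = {}
    n_ar = n_nar = 0
    for ring in rings:
        c = comp_of[ring.atoms[0]]
        comp_rings[c] = comp_rings.get(c, 0) + 1
        if ring.aromatic:
            n_ar += 1
        else:
            n_nar += 1

    for c, n_at in comp_atoms.items():
        expected = n_at - 1 + comp_rings.get(c, 0)
        actual = comp_bonds.get(c, 0)
        if actual != expected:
            raise InconsistencyError(
                f"molecule {c}: {actual} bonds but {n_at} atoms and "
                f"{comp_rings.get(c, 0)} rings imply {expected}"
            )

    return CompositionCount(
        N_O=n_o,
        N_C=n_c,
        N_H=n_h,
        N_Bonds=len(config.bonds),
        N_ARings=n_ar,
        N_NARings=n_nar,
        n_molecules=len(comp_atoms),
    )


def _n_components(config: MolecularConfiguration) -> int:
    return len({a.molecule_id for a in config.atoms}) if config.n_atoms else 0


# ---------------------------------------------------------------------------
# VABC volume
# ---------------------------------------------------------------------------

def vabc_volume(counts: CompositionCount, variant: str = "eq8") -> float:
    """Van der Waals volume (Å³) from group contributions.

    ``eq8`` uses the six-term formula with the explicit bond count;
    ``eq10`` uses the printed collapsed form, whose constant term is
    applied once per molecule.  Both sum over the whole system.
    """
    if variant == "eq8":
        c = VABC_EQ8_COEFFICIENTS
        return (
            c["N_O"] * counts.N_O
            + c["N_C"] * counts.N_C
            + c["N_H"] * counts.N_H
            + c["N_Bonds"] * counts.N_Bonds
            + c["N_ARings"] * counts.N_ARings
            + c["N_NARings"] * counts.N_NARings
        )
    if variant == "eq10":
        c = VABC_EQ10_COEFFICIENTS
        return (
            c["N_O"] * counts.N_O
            + c["N_C"] * counts.N_C
            + c["N_H"] * counts.N_H
            + c["N_ARings"] * counts.N_ARings
            + c["N_NARings"] * counts.N_NARings
            + c["constant"] * counts.n_molecules
        )
    raise ValueError(f"unknown VABC variant {variant!r} (eq8 or eq10)")


# ---------------------------------------------------------------------------
# Voxelized geometric volume
# ---------------------------------------------------------------------------

def voxel_volume(
    config: MolecularConfiguration,
    radii: ElementRadii = ElementRadii(),
    probe: float = 0.0,
    spacing: float = 0.2,
) -> float:
    """Geometric volume (Å³) of the union of van der Waals spheres.

    With ``probe`` = 0 this is the van der Waals volume: the number of
    voxel centres inside any sphere times the voxel volume, spheres
    wrapping across the periodic box faces.  With ``probe`` > 0 the
    solvent-excluded volume is computed morphologically: grow every sphere
    by the probe radius, flood-fill the probe-accessible exterior (the
    largest periodic component of the complement; smaller cavities count
    as excluded volume), then shrink the accessible region back by the
    probe.  Converges to the exact geometric volume as spacing -> 0.

    Raises :class:`ResolutionError` when ``spacing`` is not smaller than
    the smallest sphere radius present.
    """
    if config.box is None:
        raise ValueError("voxel volume requires a periodic box")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    elements = config.elements
    if config.n_atoms == 0:
        return 0.0
    r_atoms = np.array([radii.of(e) for e in elements])
    if spacing >= r_atoms.min():
        raise ResolutionError(
            f"spacing {spacing} Å must be smaller than the smallest radius {r_atoms.min()} Å"
        )
    L = config.box.as_array()
    n = np.maximum(1, np.round(L / spacing).astype(int))
    h = L / n  # per-axis true spacing
    voxel_vol = float(np.prod(h))
    pos = np.mod(config.positions, L)

    if probe == 0.0:
        covered = _union_mask(pos, r_atoms, n, h)
        return float(np.count_nonzero(covered)) * voxel_vol

    covered_p = _union_mask(pos, r_atoms + probe, n, h)
    accessible = ~covered_p
    exterior = _largest_periodic_component(accessible)
    # distance from every voxel to the nearest exterior voxel, periodic:
    # pad by wrap so the transform sees across the box faces
    pad = int(np.ceil(probe / h.min())) + 2
    ext_pad = np.pad(exterior, pad, mode="wrap")
    dt = ndimage.distance_transform_edt(~ext_pad, sampling=h)
    dt = dt[pad:-pad, pad:-pad, pad:-pad]
    excluded = dt > probe  # not reachable by any probe sphere
    return float(np.count_nonzero(excluded)) * voxel_vol


def _union_mask(pos: np.ndarray, r: np.ndarray, n: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Boolean voxel mask of the union of spheres, with periodic wrap."""
    covered = np.zeros(tuple(n), dtype=bool)
    for center, radius in zip(pos, r):
        lo = np.floor((center - radius) / h - 0.5).astype(int)
        hi = np.ceil((center + radius) / h + 0.5).astype(int)
        span = hi - lo + 1
        if np.any(span >= n):
            # sphere wraps onto itself: test the whole grid with minimum image
            axes = [(np.arange(n[k]) + 0.5) * h[k] for k in range(3)]
            grids = np.meshgrid(*axes, indexing="ij")
            d2 = np.zeros(tuple(n))
            for k in range(3):
                dk = grids[k] - center[k]
                dk -= n[k] * h[k] * np.round(dk / (n[k] * h[k]))
                d2 += dk * dk
            covered |= d2 <= radius * radius
            continue
        idx = [np.arange(lo[k], hi[k] + 1) for k in range(3)]
        centers = [(idx[k] + 0.5) * h[k] for k in range(3)]
        dx = centers[0][:, None, None] - center[0]
        dy = centers[1][None, :, None] - center[1]
        dz = centers[2][None, None, :] - center[2]
        mask = dx * dx + dy * dy + dz * dz <= radius * radius
        wrapped = np.ix_(idx[0] % n[0], idx[1] % n[1], idx[2] % n[2])
        covered[wrapped] |= mask
    return covered


def _largest_periodic_component(mask: np.ndarray) -> np.ndarray:
    """Largest connected component of a boolean mask, merging across faces."""
    labels, n_lab = ndimage.label(mask)
    if n_lab <= 1:
        return mask.copy()
    parent = list(range(n_lab + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for axis in range(3):
        lo = np.take(labels, 0, axis=axis)
        hi = np.take(labels, -1, axis=axis)
        touching = (lo > 0) & (hi > 0)
        for a, b in zip(lo[touching].ravel(), hi[touching].ravel()):
            union(int(a), int(b))
    roots = np.array([find(l) for l in range(n_lab + 1)])
    merged = roots[labels]
    sizes = np.bincount(merged.ravel())
    sizes[0] = 0
    return merged == int(np.argmax(sizes))


# ---------------------------------------------------------------------------
# Fractional free volume
# ---------------------------------------------------------------------------

def fractional_free_volume(v_OC: float, v_T: float) -> float:
    """FFV = 1 - v_OC / v_T.

    Returns a negative value (with a warning) when the occupied volume
    exceeds the total volume — a physically over-packed configuration.
    """
    if v_T <= 0:
        raise ValueError("total volume must be positive")
    if v_OC < 0:
        raise ValueError("occupied volume must be non-negative")
    ffv = 1.0 - v_OC / v_T
    if ffv < 0:
        warnings.warn(
            f"occupied volume {v_OC:.4g} exceeds total volume {v_T:.4g}: over-packed system",
            stacklevel=2,
        )
    return ffv


def volume_report(
    config: MolecularConfiguration,
    method: str = "vabc_eq8",
    radii: ElementRadii = ElementRadii(),
    probe: float = 0.0,
    spacing: float = 0.2,
) -> VolumeReport:
    """Full volume accounting for one configuration.

    ``method`` is one of ``vabc_eq8``, ``vabc_eq10`` (group contributions,
    occupied = 1.3 v_W) or ``voxel`` (geometric union of spheres, occupied
    = 1.3 v_W as well, keeping Bondi's packing correction on either
    route).  Total volume is always the periodic box volume.
    """
    if config.box is None:
        raise ValueError("volume report requires a periodic box")
    v_T = config.box.volume
    if method in ("vabc_eq8", "vabc_eq10"):
        counts = count_composition(config)
        v_w = vabc_volume(counts, variant=method.removeprefix("vabc_"))
    elif method == "voxel":
        v_w = voxel_volume(config, radii=radii, probe=probe, spacing=spacing)
    else:
        raise ValueError(f"unknown method {method!r}")
    v_oc = BONDI_FACTOR * v_w
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ffv = fractional_free_volume(v_oc, v_T)
    return VolumeReport(method=method, v_W=v_w, v_OC=v_oc, v_T=v_T, ffv=ffv, overpacked=ffv < 0)
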