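"""Radial distribution functions between atom selections, with peaks.

Single-frame estimator under orthorhombic periodic boundaries:

    g(r_k) = <pair count in shell k> / (n_A * rho_B * V_shell(k)),

where rho_B = n_B / V_box and the shells are spherical bins of width
``dr``.  Self-pairs are excluded when the two selections overlap.  The
bookkeeping identity sum_k g(r_k) rho_B V_shell(k) = mean per-A-atom pair
count within r_max holds exactly and is what coordination numbers are
integrated from.

The water-hydroxyl convenience wrapper mirrors the standard hydration
analysis of hydroxyl-bearing polymers: by default it correlates water
hydrogens with hydroxyl/acceptor oxygens, so a first peak near 1.75 Å is
an H...O hydrogen-bond distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import AtomRoles, MolecularConfiguration, classify_atoms, minimum_image

__all__ = ["RDFResult", "compute_rdf", "find_peaks", "water_hydroxyl_rdf"]


@dataclass(frozen=True)
class RDFResult:
    """Binned pair-distribution function between two selections."""

    bin_edges: np.ndarray  # (k+1,) Å
    g: np.ndarray  # (k,) dimensionless
    n_A: int
    n_B: int
    box_volume: float  # Å³

    def __post_init__(self):
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "g", np.asarray(self.g, dtype=float))
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if len(self.g) != len(self.bin_edges) - 1:
            raise ValueError("g must have one value per bin")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def shell_volumes(self) -> np.ndarray:
        return 4.0 / 3.0 * np.pi * (self.bin_edges[1:] ** 3 - self.bin_edges[:-1] ** 3)

    @property
    def rho_B(self) -> float:
        return self.n_B / self.box_volume

    def coordination_number(self, r_lo: float, r_hi: float) -> float:
        """Mean number of B atoms per A atom in shells inside [r_lo, r_hi].

        Integrates g * rho_B * V_shell over bins whose centres fall in the
        interval — the exact inverse of the histogram normalization, so it
        returns the raw per-A pair count.
        """
        mask = (self.bin_centers >= r_lo) & (self.bin_centers <= r_hi)
        return float(np.sum(self.g[mask] * self.shell_volumes[mask]) * self.rho_B)


def compute_rdf(
    config: MolecularConfiguration,
    sel_A: set[int] | list[int],
    sel_B: set[int] | list[int],
    r_max: float | None = None,
    dr: float = 0.05,
) -> RDFResult:
    """Radial distribution function between two atom-id selections.

    ``r_max`` defaults to half the smallest box length, the largest radius
    at which minimum-image distances are unambiguous; larger values are
    rejected.  Overlapping selections contribute no self-pairs.
    """
    if config.box is None:
        raise ValueError("RDF requires a periodic box")
    sel_A = sorted(set(sel_A))
    sel_B = sorted(set(sel_B))
    if not sel_A or not sel_B:
        raise ValueError("selections must be non-empty")
    L = config.box.as_array()
    half_min = config.box.min_length / 2.0
    if r_max is None:
        r_max = half_min
    if r_max > half_min + 1e-9:
        raise ValueError(f"r_max={r_max} exceeds half the smallest box length ({half_min:.4g})")
    if dr <= 0:
        raise ValueError("dr must be positive")

    idx = {a.id: i for i, a in enumerate(config.atoms)}
    pos = config.positions
    pa = pos[[idx[i] for i in sel_A]]
    pb = pos[[idx[i] for i in sel_B]]

    d = minimum_image(pa[:, None, :] - pb[None, :, :], L)
    dist = np.linalg.norm(d, axis=-1)
    # remove self-pairs where the same atom appears in both selections
    common = set(sel_A) & set(sel_B)
    if common:
        a_pos = {aid: k for k, aid in enumerate(sel_A)}
        b_pos = {aid: k for k, aid in enumerate(sel_B)}
        for aid in common:
            dist[a_pos[aid], b_pos[aid]] = np.inf

    n_bins = int(np.ceil(r_max / dr - 1e-12))
    edges = dr * np.arange(n_bins + 1)
    counts, _ = np.histogram(dist.ravel(), bins=edges)

    n_A, n_B = len(sel_A), len(sel_B)
    rho_B = n_B / config.box.volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (n_A * rho_B * shell)
    return RDFResult(edges, g, n_A, n_B, config.box.volume)


def find_peaks(rdf: RDFResult, min_height: float = 0.0) -> list[tuple[float, float]]:
    """Local maxima of g(r) above ``min_height``, ordered by r.

    A bin is a peak when its g value strictly exceeds the previous bin and
    is at least the next one (plateaus report their left edge).  Peak
    positions are bin centres.  Endpoints are not peaks.
    """
    g = rdf.g
    r = rdf.bin_centers
    peaks = []
    for i in range(1, len(g) - 1):
        if g[i] > g[i - 1] and g[i] >= g[i + 1] and g[i] >= min_height:
            peaks.append((float(r[i]), float(g[i])))
    return peaks


def water_hydroxyl_rdf(
    config: MolecularConfiguration,
    roles: AtomRoles | None = None,
    water_atoms: str = "H",
    hydroxyl_atoms: str = "O",
    r_max: float | None = None,
    dr: float = 0.05,
) -> RDFResult:
    """RDF between water-molecule atoms and polymer hydroxyl-group atoms.

    ``water_atoms`` / ``hydroxyl_atoms`` choose "O" or "H" members of each
    group.  The default water-H vs hydroxyl-O pairing makes the first peak
    a hydrogen-bond H...O distance.
    """
    if roles is None:
        roles = classify_atoms(config)
    adj = config.adjacency()
    elem = {a.id: a.element for a in config.atoms}
    if water_atoms == "O":
        sel_a = set(roles.water_oxygens)
    elif water_atoms == "H":
        sel_a = set(roles.water_hydrogens)
    else:
        raise ValueError("water_atoms must be 'O' or 'H'")
    if hydroxyl_atoms == "O":
        sel_b = set(roles.hydroxyl_oxygens)
    elif hydroxyl_atoms == "H":
        sel_b = {h for o in roles.hydroxyl_oxygens for h in adj[o] if elem[h] == "H"}
    else:
        raise ValueError("hydroxyl_atoms must be 'O' or 'H'")
    if not sel_a:
        raise ValueError("configuration contains no water molecules")
    if not sel_b:
        raise ValueError("configuration contains no hydroxyl groups")
    return compute_rdf(config, sel_a, sel_b, r_max=r_max, dr=dr)
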