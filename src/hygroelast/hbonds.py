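"""Geometric hydrogen-bond detection and 12-10-cos4 energy partitioning.

A donor-H...acceptor triple counts as a hydrogen bond when the
hydrogen-acceptor minimum-image distance is at most ``d_max`` (default
2.5 Å) and the D-H-A angle is at least ``theta_min`` (default 120°).
Each detected bond is scored with a CHARMM-style 12-10 potential modulated
by the fourth power of the angle cosine,

    E_hb = D_hb [ 5 (r_hb / r_DA)^12 - 6 (r_hb / r_DA)^10 ] cos^4(theta_DHA),

evaluated on the donor-acceptor distance r_DA.  Note the asymmetry, kept
deliberately: the *detection* cutoff applies to the H...A distance while
the *energy* uses the D...A distance; both are stored on every bond.

Totals are partitioned into the three interaction classes that matter for
moisture response: polymer-polymer (pp), water-water (ww) and
polymer-water (pw, either orientation).  The partition is exact:
all = pp + ww + pw for both energies and counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structures import AtomRoles, MolecularConfiguration, classify_atoms, minimum_image

__all__ = [
    "HBondCriteria",
    "HBondParams",
    "HBond",
    "HBondPartition",
    "hbond_energy",
    "detect_hbonds",
    "partition_hbond_energy",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric detection criteria: H...A cutoff (Å), minimum D-H-A angle (deg)."""

    d_max: float = 2.5
    theta_min: float = 120.0

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.theta_min <= 180:
            raise ValueError("theta_min must lie in (0, 180]")


@dataclass(frozen=True)
class HBondParams:
    """12-10 potential parameters: well depth D_hb (kcal/mol), equilibrium
    donor-acceptor distance r_hb (Å).

    The defaults (4.0 kcal/mol, 2.75 Å) are typical O-H...O literature
    values; both are plain attributes and can be overridden.
    """

    D_hb: float = 4.0
    r_hb: float = 2.75

    def __post_init__(self):
        if self.D_hb <= 0 or self.r_hb <= 0:
            raise ValueError("D_hb and r_hb must be positive")


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond with its geometry, class and energy."""

    donor_id: int
    hydrogen_id: int
    acceptor_id: int
    r_HA: float  # hydrogen-acceptor distance (Å, detection criterion)
    r_DA: float  # donor-acceptor distance (Å, energy argument)
    theta_DHA: float  # interior D-H-A angle (degrees; 180 = linear)
    klass: str  # pp | ww | pw
    energy: float = math.nan  # kcal/mol; nan until scored


@dataclass(frozen=True)
class HBondPartition:
    """Class-resolved energy totals (kcal/mol) and bond counts."""

    energy_all: float
    energy_pp: float
    energy_ww: float
    energy_pw: float
    count_all: int
    count_pp: int
    count_ww: int
    count_pw: int

    def to_dict(self) -> dict[str, float | int]:
        return {
            "energy_all": self.energy_all,
            "energy_pp": self.energy_pp,
            "energy_ww": self.energy_ww,
            "energy_pw": self.energy_pw,
            "count_all": self.count_all,
            "count_pp": self.count_pp,
            "count_ww": self.count_ww,
            "count_pw": self.count_pw,
        }


def hbond_energy(r_DA: float, theta_DHA: float, params: HBondParams = HBondParams()) -> float:
    """12-10-cos4 hydrogen-bond energy (kcal/mol).

    Minimum is exactly -D_hb at (r_DA = r_hb, theta = 180°); the cos^4
    factor kills the energy at theta = 90°.
    """
    if r_DA <= 0:
        raise ValueError("r_DA must be positive")
    x = params.r_hb / r_DA
    radial = 5.0 * x**12 - 6.0 * x**10
    return params.D_hb * radial * math.cos(math.radians(theta_DHA)) ** 4


def detect_hbonds(
    config: MolecularConfiguration,
    roles: AtomRoles | None = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBond]:
    """Enumerate hydrogen bonds satisfying the geometric criteria.

    For every donor oxygen D, each of its covalent hydrogens H and every
    acceptor oxygen A (A != D, A not covalently bonded to H): keep the
    triple iff the minimum-image H...A distance <= d_max and the D-H-A
    angle >= theta_min.  One hydrogen may bond to several acceptors
    (bifurcation is allowed).  Geometry only; energies are left NaN.

    Classes: ww if both D and A belong to water molecules, pp if both are
    polymer, pw otherwise.
    """
    if config.box is None:
        raise ValueError("hydrogen-bond detection requires a periodic box")
    if roles is None:
        roles = classify_atoms(config)
    adj = config.adjacency()
    L = config.box.as_array()
    pos = config.positions
    idx = {a.id: i for i, a in enumerate(config.atoms)}

    acceptors = sorted(roles.acceptor_oxygens)
    if not acceptors:
        return []
    acc_pos = pos[[idx[a] for a in acceptors]]

    out: list[HBond] = []
    for donor in sorted(roles.donor_oxygens):
        d_pos = pos[idx[donor]]
        hydrogens = sorted(h for h in adj[donor] if config.atoms[idx[h]].element == "H")
        for h in hydrogens:
            h_pos = pos[idx[h]]
            dv = minimum_image(acc_pos - h_pos, L)
            r_ha = np.linalg.norm(dv, axis=1)
            cand = np.nonzero(r_ha <= criteria.d_max)[0]
            if cand.size == 0:
                continue
            hd = minimum_image(d_pos - h_pos, L)
            nhd = np.linalg.norm(hd)
            for c in cand:
                acc = acceptors[c]
                if acc == donor or acc in adj[h]:
                    continue
                cosang = float(np.dot(hd, dv[c]) / (nhd * r_ha[c]))
                theta = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if theta < criteria.theta_min:
                    continue
                r_da = float(np.linalg.norm(minimum_image(acc_pos[c] - d_pos, L)))
                d_water = roles.is_water(donor)
                a_water = roles.is_water(acc)
                klass = "ww" if (d_water and a_water) else ("pp" if not (d_water or a_water) else "pw")
                out.append(HBond(donor, h, acc, float(r_ha[c]), r_da, theta, klass))
    return out


def partition_hbond_energy(
    config: MolecularConfiguration,
    roles: AtomRoles | None = None,
    criteria: HBondCriteria = HBondCriteria(),
    params: HBondParams = HBondParams(),
) -> HBondPartition:
    """Detect, score and partition hydrogen-bond energy by interaction class."""
    bonds = detect_hbonds(config, roles, criteria)
    scored = [
        HBond(
            b.donor_id, b.hydrogen_id, b.acceptor_id, b.r_HA, b.r_DA, b.theta_DHA, b.klass,
            hbond_energy(b.r_DA, b.theta_DHA, params),
        )
        for b in bonds
    ]
    e = {"pp": 0.0, "ww": 0.0, "pw": 0.0}
    c = {"pp": 0, "ww": 0, "pw": 0}
    for b in scored:
        e[b.klass] += b.energy
        c[b.klass] += 1
    return HBondPartition(
        energy_all=e["pp"] + e["ww"] + e["pw"],
        energy_pp=e["pp"],
        energy_ww=e["ww"],
        energy_pw=e["pw"],
        count_all=c["pp"] + c["ww"] + c["pw"],
        count_pp=c["pp"],
        count_ww=c["ww"],
        count_pw=c["pw"],
    )


def score_hbonds(bonds: list[HBond], params: HBondParams = HBondParams()) -> list[HBond]:
    """Return copies of ``bonds`` with energies filled in."""
    return [
        HBond(
            b.donor_id, b.hydrogen_id, b.acceptor_id, b.r_HA, b.r_DA, b.theta_DHA, b.klass,
            hbond_energy(b.r_DA, b.theta_DHA, params),
        )
        for b in bonds
    ]
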