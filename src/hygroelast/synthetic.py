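"""Synthetic molecular configurations for hydrated-biopolymer analyses.

The analyses in this package were designed for equilibrated atomistic
models of amorphous lignin, xylan-type hemicellulose and their crosslinked
complex.  Those models are expensive to build; this module generates small
*toy* systems that reproduce the structural features the analyses actually
key on:

* rigid water molecules (gas-phase geometry: O-H 0.9572 Å, H-O-H 104.52°),
* a lignin-like chain unit — an aromatic ring carrying a three-carbon side
  chain terminated by a hydroxymethyl (-CH2-OH) group, so the hydroxyl is
  extended away from the backbone,
* a xylan-like chain unit — a nonaromatic pyranose-style ring with exactly
  two ring-attached hydroxyls,
* hydration of a dry configuration to a prescribed moisture content
  (dry-basis mass percent), inserting waters into void space,
* simple-cubic lattices used as exactly-solvable RDF fixtures.

The templates are coarse chemical caricatures: element ratios, ring and
hydroxyl topology are right; geometry uses idealized bond lengths (C-C
1.54, C-O 1.43, O-H 0.96, aromatic C-C 1.39 Å) and is not force-field
valid.  Every generator is bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import (
    Atom,
    Box,
    ELEMENT_MASSES,
    MolecularConfiguration,
    Ring,
    assign_molecule_ids,
    classify_atoms,
    minimum_image,
)

__all__ = [
    "CapacityError",
    "MoistureTarget",
    "TemplateUnit",
    "WATER_MOLAR_MASS",
    "lignin_like_unit",
    "xylan_like_unit",
    "make_water_box",
    "make_toy_polymer",
    "hydrate",
    "make_lattice",
    "moisture_content",
    "water_count_for_target",
]

#: Molar mass of water (amu), used for moisture-content bookkeeping.
WATER_MOLAR_MASS = 18.015

# Idealized bond lengths (Å).
CC = 1.54
CO = 1.43
OH = 0.96
CH = 1.09
CC_AROMATIC = 1.39

_WATER_OH = 0.9572
_WATER_ANGLE = np.deg2rad(104.52)

#: Rigid water geometry: O at origin, both H in the xy plane.
WATER_GEOMETRY = np.array(
    [
        [0.0, 0.0, 0.0],
        [_WATER_OH, 0.0, 0.0],
        [_WATER_OH * np.cos(_WATER_ANGLE), _WATER_OH * np.sin(_WATER_ANGLE), 0.0],
    ]
)
WATER_ELEMENTS = ("O", "H", "H")


class CapacityError(Exception):
    """Random placement failed within the retry budget."""


@dataclass(frozen=True)
class MoistureTarget:
    """Moisture content target, dry-basis mass percent.

    MC = 100 x (mass of water) / (mass of dry polymer).  This is the
    wood-science convention; a 1000-amu dry polymer at 10% MC carries
    100 amu of water.
    """

    mc: float

    def __post_init__(self):
        if not np.isfinite(self.mc) or self.mc < 0:
            raise ValueError(f"moisture content must be a non-negative percent, got {self.mc}")


@dataclass(frozen=True)
class TemplateUnit:
    """One monomer template: local geometry plus linkage topology.

    ``head``/``tail`` are indices (within the unit) of the atoms that join
    consecutive units; ``hydroxyl_oxygens`` indexes the O atoms of O-H
    groups the unit contributes.
    """

    kind: str
    elements: tuple[str, ...]
    positions: np.ndarray  # (n, 3)
    bonds: frozenset[tuple[int, int]]
    rings: tuple[tuple[tuple[int, ...], bool], ...]  # (cycle, aromatic)
    hydroxyl_oxygens: tuple[int, ...]
    head: int
    tail: int

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def mass(self) -> float:
        return float(sum(ELEMENT_MASSES[e] for e in self.elements))


def _hexagon(radius: float) -> np.ndarray:
    ang = np.arange(6) * np.pi / 3.0
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1)


def lignin_like_unit() -> TemplateUnit:
    """Phenylpropanoid caricature: aromatic ring + propyl side chain ending
    in a hydroxymethyl group.

    Atoms 0-5: aromatic ring carbons (regular hexagon, C-C 1.39 Å).
    Atoms 6-8: ring hydrogens on C2, C4, C5.
    Atoms 9-11: side-chain carbons C7-C8-C9 off C1.
    Atom 12: hydroxyl oxygen on C9; atom 13: its hydrogen.
    Atoms 14-19: two hydrogens on each side-chain carbon.
    The inter-unit linkage runs through the para pair: C3 (head) and
    C0 (tail), so consecutive rings are well separated along the chain.
    """
    ring = _hexagon(CC_AROMATIC)
    elements: list[str] = ["C"] * 6
    positions: list[np.ndarray] = [p for p in ring]
    bonds = {(i, (i + 1) % 6) for i in range(6)}
    rings = (((0, 1, 2, 3, 4, 5), True),)

    # ring hydrogens on C2, C4, C5 (C1 holds the side chain; C0/C3 link)
    for c in (2, 4, 5):
        elements.append("H")
        positions.append(ring[c] * (1 + CH / CC_AROMATIC))
        bonds.add((c, len(elements) - 1))

    # side chain C7-C8-C9 rising out of the ring plane from C1 (zig-zag in
    # y), well clear of both the ring hydrogens and the next unit
    up = np.array([0.0, 0.0, 1.0])
    zig = np.array([0.0, 1.0, 0.0])
    c7 = ring[1] + CC * up
    c8 = c7 + 0.473 * CC * zig + 0.881 * CC * up
    c9 = c8 - 0.473 * CC * zig + 0.881 * CC * up
    for p in (c7, c8, c9):
        elements.append("C")
        positions.append(p)
    i7, i8, i9 = 9, 10, 11
    bonds.update({(1, i7), (i7, i8), (i8, i9)})

    # terminal hydroxyl on C9 (extended, chain-terminal carbon)
    o = c9 + 0.473 * CO * zig + 0.881 * CO * up
    h = o + OH * up
    elements.extend(["O", "H"])
    positions.extend([o, h])
    io = 12
    bonds.update({(i9, io), (io, 13)})

    # two hydrogens per side-chain carbon, straddling the zig-zag plane
    perp = np.array([1.0, 0.0, 0.0])
    for c_idx, base in ((i7, c7), (i8, c8), (i9, c9)):
        for s in (+1.0, -1.0):
            elements.append("H")
            positions.append(base + s * perp * CH * 0.9 - zig * CH * 0.44)
            bonds.add((c_idx, len(elements) - 1))

    return TemplateUnit(
        kind="lignin_like",
        elements=tuple(elements),
        positions=np.array(positions),
        bonds=frozenset(tuple(sorted(b)) for b in bonds),
        rings=rings,
        hydroxyl_oxygens=(io,),
        head=3,
        tail=0,
    )


def xylan_like_unit() -> TemplateUnit:
    """Pyranose-style caricature: one nonaromatic six-membered ring (5 C +
    1 ring O) with exactly two ring-attached hydroxyls.

    Atoms 0-4: ring carbons C1-C5; atom 5: ring oxygen O5.
    Atoms 6-7: hydroxyl O on C2 and C3; atoms 8-9: their hydrogens.
    Atoms 10-14: one hydrogen on each ring carbon.
    C1 is the head and C4 the tail of the inter-unit linkage.
    """
    ring = _hexagon(CC * 0.92)  # ring with ~1.42 Å edges, C-O-ish average
    # pucker the ring slightly so it is visibly nonplanar
    ring[:, 2] = 0.25 * np.array([1, -1, 1, -1, 1, -1])
    elements = ["C", "C", "C", "C", "C", "O"]
    positions = [p for p in ring]
    bonds = {(i, (i + 1) % 6) for i in range(6)}
    rings = (((0, 1, 2, 3, 4, 5), False),)

    # two ring-attached hydroxyls on C2 (index 1) and C3 (index 2)
    hydroxyl_os = []
    for c in (1, 2):
        direction = ring[c] / np.linalg.norm(ring[c])
        o = ring[c] + direction * CO
        h = o + direction * OH
        elements.append("O")
        positions.append(o)
        io = len(elements) - 1
        hydroxyl_os.append(io)
        bonds.add((c, io))
    for io in hydroxyl_os:
        elements.append("H")
        positions.append(positions[io] + np.array([0.0, 0.0, OH]))
        bonds.add((io, len(elements) - 1))
    # fix hydroxyl H placement radially instead (avoid clashes), keep z offset small
    # one hydrogen on each ring carbon, alternating above/below the ring
    for k, c in enumerate((0, 1, 2, 3, 4)):
        elements.append("H")
        positions.append(ring[c] + np.array([0.0, 0.0, (1 if k % 2 == 0 else -1) * CH]))
        bonds.add((c, len(elements) - 1))

    return TemplateUnit(
        kind="xylan_like",
        elements=tuple(elements),
        positions=np.array(positions),
        bonds=frozenset(tuple(sorted(b)) for b in bonds),
        rings=rings,
        hydroxyl_oxygens=tuple(hydroxyl_os),
        head=0,
        tail=3,
    )


_TEMPLATES = {"lignin_like": lignin_like_unit, "xylan_like": xylan_like_unit}


# ---------------------------------------------------------------------------
# Water boxes
# ---------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized quaternion draw."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


_MAX_TRIALS_PER_MOLECULE = 10_000


def make_water_box(
    n: int,
    box: Box,
    seed: int,
    min_dist: float = 2.0,
) -> MolecularConfiguration:
    """Place ``n`` rigid waters at random positions and orientations.

    All intermolecular atom pairs are kept at least ``min_dist`` apart
    under the minimum-image convention (rejection sampling, capped at
    10,000 trials per molecule).  Deterministic under ``seed``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    L = box.as_array()
    placed: list[np.ndarray] = []  # (3,3) coordinate blocks
    occupied = np.empty((0, 3))
    for k in range(n):
        for _ in range(_MAX_TRIALS_PER_MOLECULE):
            origin = rng.uniform(0.0, L)
            rot = _random_rotation(rng)
            coords = WATER_GEOMETRY @ rot.T + origin
            if occupied.shape[0]:
                d = minimum_image(coords[:, None, :] - occupied[None, :, :], L)
                if np.min(np.linalg.norm(d, axis=-1)) < min_dist:
                    continue
            placed.append(coords)
            occupied = np.vstack([occupied, coords])
            break
        else:
            raise CapacityError(
                f"could not place water {k + 1}/{n} at min_dist={min_dist} Å "
                f"in box {box.lengths} after {_MAX_TRIALS_PER_MOLECULE} trials"
            )
    atoms, bonds = [], set()
    for k, coords in enumerate(placed):
        base = 3 * k
        for j, (e, p) in enumerate(zip(WATER_ELEMENTS, coords)):
            atoms.append(Atom(base + j, e, tuple(p), molecule_id=k))
        bonds.update({(base, base + 1), (base, base + 2)})
    return MolecularConfiguration(atoms, bonds, [], box)


# ---------------------------------------------------------------------------
# Toy polymers
# ---------------------------------------------------------------------------

def make_toy_polymer(
    kind: str,
    n_units: int,
    seed: int,
    box: Box,
    jitter: float = 0.1,
) -> MolecularConfiguration:
    """Build a chain of ``n_units`` template copies joined tail-to-head.

    Consecutive units are joined by exactly one covalent bond (tail atom of
    unit *i* to head atom of unit *i+1*, placed 1.54 Å apart along the
    chain axis).  Coordinates receive a small Gaussian jitter (``jitter``
    Å, deterministic under ``seed``) so chains are not perfectly periodic;
    topology is untouched.  The chain is centred in ``box`` and a
    :class:`CapacityError` is raised if it does not fit.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    if kind not in _TEMPLATES:
        raise ValueError(f"unknown template kind {kind!r}; choose from {sorted(_TEMPLATES)}")
    unit = _TEMPLATES[kind]()
    rng = np.random.default_rng(seed)

    # Orient each copy identically and translate it so the tail->head
    # linkage bond (length CC) points outward from the unit body, i.e.
    # along the in-plane direction from the ring centre through the tail
    # atom.  That keeps consecutive units from overlapping.
    head_pos = unit.positions[unit.head]
    tail_pos = unit.positions[unit.tail]
    out_dir = np.array([tail_pos[0], tail_pos[1], 0.0])
    out_dir /= np.linalg.norm(out_dir)
    shift = tail_pos - head_pos + CC * out_dir

    atoms: list[Atom] = []
    bonds: set[tuple[int, int]] = set()
    rings: list[Ring] = []
    all_pos: list[np.ndarray] = []
    for u in range(n_units):
        offset = u * len(unit.elements)
        coords = unit.positions + u * shift
        coords = coords + rng.normal(0.0, jitter, size=coords.shape)
        all_pos.append(coords)
        for j, e in enumerate(unit.elements):
            atoms.append(Atom(offset + j, e, tuple(coords[j]), molecule_id=0))
        bonds.update({(offset + i, offset + j) for i, j in unit.bonds})
        for cycle, aromatic in unit.rings:
            rings.append(Ring(tuple(offset + i for i in cycle), aromatic))
        if u > 0:
            prev_offset = (u - 1) * len(unit.elements)
            bonds.add(tuple(sorted((prev_offset + unit.tail, offset + unit.head))))

    pos = np.vstack(all_pos)
    extent = pos.max(axis=0) - pos.min(axis=0)
    L = box.as_array()
    if np.any(extent >= L):
        raise CapacityError(
            f"chain extent {np.round(extent, 2)} Å does not fit in box {box.lengths}"
        )
    # centre the chain in the box
    pos = pos - pos.min(axis=0) + (L - extent) / 2.0
    atoms = [Atom(a.id, a.element, tuple(p), molecule_id=0) for a, p in zip(atoms, pos)]
    return MolecularConfiguration(atoms, bonds, rings, box)


# ---------------------------------------------------------------------------
# Hydration
# ---------------------------------------------------------------------------

def water_count_for_target(dry_mass: float, mc_percent: float) -> int:
    """Number of waters approximating a dry-basis MC target:
    round(MC/100 x dry_mass / 18.015)."""
    if dry_mass <= 0:
        raise ValueError("dry mass must be positive")
    return int(round(mc_percent / 100.0 * dry_mass / WATER_MOLAR_MASS))


def moisture_content(config: MolecularConfiguration) -> float:
    """Dry-basis moisture content (%) of a configuration from atom roles."""
    roles = classify_atoms(config)
    masses = {a.id: ELEMENT_MASSES[a.element] for a in config.atoms}
    water_mass = sum(masses[i] for i in roles.water_atoms)
    dry_mass = sum(masses[i] for i in roles.polymer_atoms)
    if dry_mass == 0:
        raise ValueError("configuration has no polymer atoms")
    return 100.0 * water_mass / dry_mass


def hydrate(
    config: MolecularConfiguration,
    target: MoistureTarget | float,
    seed: int,
    min_dist: float = 2.0,
    expansion_volume: float | None = None,
) -> MolecularConfiguration:
    """Insert waters into a dry configuration to reach a moisture target.

    The number of waters is k = round(MC/100 x dry_mass / 18.015); each is
    placed at a random position/orientation at least ``min_dist`` (Å,
    minimum image) from every existing atom.  Pre-existing atoms keep their
    coordinates exactly.

    ``expansion_volume`` models a matrix that swells to make room: when
    set, the box volume grows by that many Å³ per inserted water (isotropic
    rescale of the box lengths; coordinates are not scaled, preserving the
    dry subsystem).  Left at None the box is fixed, so insertion fills
    pre-existing void space.  Bulk liquid water corresponds to ~30 Å³ per
    molecule.

    Deterministic under ``seed``.  Raises :class:`CapacityError`, reporting
    how many waters were placed, if void space runs out.
    """
    if isinstance(target, (int, float)):
        target = MoistureTarget(float(target))
    if config.box is None:
        raise ValueError("hydrate requires a periodic box")
    roles = classify_atoms(config)
    if not roles.polymer_atoms:
        raise ValueError("hydrate requires at least one polymer atom")
    dry_mass = sum(ELEMENT_MASSES[a.element] for a in config.atoms if a.id in roles.polymer_atoms)
    k = water_count_for_target(dry_mass, target.mc)
    if k == 0:
        return config

    box = config.box
    if expansion_volume is not None:
        factor = (box.volume + k * expansion_volume) / box.volume
        box = Box(tuple(np.asarray(box.lengths) * factor ** (1.0 / 3.0)))

    rng = np.random.default_rng(seed)
    L = box.as_array()
    occupied = config.positions
    next_id = int(config.ids.max()) + 1 if config.n_atoms else 0
    next_mol = max((a.molecule_id for a in config.atoms), default=-1) + 1
    atoms = list(config.atoms)
    bonds = set(config.bonds)
    for w in range(k):
        for _ in range(_MAX_TRIALS_PER_MOLECULE):
            origin = rng.uniform(0.0, L)
            rot = _random_rotation(rng)
            coords = WATER_GEOMETRY @ rot.T + origin
            d = minimum_image(coords[:, None, :] - occupied[None, :, :], L)
            if np.min(np.linalg.norm(d, axis=-1)) < min_dist:
                continue
            o_id = next_id
            for j, (e, p) in enumerate(zip(WATER_ELEMENTS, coords)):
                atoms.append(Atom(next_id, e, tuple(p), molecule_id=next_mol))
                next_id += 1
            bonds.update({(o_id, o_id + 1), (o_id, o_id + 2)})
            next_mol += 1
            occupied = np.vstack([occupied, coords])
            break
        else:
            raise CapacityError(
                f"placed {w} of {k} waters before running out of void space "
                f"(min_dist={min_dist} Å, box {box.lengths})"
            )
    return MolecularConfiguration(atoms, bonds, list(config.rings), box)


# ---------------------------------------------------------------------------
# Lattice fixture
# ---------------------------------------------------------------------------

def make_lattice(spacing: float, n_per_side: int, element: str = "C") -> MolecularConfiguration:
    """Simple-cubic single-element lattice in a periodic box.

    Every atom has exactly six nearest neighbours at ``spacing`` under the
    minimum-image convention, which makes the first RDF peak and its
    coordination number exactly solvable.
    """
    if n_per_side < 2:
        raise ValueError("n_per_side must be >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    side = spacing * n_per_side
    atoms = []
    k = 0
    for i in range(n_per_side):
        for j in range(n_per_side):
            for l in range(n_per_side):
                pos = (spacing * (i + 0.5), spacing * (j + 0.5), spacing * (l + 0.5))
                atoms.append(Atom(k, element, pos, molecule_id=k))
                k += 1
    return MolecularConfiguration(atoms, set(), [], Box((side, side, side)))
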