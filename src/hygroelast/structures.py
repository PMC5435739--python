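"""Molecular configurations for hydrated amorphous biopolymer analysis.

The analyses in this package (hydrogen-bond partitioning, radial
distribution functions, free-volume and elasticity estimates) all operate
on a single static snapshot of a C/H/O system in an orthorhombic periodic
box.  This module defines that container, reads and writes it (PDB with
CONECT/CRYST1 records, extended XYZ with a ``Lattice=`` comment line),
perceives covalent bonds from covalent radii when a file carries no
connectivity, and classifies atoms into the roles the downstream analyses
need: water versus polymer, hydroxyl oxygens, hydrogen-bond donors and
acceptors.

Only C, H and O are supported; the systems of interest (water, lignin-like
and xylan-like polymers) contain nothing else, and acceptors are simply
all oxygens.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Atom",
    "Box",
    "MolecularConfiguration",
    "AtomRoles",
    "StructureError",
    "ParseError",
    "ValidationError",
    "COVALENT_RADII",
    "read_structure",
    "write_structure",
    "perceive_bonds",
    "perceive_rings",
    "classify_atoms",
    "assign_molecule_ids",
    "minimum_image",
]

SUPPORTED_ELEMENTS = ("C", "H", "O")

#: Covalent radii (Å) used for distance-based bond perception.
COVALENT_RADII = {"C": 0.76, "H": 0.31, "O": 0.66}

#: Atomic masses (amu).
ELEMENT_MASSES = {"C": 12.011, "H": 1.008, "O": 15.999}


class StructureError(Exception):
    """Base class for structure-related failures."""


class ParseError(StructureError):
    """A file could not be parsed under the requested dialect."""


class ValidationError(StructureError):
    """A configuration violates a structural invariant."""


def minimum_image(delta: np.ndarray, lengths: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vector(s).

    ``delta`` has shape (..., 3).  With ``lengths`` None the displacement is
    returned unchanged (non-periodic system).
    """
    delta = np.asarray(delta, dtype=float)
    if lengths is None:
        return delta
    lengths = np.asarray(lengths, dtype=float)
    return delta - lengths * np.round(delta / lengths)


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic cell with edge lengths in Å."""

    lengths: tuple[float, float, float]

    def __post_init__(self):
        L = np.asarray(self.lengths, dtype=float)
        if L.shape != (3,) or not np.all(np.isfinite(L)) or not np.all(L > 0):
            raise ValidationError(f"box lengths must be three positive finite numbers, got {self.lengths}")
        object.__setattr__(self, "lengths", tuple(float(x) for x in L))

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    @property
    def min_length(self) -> float:
        return float(min(self.lengths))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)


@dataclass(frozen=True)
class Atom:
    """A single atom: identifier, element symbol, Cartesian position (Å)."""

    id: int
    element: str
    position: tuple[float, float, float]
    molecule_id: int = -1

    def __post_init__(self):
        if self.element not in SUPPORTED_ELEMENTS:
            raise ValidationError(f"unsupported element {self.element!r} (only C/H/O)")
        p = np.asarray(self.position, dtype=float)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise ValidationError(f"atom {self.id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", tuple(float(x) for x in p))


@dataclass(frozen=True)
class Ring:
    """A closed cycle of atom ids with an aromaticity flag."""

    atoms: tuple[int, ...]
    aromatic: bool


@dataclass
class MolecularConfiguration:
    """Atoms + bonds + ring annotations + periodic box.

    ``bonds`` is a set of unordered atom-id pairs stored as sorted tuples.
    ``box`` may be None for non-periodic inputs; the periodic analyses
    (hydrogen bonds, RDF, voxel volumes) require it.
    """

    atoms: list[Atom]
    bonds: set[tuple[int, int]] = field(default_factory=set)
    rings: list[Ring] = field(default_factory=list)
    box: Box | None = None

    def __post_init__(self):
        self.bonds = {tuple(sorted(map(int, b))) for b in self.bonds}
        ids = [a.id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate atom ids")
        self._index = {a.id: i for i, a in enumerate(self.atoms)}
        for i, j in self.bonds:
            if i == j:
                raise ValidationError(f"self-bond on atom {i}")
            if i not in self._index or j not in self._index:
                raise ValidationError(f"bond ({i},{j}) references unknown atom id")
        for ring in self.rings:
            cyc = list(ring.atoms)
            for a, b in zip(cyc, cyc[1:] + cyc[:1]):
                if tuple(sorted((a, b))) not in self.bonds:
                    raise ValidationError(f"ring {ring.atoms} is not a closed path in the bond graph")

    # -- basic accessors -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index_of(self, atom_id: int) -> int:
        return self._index[atom_id]

    @property
    def ids(self) -> np.ndarray:
        return np.array([a.id for a in self.atoms], dtype=int)

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ELEMENT_MASSES[a.element] for a in self.atoms], dtype=float)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    def neighbors(self, atom_id: int) -> set[int]:
        out = set()
        for i, j in self.bonds:
            if i == atom_id:
                out.add(j)
            elif j == atom_id:
                out.add(i)
        return out

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {a.id: set() for a in self.atoms}
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def with_positions(self, positions: np.ndarray, box: Box | None = None) -> "MolecularConfiguration":
        """Copy with replaced coordinates (and optionally box)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (self.n_atoms, 3):
            raise ValidationError("position array shape mismatch")
        atoms = [replace(a, position=tuple(p)) for a, p in zip(self.atoms, positions)]
        return MolecularConfiguration(atoms, set(self.bonds), list(self.rings), box or self.box)

    def pairwise_distance(self, id_a: int, id_b: int) -> float:
        pa = np.asarray(self.atoms[self.index_of(id_a)].position)
        pb = np.asarray(self.atoms[self.index_of(id_b)].position)
        L = self.box.as_array() if self.box else None
        return float(np.linalg.norm(minimum_image(pb - pa, L)))


@dataclass(frozen=True)
class AtomRoles:
    """Role partition used by the hydrogen-bond and RDF analyses.

    Water and polymer sets are disjoint and jointly cover all atoms.
    Donors are oxygens carrying at least one hydrogen; acceptors are all
    oxygens (the systems contain no nitrogen).
    """

    water_oxygens: frozenset[int]
    water_hydrogens: frozenset[int]
    polymer_atoms: frozenset[int]
    hydroxyl_oxygens: frozenset[int]
    donor_oxygens: frozenset[int]
    acceptor_oxygens: frozenset[int]

    @property
    def water_atoms(self) -> frozenset[int]:
        return self.water_oxygens | self.water_hydrogens

    def is_water(self, atom_id: int) -> bool:
        return atom_id in self.water_oxygens or atom_id in self.water_hydrogens

    def to_dict(self) -> dict[str, list[int]]:
        return {
            "water_oxygens": sorted(self.water_oxygens),
            "water_hydrogens": sorted(self.water_hydrogens),
            "polymer_atoms": sorted(self.polymer_atoms),
            "hydroxyl_oxygens": sorted(self.hydroxyl_oxygens),
            "donor_oxygens": sorted(self.donor_oxygens),
            "acceptor_oxygens": sorted(self.acceptor_oxygens),
        }


# ---------------------------------------------------------------------------
# Molecule labelling
# ---------------------------------------------------------------------------

def assign_molecule_ids(config: MolecularConfiguration) -> MolecularConfiguration:
    """Relabel ``molecule_id`` from connected components of the bond graph.

    Component labels are assigned in order of each component's smallest
    atom index, so the labelling is invariant to bond-set iteration order.
    """
    n = config.n_atoms
    if n == 0:
        return config
    idx = config._index
    if config.bonds:
        rows, cols = zip(*[(idx[i], idx[j]) for i, j in config.bonds])
        mat = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        _, labels = connected_components(mat, directed=False)
    else:
        labels = np.arange(n)
    # canonicalize label order by first occurrence
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
    atoms = [replace(a, molecule_id=remap[int(l)]) for a, l in zip(config.atoms, labels)]
    return MolecularConfiguration(atoms, set(config.bonds), list(config.rings), config.box)


# ---------------------------------------------------------------------------
# Bond and ring perception
# ---------------------------------------------------------------------------

def perceive_bonds(config: MolecularConfiguration, scale: float = 1.2) -> MolecularConfiguration:
    """Infer covalent bonds from interatomic distances.

    A bond is added between atoms *i*, *j* whenever their minimum-image
    distance is at most ``scale`` times the sum of their covalent radii
    (C 0.76, H 0.31, O 0.66 Å).  Molecule ids are recomputed afterwards.

    Raises a :class:`StructureError` if the configuration already carries
    bonds: perception is meant for inputs without connectivity records, and
    silently merging the two sources would hide file errors.
    """
    if config.bonds:
        raise StructureError("configuration already has bonds; bond perception refused")
    if scale <= 0:
        raise ValueError("scale must be positive")
    pos = config.positions
    n = config.n_atoms
    radii = np.array([COVALENT_RADII[e] for e in config.elements])
    L = config.box.as_array() if config.box else None
    bonds: set[tuple[int, int]] = set()
    ids = config.ids
    for i in range(n - 1):
        d = minimum_image(pos[i + 1:] - pos[i], L)
        dist = np.linalg.norm(d, axis=1)
        cut = scale * (radii[i] + radii[i + 1:])
        for j in np.nonzero(dist <= cut)[0]:
            bonds.add(tuple(sorted((int(ids[i]), int(ids[i + 1 + j])))))
    out = MolecularConfiguration(list(config.atoms), bonds, [], config.box)
    return assign_molecule_ids(out)


def perceive_rings(config: MolecularConfiguration) -> list[Ring]:
    """Derive ring annotations from the bond graph (minimum cycle basis).

    Aromaticity heuristic: a ring is flagged aromatic iff every member is a
    carbon with exactly three bonded neighbours.  Generator output carries
    explicit annotations; this fallback serves files without them.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(a.id for a in config.atoms)
    g.add_edges_from(config.bonds)
    adj = config.adjacency()
    elem = {a.id: a.element for a in config.atoms}
    rings = []
    for cycle in nx.minimum_cycle_basis(g):
        ordered = _order_cycle(cycle, adj)
        aromatic = all(elem[a] == "C" and len(adj[a]) == 3 for a in ordered)
        rings.append(Ring(tuple(ordered), aromatic))
    return rings


def _order_cycle(nodes: list[int], adj: dict[int, set[int]]) -> list[int]:
    """Order a cycle's node set into a closed bond path."""
    nodes_set = set(nodes)
    start = min(nodes)
    path = [start]
    prev = None
    while len(path) < len(nodes):
        nxt = [v for v in adj[path[-1]] if v in nodes_set and v != prev]
        if not nxt:
            raise ValidationError(f"cannot order ring cycle {sorted(nodes)}")
        prev = path[-1]
        path.append(min(nxt))
    return path


# ---------------------------------------------------------------------------
# Atom role classification
# ---------------------------------------------------------------------------

def classify_atoms(config: MolecularConfiguration) -> AtomRoles:
    """Partition atoms into water/polymer and locate hydroxyls and donors.

    A water molecule is an oxygen bonded to exactly two hydrogens and
    nothing else (each of those hydrogens bonded only to that oxygen).
    Everything else is polymer.  A polymer oxygen bonded to exactly one
    hydrogen and one carbon is a hydroxyl oxygen.  Donors are all oxygens
    with at least one bonded hydrogen; acceptors are all oxygens.

    Raises :class:`ValidationError` on valence-impossible connectivity
    (hydrogen with more than one bond, oxygen with more than two, carbon
    with more than four), listing the offending atom ids.
    """
    adj = config.adjacency()
    elem = {a.id: a.element for a in config.atoms}
    max_valence = {"H": 1, "O": 2, "C": 4}
    bad = [i for i, nb in adj.items() if len(nb) > max_valence[elem[i]]]
    if bad:
        raise ValidationError(f"valence-impossible connectivity for atoms {sorted(bad)}")

    water_o, water_h = set(), set()
    for a in config.atoms:
        if a.element != "O":
            continue
        nb = adj[a.id]
        if len(nb) == 2 and all(elem[h] == "H" and adj[h] == {a.id} for h in nb):
            water_o.add(a.id)
            water_h.update(nb)
    all_ids = {a.id for a in config.atoms}
    polymer = all_ids - water_o - water_h

    hydroxyl_o = set()
    donors = set(water_o)
    acceptors = {a.id for a in config.atoms if a.element == "O"}
    for i in polymer:
        if elem[i] != "O":
            continue
        nb_elems = sorted(elem[j] for j in adj[i])
        if nb_elems == ["C", "H"]:
            hydroxyl_o.add(i)
        if any(elem[j] == "H" for j in adj[i]):
            donors.add(i)

    return AtomRoles(
        water_oxygens=frozenset(water_o),
        water_hydrogens=frozenset(water_h),
        polymer_atoms=frozenset(polymer),
        hydroxyl_oxygens=frozenset(hydroxyl_o),
        donor_oxygens=frozenset(donors),
        acceptor_oxygens=frozenset(acceptors),
    )


# ---------------------------------------------------------------------------
# File input / output
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
    else:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("pdb", "xyz"):
        raise ParseError(f"unknown structure format {fmt!r} (expected pdb or xyz)")
    return fmt


def read_structure(path: str | Path, format: str | None = None) -> MolecularConfiguration:
    """Read a configuration from PDB (CONECT/CRYST1) or extended XYZ.

    Coordinates are taken as Å.  Bonds come from CONECT records when
    present (extended XYZ carries none); the box comes from CRYST1 or the
    ``Lattice=`` comment.  Triclinic cells are rejected.  Atom ids are
    assigned 0..n-1 in file order and molecule ids recomputed from bonds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        config = _read_pdb(path)
    else:
        config = _read_extxyz(path)
    if config.n_atoms == 0:
        raise ParseError(f"{path}: no atom records found")
    return assign_molecule_ids(config)


def _read_pdb(path: Path) -> MolecularConfiguration:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # MDAnalysis raises a zoo of types
            raise ParseError(f"{path}: {exc}") from exc
        try:
            elements = [str(e).capitalize() for e in u.atoms.elements]
        except AttributeError:
            from MDAnalysis.topology.guessers import guess_types

            elements = [str(e).capitalize() for e in guess_types(u.atoms.names)]
    for e in elements:
        if e not in SUPPORTED_ELEMENTS:
            raise ParseError(f"{path}: unsupported element symbol {e!r}")
    box = None
    dims = u.dimensions
    if dims is not None and np.all(dims[:3] > 0):
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise ParseError(f"{path}: triclinic cells are not supported")
        box = Box(tuple(float(x) for x in dims[:3]))
    atoms = [
        Atom(i, elements[i], tuple(float(x) for x in u.atoms.positions[i]))
        for i in range(len(u.atoms))
    ]
    bonds = set()
    if hasattr(u, "bonds"):
        for i, j in u.bonds.indices:
            bonds.add(tuple(sorted((int(i), int(j)))))
    return MolecularConfiguration(atoms, bonds, [], box)


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def _read_extxyz(path: Path) -> MolecularConfiguration:
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}:1: expected atom count") from exc
    if len(lines) < n + 2:
        raise ParseError(f"{path}: truncated file ({len(lines)} lines for {n} atoms)")
    box = None
    m = _LATTICE_RE.search(lines[1])
    if m:
        vals = [float(x) for x in m.group(1).split()]
        if len(vals) != 9:
            raise ParseError(f"{path}:2: Lattice must have 9 components")
        cell = np.array(vals).reshape(3, 3)
        if not np.allclose(cell, np.diag(np.diag(cell)), atol=1e-8):
            raise ParseError(f"{path}: triclinic cells are not supported")
        box = Box(tuple(np.diag(cell)))
    atoms = []
    for k in range(n):
        lineno = k + 3
        parts = lines[k + 2].split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{lineno}: expected 'element x y z'")
        e = parts[0].capitalize()
        if e not in SUPPORTED_ELEMENTS:
            raise ParseError(f"{path}:{lineno}: unsupported element symbol {e!r}")
        try:
            xyz = tuple(float(v) for v in parts[1:4])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed coordinates") from exc
        atoms.append(Atom(k, e, xyz))
    return MolecularConfiguration(atoms, set(), [], box)


def write_structure(config: MolecularConfiguration, path: str | Path, format: str | None = None) -> Path:
    """Write a configuration to PDB or extended XYZ.

    PDB keeps bonds as CONECT and the box as CRYST1 (coordinates at the
    format's 3-decimal precision); extended XYZ stores the box on the
    comment line at full double precision but no connectivity.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        _write_pdb(config, path)
    else:
        _write_extxyz(config, path)
    return path


def _write_pdb(config: MolecularConfiguration, path: Path) -> None:
    import MDAnalysis as mda

    n = config.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=1, atom_resindex=np.zeros(n, dtype=int), trajectory=True)
        elements = list(config.elements)
        u.add_TopologyAttr("names", elements)
        u.add_TopologyAttr("elements", elements)
        u.add_TopologyAttr("resids", [1])
        u.add_TopologyAttr("resnames", ["SYS"])
        u.atoms.positions = config.positions.astype(np.float32)
        if config.bonds:
            idx = config._index
            u.add_bonds([(idx[i], idx[j]) for i, j in sorted(config.bonds)])
        if config.box is not None:
            u.dimensions = [*config.box.lengths, 90.0, 90.0, 90.0]
        u.atoms.write(str(path), bonds="all")


def _write_extxyz(config: MolecularConfiguration, path: Path) -> None:
    lines = [str(config.n_atoms)]
    comment = 'Properties=species:S:1:pos:R:3'
    if config.box is not None:
        lx, ly, lz = config.box.lengths
        comment = f'Lattice="{lx:.10g} 0 0 0 {ly:.10g} 0 0 0 {lz:.10g}" ' + comment
    lines.append(comment)
    for a in config.atoms:
        x, y, z = a.position
        lines.append(f"{a.element} {x:.10f} {y:.10f} {z:.10f}")
    path.write_text("\n".join(lines) + "\n")
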