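"""Internal-coordinate geometry: distances, angles, dihedrals, atom placement.

All public functions accept and return angles in **degrees**; torsions live in
(-180, 180] under the IUPAC sign convention.  Coordinates are in angstroms.
These primitives are shared by every other module: polymer chains are realized
by sequential NeRF-style placement (:func:`place_atom`) from internal
coordinate records, and conformer extraction is the inverse
(:func:`measure_internals`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Topology",
    "Conformation",
    "InternalCoordinateRecord",
    "distance",
    "bond_angle",
    "dihedral",
    "place_atom",
    "measure_internals",
    "rebuild_from_internals",
    "superpose_three_points",
    "wrap_angle",
]


def wrap_angle(a):
    """Wrap an angle (degrees) into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = 180.0 - ((180.0 - a) % 360.0)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Molecular model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_index: int
    residue_type: str


@dataclass
class LinkageSite:
    """Atom indices playing the glycosidic-junction roles for one junction.

    phi = O5-C1-O-Cn, psi = C1-O-Cn-C(n-1); ``cn_prev2`` is C(n-2), the extra
    frame atom used to place the glycosidic O off the acceptor ring.
    """

    linkage_type: str
    o5: int
    c1: int
    o: int
    cn: int
    cn_prev: int
    cn_prev2: int
    donor_residue: int
    acceptor_residue: int


@dataclass
class Topology:
    """Atoms, bonds and junction bookkeeping for one polymer specification.

    Atom order is a function of the polymer spec alone, so every conformation
    of the same spec shares one topology object.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    residue_ranges: list[tuple[int, int]]  # half-open [start, stop) per residue
    linkages: list[LinkageSite]
    placement_plan: "InternalCoordinateRecord | None" = None
    residue_meta: list | None = None  # (sugar, anomer, acceptor_pos) per residue

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ranges)

    def residue_atoms(self, i: int) -> range:
        start, stop = self.residue_ranges[i]
        return range(start, stop)

    def atom_index(self, residue: int, name: str) -> int:
        for i in self.residue_atoms(residue):
            if self.atoms[i].name == name:
                return i
        raise KeyError(f"atom {name!r} not found in residue {residue}")

    def ring_indices(self, residue: int) -> list[int]:
        """Indices of the six ring atoms in C-P order O5,C1,C2,C3,C4,C5."""
        return [self.atom_index(residue, n)
                for n in ("O5", "C1", "C2", "C3", "C4", "C5")]

    def validate(self) -> None:
        n = self.n_atoms
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
        for r in range(self.n_residues):
            self.ring_indices(r)  # raises if a ring atom is missing
        bondset = {frozenset(b) for b in self.bonds}
        for lk in self.linkages:
            if frozenset((lk.c1, lk.o)) not in bondset or \
               frozenset((lk.o, lk.cn)) not in bondset:
                raise ValueError(
                    f"linkage map for {lk.linkage_type} inconsistent with bonds")


@dataclass
class Conformation:
    """Cartesian coordinates for one polymer conformation."""

    topology: Topology
    coords: np.ndarray  # (n_atoms, 3)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{self.topology.n_atoms} atoms")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    def copy(self) -> "Conformation":
        return Conformation(self.topology, self.coords.copy(),
                            dict(self.provenance))


@dataclass
class InternalCoordinateRecord:
    """Spanning-tree internal coordinates sufficient to rebuild a structure.

    The first three atoms are seeded by (bond01,) and (bond12, angle012); every
    later atom ``entries[k] = (i, a, b, c, bond, angle, torsion)`` is placed
    from three previously-placed frame atoms a,b,c.  Angles in degrees.
    """

    seed_atoms: tuple[int, int, int]
    seed_bond01: float
    seed_bond12: float
    seed_angle012: float
    entries: list[tuple[int, int, int, int, float, float, float]]

    def n_atoms(self) -> int:
        return 3 + len(self.entries)

    def validate(self) -> None:
        if self.seed_bond01 <= 0 or self.seed_bond12 <= 0:
            raise ValueError("seed bond lengths must be positive")
        if not 0.0 < self.seed_angle012 < 180.0:
            raise ValueError("seed angle out of (0, 180)")
        for (i, a, b, c, bond, angle, torsion) in self.entries:
            if bond <= 0:
                raise ValueError(f"bond length {bond} for atom {i} must be > 0")
            if not 0.0 < angle < 180.0:
                raise ValueError(f"angle {angle} for atom {i} out of (0, 180)")
            if not -180.0 < torsion <= 180.0:
                raise ValueError(f"torsion {torsion} for atom {i} out of range")


# ---------------------------------------------------------------------------
# Scalar geometry
# ---------------------------------------------------------------------------

def distance(p, q) -> float:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.linalg.norm(p - q))


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in [0, 180] degrees; p2 is the vertex."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u = p1 - p2
    v = p3 - p2
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("coincident vertex atoms in bond_angle")
    c = np.dot(u, v) / (nu * nv)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion p1-p2-p3-p4 in (-180, 180], IUPAC sign convention."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("collinear reference triple in dihedral")
    x = np.dot(n1, n2)
    y = np.linalg.norm(b2) * np.dot(b1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return wrap_angle(ang)


def dihedral_many(p1, p2, p3, p4) -> np.ndarray:
    """Vectorized torsions for stacked point arrays of shape (n, 3)."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.linalg.norm(b2, axis=1) * np.einsum("ij,ij->i", b1, n2)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a new atom d bonded to c with the given internal coordinates.

    distance(d, c) = bond, bond_angle(b, c, d) = angle and
    dihedral(a, b, c, d) = torsion.  a, b, c must be non-collinear.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    if bond <= 0:
        raise ValueError("bond length must be positive")
    if not 0.0 < angle < 180.0:
        raise ValueError("bond angle must be in (0, 180)")
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc == 0.0:
        raise ValueError("coincident frame atoms b, c")
    bc = bc / nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear frame atoms a, b, c")
    n = n / nn
    m = np.cross(n, bc)
    th = np.radians(angle)
    ph = np.radians(torsion)
    d_local = bond * np.array([
        -np.cos(th),
        np.sin(th) * np.cos(ph),
        np.sin(th) * np.sin(ph),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ---------------------------------------------------------------------------
# Measure / rebuild (inverse pair)
# ---------------------------------------------------------------------------

def measure_internals(coords: np.ndarray,
                      plan: InternalCoordinateRecord) -> InternalCoordinateRecord:
    """Measure the internal coordinates of ``coords`` along ``plan``.

    Returns a new record with the same tree but values read off the
    coordinates.  Rebuilding from the result reproduces the structure up to a
    rigid transform.
    """
    coords = np.asarray(coords, dtype=float)
    i0, i1, i2 = plan.seed_atoms
    n = coords.shape[0]
    for idx in (i0, i1, i2):
        if not 0 <= idx < n:
            raise IndexError(f"plan seed index {idx} out of range")
    entries = []
    for (i, a, b, c, _bond, _angle, _torsion) in plan.entries:
        for idx in (i, a, b, c):
            if not 0 <= idx < n:
                raise IndexError(f"plan index {idx} out of range")
        entries.append((
            i, a, b, c,
            distance(coords[i], coords[c]),
            bond_angle(coords[b], coords[c], coords[i]),
            dihedral(coords[a], coords[b], coords[c], coords[i]),
        ))
    return InternalCoordinateRecord(
        seed_atoms=plan.seed_atoms,
        seed_bond01=distance(coords[i0], coords[i1]),
        seed_bond12=distance(coords[i1], coords[i2]),
        seed_angle012=bond_angle(coords[i0], coords[i1], coords[i2]),
        entries=entries,
    )


try:
    import numba as _numba

    @_numba.njit(cache=True)
    def _nerf_chain(coords, entries):
        for m in range(entries.shape[0]):
            i = int(entries[m, 0])
            a = int(entries[m, 1])
            b = int(entries[m, 2])
            c = int(entries[m, 3])
            bond = entries[m, 4]
            th = entries[m, 5]
            ph = entries[m, 6]
            bcx = coords[c, 0] - coords[b, 0]
            bcy = coords[c, 1] - coords[b, 1]
            bcz = coords[c, 2] - coords[b, 2]
            nbc = (bcx * bcx + bcy * bcy + bcz * bcz) ** 0.5
            bcx /= nbc; bcy /= nbc; bcz /= nbc
            abx = coords[b, 0] - coords[a, 0]
            aby = coords[b, 1] - coords[a, 1]
            abz = coords[b, 2] - coords[a, 2]
            nx = aby * bcz - abz * bcy
            ny = abz * bcx - abx * bcz
            nz = abx * bcy - aby * bcx
            nn = (nx * nx + ny * ny + nz * nz) ** 0.5
            if nn < 1e-10:
                return m  # collinear frame: report the failing entry
            nx /= nn; ny /= nn; nz /= nn
            mx = ny * bcz - nz * bcy
            my = nz * bcx - nx * bcz
            mz = nx * bcy - ny * bcx
            d0 = -bond * np.cos(th)
            d1 = bond * np.sin(th) * np.cos(ph)
            d2 = bond * np.sin(th) * np.sin(ph)
            coords[i, 0] = coords[c, 0] + d0 * bcx + d1 * mx + d2 * nx
            coords[i, 1] = coords[c, 1] + d0 * bcy + d1 * my + d2 * ny
            coords[i, 2] = coords[c, 2] + d0 * bcz + d1 * mz + d2 * nz
        return -1

    _HAVE_NUMBA_NERF = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA_NERF = False


def _entries_array(record: "InternalCoordinateRecord") -> np.ndarray:
    arr = np.empty((len(record.entries), 7))
    for k, (i, a, b, c, bond, angle, torsion) in enumerate(record.entries):
        arr[k] = (i, a, b, c, bond, np.radians(angle), np.radians(torsion))
    return arr


def rebuild_from_internals(record: InternalCoordinateRecord,
                           n_atoms: int | None = None) -> np.ndarray:
    """Realize a structure in a canonical local frame from internals.

    Seed atom 0 sits at the origin, atom 1 on +x, atom 2 in the xy plane with
    positive y.  Returns an (n, 3) array indexed by the record's atom indices.
    """
    if n_atoms is None:
        idxs = list(record.seed_atoms) + [e[0] for e in record.entries]
        n_atoms = max(idxs) + 1
    coords = np.full((n_atoms, 3), np.nan)
    i0, i1, i2 = record.seed_atoms
    coords[i0] = (0.0, 0.0, 0.0)
    coords[i1] = (record.seed_bond01, 0.0, 0.0)
    th = np.radians(record.seed_angle012)
    coords[i2] = coords[i1] + record.seed_bond12 * np.array(
        [-np.cos(th), np.sin(th), 0.0])
    if _HAVE_NUMBA_NERF:
        cached = getattr(record, "_entries_cache", None)
        if cached is None:
            cached = _entries_array(record)
            object.__setattr__(record, "_entries_cache", cached)
        fail = _nerf_chain(coords, cached)
        if fail >= 0:
            e = record.entries[fail]
            raise ValueError(
                f"collinear frame atoms {e[1:4]} placing atom {e[0]}")
        return coords
    for (i, a, b, c, bond, angle, torsion) in record.entries:
        coords[i] = place_atom(coords[a], coords[b], coords[c],
                               bond, angle, torsion)
    return coords


def superpose_three_points(local: np.ndarray, target: np.ndarray,
                           coords: np.ndarray) -> np.ndarray:
    """Rigidly map ``coords`` so three local anchor points land on targets.

    ``local`` and ``target`` are (3, 3) arrays of matching anchor triples with
    identical internal geometry (same pairwise distances); the transform is the
    unique proper rigid motion aligning their frames.
    """
    local = np.asarray(local, dtype=float)
    target = np.asarray(target, dtype=float)

    def frame(p):
        e1 = p[1] - p[0]
        e1 = e1 / np.linalg.norm(e1)
        v = p[2] - p[0]
        e2 = v - np.dot(v, e1) * e1
        e2 = e2 / np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        return np.column_stack([e1, e2, e3])

    R = frame(target) @ frame(local).T
    return (coords - local[0]) @ R.T + target[0]
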