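"""Idealized heavy-atom residue templates for GAG monosaccharides.

Templates are constructed programmatically, not read from a library file: the
six-membered ring is solved by least squares against ideal bond lengths
(C-C 1.52 A, C-O 1.43 A), near-tetrahedral ring angles and a target
Cremer-Pople pucker (4C1 for all sugars except IdoA, which is built in its
force-field-preferred 1C4 chair); exocyclic heavy atoms are then attached with
a tetrahedral construction whose handedness at each stereocenter is taken from
the D-pyranose equatorial/axial table in the 4C1 reference frame.  The
handedness sign is a rigid invariant, so the same construction places
substituents correctly on boats and skew-boats when synthetic ring conformers
are generated at arbitrary puckers.

Only heavy atoms are modelled.  The hydroxyl oxygen at the acceptor carbon
(O3 or O4) is *not* part of the template core: in a polymer it is the
glycosidic bridge oxygen and belongs to the junction, whose placement
geometry (bond, angle and placement torsion at the acceptor, plus the
anomeric torsion at the donor) is measured off the template and stored in
:class:`LinkageTemplate`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .geometry import (InternalCoordinateRecord, bond_angle, dihedral,
                       distance, place_atom)
from .pucker import PuckerCoords, cremer_pople, ring_from_pucker

__all__ = [
    "ResidueTemplate",
    "LinkageTemplate",
    "get_template",
    "get_linkage_template",
    "GAG_REPEATS",
    "residue_sequence",
    "linkage_sequence",
]

RING_NAMES = ("O5", "C1", "C2", "C3", "C4", "C5")

# ideal heavy-atom bond lengths (angstrom)
BL = {
    "ring_CC": 1.52, "ring_CO": 1.43,
    "C-OH": 1.42, "C1-O1": 1.41,
    "C-C": 1.52, "C-N": 1.45, "N-C(=O)": 1.33,
    "C=O": 1.23, "C-CH3": 1.50, "C-Ocarb": 1.25,
    "O-Cn": 1.43,
}
GLYCOSIDIC_C1_O = 1.41
GLYCOSIDIC_ANGLE_C1_O_CN = 116.5  # ether C-O-C angle at the bridge oxygen
TETRAHEDRAL = 109.47

# substituent patterns: name -> (parent, bond-length key, element)
_URONIC_SUBS = {
    "O2": ("C2", "C-OH", "O"), "O3": ("C3", "C-OH", "O"),
    "O4": ("C4", "C-OH", "O"),
    "C6": ("C5", "C-C", "C"),
}
_HEXNAC_SUBS = {
    "N2": ("C2", "C-N", "N"), "O3": ("C3", "C-OH", "O"),
    "O4": ("C4", "C-OH", "O"), "C6": ("C5", "C-C", "C"),
}
_GAL_SUBS = {
    "O2": ("C2", "C-OH", "O"), "O3": ("C3", "C-OH", "O"),
    "O4": ("C4", "C-OH", "O"), "C6": ("C5", "C-C", "C"),
}

#: equatorial(True)/axial(False) of each ring substituent in the 4C1
#: reference frame of the D-pyranose drawing; IdoA is the C5 epimer of GlcA
#: (C6 axial in the 4C1 frame), GalNAc/Gal are C4 epimers (O4 axial).
_SUGARS = {
    "GlcA":   dict(subs=_URONIC_SUBS, eq={"O1": True, "O2": True, "O3": True,
                                          "O4": True, "C6": True},
                   uronic=True, ring="4C1"),
    "IdoA":   dict(subs=_URONIC_SUBS, eq={"O1": True, "O2": True, "O3": True,
                                          "O4": True, "C6": False},
                   uronic=True, ring="1C4", L=True),
    "GlcNAc": dict(subs=_HEXNAC_SUBS, eq={"O1": True, "N2": True, "O3": True,
                                          "O4": True, "C6": True},
                   uronic=False, ring="4C1"),
    "GalNAc": dict(subs=_HEXNAC_SUBS, eq={"O1": True, "N2": True, "O3": True,
                                          "O4": False, "C6": True},
                   uronic=False, ring="4C1"),
    "Gal":    dict(subs=_GAL_SUBS, eq={"O1": True, "O2": True, "O3": True,
                                       "O4": False, "C6": True},
                   uronic=False, ring="4C1"),
}

#: repeat units from the reducing end: (sugar, anomer, acceptor position).
#: hyaluronan [-4GlcAb1-3GlcNAcb1-], dermatan [-4IdoAa1-3GalNAcb1-],
#: keratan [-3Galb1-4GlcNAcb1-], heparan [-4IdoAa1-4GlcNAca1-].
GAG_REPEATS = {
    "hyaluronan": [("GlcNAc", "b", 3), ("GlcA", "b", 4)],
    "dermatan": [("GalNAc", "b", 3), ("IdoA", "a", 4)],
    "keratan": [("GlcNAc", "b", 4), ("Gal", "b", 3)],
    "heparan": [("GlcNAc", "a", 4), ("IdoA", "a", 4)],
}


def residue_sequence(gag_type: str, n_residues: int,
                     repeat=None) -> list[tuple[str, str, int]]:
    """(sugar, anomer, acceptor_pos) per residue, reducing end first."""
    if repeat is None:
        if gag_type not in GAG_REPEATS:
            raise KeyError(f"unknown GAG type {gag_type!r}; "
                           f"supported: {sorted(GAG_REPEATS)}")
        repeat = GAG_REPEATS[gag_type]
    if n_residues < 2:
        raise ValueError("polymers need at least 2 residues")
    return [repeat[i % len(repeat)] for i in range(n_residues)]


def linkage_name(donor: tuple[str, str, int], acceptor: tuple[str, str, int]) -> str:
    sugar_d, anomer_d, _ = donor
    sugar_a, _, pos_a = acceptor
    return f"{sugar_d}{anomer_d}1-{pos_a}{sugar_a}"


def linkage_sequence(gag_type: str, n_residues: int, repeat=None) -> list[str]:
    seq = residue_sequence(gag_type, n_residues, repeat)
    return [linkage_name(seq[i + 1], seq[i]) for i in range(n_residues - 1)]


# ---------------------------------------------------------------------------
# Ring construction
# ---------------------------------------------------------------------------

_RING_BONDS = [("O5", "C1"), ("C1", "C2"), ("C2", "C3"),
               ("C3", "C4"), ("C4", "C5"), ("C5", "O5")]


def _ring_bond_targets() -> np.ndarray:
    return np.array([BL["ring_CO"] if "O5" in b else BL["ring_CC"]
                     for b in _RING_BONDS])


def _ideal_ring(theta: float, Q: float = 0.55) -> np.ndarray:
    """Closed six-ring with ideal bonds/angles at the target C-P pucker."""
    x0 = ring_from_pucker(PuckerCoords(Q, theta, 30.0), mean_bond=1.49).ravel()
    targets = _ring_bond_targets()

    def resid(x):
        p = x.reshape(6, 3)
        bonds = np.linalg.norm(p - np.roll(p, -1, axis=0), axis=1)
        angs = np.array([bond_angle(p[(j - 1) % 6], p[j], p[(j + 1) % 6])
                         for j in range(6)])
        ang_t = np.where(np.arange(6) == 0, 112.0, 111.0)
        cp = cremer_pople(p)
        dtheta = np.radians(cp.theta - theta)
        return np.concatenate([
            50.0 * (bonds - targets),
            5.0 * np.radians(angs - ang_t),
            [10.0 * dtheta, 10.0 * (cp.Q - Q)],
        ])

    sol = least_squares(resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    return sol.x.reshape(6, 3)


def _ring_neighbors(j: int) -> tuple[int, int]:
    return (j - 1) % 6, (j + 1) % 6


def substituent_direction(ring: np.ndarray, j: int, sign: float,
                          angle_target: float | None = None) -> np.ndarray:
    """Unit vector for an exocyclic substituent at ring atom j.

    ``sign`` selects the side of the local ring plane (the rigid-invariant
    handedness of the stereocenter); the in/out-of-plane split is chosen so
    the angles to both ring neighbors are ~``angle_target``.
    """
    if angle_target is None:
        angle_target = TETRAHEDRAL
    jp, jn = _ring_neighbors(j)
    a = ring[jp] - ring[j]
    b = ring[jn] - ring[j]
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    v = v / np.linalg.norm(v)
    u = -(a + b)
    u = u / np.linalg.norm(u)
    gamma = 0.5 * np.radians(bond_angle(ring[jp], ring[j], ring[jn]))
    cmu = np.clip(-np.cos(np.radians(angle_target)) / np.cos(gamma), -1.0, 1.0)
    mu = np.arccos(cmu)
    return np.cos(mu) * u + sign * np.sin(mu) * v


def _ring_plane_normal(ring: np.ndarray) -> np.ndarray:
    r = ring - ring.mean(axis=0)
    jj = np.arange(6)
    R1 = (r * np.sin(2 * np.pi * jj / 6)[:, None]).sum(axis=0)
    R2 = (r * np.cos(2 * np.pi * jj / 6)[:, None]).sum(axis=0)
    n = np.cross(R1, R2)
    return n / np.linalg.norm(n)


@lru_cache(maxsize=None)
def _stereo_signs(sugar: str, anomer: str) -> dict:
    """Handedness sign per substituent site, calibrated on the 4C1 frame."""
    info = _SUGARS[sugar]
    ring = _ideal_ring(theta=0.0)  # 4C1 reference, whatever the native pucker
    normal = _ring_plane_normal(ring)
    site_of = {"O1": 1, "O2": 2, "N2": 2, "O3": 3, "O4": 4, "C6": 5}
    eq_table = dict(info["eq"])
    # The table records the beta-D anomeric orientation (equatorial in 4C1).
    # Alpha-D flips it to axial.  For L-sugars (IdoA) the anomeric reference
    # inverts: alpha-L at C1 is the spatial configuration of beta-D (the C5
    # epimerase that makes IdoA from GlcA never touches C1), so the flip
    # applies to beta-L instead.
    is_L = info.get("L", False)
    if (anomer == "a") != is_L:
        eq_table["O1"] = not eq_table["O1"]
    signs = {}
    for name, want_eq in eq_table.items():
        j = site_of[name]
        d_plus = substituent_direction(ring, j, +1.0)
        d_minus = substituent_direction(ring, j, -1.0)
        # axial direction is the one more parallel to the ring normal
        plus_is_axial = abs(d_plus @ normal) > abs(d_minus @ normal)
        if want_eq:
            signs[name] = -1.0 if plus_is_axial else +1.0
        else:
            signs[name] = +1.0 if plus_is_axial else -1.0
    return signs


# ---------------------------------------------------------------------------
# Full residue templates
# ---------------------------------------------------------------------------

def core_atom_names(sugar: str, acceptor_pos: int) -> list[str]:
    info = _SUGARS[sugar]
    names = list(RING_NAMES)
    sub_order = ["O2", "N2", "O3", "O4", "C6"]
    for s in sub_order:
        if s in info["subs"] and s != f"O{acceptor_pos}":
            names.append(s)
    if info["uronic"]:
        names += ["O6A", "O6B"]
    else:
        names.append("O6")
        if "N2" in info["subs"]:
            names += ["C7", "O7", "C8"]
    return names


def _element(name: str) -> str:
    return name[0]


@dataclass
class ResidueTemplate:
    """Reference geometry and placement plan for one residue-type instance."""

    sugar: str
    anomer: str
    acceptor_pos: int
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray                     # (n_core, 3), local frame
    plan: InternalCoordinateRecord         # local indices, core atoms
    bonds: list[tuple[int, int]]           # local index pairs, core only
    ring_label: str
    # reducing-end anomeric hydroxyl: frame (C5, O5, C1)
    o1_internal: tuple[float, float, float]
    # donor-side junction geometry: angle O5-C1-O and torsion C5-O5-C1-O
    o5_c1_o_angle: float
    anomeric_torsion: float
    # acceptor-side junction geometry for the bridge O off Cn
    o_cn_bond: float
    o_cn_angle: float                      # O-Cn-C(n-1)
    o_placement_torsion: float             # O-Cn-C(n-1)-C(n-2)
    # reference Cartesian positions of the junction oxygens in the template
    # frame (for angle equilibria around C1 and Cn)
    o1_pos: np.ndarray | None = None
    on_pos: np.ndarray | None = None

    @property
    def key(self) -> tuple:
        return (self.sugar, self.anomer, self.acceptor_pos)

    def index(self, name: str) -> int:
        return self.atom_names.index(name)

    def ring_coords(self) -> np.ndarray:
        return self.coords[:6]

    def bond_equilibria(self) -> dict[tuple[str, str], float]:
        """Template equilibrium length per intra-residue bond."""
        out = {}
        for i, j in self.bonds:
            key = tuple(sorted((self.atom_names[i], self.atom_names[j])))
            out[key] = distance(self.coords[i], self.coords[j])
        return out


def _attach_substituents(sugar: str, anomer: str, acceptor_pos: int,
                         ring: np.ndarray) -> tuple[list[str], np.ndarray,
                                                    list[tuple[int, int]]]:
    """Place all exocyclic core atoms on a (possibly puckered) ring."""
    info = _SUGARS[sugar]
    signs = _stereo_signs(sugar, anomer)
    names = core_atom_names(sugar, acceptor_pos)
    coords = {RING_NAMES[j]: ring[j] for j in range(6)}
    bonds = list(_RING_BONDS)
    site_of = {"O2": 2, "N2": 2, "O3": 3, "O4": 4, "C6": 5}

    for name, (parent, blkey, _el) in info["subs"].items():
        if name == f"O{acceptor_pos}":
            continue
        j = site_of[name]
        d = substituent_direction(ring, j, signs[name])
        coords[name] = ring[j] + BL[blkey] * d
        bonds.append((parent, name))

    # C6 appendages
    c6 = coords["C6"]
    if info["uronic"]:
        # planar carboxylate; torsion of O6A about C5-C6 fixed at -30 deg
        for nm, tor in (("O6A", -30.0), ("O6B", 150.0)):
            coords[nm] = place_atom(coords["C4"], coords["C5"], c6,
                                    BL["C-Ocarb"], 118.0, tor)
            bonds.append(("C6", nm))
    else:
        # gt hydroxymethyl rotamer
        coords["O6"] = place_atom(coords["C4"], coords["C5"], c6,
                                  BL["C-OH"], TETRAHEDRAL, -60.0)
        bonds.append(("C6", "O6"))
        if "N2" in info["subs"]:
            n2 = coords["N2"]
            coords["C7"] = place_atom(coords["C1"], coords["C2"], n2,
                                      BL["N-C(=O)"], 122.0, -120.0)
            coords["O7"] = place_atom(coords["C2"], n2, coords["C7"],
                                      BL["C=O"], 122.0, 0.0)
            coords["C8"] = place_atom(coords["C2"], n2, coords["C7"],
                                      BL["C-CH3"], 115.0, 180.0)
            bonds += [("N2", "C7"), ("C7", "O7"), ("C7", "C8")]

    idx = {nm: k for k, nm in enumerate(names)}
    arr = np.array([coords[nm] for nm in names])
    bond_idx = [(idx[a], idx[b]) for a, b in bonds]
    return names, arr, bond_idx


def _core_plan(names: list[str]) -> InternalCoordinateRecord:
    """Canonical placement plan: ring spanning tree, then exocyclic atoms."""
    idx = {nm: k for k, nm in enumerate(names)}
    frames = {
        "C3": ("O5", "C1", "C2"), "C4": ("C1", "C2", "C3"),
        "C5": ("C2", "C3", "C4"),
        "O2": ("O5", "C1", "C2"), "N2": ("O5", "C1", "C2"),
        "O3": ("C1", "C2", "C3"), "O4": ("C2", "C3", "C4"),
        "C6": ("C3", "C4", "C5"),
        "O6": ("C4", "C5", "C6"), "O6A": ("C4", "C5", "C6"),
        "O6B": ("C4", "C5", "C6"),
        "C7": ("C1", "C2", "N2"), "O7": ("C2", "N2", "C7"),
        "C8": ("C2", "N2", "C7"),
    }
    entries = []
    for nm in names[3:]:
        a, b, c = frames[nm]
        entries.append((idx[nm], idx[a], idx[b], idx[c], 1.5, 109.5, 60.0))
    return InternalCoordinateRecord(
        seed_atoms=(idx["O5"], idx["C1"], idx["C2"]),
        seed_bond01=1.43, seed_bond12=1.52, seed_angle012=111.0,
        entries=entries,
    )


@lru_cache(maxsize=None)
def get_template(sugar: str, anomer: str, acceptor_pos: int) -> ResidueTemplate:
    if sugar not in _SUGARS:
        raise KeyError(f"unknown sugar {sugar!r}")
    info = _SUGARS[sugar]
    theta = 0.0 if info["ring"] == "4C1" else 180.0
    ring = _ideal_ring(theta)
    names, coords, bonds = _attach_substituents(sugar, anomer, acceptor_pos,
                                                ring)
    from .geometry import measure_internals
    plan = measure_internals(coords, _core_plan(names))

    signs = _stereo_signs(sugar, anomer)
    # donor-side anomeric direction (O1 / glycosidic O off C1)
    o1_dir = substituent_direction(ring, 1, signs["O1"])
    o1_pos = ring[1] + BL["C1-O1"] * o1_dir
    i = {nm: k for k, nm in enumerate(names)}
    c5, o5, c1 = coords[i["C5"]], coords[i["O5"]], coords[i["C1"]]
    o1_internal = (
        distance(o1_pos, c1),
        bond_angle(o5, c1, o1_pos),
        dihedral(c5, o5, c1, o1_pos),
    )
    # acceptor-side bridge O geometry off Cn
    cn = coords[i[f"C{acceptor_pos}"]]
    cn1 = coords[i[f"C{acceptor_pos - 1}"]]
    cn2 = coords[i[f"C{acceptor_pos - 2}"]] if acceptor_pos >= 3 else None
    on_dir = substituent_direction(ring, acceptor_pos, signs[f"O{acceptor_pos}"])
    on_pos = cn + BL["O-Cn"] * on_dir
    return ResidueTemplate(
        sugar=sugar, anomer=anomer, acceptor_pos=acceptor_pos,
        atom_names=names, elements=[_element(nm) for nm in names],
        coords=coords, plan=plan, bonds=bonds, ring_label=info["ring"],
        o1_internal=o1_internal,
        o5_c1_o_angle=o1_internal[1],
        anomeric_torsion=o1_internal[2],
        o_cn_bond=BL["O-Cn"],
        o_cn_angle=bond_angle(on_pos, cn, cn1),
        o_placement_torsion=dihedral(cn2, cn1, cn, on_pos),
        o1_pos=o1_pos,
        on_pos=on_pos,
    )


@dataclass(frozen=True)
class LinkageTemplate:
    """Equilibrium junction geometry between a donor and an acceptor type."""

    linkage_type: str
    c1_o_length: float
    o_cn_length: float
    o5_c1_o_angle: float
    c1_o_cn_angle: float
    o_cn_angle: float
    o_placement_torsion: float
    anomeric_torsion: float


def get_linkage_template(donor: tuple[str, str, int],
                         acceptor: tuple[str, str, int]) -> LinkageTemplate:
    tpl_d = get_template(*donor)
    tpl_a = get_template(*acceptor)
    return LinkageTemplate(
        linkage_type=linkage_name(donor, acceptor),
        c1_o_length=GLYCOSIDIC_C1_O,
        o_cn_length=tpl_a.o_cn_bond,
        o5_c1_o_angle=tpl_d.o5_c1_o_angle,
        c1_o_cn_angle=GLYCOSIDIC_ANGLE_C1_O_CN,
        o_cn_angle=tpl_a.o_cn_angle,
        o_placement_torsion=tpl_a.o_placement_torsion,
        anomeric_torsion=tpl_d.anomeric_torsion,
    )
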