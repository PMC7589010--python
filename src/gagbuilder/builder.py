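"""Assemble GAG polymer conformations from independently sampled conformers.

A chain is grown from the reducing end.  For each junction the bridge oxygen
is placed off the acceptor ring (bond, angle and placement torsion from the
linkage conformer), then the donor anomeric carbon via psi, the donor ring
oxygen via phi and the donor C5 via the anomeric torsion; the rest of the
donor residue, realized in a local frame from its ring conformer's internal
coordinates, is docked rigidly onto those three anchor atoms.  Every sampled
internal coordinate is therefore reproduced exactly in the Cartesian chain.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .conformers import (ConformerDatabase, LinkageConformer, RingConformer,
                         sample_conformer)
from .geometry import (Atom, Conformation, InternalCoordinateRecord,
                       LinkageSite, Topology, distance, place_atom,
                       rebuild_from_internals, superpose_three_points)
from .pucker import PuckerCoords, PuckerLabel, classify_pucker, cremer_pople
from .templates import (GAG_REPEATS, get_linkage_template, get_template,
                        linkage_name, linkage_sequence, residue_sequence)

logger = logging.getLogger(__name__)

__all__ = [
    "INITIAL_DIHEDRALS",
    "PolymerSpec",
    "make_topology",
    "build_chain",
    "build_fixed",
    "build_extended_reference",
    "end_to_end_indices",
    "template_ring_conformer",
    "template_linkage_conformer",
]


#: Homogeneous glycosidic dihedrals of the classic initial (near-extended)
#: conformation of each GAG type, under the heavy-atom IUPAC definitions
#: phi = O5-C1-O-Cn, psi = C1-O-Cn-C(n-1).  The values derive from the most
#: stable chondroitin disaccharide linkage conformations (1-3 and 1-4) and
#: from NMR/force-field work on heparan disaccharides.  Note the keratan
#: Galb1-4GlcNAc entry: the conformation was determined on a 1->3 linkage,
#: where psi references C2; re-expressed against C3 (the reference carbon of
#: a 1->4 linkage, offset by 120 degrees per the standard proton-to-heavy-atom
#: conversion) the same conformation has psi = +83.75.
INITIAL_DIHEDRALS = {
    "hyaluronan": {"GlcAb1-3GlcNAc": (-83.75, -156.25),
                   "GlcNAcb1-4GlcA": (-63.75, 118.75)},
    "dermatan": {"IdoAa1-3GalNAc": (-83.75, -156.25),
                 "GalNAcb1-4IdoA": (-63.75, 118.75)},
    "keratan": {"Galb1-4GlcNAc": (-83.75, 83.75),
                "GlcNAcb1-3Gal": (-63.75, 118.75)},
    "heparan": {"IdoAa1-4GlcNAc": (-69.0, 147.0),
                "GlcNAca1-4IdoA": (77.0, 30.0)},
}


@dataclass(frozen=True)
class PolymerSpec:
    """A GAG polymer: named type (or custom repeat) and length in residues."""

    gag_type: str
    n_residues: int
    repeat: tuple | None = None  # custom: ((sugar, anomer, acceptor_pos), ...)

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")
        if self.repeat is None and self.gag_type not in GAG_REPEATS:
            raise KeyError(f"unknown GAG type {self.gag_type!r}")

    @property
    def residues(self) -> list[tuple[str, str, int]]:
        return residue_sequence(self.gag_type, self.n_residues,
                                list(self.repeat) if self.repeat else None)

    @property
    def linkage_types(self) -> list[str]:
        return linkage_sequence(self.gag_type, self.n_residues,
                                list(self.repeat) if self.repeat else None)


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _topology_cached(gag_type: str, n_residues: int, repeat) -> Topology:
    seq = residue_sequence(gag_type, n_residues,
                           list(repeat) if repeat else None)
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    ranges: list[tuple[int, int]] = []
    link_o_index: dict[int, int] = {}
    offsets: list[dict[str, int]] = []

    for r, (sugar, anomer, acc) in enumerate(seq):
        tpl = get_template(sugar, anomer, acc)
        start = len(atoms)
        local = {}
        for nm, el in zip(tpl.atom_names, tpl.elements):
            local[nm] = len(atoms)
            atoms.append(Atom(nm, el, r, sugar))
        for i, j in tpl.bonds:
            bonds.append((start + i, start + j))
        if r == 0:
            local["O1"] = len(atoms)
            atoms.append(Atom("O1", "O", r, sugar))
            bonds.append((local["C1"], local["O1"]))
        if r < len(seq) - 1:
            o_name = f"O{acc}"
            local[o_name] = len(atoms)
            link_o_index[r] = len(atoms)
            atoms.append(Atom(o_name, "O", r, sugar))
            bonds.append((local[f"C{acc}"], local[o_name]))
        offsets.append(local)
        ranges.append((start, len(atoms)))

    linkages = []
    for j in range(len(seq) - 1):
        acc_sugar, _, acc_pos = seq[j]
        don = offsets[j + 1]
        accs = offsets[j]
        site = LinkageSite(
            linkage_type=linkage_name(seq[j + 1], seq[j]),
            o5=don["O5"], c1=don["C1"], o=link_o_index[j],
            cn=accs[f"C{acc_pos}"], cn_prev=accs[f"C{acc_pos - 1}"],
            cn_prev2=accs[f"C{acc_pos - 2}"],
            donor_residue=j + 1, acceptor_residue=j,
        )
        bonds.append((site.o, site.c1))
        linkages.append(site)

    topo = Topology(atoms=atoms, bonds=bonds, residue_ranges=ranges,
                    linkages=linkages, residue_meta=list(seq))
    topo.placement_plan = _global_plan(topo, offsets)
    topo.validate()
    return topo


def _global_plan(topo: Topology, offsets: list[dict]) -> InternalCoordinateRecord:
    """Whole-chain spanning-tree placement plan (used for restraints/measure)."""
    entries = []
    seq = topo.residue_meta
    tpl0 = get_template(*seq[0])
    o0 = offsets[0]
    for (i, a, b, c, bond, angle, torsion) in tpl0.plan.entries:
        s = topo.residue_ranges[0][0]
        entries.append((s + i, s + a, s + b, s + c, bond, angle, torsion))
    entries.append((o0["O1"], o0["C5"], o0["O5"], o0["C1"], 1.41, 109.5, 60.0))
    for j, lk in enumerate(topo.linkages):
        don = offsets[j + 1]
        dummy = (1.4, 110.0, 60.0)
        entries.append((lk.o, lk.cn_prev2, lk.cn_prev, lk.cn) + dummy)
        entries.append((lk.c1, lk.cn_prev, lk.cn, lk.o) + dummy)
        entries.append((lk.o5, lk.cn, lk.o, lk.c1) + dummy)
        entries.append((don["C5"], lk.o, lk.c1, lk.o5) + dummy)
        entries.append((don["C4"], lk.c1, lk.o5, don["C5"]) + dummy)
        entries.append((don["C3"], lk.o5, don["C5"], don["C4"]) + dummy)
        entries.append((don["C2"], don["C5"], don["C4"], don["C3"]) + dummy)
        tpl = get_template(*seq[j + 1])
        ring_set = {"O5", "C1", "C2", "C3", "C4", "C5"}
        local_plan = {e[0]: e for e in tpl.plan.entries}
        for k, nm in enumerate(tpl.atom_names):
            if nm in ring_set:
                continue
            _, a, b, c, *_ = local_plan[k]
            s = topo.residue_ranges[j + 1][0]
            entries.append((s + k, s + a, s + b, s + c) + dummy)
    s0 = topo.residue_ranges[0][0]
    i0, i1, i2 = tpl0.plan.seed_atoms
    return InternalCoordinateRecord(
        seed_atoms=(s0 + i0, s0 + i1, s0 + i2),
        seed_bond01=1.43, seed_bond12=1.52, seed_angle012=111.0,
        entries=entries,
    )


def make_topology(spec: PolymerSpec) -> Topology:
    return _topology_cached(spec.gag_type, spec.n_residues, spec.repeat)


def end_to_end_indices(topo: Topology) -> tuple[int, int]:
    """Endpoint atoms: reducing-end C1 and nonreducing-end linkage carbon."""
    last = topo.n_residues - 1
    _, _, acc = topo.residue_meta[last]
    return topo.atom_index(0, "C1"), topo.atom_index(last, f"C{acc}")


# ---------------------------------------------------------------------------
# Template-geometry conformers (for fixed builds and synthetic generation)
# ---------------------------------------------------------------------------

def template_ring_conformer(sugar: str, anomer: str,
                            acceptor_pos: int) -> RingConformer:
    tpl = get_template(sugar, anomer, acceptor_pos)
    p = cremer_pople(tpl.ring_coords())
    return RingConformer(sugar, anomer, acceptor_pos, tpl.plan, p,
                         classify_pucker(p), source="template")


def template_linkage_conformer(donor, acceptor, phi: float,
                               psi: float) -> LinkageConformer:
    lt = get_linkage_template(donor, acceptor)
    return LinkageConformer(
        linkage_type=lt.linkage_type,
        c1_o_length=lt.c1_o_length, o_cn_length=lt.o_cn_length,
        o5_c1_o_angle=lt.o5_c1_o_angle, c1_o_cn_angle=lt.c1_o_cn_angle,
        phi=phi, psi=psi,
        anomeric_torsion=lt.anomeric_torsion,
        o_cn_angle=lt.o_cn_angle,
        o_placement_torsion=lt.o_placement_torsion,
        source="template",
    )


# ---------------------------------------------------------------------------
# Chain realization
# ---------------------------------------------------------------------------

def _realize(topo: Topology, rings: list[RingConformer],
             links: list[LinkageConformer]) -> np.ndarray:
    seq = topo.residue_meta
    n = topo.n_atoms
    coords = np.full((n, 3), np.nan)

    tpl0 = get_template(*seq[0])
    local0 = rebuild_from_internals(rings[0].internals, len(tpl0.atom_names))
    s0 = topo.residue_ranges[0][0]
    coords[s0:s0 + len(tpl0.atom_names)] = local0
    # reducing-end anomeric hydroxyl at template geometry
    b, ang, tor = tpl0.o1_internal
    coords[topo.atom_index(0, "O1")] = place_atom(
        coords[topo.atom_index(0, "C5")], coords[topo.atom_index(0, "O5")],
        coords[topo.atom_index(0, "C1")], b, ang, tor)

    for j, lk in enumerate(topo.linkages):
        L = links[j]
        o = place_atom(coords[lk.cn_prev2], coords[lk.cn_prev], coords[lk.cn],
                       L.o_cn_length, L.o_cn_angle, L.o_placement_torsion)
        c1 = place_atom(coords[lk.cn_prev], coords[lk.cn], o,
                        L.c1_o_length, L.c1_o_cn_angle, L.psi)
        tpl = get_template(*seq[j + 1])
        local = rebuild_from_internals(rings[j + 1].internals,
                                       len(tpl.atom_names))
        li = {nm: k for k, nm in enumerate(tpl.atom_names)}
        lc1, lo5, lc5 = local[li["C1"]], local[li["O5"]], local[li["C5"]]
        o5 = place_atom(coords[lk.cn], o, c1,
                        distance(lc1, lo5), L.o5_c1_o_angle, L.phi)
        from .geometry import bond_angle
        c5 = place_atom(o, c1, o5, distance(lo5, lc5),
                        bond_angle(lc1, lo5, lc5), L.anomeric_torsion)
        placed = superpose_three_points(
            np.array([lc1, lo5, lc5]), np.array([c1, o5, c5]), local)
        s = topo.residue_ranges[j + 1][0]
        coords[s:s + len(tpl.atom_names)] = placed
        coords[lk.o] = o
    return coords


def _conformer_lists(spec: PolymerSpec, db: ConformerDatabase,
                     rng: np.random.Generator):
    rings, links = [], []
    for (sugar, anomer, acc) in spec.residues:
        rings.append(sample_conformer(db, sugar, rng))
    for ltype in spec.linkage_types:
        links.append(sample_conformer(db, ltype, rng))
    return rings, links


def build_chain(spec: PolymerSpec, db: ConformerDatabase,
                rng: np.random.Generator, max_retries: int = 10) -> Conformation:
    """Build one conformation by uniform independent conformer sampling."""
    topo = make_topology(spec)
    for attempt in range(max_retries):
        rings, links = _conformer_lists(spec, db, rng)
        try:
            coords = _realize(topo, rings, links)
        except ValueError:
            logger.warning("placement failure (attempt %d), resampling",
                           attempt + 1)
            continue
        prov = {"rings": [rc.source for rc in rings],
                "linkages": [lc.source for lc in links]}
        return Conformation(topo, coords, prov)
    raise RuntimeError(f"chain placement failed after {max_retries} retries")


def build_fixed(spec: PolymerSpec, dihedral_assignment: dict,
                ring_assignment: dict | None = None) -> Conformation:
    """Deterministic build with explicit per-junction (phi, psi) values.

    ``dihedral_assignment`` maps linkage-type names (or junction indices) to
    (phi, psi); rings default to template geometry unless ``ring_assignment``
    maps a residue index to a :class:`RingConformer`.
    """
    topo = make_topology(spec)
    seq = spec.residues
    rings = []
    for r, res in enumerate(seq):
        if ring_assignment and r in ring_assignment:
            rings.append(ring_assignment[r])
        else:
            rings.append(template_ring_conformer(*res))
    links = []
    for j, ltype in enumerate(spec.linkage_types):
        if j in dihedral_assignment:
            phi, psi = dihedral_assignment[j]
        elif ltype in dihedral_assignment:
            phi, psi = dihedral_assignment[ltype]
        else:
            raise KeyError(f"no dihedral assignment for junction {j} "
                           f"({ltype})")
        links.append(template_linkage_conformer(seq[j + 1], seq[j], phi, psi))
    coords = _realize(topo, rings, links)
    return Conformation(topo, coords, {"fixed": dict(dihedral_assignment)})


def end_to_end(conf: Conformation) -> float:
    i, j = end_to_end_indices(conf.topology)
    return distance(conf.coords[i], conf.coords[j])


# ---------------------------------------------------------------------------
# Fully-extended reference
# ---------------------------------------------------------------------------

def _basin_candidates(samples: np.ndarray, dg_window: float = 1.0,
                      max_candidates: int = 30) -> list[tuple[float, float]]:
    """(phi, psi) bin centers within ``dg_window`` kcal/mol of the minimum."""
    from .analysis import free_energy_map
    fem = free_energy_map([tuple(s) for s in samples])
    dg = fem.dg
    mask = np.isfinite(dg) & (dg <= dg_window)
    ii, jj = np.nonzero(mask)
    order = np.argsort(dg[ii, jj], kind="stable")
    out = []
    for k in order[:max_candidates]:
        out.append((fem.centers[ii[k]], fem.centers[jj[k]]))
    return out


def _dominant_ring(db: ConformerDatabase, sugar: str) -> RingConformer:
    pool = db.ring_pools[sugar]
    labels = [rc.label.label for rc in pool]
    vals, counts = np.unique(labels, return_counts=True)
    dominant = vals[np.argmax(counts)]
    for rc in pool:
        if rc.label.label == dominant:
            return rc
    raise RuntimeError("unreachable")


def build_extended_reference(spec: PolymerSpec,
                             db: ConformerDatabase) -> Conformation:
    """Homogeneous-dihedral chain maximizing end-to-end distance.

    Per linkage type, candidate (phi, psi) values are the free-energy-map bin
    centers within 1 kcal/mol of the basin minimum of the database sample; the
    Cartesian product is searched exhaustively and the most extended chain
    wins.  Rings are fixed at each residue type's dominant pucker.  The result
    is deterministic given the database.
    """
    db.validate()
    ltypes = sorted(set(spec.linkage_types))
    candidates = {}
    for lt in ltypes:
        pool = db.linkage_pools[lt]
        samples = np.array([(c.phi, c.psi) for c in pool])
        candidates[lt] = _basin_candidates(samples)
    ring_assignment = {}
    for r, (sugar, anomer, acc) in enumerate(spec.residues):
        ring_assignment[r] = _dominant_ring(db, sugar)

    def sweep(sp, combos, rings, keep=1):
        scored = []
        for combo in combos:
            assignment = dict(zip(ltypes, combo))
            conf = build_fixed(sp, assignment, rings)
            scored.append((end_to_end(conf), combo, conf))
        scored.sort(key=lambda t: -t[0])
        return scored[:keep]

    combos = list(itertools.product(*(candidates[lt] for lt in ltypes)))
    if spec.n_residues > 40:
        # two-stage: rank the homogeneous-dihedral candidates on a short
        # homolog (helical rise ranks almost identically at any length),
        # then re-score the leaders at full length
        proxy = PolymerSpec(spec.gag_type, 20, spec.repeat)
        proxy_rings = {r: ring_assignment[r] for r in range(20)}
        leaders = sweep(proxy, combos, proxy_rings, keep=20)
        combos = [c for _, c, _ in leaders]
    best = sweep(spec, combos, ring_assignment, keep=1)[0]
    return best[2]
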