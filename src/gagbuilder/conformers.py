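"""Conformer database: ring and linkage internal-coordinate records.

A conformer database holds, per residue type, the per-snapshot internal
coordinates of whole monosaccharide rings (ring plus exocyclic heavy atoms not
in a glycosidic junction) and, per linkage type, the junction parameters: the
C1-O and O-Cn bond lengths, O5-C1-O and C1-O-Cn bond angles, the phi/psi
dihedrals and three auxiliary placement coordinates needed to realize the
junction in Cartesian space.  The chain builder samples the two pools
independently, which encodes the hypothesis that rings and linkages behave
independently in solution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .geometry import (Conformation, InternalCoordinateRecord, Topology,
                       bond_angle, dihedral, distance, measure_internals)
from .pucker import PuckerCoords, PuckerLabel, classify_pucker, cremer_pople
from .templates import get_template

__all__ = [
    "RingConformer",
    "LinkageConformer",
    "ConformerDatabase",
    "extract_conformers",
    "sample_conformer",
    "save_db",
    "load_db",
]

SCHEMA_VERSION = 1


@dataclass
class RingConformer:
    """Internal coordinates of one monosaccharide (ring + exocyclic atoms)."""

    residue_type: str            # e.g. "GlcNAc"
    anomer: str
    acceptor_pos: int
    internals: InternalCoordinateRecord
    pucker: PuckerCoords
    label: PuckerLabel
    source: str = ""

    @property
    def template(self):
        return get_template(self.residue_type, self.anomer, self.acceptor_pos)

    def local_coords(self) -> np.ndarray:
        from .geometry import rebuild_from_internals
        return rebuild_from_internals(self.internals,
                                      len(self.template.atom_names))

    def validate(self, closure_tol: float = 0.2) -> None:
        self.internals.validate()
        tpl = self.template
        coords = self.local_coords()
        closure = distance(coords[tpl.index("C5")], coords[tpl.index("O5")])
        b0 = distance(tpl.coords[tpl.index("C5")], tpl.coords[tpl.index("O5")])
        if abs(closure - b0) > closure_tol:
            raise ValueError(
                f"ring closure bond {closure:.3f} A deviates more than "
                f"{closure_tol} A from template {b0:.3f} A")
        p = cremer_pople(coords[:6])
        if (abs(p.Q - self.pucker.Q) > 1e-6
                or abs(p.theta - self.pucker.theta) > 1e-4):
            raise ValueError("cached pucker does not match recomputation")


@dataclass
class LinkageConformer:
    """Junction parameters for one glycosidic linkage snapshot.

    phi = O5-C1-O-Cn and psi = C1-O-Cn-C(n-1).  The three auxiliary fields
    complete the Cartesian reconstruction: ``o_placement_torsion``
    (O-Cn-C(n-1)-C(n-2)) orients the bridge O off the acceptor ring,
    ``o_cn_angle`` (O-Cn-C(n-1)) opens the acceptor ring off the bridge O and
    ``anomeric_torsion`` (C5-O5-C1-O) orients the donor ring about its
    anomeric bond.
    """

    linkage_type: str            # e.g. "GlcAb1-3GlcNAc"
    c1_o_length: float
    o_cn_length: float
    o5_c1_o_angle: float
    c1_o_cn_angle: float
    phi: float
    psi: float
    anomeric_torsion: float
    o_cn_angle: float
    o_placement_torsion: float
    source: str = ""

    def validate(self) -> None:
        for nm in ("c1_o_length", "o_cn_length"):
            v = getattr(self, nm)
            if not 1.0 < v < 2.0:
                raise ValueError(f"{nm}={v} outside (1.0, 2.0) A")
        for nm in ("o5_c1_o_angle", "c1_o_cn_angle", "o_cn_angle"):
            v = getattr(self, nm)
            if not 90.0 < v < 160.0:
                raise ValueError(f"{nm}={v} outside (90, 160) deg")
        for nm in ("phi", "psi", "anomeric_torsion", "o_placement_torsion"):
            v = getattr(self, nm)
            if not -180.0 < v <= 180.0:
                raise ValueError(f"{nm}={v} outside (-180, 180]")


@dataclass
class ConformerDatabase:
    """Pools of ring and linkage conformers for one GAG type."""

    gag_type: str
    ring_pools: dict[str, list[RingConformer]] = field(default_factory=dict)
    linkage_pools: dict[str, list[LinkageConformer]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def counts(self) -> dict:
        return {
            "rings": {k: len(v) for k, v in self.ring_pools.items()},
            "linkages": {k: len(v) for k, v in self.linkage_pools.items()},
        }

    def validate(self) -> None:
        if not self.ring_pools or not self.linkage_pools:
            raise ValueError("database has empty pools")
        for k, pool in {**self.ring_pools, **self.linkage_pools}.items():
            if not pool:
                raise ValueError(f"pool {k!r} is empty")

    def merge(self, other: "ConformerDatabase") -> "ConformerDatabase":
        """Pool-wise concatenation (aggregation across runs)."""
        if other.gag_type != self.gag_type:
            raise ValueError("cannot merge databases of different GAG types")
        out = ConformerDatabase(self.gag_type, metadata=dict(self.metadata))
        for k in set(self.ring_pools) | set(other.ring_pools):
            out.ring_pools[k] = (self.ring_pools.get(k, [])
                                 + other.ring_pools.get(k, []))
        for k in set(self.linkage_pools) | set(other.linkage_pools):
            out.linkage_pools[k] = (self.linkage_pools.get(k, [])
                                    + other.linkage_pools.get(k, []))
        return out


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def _residue_meta(topology: Topology, r: int) -> tuple[str, str, int]:
    """(sugar, anomer, acceptor_pos) for residue r, stored by the builder."""
    meta = topology.residue_meta
    if meta is None:
        raise ValueError("topology lacks residue metadata for extraction")
    return meta[r]


def extract_ring(conf: Conformation, r: int) -> RingConformer:
    topo = conf.topology
    sugar, anomer, acc = _residue_meta(topo, r)
    tpl = get_template(sugar, anomer, acc)
    idx = [topo.atom_index(r, nm) for nm in tpl.atom_names]
    coords = conf.coords[idx]
    rec = measure_internals(coords, tpl.plan)
    p = cremer_pople(coords[:6])
    return RingConformer(sugar, anomer, acc, rec, p, classify_pucker(p),
                         source=str(conf.provenance.get("source", "")))


def extract_linkage(conf: Conformation, j: int) -> LinkageConformer:
    topo = conf.topology
    lk = topo.linkages[j]
    x = conf.coords
    donor = lk.donor_residue
    c5 = x[topo.atom_index(donor, "C5")]
    return LinkageConformer(
        linkage_type=lk.linkage_type,
        c1_o_length=distance(x[lk.c1], x[lk.o]),
        o_cn_length=distance(x[lk.o], x[lk.cn]),
        o5_c1_o_angle=bond_angle(x[lk.o5], x[lk.c1], x[lk.o]),
        c1_o_cn_angle=bond_angle(x[lk.c1], x[lk.o], x[lk.cn]),
        phi=dihedral(x[lk.o5], x[lk.c1], x[lk.o], x[lk.cn]),
        psi=dihedral(x[lk.c1], x[lk.o], x[lk.cn], x[lk.cn_prev]),
        anomeric_torsion=dihedral(c5, x[lk.o5], x[lk.c1], x[lk.o]),
        o_cn_angle=bond_angle(x[lk.o], x[lk.cn], x[lk.cn_prev]),
        o_placement_torsion=dihedral(x[lk.cn_prev2], x[lk.cn_prev], x[lk.cn],
                                     x[lk.o]),
        source=str(conf.provenance.get("source", "")),
    )


def extract_conformers(ensemble: list[Conformation],
                       topology: Topology | None = None,
                       gag_type: str = "custom") -> ConformerDatabase:
    """Extract every ring and every linkage from every conformation.

    Pool sizes are (#conformations x #residues-of-type) and
    (#conformations x #linkages-of-type); aggregation over runs is plain
    concatenation (:meth:`ConformerDatabase.merge`).
    """
    if not ensemble:
        raise ValueError("cannot extract from an empty ensemble")
    if topology is None:
        topology = ensemble[0].topology
    db = ConformerDatabase(gag_type=gag_type,
                           metadata={"source": "extracted",
                                     "n_conformations": len(ensemble)})
    for conf in ensemble:
        if conf.topology.n_atoms != topology.n_atoms:
            raise ValueError("conformation/topology mismatch")
        for r in range(topology.n_residues):
            rc = extract_ring(conf, r)
            db.ring_pools.setdefault(rc.residue_type, []).append(rc)
        for j in range(len(topology.linkages)):
            lc = extract_linkage(conf, j)
            db.linkage_pools.setdefault(lc.linkage_type, []).append(lc)
    return db


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_conformer(db: ConformerDatabase, kind: str,
                     rng: np.random.Generator):
    """Uniform draw from the named ring or linkage pool."""
    if kind in db.ring_pools:
        pool = db.ring_pools[kind]
    elif kind in db.linkage_pools:
        pool = db.linkage_pools[kind]
    else:
        raise KeyError(f"unknown conformer kind {kind!r}; available: "
                       f"{sorted(db.ring_pools) + sorted(db.linkage_pools)}")
    if not pool:
        raise ValueError(f"pool {kind!r} is empty")
    return pool[int(rng.integers(len(pool)))]


# ---------------------------------------------------------------------------
# Serialization (JSON lines, one conformer per line)
# ---------------------------------------------------------------------------

def _ring_to_json(rc: RingConformer) -> dict:
    return {
        "kind": "ring",
        "type": rc.residue_type, "anomer": rc.anomer,
        "acceptor_pos": rc.acceptor_pos,
        "seed": [list(rc.internals.seed_atoms), rc.internals.seed_bond01,
                 rc.internals.seed_bond12, rc.internals.seed_angle012],
        "entries": [list(e) for e in rc.internals.entries],
        "pucker": [rc.pucker.Q, rc.pucker.theta, rc.pucker.phi],
        "label": [rc.label.label, rc.label.family],
        "source": rc.source,
    }


def _ring_from_json(d: dict) -> RingConformer:
    seed = d["seed"]
    rec = InternalCoordinateRecord(
        seed_atoms=tuple(seed[0]), seed_bond01=seed[1],
        seed_bond12=seed[2], seed_angle012=seed[3],
        entries=[tuple(e) for e in d["entries"]],
    )
    return RingConformer(
        d["type"], d["anomer"], d["acceptor_pos"], rec,
        PuckerCoords(*d["pucker"]), PuckerLabel(*d["label"]),
        source=d.get("source", ""),
    )


_LINKAGE_FIELDS = ("c1_o_length", "o_cn_length", "o5_c1_o_angle",
                   "c1_o_cn_angle", "phi", "psi", "anomeric_torsion",
                   "o_cn_angle", "o_placement_torsion")


def save_db(db: ConformerDatabase, path) -> None:
    db.validate()
    with open(path, "w") as fh:
        header = {"kind": "header", "schema": SCHEMA_VERSION,
                  "gag_type": db.gag_type, "metadata": db.metadata,
                  "counts": db.counts()}
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for pool in db.ring_pools.values():
            for rc in pool:
                fh.write(json.dumps(_ring_to_json(rc), sort_keys=True) + "\n")
        for ltype, pool in db.linkage_pools.items():
            for lc in pool:
                rec = {"kind": "linkage", "type": ltype,
                       "params": {k: getattr(lc, k) for k in _LINKAGE_FIELDS},
                       "source": lc.source}
                fh.write(json.dumps(rec, sort_keys=True) + "\n")


def load_db(path) -> ConformerDatabase:
    db = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            try:
                d = json.loads(line)
            except json.JSONDecodeError as e:
                raise ValueError(
                    f"{path}: malformed record at line {lineno}: {e}") from e
            if lineno == 1:
                if d.get("kind") != "header":
                    raise ValueError(f"{path}: missing header record")
                if d.get("schema") != SCHEMA_VERSION:
                    raise ValueError(
                        f"{path}: schema {d.get('schema')} unsupported "
                        f"(expected {SCHEMA_VERSION})")
                db = ConformerDatabase(gag_type=d["gag_type"],
                                       metadata=d.get("metadata", {}))
                continue
            if d["kind"] == "ring":
                db.ring_pools.setdefault(d["type"], []).append(
                    _ring_from_json(d))
            elif d["kind"] == "linkage":
                lc = LinkageConformer(linkage_type=d["type"],
                                      source=d.get("source", ""),
                                      **d["params"])
                db.linkage_pools.setdefault(d["type"], []).append(lc)
            else:
                raise ValueError(
                    f"{path}: unknown record kind {d['kind']!r} "
                    f"at line {lineno}")
    if db is None:
        raise ValueError(f"{path}: empty database file")
    db.validate()
    return db
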