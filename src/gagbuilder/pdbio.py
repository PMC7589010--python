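"""PDB reading/writing for GAG conformations and ensembles.

Files use HETATM records with PDB carbohydrate residue codes (GCU, NAG, NDG,
IDO, NGA, GAL), chain A, occupancy 1.00 and MODEL/ENDMDL framing for
ensembles; inter-residue connectivity is emitted as CONECT records.  Parsing
goes through biotite; the molecular topology is reconstructed from residue
codes and the documented atom-name conventions (ring atoms O5, C1..C5;
linkage oxygen named O3/O4 on the acceptor residue).
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .builder import PolymerSpec, make_topology
from .geometry import Conformation, Topology

__all__ = ["RESIDUE_CODES", "write_pdb", "read_pdb_ensemble"]

#: (sugar, anomer) -> 3-letter PDB residue code
RESIDUE_CODES = {
    ("GlcA", "b"): "GCU",
    ("GlcNAc", "b"): "NAG",
    ("GlcNAc", "a"): "NDG",
    ("IdoA", "a"): "IDO",
    ("GalNAc", "b"): "NGA",
    ("Gal", "b"): "GAL",
}
_CODE_TO_SUGAR = {v: k for k, v in RESIDUE_CODES.items()}


def _atom_array(topo: Topology) -> struc.AtomArray:
    n = topo.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.array([a.residue_index + 1 for a in topo.atoms])
    arr.res_name = np.array([
        RESIDUE_CODES[(topo.residue_meta[a.residue_index][0],
                       topo.residue_meta[a.residue_index][1])]
        for a in topo.atoms])
    arr.atom_name = np.array([a.name for a in topo.atoms])
    arr.element = np.array([a.element for a in topo.atoms])
    arr.hetero = np.full(n, True)
    arr.set_annotation("occupancy", np.full(n, 1.0))
    arr.set_annotation("b_factor", np.zeros(n))
    bonds = struc.BondList(n, np.array([[i, j, 1] for i, j in topo.bonds]))
    arr.bonds = bonds
    return arr


def write_pdb(conformations, path, multi_model: bool = True) -> None:
    """Write one conformation or a list of them (MODEL records per member)."""
    if isinstance(conformations, Conformation):
        conformations = [conformations]
    members = getattr(conformations, "members", conformations)
    if not members:
        raise ValueError("nothing to write")
    topo = members[0].topology
    template = _atom_array(topo)
    pdb = PDBFile()
    if multi_model and len(members) > 1:
        stack = struc.stack([template] * len(members))
        stack.coord = np.array([m.coords for m in members], dtype=np.float32)
        pdb.set_structure(stack)
    else:
        template.coord = members[0].coords.astype(np.float32)
        pdb.set_structure(template)
    pdb.write(str(path))


def _infer_spec(codes, coords_first, atom_names, res_ranges):
    """Reconstruct (Topology, PolymerSpec) from parsed residues."""
    n_res = len(codes)
    seq = []
    for code in codes:
        if code not in _CODE_TO_SUGAR:
            raise ValueError(
                f"unknown residue code {code!r}; supported: "
                f"{sorted(_CODE_TO_SUGAR)}")
        sugar, anomer = _CODE_TO_SUGAR[code]
        seq.append((sugar, anomer, None))

    def find(r, name):
        lo, hi = res_ranges[r]
        for k in range(lo, hi):
            if atom_names[k] == name:
                return k
        return None

    # acceptor position: the O3/O4 nearest the next residue's C1
    for r in range(n_res - 1):
        next_c1 = coords_first[find(r + 1, "C1")]
        best = None
        for cand in ("O3", "O4"):
            k = find(r, cand)
            if k is not None:
                d = np.linalg.norm(coords_first[k] - next_c1)
                if best is None or d < best[0]:
                    best = (d, cand)
        seq[r] = (seq[r][0], seq[r][1], int(best[1][1]))
    # terminal residue: copy the acceptor position of the nearest same-sugar
    # residue (repeat phase), defaulting to 4
    pos = next((seq[r][2] for r in range(n_res - 2, -1, -1)
                if seq[r][0] == seq[-1][0]), 4)
    seq[-1] = (seq[-1][0], seq[-1][1], pos)
    spec = PolymerSpec("custom", n_res, repeat=tuple(seq))
    return make_topology(spec), spec


def read_pdb_ensemble(path) -> tuple[Topology, list[Conformation]]:
    """Parse a (multi-model) PDB file written by :func:`write_pdb`.

    Atom order must be consistent across models; the topology is rebuilt from
    residue codes and atom names, and coordinates are re-indexed into the
    canonical atom order.
    """
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure()
    except Exception as e:
        raise ValueError(f"{path}: inconsistent models: {e}") from e
    if stack.array_length() == 0:
        raise ValueError(f"{path}: empty structure")
    arr0 = stack[0]
    res_ids = arr0.res_id
    atom_names = list(arr0.atom_name)
    starts, codes = [], []
    seen = None
    for k in range(arr0.array_length()):
        if res_ids[k] != seen:
            seen = res_ids[k]
            starts.append(k)
            codes.append(arr0.res_name[k])
    ranges = [(starts[i], starts[i + 1] if i + 1 < len(starts)
               else arr0.array_length()) for i in range(len(starts))]
    topo, spec = _infer_spec(codes, arr0.coord, atom_names, ranges)
    # map canonical topology order onto file order
    index_of = {}
    for k in range(arr0.array_length()):
        r = int(res_ids[k]) - 1
        index_of[(r, atom_names[k])] = k
    try:
        perm = [index_of[(a.residue_index, a.name)] for a in topo.atoms]
    except KeyError as e:
        raise ValueError(f"{path}: missing atom {e} for inferred topology")
    confs = []
    for m in range(stack.stack_depth()):
        coords = np.asarray(stack[m].coord, dtype=float)[perm]
        confs.append(Conformation(topo, coords,
                                  {"source": f"{path}:model{m + 1}"}))
    return topo, confs
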