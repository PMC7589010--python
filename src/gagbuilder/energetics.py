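"""Bond potential energy, restrained minimization and the exclusion cutoff.

Constructed chains are relaxed with a gradient-based minimization of a
restrained potential: harmonic bonds and angles around template equilibria, a
steep short-range repulsive wall between topologically distant atoms, and
stiff harmonic restraints holding every placement torsion at its constructed
value so the sampled conformation is preserved.  A geometrically defective
chain (overlapping bonds or a bond threading another ring) cannot relax: the
repulsion forces bonds to stretch to nonphysical lengths, which shows up as a
large post-minimization *bond* potential energy.  The exclusion cutoff is the
post-minimization bond PE of the fully-extended reference conformation plus a
100 kcal/mol buffer; members above the cutoff are discarded and replaced.

Energy constants are generic heavy-atom values (documented defaults), not a
specific biomolecular force field; only the screening logic depends on them,
and the defect/no-defect energy separation is orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial import cKDTree

from .builder import (PolymerSpec, build_chain, build_extended_reference,
                      make_topology)
from .conformers import ConformerDatabase
from .geometry import Conformation, Topology, wrap_angle
from .templates import GLYCOSIDIC_ANGLE_C1_O_CN, get_template

__all__ = [
    "EnergyParams",
    "MinimizationResult",
    "CutoffSpec",
    "Ensemble",
    "bond_potential",
    "detect_nonphysical",
    "minimize_restrained",
    "compute_cutoff",
    "generate_ensemble",
]


@dataclass
class EnergyParams:
    """Constants of the restrained potential (kcal/mol, angstrom, radians)."""

    k_bond: float = 300.0       # kcal/mol/A^2
    k_angle: float = 60.0       # kcal/mol/rad^2
    k_torsion: float = 500.0    # kcal/mol/rad^2 restraint on placement torsions
    # purely repulsive cut-and-shifted LJ core: eps[(s/r)^12 - 2(s/r)^6 + 1]
    # for r < s; zero outside.  A hard core is what forces overlapping or
    # ring-piercing bonds to stretch during restrained minimization.  The
    # core diameter is per element pair: polar (O/N) pairs hydrogen-bond at
    # ~2.6 A and get the smaller core.
    repulsion_eps: float = 0.15
    repulsion_rmin: float = 2.8       # core diameter s (angstrom)
    repulsion_rmin_polar: float = 2.5  # O/N...O/N core diameter
    max_iterations: int = 2000
    gradient_tol: float = 1e-4   # kcal/mol/A

    def __post_init__(self):
        for nm in ("k_bond", "k_angle", "k_torsion", "repulsion_eps",
                   "repulsion_rmin"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")


@dataclass
class MinimizationResult:
    conformation: Conformation
    pre_bond_pe: float
    post_bond_pe: float
    post_total_pe: float
    converged: bool
    iterations: int
    max_dihedral_drift: float


@dataclass
class CutoffSpec:
    reference_pe: float
    buffer: float = 100.0

    @property
    def cutoff(self) -> float:
        return self.reference_pe + self.buffer


@dataclass
class Ensemble:
    """Retained conformations plus per-member statistics and bookkeeping."""

    spec: PolymerSpec
    members: list[Conformation]
    stats: pd.DataFrame            # e2e, rg, pre_pe, post_pe, retained
    cutoff: CutoffSpec
    excluded_count: int
    excluded: list[Conformation] = field(default_factory=list)

    @property
    def topology(self) -> Topology:
        return make_topology(self.spec)


# ---------------------------------------------------------------------------
# Parameter assignment from templates
# ---------------------------------------------------------------------------

class _TermTables:
    """Index arrays and equilibria for all bonded terms of one topology."""

    def __init__(self, topo: Topology):
        self.topo = topo
        self.bond_idx = np.array(topo.bonds)
        self.b0 = _bond_equilibria(topo)
        self.angle_idx, self.theta0 = _angle_terms(topo)
        plan = topo.placement_plan
        self.torsion_idx = np.array(
            [(a, b, c, i) for (i, a, b, c, *_rest) in plan.entries])
        self.excluded_pairs = _graph_neighbors(topo, max_depth=3)


_TABLE_CACHE: dict[int, _TermTables] = {}


def _tables(topo: Topology) -> _TermTables:
    key = id(topo)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = _TermTables(topo)
    return _TABLE_CACHE[key]


def _template_positions(topo: Topology, r: int) -> dict[str, np.ndarray]:
    tpl = get_template(*topo.residue_meta[r])
    pos = {nm: tpl.coords[k] for k, nm in enumerate(tpl.atom_names)}
    pos["O1"] = tpl.o1_pos
    pos[f"O{tpl.acceptor_pos}"] = tpl.on_pos
    return pos


def _bond_equilibria(topo: Topology) -> np.ndarray:
    from .templates import GLYCOSIDIC_C1_O
    b0 = np.empty(len(topo.bonds))
    for k, (i, j) in enumerate(topo.bonds):
        ai, aj = topo.atoms[i], topo.atoms[j]
        if ai.residue_index == aj.residue_index:
            pos = _template_positions(topo, ai.residue_index)
            b0[k] = np.linalg.norm(pos[ai.name] - pos[aj.name])
        else:
            b0[k] = GLYCOSIDIC_C1_O  # bridge O to donor anomeric carbon
    return b0


def _angle_terms(topo: Topology) -> tuple[np.ndarray, np.ndarray]:
    from .geometry import bond_angle
    neighbors: dict[int, list[int]] = {}
    for i, j in topo.bonds:
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)
    triples, theta0 = [], []
    bridge = {lk.o: lk for lk in topo.linkages}
    for j, nbrs in neighbors.items():
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                i, k = nbrs[a], nbrs[b]
                triples.append((i, j, k))
                ai, aj, ak = topo.atoms[i], topo.atoms[j], topo.atoms[k]
                if j in bridge and {i, k} == {bridge[j].c1, bridge[j].cn}:
                    theta0.append(np.radians(GLYCOSIDIC_ANGLE_C1_O_CN))
                elif (ai.residue_index == aj.residue_index ==
                      ak.residue_index):
                    pos = _template_positions(topo, aj.residue_index)
                    theta0.append(np.radians(
                        bond_angle(pos[ai.name], pos[aj.name], pos[ak.name])))
                else:
                    # the only cross-residue triples have the donor C1 as
                    # vertex and the bridge O as the foreign atom, which
                    # plays the anomeric-O1 role in the donor template
                    pos = _template_positions(topo, aj.residue_index)
                    pts = [pos[at.name] if at.residue_index == aj.residue_index
                           else pos["O1"] for at in (ai, aj, ak)]
                    theta0.append(np.radians(bond_angle(*pts)))
    return np.array(triples), np.array(theta0)


def _graph_neighbors(topo: Topology, max_depth: int = 3) -> set:
    """Pairs within ``max_depth`` bonds (1-2, 1-3, 1-4): excluded from
    repulsion."""
    adj: dict[int, set[int]] = {i: set() for i in range(topo.n_atoms)}
    for i, j in topo.bonds:
        adj[i].add(j)
        adj[j].add(i)
    excluded = set()
    for start in range(topo.n_atoms):
        seen = {start}
        frontier = {start}
        for _ in range(max_depth):
            frontier = {k for f in frontier for k in adj[f]} - seen
            seen |= frontier
        for other in seen:
            if other > start:
                excluded.add((start, other))
    return excluded


# ---------------------------------------------------------------------------
# Energy and analytic gradient
# ---------------------------------------------------------------------------

def _scatter_add(g: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    n = g.shape[0]
    for k in range(3):
        g[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)


def _bond_energy_grad(x, idx, b0, k):
    d = x[idx[:, 0]] - x[idx[:, 1]]
    r = np.linalg.norm(d, axis=1)
    dr = r - b0
    e = k * np.sum(dr**2)
    g = np.zeros_like(x)
    f = (2.0 * k * dr / r)[:, None] * d
    _scatter_add(g, idx[:, 0], f)
    _scatter_add(g, idx[:, 1], -f)
    return e, g


def _angle_energy_grad(x, idx, theta0, k):
    i, j, l = idx[:, 0], idx[:, 1], idx[:, 2]
    u = x[i] - x[j]
    v = x[l] - x[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    uh = u / nu[:, None]
    vh = v / nv[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    s = np.sqrt(np.clip(1.0 - c**2, 1e-12, None))
    theta = np.arccos(c)
    dt = theta - theta0
    e = k * np.sum(dt**2)
    coeff = (2.0 * k * dt / s)
    gi = coeff[:, None] * (c[:, None] * uh - vh) / nu[:, None]
    gl = coeff[:, None] * (c[:, None] * vh - uh) / nv[:, None]
    g = np.zeros_like(x)
    _scatter_add(g, i, gi)
    _scatter_add(g, l, gl)
    _scatter_add(g, j, -(gi + gl))
    return e, g


def _dihedral_vals_grads(x, idx):
    """Torsions (radians) and gradients for quads idx = (a, b, c, d)."""
    p1, p2, p3, p4 = (x[idx[:, k]] for k in range(4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    xcomp = np.einsum("ij,ij->i", n1, n2)
    ycomp = nb2 * np.einsum("ij,ij->i", b1, n2)
    phi = np.arctan2(ycomp, xcomp)
    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    g1 = -(nb2 / n1sq)[:, None] * n1
    g4 = (nb2 / n2sq)[:, None] * n2
    c12 = (np.einsum("ij,ij->i", b1, b2) / nb2**2)[:, None]
    c32 = (np.einsum("ij,ij->i", b3, b2) / nb2**2)[:, None]
    g2 = -g1 + c12 * g1 - c32 * g4
    g3 = -g4 - c12 * g1 + c32 * g4
    return phi, (g1, g2, g3, g4)


def _torsion_energy_grad(x, idx, targets, k):
    phi, grads = _dihedral_vals_grads(x, idx)
    dphi = np.radians(wrap_angle(np.degrees(phi - targets)))
    e = k * np.sum(dphi**2)
    coeff = 2.0 * k * dphi
    g = np.zeros_like(x)
    for col, gk in enumerate(grads):
        _scatter_add(g, idx[:, col], coeff[:, None] * gk)
    return e, g


def _repulsion_energy_grad(x, pairs, eps, rmin):
    """``rmin`` may be a scalar or a per-pair array of core diameters."""
    if len(pairs) == 0:
        return 0.0, np.zeros_like(x)
    rmin = np.broadcast_to(np.asarray(rmin, dtype=float), (len(pairs),))
    d = x[pairs[:, 0]] - x[pairs[:, 1]]
    r = np.linalg.norm(d, axis=1)
    mask = r < rmin
    if not mask.any():
        return 0.0, np.zeros_like(x)
    d, r, p, rmin = d[mask], r[mask], pairs[mask], rmin[mask]
    s6 = (rmin / r) ** 6
    e = eps * np.sum(s6 * s6 - 2.0 * s6 + 1.0)
    deds = -12.0 * eps * (s6 * s6 - s6) / r
    g = np.zeros_like(x)
    f = (deds / r)[:, None] * d
    _scatter_add(g, p[:, 0], f)
    _scatter_add(g, p[:, 1], -f)
    return e, g


# ---------------------------------------------------------------------------
# Fused numba kernel (falls back to the numpy terms above if unavailable)
# ---------------------------------------------------------------------------

try:
    import numba as _numba

    @_numba.njit(cache=True, fastmath=True)
    def _fused_energy_grad(x, bond_idx, b0, kb, angle_idx, theta0, ka,
                           tors_idx, targets, kt, pairs, eps, sig):
        n = x.shape[0]
        g = np.zeros((n, 3))
        e = 0.0
        for m in range(bond_idx.shape[0]):
            i, j = bond_idx[m, 0], bond_idx[m, 1]
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            r = (dx * dx + dy * dy + dz * dz) ** 0.5
            dr = r - b0[m]
            e += kb * dr * dr
            c = 2.0 * kb * dr / r
            g[i, 0] += c * dx; g[i, 1] += c * dy; g[i, 2] += c * dz
            g[j, 0] -= c * dx; g[j, 1] -= c * dy; g[j, 2] -= c * dz
        for m in range(angle_idx.shape[0]):
            i, j, l = angle_idx[m, 0], angle_idx[m, 1], angle_idx[m, 2]
            ux = x[i, 0] - x[j, 0]; uy = x[i, 1] - x[j, 1]; uz = x[i, 2] - x[j, 2]
            vx = x[l, 0] - x[j, 0]; vy = x[l, 1] - x[j, 1]; vz = x[l, 2] - x[j, 2]
            nu = (ux * ux + uy * uy + uz * uz) ** 0.5
            nv = (vx * vx + vy * vy + vz * vz) ** 0.5
            c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            s2 = 1.0 - c * c
            if s2 < 1e-12:
                s2 = 1e-12
            s = s2 ** 0.5
            theta = np.arccos(c)
            dt = theta - theta0[m]
            e += ka * dt * dt
            coeff = 2.0 * ka * dt / s
            uhx, uhy, uhz = ux / nu, uy / nu, uz / nu
            vhx, vhy, vhz = vx / nv, vy / nv, vz / nv
            gix = coeff * (c * uhx - vhx) / nu
            giy = coeff * (c * uhy - vhy) / nu
            giz = coeff * (c * uhz - vhz) / nu
            glx = coeff * (c * vhx - uhx) / nv
            gly = coeff * (c * vhy - uhy) / nv
            glz = coeff * (c * vhz - uhz) / nv
            g[i, 0] += gix; g[i, 1] += giy; g[i, 2] += giz
            g[l, 0] += glx; g[l, 1] += gly; g[l, 2] += glz
            g[j, 0] -= gix + glx; g[j, 1] -= giy + gly; g[j, 2] -= giz + glz
        for m in range(tors_idx.shape[0]):
            a, b, cc, d = (tors_idx[m, 0], tors_idx[m, 1],
                           tors_idx[m, 2], tors_idx[m, 3])
            b1x = x[b, 0] - x[a, 0]; b1y = x[b, 1] - x[a, 1]; b1z = x[b, 2] - x[a, 2]
            b2x = x[cc, 0] - x[b, 0]; b2y = x[cc, 1] - x[b, 1]; b2z = x[cc, 2] - x[b, 2]
            b3x = x[d, 0] - x[cc, 0]; b3y = x[d, 1] - x[cc, 1]; b3z = x[d, 2] - x[cc, 2]
            n1x = b1y * b2z - b1z * b2y
            n1y = b1z * b2x - b1x * b2z
            n1z = b1x * b2y - b1y * b2x
            n2x = b2y * b3z - b2z * b3y
            n2y = b2z * b3x - b2x * b3z
            n2z = b2x * b3y - b2y * b3x
            nb2 = (b2x * b2x + b2y * b2y + b2z * b2z) ** 0.5
            xc = n1x * n2x + n1y * n2y + n1z * n2z
            yc = nb2 * (b1x * n2x + b1y * n2y + b1z * n2z)
            phi = np.arctan2(yc, xc)
            dphi = phi - targets[m]
            while dphi > np.pi:
                dphi -= 2.0 * np.pi
            while dphi <= -np.pi:
                dphi += 2.0 * np.pi
            e += kt * dphi * dphi
            coeff = 2.0 * kt * dphi
            n1sq = n1x * n1x + n1y * n1y + n1z * n1z
            n2sq = n2x * n2x + n2y * n2y + n2z * n2z
            f1 = -nb2 / n1sq
            f4 = nb2 / n2sq
            g1x, g1y, g1z = f1 * n1x, f1 * n1y, f1 * n1z
            g4x, g4y, g4z = f4 * n2x, f4 * n2y, f4 * n2z
            c12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (nb2 * nb2)
            c32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (nb2 * nb2)
            g2x = -g1x + c12 * g1x - c32 * g4x
            g2y = -g1y + c12 * g1y - c32 * g4y
            g2z = -g1z + c12 * g1z - c32 * g4z
            g3x = -g4x - c12 * g1x + c32 * g4x
            g3y = -g4y - c12 * g1y + c32 * g4y
            g3z = -g4z - c12 * g1z + c32 * g4z
            g[a, 0] += coeff * g1x; g[a, 1] += coeff * g1y; g[a, 2] += coeff * g1z
            g[b, 0] += coeff * g2x; g[b, 1] += coeff * g2y; g[b, 2] += coeff * g2z
            g[cc, 0] += coeff * g3x; g[cc, 1] += coeff * g3y; g[cc, 2] += coeff * g3z
            g[d, 0] += coeff * g4x; g[d, 1] += coeff * g4y; g[d, 2] += coeff * g4z
        for m in range(pairs.shape[0]):
            i, j = pairs[m, 0], pairs[m, 1]
            rmin = sig[m]
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            r = (dx * dx + dy * dy + dz * dz) ** 0.5
            if r < rmin:
                s6 = (rmin / r) ** 6
                e += eps * (s6 * s6 - 2.0 * s6 + 1.0)
                c = -12.0 * eps * (s6 * s6 - s6) / (r * r)
                g[i, 0] += c * dx; g[i, 1] += c * dy; g[i, 2] += c * dz
                g[j, 0] -= c * dx; g[j, 1] -= c * dy; g[j, 2] -= c * dz
        return e, g

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False


def bond_potential(conf: Conformation, params: EnergyParams | None = None) -> float:
    """Sum of k_b (b - b0)^2 over all bonds (kcal/mol)."""
    params = params or EnergyParams()
    tab = _tables(conf.topology)
    e, _ = _bond_energy_grad(conf.coords, tab.bond_idx, tab.b0, params.k_bond)
    return float(e)


def _candidate_pairs(coords: np.ndarray, excluded: set, rmin: float,
                     margin: float = 1.2) -> np.ndarray:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(rmin + margin, output_type="ndarray")
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    keep = [k for k, (i, j) in enumerate(pairs)
            if (int(i), int(j)) not in excluded]
    return pairs[keep]


def minimize_restrained(conf: Conformation,
                        params: EnergyParams | None = None) -> MinimizationResult:
    """Relax sterics while holding every placement torsion near its value."""
    params = params or EnergyParams()
    topo = conf.topology
    tab = _tables(topo)
    x0 = conf.coords
    targets, _ = _dihedral_vals_grads(x0, tab.torsion_idx)
    pairs = _candidate_pairs(x0, tab.excluded_pairs, params.repulsion_rmin)
    polar = np.array([a.element in ("O", "N") for a in topo.atoms])
    if len(pairs):
        sig = np.where(polar[pairs[:, 0]] & polar[pairs[:, 1]],
                       params.repulsion_rmin_polar, params.repulsion_rmin)
    else:
        sig = np.zeros(0)
    pre_pe, _ = _bond_energy_grad(x0, tab.bond_idx, tab.b0, params.k_bond)

    if _HAVE_NUMBA:
        pairs64 = np.ascontiguousarray(pairs.astype(np.int64)).reshape(-1, 2)
        sig64 = np.ascontiguousarray(sig, dtype=np.float64)

        def fun(flat):
            x = np.ascontiguousarray(flat.reshape(-1, 3))
            e, g = _fused_energy_grad(
                x, tab.bond_idx, tab.b0, params.k_bond,
                tab.angle_idx, tab.theta0, params.k_angle,
                tab.torsion_idx, targets, params.k_torsion,
                pairs64, params.repulsion_eps, sig64)
            return e, g.ravel()
    else:
        def fun(flat):
            x = flat.reshape(-1, 3)
            e1, g1 = _bond_energy_grad(x, tab.bond_idx, tab.b0, params.k_bond)
            e2, g2 = _angle_energy_grad(x, tab.angle_idx, tab.theta0,
                                        params.k_angle)
            e3, g3 = _torsion_energy_grad(x, tab.torsion_idx, targets,
                                          params.k_torsion)
            e4, g4 = _repulsion_energy_grad(x, pairs, params.repulsion_eps,
                                            sig)
            return e1 + e2 + e3 + e4, (g1 + g2 + g3 + g4).ravel()

    opts = {"maxiter": params.max_iterations,
            "gtol": params.gradient_tol, "ftol": 1e-12}
    # hard-core overlaps produce enormous gradients that break the Wolfe
    # line search; a short capped-step descent (max 0.25 A per atom per
    # step, monotone in energy) clears them before quasi-Newton refinement
    flat = x0.ravel().copy()
    e_cur, g = fun(flat)
    pre_steps = 0
    while np.abs(g).max() > 500.0 and pre_steps < 100:
        gmax = np.abs(g).max()
        step = min(0.25 / gmax, 0.02)
        trial = flat - step * g
        e_new, g_new = fun(trial)
        if e_new >= e_cur:
            step *= 0.25
            trial = flat - step * g
            e_new, g_new = fun(trial)
            if e_new >= e_cur:
                break
        flat, e_cur, g = trial, e_new, g_new
        pre_steps += 1
    res = _scipy_minimize(fun, flat, jac=True, method="L-BFGS-B",
                          options=opts)
    nit = res.nit
    if (not res.success and res.nit < params.max_iterations
            and np.abs(res.jac).max() > 2.0):
        # line-search stall far from the minimum (common with the stiff
        # hard-core term): one restart with a fresh Hessian approximation
        # pushes the gradient down further; stalls at already-small
        # gradients are left as-is
        res2 = _scipy_minimize(fun, res.x, jac=True, method="L-BFGS-B",
                               options=opts)
        if res2.fun <= res.fun:
            res = res2
        nit += res2.nit
    x = res.x.reshape(-1, 3)
    post_pe, _ = _bond_energy_grad(x, tab.bond_idx, tab.b0, params.k_bond)
    final_t, _ = _dihedral_vals_grads(x, tab.torsion_idx)
    drift = np.abs(wrap_angle(np.degrees(final_t - targets))).max()
    out = Conformation(topo, x, dict(conf.provenance))
    gmax = float(np.abs(res.jac).max())
    return MinimizationResult(
        conformation=out,
        pre_bond_pe=float(pre_pe), post_bond_pe=float(post_pe),
        post_total_pe=float(res.fun),
        converged=bool(res.success or gmax <= 10 * params.gradient_tol),
        iterations=int(nit), max_dihedral_drift=float(drift),
    )


# ---------------------------------------------------------------------------
# Nonphysical-geometry detection
# ---------------------------------------------------------------------------

def _segment_segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between segments p1-q1 and p2-q2."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    c = d1 @ r
    b = d1 @ d2
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
    t = (b * s + f) / e if e > 1e-12 else 0.0
    if t < 0.0:
        t = 0.0
        s = np.clip(-c / a, 0.0, 1.0) if a > 1e-12 else 0.0
    elif t > 1.0:
        t = 1.0
        s = np.clip((b - c) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm((p1 + s * d1) - (p2 + t * d2)))


def _segment_hits_triangle(p, q, tri) -> bool:
    """Moller-Trumbore segment/triangle intersection."""
    v0, v1, v2 = tri
    d = q - p
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(d, e2)
    a = e1 @ h
    if abs(a) < 1e-12:
        return False
    f = 1.0 / a
    s = p - v0
    u = f * (s @ h)
    if u < 0.0 or u > 1.0:
        return False
    qv = np.cross(s, e1)
    v = f * (d @ qv)
    if v < 0.0 or u + v > 1.0:
        return False
    t = f * (e2 @ qv)
    return 0.0 <= t <= 1.0


def detect_nonphysical(conf: Conformation, overlap_cutoff: float = 0.5) -> dict:
    """Report overlapping bond pairs and ring-piercing bonds.

    Overlap: two bonds sharing no atom whose segments pass within
    ``overlap_cutoff`` angstrom.  Piercing: a bond from another residue whose
    segment crosses the fan-triangulated surface of a ring hexagon.
    """
    topo = conf.topology
    x = conf.coords
    bonds = np.array(topo.bonds)
    mids = 0.5 * (x[bonds[:, 0]] + x[bonds[:, 1]])
    lengths = np.linalg.norm(x[bonds[:, 0]] - x[bonds[:, 1]], axis=1)
    search_r = lengths.max() + overlap_cutoff

    overlapping = []
    tree = cKDTree(mids)
    for a, b in tree.query_pairs(search_r):
        i1, j1 = bonds[a]
        i2, j2 = bonds[b]
        if len({i1, j1, i2, j2}) < 4:
            continue
        dmin = _segment_segment_distance(x[i1], x[j1], x[i2], x[j2])
        if dmin < overlap_cutoff:
            overlapping.append((tuple(bonds[a]), tuple(bonds[b])))

    piercing = []
    ring_sets = [topo.ring_indices(r) for r in range(topo.n_residues)]
    centroids = np.array([x[idx].mean(axis=0) for idx in ring_sets])
    res_of_bond = [
        (topo.atoms[i].residue_index, topo.atoms[j].residue_index)
        for i, j in topo.bonds]
    ctree = cKDTree(centroids)
    for k, (i, j) in enumerate(topo.bonds):
        near = ctree.query_ball_point(mids[k], lengths[k] / 2 + 2.5)
        for r in near:
            if r in res_of_bond[k]:
                continue
            ring = x[ring_sets[r]]
            c = centroids[r]
            for m in range(6):
                tri = (c, ring[m], ring[(m + 1) % 6])
                if _segment_hits_triangle(x[i], x[j], tri):
                    piercing.append(((i, j), r))
                    break
    return {"overlapping_bond_pairs": overlapping,
            "piercing_events": piercing}


def find_planted_piercing(spec: PolymerSpec, db: ConformerDatabase,
                          seed: int, max_attempts: int = 5000):
    """Deterministic ring-piercing fixture with a defect-free counterpart.

    Scans the counter-based member streams of ``seed`` until the geometric
    detector confirms a bond piercing a ring surface *and* the piercing
    persists through restrained minimization (a bond can graze a ring
    surface without being topologically locked; such crossings relax away
    and are not defects in the screening sense).  A single glycosidic
    junction whose replacement by its free-energy-basin-minimum conformation
    clears every defect provides the counterpart: ``(pierced, clean,
    junction)`` are built from the same ring and linkage draws except for
    that one junction, so the planted defect is exactly the culprit linkage
    conformation.
    """
    from .builder import (_conformer_lists, _realize, make_topology,
                          template_linkage_conformer)
    from .analysis import free_energy_map

    topo = make_topology(spec)
    seq = spec.residues
    minima = {}
    for lt, pool in db.linkage_pools.items():
        fem = free_energy_map([(c.phi, c.psi) for c in pool])
        minima[lt] = fem.minimum()
    for k in range(max_attempts):
        rng = np.random.default_rng([seed, k])
        rings, links = _conformer_lists(spec, db, rng)
        try:
            pierced = Conformation(topo, _realize(topo, rings, links))
        except ValueError:
            continue
        rep = detect_nonphysical(pierced)
        if not rep["piercing_events"]:
            continue
        relaxed = minimize_restrained(pierced).conformation
        if not detect_nonphysical(relaxed)["piercing_events"]:
            continue  # grazing crossing, not a locked threading
        # junctions nearest the piercing bonds first
        order = []
        for (i, j), _r in rep["piercing_events"]:
            jc = min(topo.atoms[i].residue_index,
                     topo.atoms[j].residue_index)
            order += [jc, max(jc - 1, 0), min(jc + 1, len(links) - 1)]
        order += list(range(len(links)))
        tried = set()
        for j in order:
            if j in tried:
                continue
            tried.add(j)
            lt = topo.linkages[j].linkage_type
            links2 = list(links)
            links2[j] = template_linkage_conformer(seq[j + 1], seq[j],
                                                   *minima[lt])
            try:
                clean = Conformation(topo, _realize(topo, rings, links2))
            except ValueError:
                continue
            rep_c = detect_nonphysical(clean)
            if (not rep_c["piercing_events"]
                    and not rep_c["overlapping_bond_pairs"]):
                return pierced, clean, j
    raise RuntimeError(
        f"no planted-piercing pair found in {max_attempts} attempts")


# ---------------------------------------------------------------------------
# Cutoff and ensemble generation
# ---------------------------------------------------------------------------

def compute_cutoff(spec: PolymerSpec, db: ConformerDatabase,
                   params: EnergyParams | None = None,
                   extended: Conformation | None = None) -> CutoffSpec:
    """Cutoff = post-minimization bond PE of the extended reference + 100."""
    params = params or EnergyParams()
    if extended is None:
        extended = build_extended_reference(spec, db)
    res = minimize_restrained(extended, params)
    return CutoffSpec(reference_pe=res.post_bond_pe)


def generate_ensemble(spec: PolymerSpec, db: ConformerDatabase, n_members: int,
                      seed: int, params: EnergyParams | None = None,
                      keep_excluded: bool = False,
                      cutoff: CutoffSpec | None = None) -> Ensemble:
    """Build, minimize and filter until ``n_members`` chains are retained.

    Excluded members are replaced by fresh draws so the ensemble reaches the
    requested size.  Fully deterministic: member i uses the counter-based
    stream seeded by (seed, i).
    """
    from .analysis import end_to_end, radius_of_gyration
    params = params or EnergyParams()
    if cutoff is None:
        cutoff = compute_cutoff(spec, db, params)
    members: list[Conformation] = []
    rows = []
    excluded: list[Conformation] = []
    n_excluded = 0
    attempt = 0
    max_attempts = max(200, 100 * n_members)
    while len(members) < n_members:
        if attempt >= max_attempts:
            raise RuntimeError(
                f"retention rate {len(members)}/{attempt} below 1%; "
                f"cutoff={cutoff.cutoff:.1f} kcal/mol")
        rng = np.random.default_rng([seed, attempt])
        conf = build_chain(spec, db, rng)
        res = minimize_restrained(conf, params)
        retained = res.post_bond_pe <= cutoff.cutoff
        rows.append({
            "index": attempt,
            "e2e": end_to_end(res.conformation),
            "rg": radius_of_gyration(res.conformation),
            "pre_pe": res.pre_bond_pe,
            "post_pe": res.post_bond_pe,
            "retained": retained,
        })
        if retained:
            members.append(res.conformation)
        else:
            n_excluded += 1
            if keep_excluded:
                excluded.append(res.conformation)
        attempt += 1
    stats = pd.DataFrame(rows)
    return Ensemble(spec=spec, members=members, stats=stats, cutoff=cutoff,
                    excluded_count=n_excluded, excluded=excluded)
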