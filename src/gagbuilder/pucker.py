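"""Cremer-Pople puckering for six-membered rings.

Rings are always passed in the atom order O5, C1, C2, C3, C4, C5.  With that
ordering and the phase convention below, the standard D-pyranose chair (all
equatorial substituents) sits at theta ~ 0 and is labelled 4C1, the inverted
chair at theta ~ 180 is 1C4, and the twelve canonical boats/skew-boats live on
the theta = 90 equator at 30-degree phase spacing.  The label wheel is
calibrated executably from the defining out-of-plane displacement patterns
rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .geometry import wrap_angle

__all__ = [
    "PuckerCoords",
    "PuckerLabel",
    "cremer_pople",
    "ring_from_pucker",
    "classify_pucker",
    "CANONICAL_LABELS",
]

_N = 6
_J = np.arange(_N)

#: chair band half-width: theta <= 45 is 4C1, theta >= 135 is 1C4
CHAIR_THETA = 45.0

#: 2 chairs + 6 boats + 6 skew-boats
CANONICAL_LABELS = (
    "4C1", "1C4",
    "B1,4", "1,4B", "B2,5", "2,5B", "B3,O", "3,OB",
    "1S3", "3S1", "1S5", "5S1", "2SO", "OS2",
)


@dataclass(frozen=True)
class PuckerCoords:
    """Total amplitude Q (angstrom), polar theta and azimuth phi (degrees)."""

    Q: float
    theta: float
    phi: float

    def __post_init__(self):
        if self.Q < 0:
            raise ValueError("Q must be >= 0")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError("theta must be in [0, 180]")
        if not 0.0 <= self.phi < 360.0:
            raise ValueError("phi must be in [0, 360)")


@dataclass(frozen=True)
class PuckerLabel:
    label: str
    family: str  # chair | boat | skew-boat | intermediate

    def __post_init__(self):
        if self.label not in CANONICAL_LABELS:
            raise ValueError(f"unknown pucker label {self.label!r}")


def _displacements(ring_coords: np.ndarray) -> np.ndarray:
    """Out-of-plane displacements z_j relative to the C-P mean plane."""
    r = ring_coords - ring_coords.mean(axis=0)
    s = np.sin(2 * np.pi * _J / _N)
    c = np.cos(2 * np.pi * _J / _N)
    R1 = (r * s[:, None]).sum(axis=0)
    R2 = (r * c[:, None]).sum(axis=0)
    n = np.cross(R1, R2)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("degenerate ring: cannot define mean plane")
    return r @ (n / nn)


def _pucker_from_z(z: np.ndarray) -> PuckerCoords:
    c2 = np.cos(4 * np.pi * _J / _N)
    s2 = np.sin(4 * np.pi * _J / _N)
    qc = np.sqrt(1.0 / 3.0) * (z * c2).sum()
    qs = -np.sqrt(1.0 / 3.0) * (z * s2).sum()
    q3 = np.sqrt(1.0 / 6.0) * (z * (-1.0) ** _J).sum()
    q2 = np.hypot(qc, qs)
    Q = np.hypot(q2, q3)
    if Q < 1e-12:
        return PuckerCoords(0.0, 0.0, 0.0)
    theta = np.degrees(np.arccos(np.clip(q3 / Q, -1.0, 1.0)))
    if q2 < 1e-12 or theta in (0.0, 180.0):
        phi = 0.0
    else:
        phi = float(np.degrees(np.arctan2(qs, qc)) % 360.0)
        if phi >= 360.0:  # floating-point edge of the modulo
            phi = 0.0
    return PuckerCoords(float(Q), float(theta), phi)


def cremer_pople(ring_coords) -> PuckerCoords:
    """C-P (Q, theta, phi) of six points ordered O5,C1,C2,C3,C4,C5."""
    ring_coords = np.asarray(ring_coords, dtype=float)
    if ring_coords.shape != (6, 3):
        raise ValueError("ring_coords must have shape (6, 3)")
    if len({tuple(np.round(p, 9)) for p in ring_coords}) < 6:
        raise ValueError("coincident ring atoms")
    return _pucker_from_z(_displacements(ring_coords))


def _z_from_pucker(p: PuckerCoords) -> np.ndarray:
    th = np.radians(p.theta)
    ph = np.radians(p.phi)
    q2 = p.Q * np.sin(th)
    q3 = p.Q * np.cos(th)
    z = (np.sqrt(1.0 / 3.0) * q2 * np.cos(ph + 4 * np.pi * _J / _N)
         + np.sqrt(1.0 / 6.0) * q3 * (-1.0) ** _J)
    return z


def ring_from_pucker(p: PuckerCoords, mean_bond: float = 1.49) -> np.ndarray:
    """Inverse transform: six ring coordinates realizing the given pucker.

    Atoms sit on a circle in the xy plane (regular-hexagon azimuths) with the
    C-P out-of-plane displacements superimposed; the circle radius is shrunk so
    bond lengths average ``mean_bond``.  The forward transform recovers
    (Q, theta, phi) exactly because the displacement pattern contains no
    first-harmonic component.  Q beyond ~1.2 A is geometrically infeasible.
    """
    if p.Q > 1.2:
        raise ValueError("puckering amplitude Q > 1.2 A is infeasible")
    z = _z_from_pucker(p)
    dz2 = np.mean((z - np.roll(z, -1)) ** 2)
    rad2 = mean_bond**2 - dz2
    if rad2 <= 0:
        raise ValueError("pucker amplitude incompatible with bond length")
    rho = np.sqrt(rad2)  # regular hexagon: side length equals radius
    # clockwise azimuths so the C-P mean-plane normal points along +z
    ang = -2 * np.pi * _J / _N
    return np.column_stack([rho * np.cos(ang), rho * np.sin(ang), z])


# ---------------------------------------------------------------------------
# Label wheel calibration
# ---------------------------------------------------------------------------

_RING_NAMES = ("O", "1", "2", "3", "4", "5")  # index in C-P order


def _equator_phase(z: np.ndarray) -> float:
    """C-P phase phi2 of a pure-equatorial displacement pattern."""
    p = _pucker_from_z(z - z.mean())
    return p.phi


@lru_cache(maxsize=1)
def _label_wheel() -> dict:
    """Map equator label -> calibrated C-P phase (degrees).

    Boats B with atoms x,y displaced toward one side; 'above' (superscript,
    written before the letter) means positive C-P z.  Skew-boats xSy have atom
    x above and atom y below.  Patterns follow the defining geometry, the
    phases follow from the C-P sums, so the wheel is computed, not assumed.
    """
    wheel = {}
    # boats: opposite pair (j, j+3) displaced together, others opposite
    for j in range(3):
        pair = (j, j + 3)
        z = np.full(_N, -0.5)
        z[list(pair)] = 1.0
        names = sorted((_RING_NAMES[pair[0]], _RING_NAMES[pair[1]]),
                       key=lambda s: (s == "O", s))
        up = f"{names[0]},{names[1]}B"      # pair above the plane
        down = f"B{names[0]},{names[1]}"    # pair below the plane
        wheel[up] = _equator_phase(z)
        wheel[down] = _equator_phase(-z)
    # skew-boats: atom x up, atom x+... down; canonical six
    for up_i, dn_i in ((1, 3), (3, 1), (1, 5), (5, 1), (2, 0), (0, 2)):
        z = np.zeros(_N)
        z[up_i] = 1.0
        z[dn_i] = -1.0
        name = f"{_RING_NAMES[up_i]}S{_RING_NAMES[dn_i]}"
        wheel[name] = _equator_phase(z)
    return wheel


def classify_pucker(p: PuckerCoords) -> PuckerLabel:
    """Deterministic canonical label for a point on the C-P sphere.

    Chairs for theta <= 45 (4C1) or theta >= 135 (1C4); otherwise the nearest
    canonical equator vertex, boats on even multiples of 30 degrees in the
    calibrated phase, skew-boats on odd multiples.  Phase ties break toward
    the lower phase vertex.
    """
    if p.theta <= CHAIR_THETA:
        return PuckerLabel("4C1", "chair")
    if p.theta >= 180.0 - CHAIR_THETA:
        return PuckerLabel("1C4", "chair")
    wheel = _label_wheel()
    best = None
    for label, phase in sorted(wheel.items(), key=lambda kv: kv[1]):
        d = abs(wrap_angle(p.phi - phase))
        if best is None or d < best[0] - 1e-9:
            best = (d, label)
    label = best[1]
    family = "skew-boat" if "S" in label else "boat"
    return PuckerLabel(label, family)


def label_vertex(label: str) -> PuckerCoords:
    """Canonical (theta, phi) sphere point for a label (Q defaulted to 0.55)."""
    if label == "4C1":
        return PuckerCoords(0.55, 0.0, 0.0)
    if label == "1C4":
        return PuckerCoords(0.55, 180.0, 0.0)
    wheel = _label_wheel()
    if label not in wheel:
        raise KeyError(f"unknown pucker label {label!r}")
    return PuckerCoords(0.55, 90.0, wheel[label] % 360.0)
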