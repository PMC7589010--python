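"""Internal-coordinate geometry: measures, placement, and their inverses."""

import numpy as np
import pytest

from gagbuilder.geometry import (InternalCoordinateRecord, bond_angle,
                                 dihedral, distance, measure_internals,
                                 place_atom, rebuild_from_internals,
                                 superpose_three_points, wrap_angle)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestScalarMeasures:
    @pytest.mark.parametrize("p,q,expected", [
        ((0, 0, 0), (3, 4, 0), 5.0),
        ((1, 2, 3), (1, 2, 3), 0.0),
    ])
    def test_distance_examples(self, p, q, expected):
        assert distance(p, q) == pytest.approx(expected)

    def test_distance_translation_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p, q, t = rng.normal(size=(3, 3))
            assert distance(p + t, q + t) == pytest.approx(distance(p, q))

    @pytest.mark.parametrize("p1,p2,p3,expected", [
        ((1, 0, 0), (0, 0, 0), (0, 1, 0), 90.0),
        ((-1, 0, 0), (0, 0, 0), (1, 0, 0), 180.0),
        ((1, 0, 0), (0, 0, 0), (0.5, np.sqrt(3) / 2, 0), 60.0),
    ])
    def test_bond_angle_examples(self, p1, p2, p3, expected):
        assert bond_angle(p1, p2, p3) == pytest.approx(expected)

    def test_bond_angle_coincident_vertex_raises(self):
        with pytest.raises(ValueError):
            bond_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    @pytest.mark.parametrize("pts,expected", [
        # hand evaluation of the atan2 cross-product formula
        ([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)], 90.0),
        # coplanar trans and cis
        ([(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)], 180.0),
        ([(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)], 0.0),
    ])
    def test_dihedral_examples(self, pts, expected):
        assert dihedral(*pts) == pytest.approx(expected)

    def test_dihedral_sign_flips_under_mirror(self):
        pts = np.array([(0.1, 0.2, 0.3), (1, 0, 0), (1.2, 1.1, 0.1),
                        (2, 1, 1)])
        mirrored = pts * np.array([1, 1, -1])
        assert dihedral(*mirrored) == pytest.approx(-dihedral(*pts))

    def test_dihedral_rigid_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(4, 3))
        ref = dihedral(*pts)
        for _ in range(25):
            R = random_rotation(rng)
            t = rng.normal(size=3)
            moved = pts @ R.T + t
            assert dihedral(*moved) == pytest.approx(ref, abs=1e-9)

    def test_dihedral_collinear_raises(self):
        with pytest.raises(ValueError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestPlacement:
    def test_hand_solved_example(self):
        d = place_atom((0, 0, 0), (1, 0, 0), (1, 1, 0), 1.0, 90.0, 180.0)
        assert np.allclose(d, (2, 1, 0), atol=1e-12)

    def test_round_trip_many(self):
        """place/measure are exact inverses over 10^4 random valid draws."""
        rng = np.random.default_rng(42)
        n = 10_000
        a = rng.normal(size=(n, 3))
        b = a + rng.normal(size=(n, 3))
        c = b + rng.normal(size=(n, 3))
        # reject (nearly) degenerate frames
        ok = (np.linalg.norm(np.cross(b - a, c - b), axis=1) > 1e-2)
        a, b, c = a[ok], b[ok], c[ok]
        bonds = rng.uniform(0.5, 3.0, size=len(a))
        angles = rng.uniform(5.0, 175.0, size=len(a))
        torsions = rng.uniform(-179.99, 180.0, size=len(a))
        for k in range(len(a)):
            d = place_atom(a[k], b[k], c[k], bonds[k], angles[k], torsions[k])
            assert distance(d, c[k]) == pytest.approx(bonds[k], rel=1e-9)
            assert bond_angle(b[k], c[k], d) == pytest.approx(
                angles[k], rel=1e-9, abs=1e-9)
            assert dihedral(a[k], b[k], c[k], d) == pytest.approx(
                torsions[k], rel=1e-9, abs=1e-9)

    def test_collinear_frame_raises(self):
        with pytest.raises(ValueError):
            place_atom((0, 0, 0), (1, 0, 0), (2, 0, 0), 1.0, 109.5, 60.0)


def zigzag_record():
    """Planar zig-zag chain of 6 atoms: all torsions are 180 degrees."""
    entries = [(k, k - 3, k - 2, k - 1, 1.5, 110.0, 180.0)
               for k in range(3, 6)]
    return InternalCoordinateRecord(
        seed_atoms=(0, 1, 2), seed_bond01=1.5, seed_bond12=1.5,
        seed_angle012=110.0, entries=entries)


class TestMeasureRebuild:
    def test_round_trip_reproduces_internals(self):
        rec = zigzag_record()
        coords = rebuild_from_internals(rec)
        measured = measure_internals(coords, rec)
        assert measured.seed_bond01 == pytest.approx(1.5)
        assert measured.seed_angle012 == pytest.approx(110.0)
        for e in measured.entries:
            assert e[4] == pytest.approx(1.5)
            assert e[5] == pytest.approx(110.0)
            assert abs(e[6]) == pytest.approx(180.0)

    def test_planar_zigzag_all_trans(self):
        coords = rebuild_from_internals(zigzag_record())
        assert np.allclose(coords[:, 2], 0.0, atol=1e-9)

    def test_isometry_invariance(self):
        rec = zigzag_record()
        coords = rebuild_from_internals(rec)
        rng = np.random.default_rng(3)
        moved = coords @ random_rotation(rng).T + rng.normal(size=3)
        m1 = measure_internals(coords, rec)
        m2 = measure_internals(moved, rec)
        for e1, e2 in zip(m1.entries, m2.entries):
            assert e1[4:] == pytest.approx(e2[4:], abs=1e-9)

    def test_rebuild_rmsd_after_superposition(self):
        """Rebuilding measured internals reproduces coordinates rigidly."""
        rng = np.random.default_rng(7)
        rec = zigzag_record()
        coords = rebuild_from_internals(rec)
        coords += 0.05 * rng.normal(size=coords.shape)  # perturb
        rebuilt = rebuild_from_internals(measure_internals(coords, rec))
        aligned = superpose_three_points(rebuilt[:3], coords[:3], rebuilt)
        rmsd = np.sqrt(((aligned - coords) ** 2).sum(axis=1).mean())
        assert rmsd < 1e-6

    def test_invalid_indices_raise(self):
        rec = zigzag_record()  # references six atoms
        coords = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(IndexError):
            measure_internals(coords, rec)


def test_wrap_angle_range():
    vals = np.array([-540.0, -180.0, -179.9, 0.0, 179.9, 180.0, 360.0, 541.0])
    w = wrap_angle(vals)
    assert np.all(w > -180.0) and np.all(w <= 180.0)
    assert w[1] == 180.0 and w[5] == 180.0  # -180 wraps to +180
    assert wrap_angle(-180.0) == 180.0
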