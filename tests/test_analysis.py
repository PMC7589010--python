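"""Free-energy maps, size descriptors, histogram modes, sub-ensembles."""

import numpy as np
import pytest

from gagbuilder.analysis import (R_KCAL, contour_length, e2e_rg_r2,
                                 end_to_end, free_energy_map, histogram_mode,
                                 linkage_dihedrals, near_basin,
                                 percent_difference, radius_of_gyration,
                                 ring_pucker_labels, subset_ensemble)
from gagbuilder.builder import INITIAL_DIHEDRALS, PolymerSpec, build_fixed


class TestFreeEnergyMap:
    def test_minimum_is_exactly_zero(self):
        rng = np.random.default_rng(0)
        samples = np.column_stack([rng.normal(-70, 10, 2000),
                                   rng.normal(-120, 10, 2000)])
        fem = free_energy_map(samples)
        assert np.nanmin(fem.dg) == 0.0
        i, j = np.unravel_index(np.argmax(fem.counts), fem.counts.shape)
        assert fem.dg[i, j] == 0.0

    def test_two_bin_count_ratio_gives_rt_ln10(self):
        """Counts 100 vs 10 at 310 K differ by RT ln 10 = 1.418 kcal/mol."""
        samples = [(-70.0, -120.0)] * 100 + [(50.0, 50.0)] * 10
        fem = free_energy_map(samples, temperature=310.0)
        lo = fem.value_at(-70.0, -120.0)
        hi = fem.value_at(50.0, 50.0)
        assert lo == 0.0
        assert hi - lo == pytest.approx(R_KCAL * 310.0 * np.log(10.0),
                                        abs=1e-9)
        assert hi - lo == pytest.approx(1.418, abs=5e-4)

    def test_bin_centering_matches_reported_convention(self):
        """A sample at -71.3 deg falls in the bin centered at -71.25."""
        fem = free_energy_map([(-71.3, -123.8)])
        assert fem.minimum() == pytest.approx((-71.25, -123.75))

    def test_round_trip_counts_to_dg(self):
        rng = np.random.default_rng(1)
        samples = np.column_stack([rng.uniform(-180, 180, 500),
                                   rng.uniform(-180, 180, 500)])
        fem = free_energy_map(samples)
        assert fem.counts.sum() == 500
        occupied = fem.counts > 0
        rt = R_KCAL * fem.temperature
        back = np.exp(-(fem.dg[occupied] + fem.normalization) / rt)
        assert back == pytest.approx(fem.counts[occupied])

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            free_energy_map([])


class TestSizeDescriptors:
    def test_rg_two_point(self):
        """Two equal masses 2 A apart: Rg = 1 A (by definition)."""

        class FakeAtom:
            element = "C"

        class FakeTopo:
            atoms = [FakeAtom(), FakeAtom()]

        class FakeConf:
            topology = FakeTopo()
            coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])

        assert radius_of_gyration(FakeConf()) == pytest.approx(1.0)

    def test_e2e_within_contour_bound(self):
        conf = build_fixed(PolymerSpec("hyaluronan", 10),
                           INITIAL_DIHEDRALS["hyaluronan"])
        assert end_to_end(conf) <= contour_length(conf)

    def test_rigid_invariance(self):
        conf = build_fixed(PolymerSpec("dermatan", 4),
                           INITIAL_DIHEDRALS["dermatan"])
        moved = conf.copy()
        moved.coords = conf.coords + np.array([10.0, -3.0, 7.0])
        assert end_to_end(moved) == pytest.approx(end_to_end(conf))
        assert radius_of_gyration(moved) == pytest.approx(
            radius_of_gyration(conf))


class TestHistogramMode:
    def test_single_bin(self):
        hist, mode = histogram_mode([10.1, 10.2, 10.3], 0.5)
        assert mode == pytest.approx(10.25)

    def test_tie_breaks_to_lower_center(self):
        hist, mode = histogram_mode([1.1, 1.2, 2.1, 2.2], 1.0)
        assert mode == pytest.approx(1.5)

    def test_uniform_grid_takes_first_bin(self):
        vals = np.arange(0.25, 10.0, 0.5)
        _, mode = histogram_mode(vals, 0.5)
        assert mode == pytest.approx(0.25)

    def test_bins_anchored_at_zero(self):
        hist, mode = histogram_mode([80.1], 0.5)
        assert mode == pytest.approx(80.25)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            histogram_mode([], 0.5)
        with pytest.raises(ValueError):
            histogram_mode([1.0], 0.0)


class TestPercentDifference:
    @pytest.mark.parametrize("a,b,expected", [
        (80.0, 78.0, 2.53), (90.0, 87.0, 3.39), (68.5, 72.0, 4.98),
        (83.5, 81.5, 2.42),
    ])
    def test_reported_table_values(self, a, b, expected):
        """Mean-denominator form reproduces the published values."""
        assert percent_difference(a, b) == pytest.approx(expected, abs=5e-3)

    def test_identity(self):
        assert percent_difference(5.0, 5.0) == 0.0

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)


class TestRegression:
    def test_collinear_gives_one(self):
        e2e = np.linspace(10, 50, 20)
        rg = 0.3 * e2e + 2.0
        assert e2e_rg_r2(e2e, rg) == pytest.approx(1.0)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            e2e_rg_r2([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_too_few_members_raises(self):
        with pytest.raises(ValueError):
            e2e_rg_r2([1.0, 2.0], [1.0, 2.0])


def test_e2e_rg_correlation_decreases_with_length(ens10, ens200):
    """End-to-end vs radius-of-gyration becomes decreasingly linear with
    polymer length: conformations of a long chain with equal end-to-end
    distance span a wider range of Rg."""
    r2_10 = e2e_rg_r2(ens10.stats.e2e, ens10.stats.rg)
    r2_200 = e2e_rg_r2(ens200.stats.e2e, ens200.stats.rg)
    assert r2_10 > r2_200


class TestSubsets:
    def test_all_chair_ensemble_has_no_nonchair_members(self):
        members = [build_fixed(PolymerSpec("hyaluronan", 6),
                               INITIAL_DIHEDRALS["hyaluronan"])]

        def any_non_chair(conf):
            return any(l != "4C1" for ls in ring_pucker_labels(conf).values()
                       for l in ls)

        assert subset_ensemble(members, any_non_chair) == []
        assert subset_ensemble(members, lambda c: True) == members

    def test_basin_membership_matches_manual_count(self):
        """Linkage-basin predicate agrees with brute-force checking."""
        rng = np.random.default_rng(4)
        members = []
        assigns = []
        for _ in range(10):
            phi = float(rng.uniform(-120, -40))
            psi = float(rng.uniform(-180, -80))
            assign = {"GlcAb1-3GlcNAc": (phi, psi),
                      "GlcNAcb1-4GlcA": (-63.75, 118.75)}
            members.append(build_fixed(PolymerSpec("hyaluronan", 6), assign))
            assigns.append((phi, psi))
        center = (-71.25, -123.75)

        def in_basin(conf):
            vals = linkage_dihedrals(conf)["GlcAb1-3GlcNAc"]
            return all(near_basin(phi, psi, center) for phi, psi in vals)

        got = subset_ensemble(members, in_basin)
        expected = [m for m, (phi, psi) in zip(members, assigns)
                    if np.hypot(phi - center[0], psi - center[1]) <= 30.0]
        assert got == expected
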