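"""Chain construction: topology, fixed builds, sampling, extended reference."""

import numpy as np
import pytest

from gagbuilder.analysis import contour_length, end_to_end, linkage_dihedrals
from gagbuilder.builder import (INITIAL_DIHEDRALS, PolymerSpec, build_chain,
                                build_extended_reference, build_fixed,
                                make_topology, template_ring_conformer)
from gagbuilder.pucker import classify_pucker, cremer_pople
from gagbuilder.synthetic import generate_db
from gagbuilder.templates import get_template


@pytest.fixture(scope="module")
def db():
    return generate_db("hyaluronan", n_per_pool=300, seed=21)


class TestTopology:
    def test_hyaluronan_20mer_composition(self):
        """20 residues alternating GlcNAc/GlcA; 19 alternating linkages."""
        topo = make_topology(PolymerSpec("hyaluronan", 20))
        assert topo.n_residues == 20
        sugars = [topo.residue_meta[r][0] for r in range(20)]
        assert sugars[0::2] == ["GlcNAc"] * 10
        assert sugars[1::2] == ["GlcA"] * 10
        types = [lk.linkage_type for lk in topo.linkages]
        assert len(types) == 19
        assert types[0::2] == ["GlcAb1-3GlcNAc"] * 10
        assert types[1::2] == ["GlcNAcb1-4GlcA"] * 9
        topo.validate()

    @pytest.mark.parametrize("gag,expected_types", [
        ("dermatan", {"IdoAa1-3GalNAc", "GalNAcb1-4IdoA"}),
        ("keratan", {"Galb1-4GlcNAc", "GlcNAcb1-3Gal"}),
        ("heparan", {"IdoAa1-4GlcNAc", "GlcNAca1-4IdoA"}),
    ])
    def test_repeat_units(self, gag, expected_types):
        topo = make_topology(PolymerSpec(gag, 8))
        assert {lk.linkage_type for lk in topo.linkages} == expected_types

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            PolymerSpec("hyaluronan", 1)

    def test_unknown_gag_raises(self):
        with pytest.raises(KeyError):
            PolymerSpec("chitin", 10)


class TestTemplates:
    @pytest.mark.parametrize("sugar,anomer,acc,label", [
        ("GlcA", "b", 4, "4C1"), ("GlcNAc", "b", 3, "4C1"),
        ("GlcNAc", "a", 4, "4C1"), ("GalNAc", "b", 3, "4C1"),
        ("Gal", "b", 3, "4C1"), ("IdoA", "a", 4, "1C4"),
    ])
    def test_template_ring_classifies_native_chair(self, sugar, anomer, acc,
                                                   label):
        tpl = get_template(sugar, anomer, acc)
        assert classify_pucker(cremer_pople(tpl.ring_coords())).label == label

    def test_anomeric_torsion_distinguishes_alpha_beta(self):
        """Alpha and beta anomers place the glycosidic O on opposite faces."""
        beta = get_template("GlcNAc", "b", 4)
        alpha = get_template("GlcNAc", "a", 4)
        assert abs(beta.anomeric_torsion - alpha.anomeric_torsion) > 90.0


class TestFixedBuilds:
    @pytest.mark.parametrize("gag,expected", [
        ("hyaluronan", 99.0), ("dermatan", 89.7),
        ("keratan", 85.8), ("heparan", 87.5),
    ])
    def test_initial_conformation_end_to_end(self, gag, expected):
        """Homogeneous-dihedral 20-mers reproduce the classic end-to-end
        distances of the near-extended starting conformations."""
        conf = build_fixed(PolymerSpec(gag, 20), INITIAL_DIHEDRALS[gag])
        assert end_to_end(conf) == pytest.approx(expected, rel=0.03)

    def test_deterministic_bit_for_bit(self):
        spec = PolymerSpec("heparan", 12)
        c1 = build_fixed(spec, INITIAL_DIHEDRALS["heparan"])
        c2 = build_fixed(spec, INITIAL_DIHEDRALS["heparan"])
        assert np.array_equal(c1.coords, c2.coords)

    def test_measured_dihedrals_equal_assignment(self):
        assign = {"GlcAb1-3GlcNAc": (-100.0, 45.0),
                  "GlcNAcb1-4GlcA": (30.0, -170.0)}
        conf = build_fixed(PolymerSpec("hyaluronan", 8), assign)
        for lt, vals in linkage_dihedrals(conf).items():
            for phi, psi in vals:
                assert phi == pytest.approx(assign[lt][0], abs=1e-6)
                assert psi == pytest.approx(assign[lt][1], abs=1e-6)

    def test_incomplete_assignment_raises(self):
        with pytest.raises(KeyError):
            build_fixed(PolymerSpec("hyaluronan", 8),
                        {"GlcAb1-3GlcNAc": (-80.0, -150.0)})


class TestSampledBuilds:
    def test_round_trip_contract(self, db):
        """Measured phi/psi of every junction equal the sampled values."""
        spec = PolymerSpec("hyaluronan", 10)
        rng = np.random.default_rng(5)
        conf = build_chain(spec, db, rng)
        from gagbuilder.conformers import extract_linkage
        sampled = conf.provenance["linkages"]
        assert len(sampled) == 9
        for j in range(9):
            lc = extract_linkage(conf, j)
            pool = db.linkage_pools[lc.linkage_type]
            src = [c for c in pool if c.source == sampled[j]]
            assert len(src) == 1
            assert lc.phi == pytest.approx(src[0].phi, abs=1e-6)
            assert lc.psi == pytest.approx(src[0].psi, abs=1e-6)
            assert lc.c1_o_length == pytest.approx(src[0].c1_o_length,
                                                   abs=1e-9)

    def test_provenance_records_all_draws(self, db):
        conf = build_chain(PolymerSpec("hyaluronan", 12), db,
                           np.random.default_rng(1))
        assert len(conf.provenance["rings"]) == 12
        assert len(conf.provenance["linkages"]) == 11

    def test_seed_determinism(self, db):
        spec = PolymerSpec("hyaluronan", 10)
        c1 = build_chain(spec, db, np.random.default_rng(9))
        c2 = build_chain(spec, db, np.random.default_rng(9))
        assert np.array_equal(c1.coords, c2.coords)

    def test_adjacent_linkage_independence(self, db):
        """Sample correlation between adjacent phi values is ~0 (the draws
        are independent by construction)."""
        spec = PolymerSpec("hyaluronan", 20)
        phis = []
        for k in range(400):
            conf = build_chain(spec, db, np.random.default_rng([31, k]))
            vals = linkage_dihedrals(conf)["GlcAb1-3GlcNAc"]
            phis.append([v[0] for v in vals])
        phis = np.array(phis)
        r = np.corrcoef(phis[:, 0], phis[:, 1])[0, 1]
        assert abs(r) < 3.0 / np.sqrt(len(phis))

    def test_contour_bound(self, db):
        spec = PolymerSpec("hyaluronan", 20)
        for k in range(25):
            conf = build_chain(spec, db, np.random.default_rng([41, k]))
            assert end_to_end(conf) <= contour_length(conf) + 1e-9


class TestExtendedReference:
    def test_dominates_random_chains(self, db):
        """The extended reference is at least as long as sampled chains."""
        spec = PolymerSpec("hyaluronan", 10)
        ext = build_extended_reference(spec, db)
        d_ext = end_to_end(ext)
        rng = np.random.default_rng(2)
        draws = [end_to_end(build_chain(spec, db, rng)) for _ in range(1000)]
        assert d_ext >= max(draws)

    def test_monotone_in_length(self, db):
        e10 = end_to_end(build_extended_reference(PolymerSpec("hyaluronan", 10), db))
        e20 = end_to_end(build_extended_reference(PolymerSpec("hyaluronan", 20), db))
        assert e20 > e10

    def test_deterministic(self, db):
        spec = PolymerSpec("hyaluronan", 8)
        a = build_extended_reference(spec, db)
        b = build_extended_reference(spec, db)
        assert np.array_equal(a.coords, b.coords)
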