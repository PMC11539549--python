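"""Geometry construction: stagger architecture, mineral slots, AGE
insertion, diagnostic report."""

import numpy as np
import pytest

from fibrilmech.fibril import (BOND_AGE, BOND_COLLAGEN, BOND_GRIP,
                               SPECIES_COLLAGEN, SPECIES_GRIP,
                               SPECIES_MINERAL, BuildConfig, CrosslinkSpec,
                               MineralSpec, build_fibril, insert_crosslinks,
                               make_fixture, mineralize, validate_geometry)


def desk_config(**kw):
    base = dict(particles_per_molecule=58, molecules_per_cross_section=19,
                grip_particles_per_molecule_end=10, seed=0)
    base.update(kw)
    return BuildConfig(**base)


@pytest.fixture(scope="module")
def desk_system():
    return build_fibril(desk_config())


class TestBuild:
    def test_default_molecule_has_218_backbone_particles(self):
        system = build_fibril(BuildConfig())
        rep = validate_geometry(system)
        assert set(rep.particles_per_molecule.values()) == {218}

    def test_default_cross_section_has_155_molecules(self):
        system = build_fibril(BuildConfig())
        rep = validate_geometry(system)
        assert rep.molecules_per_cross_section == 155

    def test_gap_to_period_ratio_is_exactly_0_6(self, desk_system):
        rep = validate_geometry(desk_system)
        assert rep.gap_to_period_ratio == pytest.approx(0.600, abs=1e-6)

    def test_backbone_spacing_is_equilibrium_distance(self, desk_system):
        i, j = desk_system.bonds[:, 0], desk_system.bonds[:, 1]
        col = desk_system.bond_class == BOND_COLLAGEN
        r = np.linalg.norm(desk_system.positions[j[col]]
                           - desk_system.positions[i[col]], axis=1)
        np.testing.assert_allclose(r, 14.00, rtol=0, atol=1e-9)

    def test_all_five_stagger_phases_present(self, desk_system):
        assert set(desk_system.column_phase.tolist()) == {0, 1, 2, 3, 4}

    def test_single_molecule_build_is_a_gripped_chain(self):
        system = build_fibril(desk_config(molecules_per_cross_section=1,
                                          grip_particles_per_molecule_end=4))
        assert system.n_molecules == 1
        assert np.sum(system.grip_end == -1) == 4
        assert np.sum(system.grip_end == +1) == 4
        assert system.gap_lower.size == 0

    def test_determinism(self):
        a = build_fibril(desk_config())
        b = build_fibril(desk_config())
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.bonds, b.bonds)

    def test_minimum_interparticle_distance(self, desk_system):
        rep = validate_geometry(desk_system)
        assert rep.min_interparticle_distance >= 0.5 * 14.00

    def test_bond_table_invariants(self, desk_system):
        b = desk_system.bonds
        assert np.all(b[:, 0] != b[:, 1])
        assert len({tuple(sorted(x)) for x in b.tolist()}) == len(b)
        # collagen bonds join consecutive backbone particles of one molecule
        col = desk_system.bond_class == BOND_COLLAGEN
        mi = desk_system.molecule_id
        bi, bj = b[col, 0], b[col, 1]
        assert np.all(mi[bi] == mi[bj])
        assert np.all(np.abs(desk_system.backbone_index[bi]
                             - desk_system.backbone_index[bj]) == 1)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            BuildConfig(particles_per_molecule=2)
        with pytest.raises(ValueError):
            BuildConfig(gap_fraction=0.0)
        with pytest.raises(ValueError):
            BuildConfig(gap_fraction=1.2)
        with pytest.raises(ValueError):
            BuildConfig(particle_spacing=-1.0)

    def test_periodic_build_has_no_grips_and_wrap_gap(self):
        system = build_fibril(desk_config(periodic_axial=True))
        assert np.all(system.grip_end == 0)
        assert np.all(system.species != SPECIES_GRIP)
        # every column shows exactly one gap per period, incl. the seam
        assert system.gap_lower.size == system.n_columns


class TestMineralize:
    def test_zero_content_adds_no_particles(self, desk_system):
        out = mineralize(desk_system, MineralSpec(content_percent=0))
        assert np.sum(out.species == SPECIES_MINERAL) == 0
        assert out.mineral_content_achieved == 0.0

    def test_toy_gap_edge_slot_oracle(self, toy_gap):
        # gap 100 A, spacing 10, transition 10, target 40%:
        # two particles per side, occupied length 2*(10+10) = 40 A
        out = mineralize(toy_gap, MineralSpec(
            pattern="edge", content_percent=40,
            mineral_spacing=10.0, transition_spacing=10.0))
        minerals = np.where(out.species == SPECIES_MINERAL)[0]
        assert minerals.size == 4
        assert out.mineral_content_achieved == pytest.approx(40.0)
        x = np.sort(out.positions[minerals, 0])
        x_lo = out.positions[out.gap_lower[0], 0]
        np.testing.assert_allclose(x - x_lo, [10, 20, 80, 90])

    def test_full_fill_quantization_bound(self, toy_gap):
        # brute-force slot enumeration: with t = spacing = 10 on a
        # 100 A gap the densest admissible edge packing occupies 90 A
        out = mineralize(toy_gap, MineralSpec(
            pattern="edge", content_percent=100,
            mineral_spacing=10.0, transition_spacing=10.0))
        assert out.mineral_content_achieved == pytest.approx(90.0)
        assert 100.0 - out.mineral_content_achieved <= 10.0 / 100.0 * 100.0

    def test_achieved_content_never_exceeds_request(self, desk_system):
        for target in (10, 15, 33, 40, 77, 100):
            out = mineralize(desk_system,
                             MineralSpec(pattern="edge",
                                         content_percent=target))
            assert out.mineral_content_achieved <= target + 1e-9

    def test_minerals_carry_no_bonds(self, desk_system):
        out = mineralize(desk_system, MineralSpec(content_percent=40))
        minerals = np.where(out.species == SPECIES_MINERAL)[0]
        assert not np.isin(out.bonds, minerals).any()

    def test_double_row_doubles_particle_count(self, desk_system):
        edge = mineralize(desk_system, MineralSpec(pattern="edge",
                                                   content_percent=30))
        dbl = mineralize(desk_system, MineralSpec(pattern="double_row",
                                                  content_percent=30))
        assert np.sum(dbl.species == SPECIES_MINERAL) == \
            2 * np.sum(edge.species == SPECIES_MINERAL)

    def test_sparse_half_uses_fewer_particles_at_same_content(self,
                                                              desk_system):
        edge = mineralize(desk_system, MineralSpec(pattern="edge",
                                                   content_percent=60))
        sparse = mineralize(desk_system, MineralSpec(pattern="sparse_half",
                                                     content_percent=60))
        n_e = np.sum(edge.species == SPECIES_MINERAL)
        n_s = np.sum(sparse.species == SPECIES_MINERAL)
        assert n_s < n_e

    def test_center_pattern_grows_from_midpoint(self, toy_gap):
        out = mineralize(toy_gap, MineralSpec(
            pattern="center", content_percent=20,
            mineral_spacing=10.0, transition_spacing=10.0))
        minerals = np.where(out.species == SPECIES_MINERAL)[0]
        x_lo = out.positions[out.gap_lower[0], 0]
        mid = x_lo + 50.0
        np.testing.assert_allclose(
            np.sort(out.positions[minerals, 0]), [mid - 5.0, mid + 5.0])

    def test_double_mineralization_rejected(self, desk_system):
        once = mineralize(desk_system, MineralSpec(content_percent=20))
        with pytest.raises(ValueError):
            mineralize(once, MineralSpec(content_percent=20))

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            MineralSpec(pattern="diagonal")

    def test_minimum_spacing_respected(self, desk_system):
        out = mineralize(desk_system, MineralSpec(pattern="double_row",
                                                  content_percent=100))
        rep = validate_geometry(out)
        assert rep.min_interparticle_distance >= \
            0.5 * min(14.0, MineralSpec().mineral_spacing)


class TestCrosslinks:
    def test_zero_request_adds_nothing(self, desk_system):
        out = insert_crosslinks(desk_system, CrosslinkSpec(n_per_molecule=0))
        assert out.n_age_bonds == 0

    def test_exact_count_per_molecule(self, desk_system):
        out = insert_crosslinks(desk_system,
                                CrosslinkSpec(n_per_molecule=10, seed=3))
        assert out.n_age_bonds == 10 * desk_system.n_molecules == 190

    def test_links_join_distinct_neighboring_molecules(self, desk_system):
        out = insert_crosslinks(desk_system,
                                CrosslinkSpec(n_per_molecule=5, seed=3))
        age = out.bonds[out.bond_class == BOND_AGE]
        mi = out.molecule_id
        assert np.all(mi[age[:, 0]] != mi[age[:, 1]])
        assert np.all(out.species[age].ravel() == SPECIES_COLLAGEN)

    def test_endpoints_confined_to_central_95_percent(self, desk_system):
        out = insert_crosslinks(desk_system,
                                CrosslinkSpec(n_per_molecule=10, seed=5))
        age = out.bonds[out.bond_class == BOND_AGE]
        bb = out.backbone_index[age.ravel()]
        n = 58
        lo = np.ceil(0.025 * (n - 1))
        assert bb.min() >= lo
        assert bb.max() <= (n - 1) - lo

    def test_reproducible_for_fixed_seed(self, desk_system):
        a = insert_crosslinks(desk_system, CrosslinkSpec(n_per_molecule=8,
                                                         seed=11))
        b = insert_crosslinks(desk_system, CrosslinkSpec(n_per_molecule=8,
                                                         seed=11))
        assert np.array_equal(a.bonds, b.bonds)

    def test_overdense_request_raises(self):
        system = build_fibril(desk_config(particles_per_molecule=12,
                                          molecules_per_cross_section=7))
        with pytest.raises(RuntimeError):
            insert_crosslinks(system, CrosslinkSpec(n_per_molecule=40,
                                                    seed=1))


class TestValidateGeometry:
    def test_unmineralized_content_is_zero(self, desk_system):
        assert validate_geometry(desk_system).mineral_content_percent == 0.0

    def test_report_invariant_under_rigid_translation(self, desk_system):
        moved = desk_system.copy()
        moved.positions = moved.positions + np.array([123.4, -7.7, 3.1])
        a = validate_geometry(desk_system)
        b = validate_geometry(moved)
        assert b.gap_to_period_ratio == pytest.approx(a.gap_to_period_ratio)
        assert b.measured_stagger_period == pytest.approx(
            a.measured_stagger_period)
        assert b.molecules_per_cross_section == a.molecules_per_cross_section


class TestFixtures:
    def test_pair_fixture(self):
        s = make_fixture("pair")
        assert s.n_particles == 2
        assert len(s.bonds) == 1
        assert np.linalg.norm(s.positions[1] - s.positions[0]) == 14.00

    def test_mini7_covers_all_phases(self, mini7):
        assert mini7.n_molecules == 7
        assert set(mini7.column_phase.tolist()) == {0, 1, 2, 3, 4}

    def test_fixture_determinism(self):
        a = make_fixture("mini7")
        b = make_fixture("mini7")
        assert np.array_equal(a.positions, b.positions)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_fixture("nonsense")
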