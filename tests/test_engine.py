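"""Engine correctness: neighbor lists, force oracle equivalence,
integrators, thermostat, minimizer, axial barostat."""

import numpy as np
import pytest

from conftest import naive_forces
from fibrilmech.engine import Engine, SimState, kinetic_temperature
from fibrilmech.fibril import (BuildConfig, CrosslinkSpec, MineralSpec,
                               build_fibril, insert_crosslinks, make_fixture,
                               mineralize, _bare_chain)
from fibrilmech.force_field import COLLAGEN_BOND
from fibrilmech.units import FORCE_TO_ACC, KB, MVV_TO_KCAL


def small_random_system(seed=0, n_mol=7, ppm=14):
    """A perturbed, mineralized, cross-linked miniature fibril."""
    cfg = BuildConfig(particles_per_molecule=ppm,
                      molecules_per_cross_section=n_mol,
                      grip_particles_per_molecule_end=2, seed=seed)
    s = build_fibril(cfg)
    s = mineralize(s, MineralSpec(pattern="edge", content_percent=50))
    s = insert_crosslinks(s, CrosslinkSpec(n_per_molecule=2, seed=seed))
    rng = np.random.default_rng(seed)
    s.positions = s.positions + rng.normal(scale=0.8, size=s.positions.shape)
    return s


class TestNeighborList:
    def test_distant_pair_not_listed(self):
        s = make_fixture("pair")
        s.positions[1, 0] = 500.0
        eng = Engine(s)
        st = eng.init_state()
        nl = eng.build_neighbor_list(st)
        assert nl.n_pairs == 0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        s = _bare_chain(2, 14.0)
        # 200 unbonded random particles in a box comparable to cutoffs
        n = 200
        pos = rng.uniform(0, 60.0, size=(n, 3))
        s.positions = pos
        s.species = np.zeros(n, np.int8)
        s.molecule_id = np.arange(n, dtype=np.int32)
        s.column_id = np.zeros(n, np.int32)
        s.stagger_phase = np.zeros(n, np.int8)
        s.backbone_index = np.full(n, -1, np.int32)
        s.grip_end = np.zeros(n, np.int8)
        s.bonds = np.array([[0, 1]], dtype=np.int32)
        s.bond_class = np.zeros(1, np.int8)
        s.bond_broken = np.zeros(1, bool)
        s.bond_max_extension = np.zeros(1)
        s.angles = np.empty((0, 3), np.int32)
        s.angle_phi0 = np.empty(0)
        eng = Engine(s)
        st = eng.init_state()
        nl = eng.build_neighbor_list(st)
        got = set(zip(nl.i.tolist(), nl.j.tolist()))
        rc = eng.max_cutoff + eng.skin
        expect = set()
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) == (0, 1):
                    continue
                if np.linalg.norm(pos[j] - pos[i]) <= rc:
                    expect.add((i, j))
        assert got == expect

    def test_bonded_neighbors_excluded(self):
        s = make_fixture("mini7")
        eng = Engine(s)
        nl = eng.build_neighbor_list(eng.init_state())
        listed = set(zip(nl.i.tolist(), nl.j.tolist()))
        for i, j in s.bonds:
            assert (min(i, j), max(i, j)) not in listed


class TestForceOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_vectorized_matches_naive_loop(self, seed):
        s = small_random_system(seed)
        eng = Engine(s, use_compiled_kernels=False)
        st = eng.init_state()
        eng.compute_forces(st, allow_breaking=False)
        ref = naive_forces(s, st.positions)
        scale = np.abs(ref).max()
        np.testing.assert_allclose(st.forces, ref, rtol=0,
                                   atol=1e-10 * scale)

    def test_compiled_kernels_match_numpy_path(self):
        s = small_random_system(3)
        e1 = Engine(s.copy(), use_compiled_kernels=True)
        e2 = Engine(s.copy(), use_compiled_kernels=False)
        st1, st2 = e1.init_state(), e2.init_state()
        en1 = e1.compute_forces(st1, allow_breaking=False)
        en2 = e2.compute_forces(st2, allow_breaking=False)
        scale = np.abs(st2.forces).max()
        np.testing.assert_allclose(st1.forces, st2.forces, rtol=0,
                                   atol=1e-12 * scale)
        assert en1.total == pytest.approx(en2.total, rel=1e-12)

    def test_total_force_is_zero(self):
        s = small_random_system(1)
        eng = Engine(s)
        st = eng.init_state()
        eng.compute_forces(st, allow_breaking=False)
        np.testing.assert_allclose(st.forces.sum(axis=0), 0.0, atol=1e-9)

    def test_forces_are_energy_gradient(self):
        s = small_random_system(2)
        eng = Engine(s, use_compiled_kernels=False)
        st = eng.init_state()
        e0 = eng.compute_forces(st, allow_breaking=False).total
        f = st.forces.copy()
        rng = np.random.default_rng(0)
        h = 1e-6
        for p in rng.choice(s.n_particles, 5, replace=False):
            for dim in range(3):
                up = st.copy()
                up.positions[p, dim] += h
                dn = st.copy()
                dn.positions[p, dim] -= h
                eu = eng.compute_forces(up, allow_breaking=False).total
                ed = eng.compute_forces(dn, allow_breaking=False).total
                fd = -(eu - ed) / (2 * h)
                assert f[p, dim] == pytest.approx(fd, rel=1e-4, abs=1e-4)

    def test_equilibrium_interior_bond_forces_vanish(self):
        # freshly built chain: every bond at r0, angles at 180
        ch = _bare_chain(10, 14.0)
        eng = Engine(ch)
        st = eng.init_state()
        eng.compute_forces(st)
        np.testing.assert_allclose(st.forces, 0.0, atol=1e-10)


class TestIntegrators:
    def test_free_particle_moves_uniformly(self):
        ch = _bare_chain(2, 14.0)
        ch.bonds = np.empty((0, 2), np.int32)
        ch.bond_class = np.empty(0, np.int8)
        ch.bond_broken = np.empty(0, bool)
        ch.bond_max_extension = np.empty(0)
        ch.angles = np.empty((0, 3), np.int32)
        ch.angle_phi0 = np.empty(0)
        ch.positions[1, 0] = 500.0
        eng = Engine(ch)
        st = eng.init_state()
        st.velocities[0] = [1e-3, 0, 0]
        for _ in range(100):
            eng.step_nve(st, 10.0)
        assert st.positions[0, 0] == pytest.approx(1e-3 * 1000.0, rel=1e-12)

    def test_harmonic_dimer_period(self):
        s = make_fixture("pair")
        eng = Engine(s)
        st = eng.init_state()
        st.positions[1, 0] += 0.1   # small stretch, first branch
        eng.compute_forces(st)
        mu = 1548.0 / 2.0
        period = 2 * np.pi * np.sqrt(mu / (COLLAGEN_BOND.k0 * FORCE_TO_ACC))
        dt = period / 200.0
        # count zero crossings of the extension over ~8 periods
        prev = 0.1
        crossings = []
        for k in range(1700):
            eng.step_nve(st, dt)
            ext = st.positions[1, 0] - st.positions[0, 0] - 14.0
            if prev > 0 >= ext or prev < 0 <= ext:
                crossings.append(st.time)
            prev = ext
        measured = 2 * np.mean(np.diff(crossings))
        assert measured == pytest.approx(period, rel=1e-3)

    def test_nve_energy_conservation(self):
        ch = _bare_chain(20, 14.0)
        eng = Engine(ch)
        rng = np.random.default_rng(1)
        st = eng.init_state(T=300.0, rng=rng)
        en = eng.compute_forces(st)

        def total(e):
            ke = 0.5 * np.sum(st.masses[:, None]
                              * st.velocities ** 2) * MVV_TO_KCAL
            return ke + e.total

        e0 = total(en)
        worst = 0.0
        for _ in range(10000):
            en = eng.step_nve(st, 10.0)
            worst = max(worst, abs(total(en) - e0))
        assert worst / abs(e0) < 1e-4

    def test_nve_momentum_conservation(self):
        ch = _bare_chain(20, 14.0)
        eng = Engine(ch)
        st = eng.init_state(T=300.0, rng=np.random.default_rng(3))
        p0 = (st.masses[:, None] * st.velocities).sum(axis=0)
        for _ in range(2000):
            eng.step_nve(st, 10.0, want_energy=False)
        p1 = (st.masses[:, None] * st.velocities).sum(axis=0)
        assert np.abs(p1 - p0).max() < 1e-8 * 2000


class TestLangevin:
    def _free_gas(self, n=1000):
        ch = _bare_chain(2, 14.0)
        rng = np.random.default_rng(0)
        # dilute: essentially no pair within cutoff
        ch.positions = rng.uniform(0, 4000.0, size=(n, 3))
        ch.species = np.zeros(n, np.int8)
        ch.molecule_id = np.arange(n, dtype=np.int32)
        ch.column_id = np.zeros(n, np.int32)
        ch.stagger_phase = np.zeros(n, np.int8)
        ch.backbone_index = np.full(n, -1, np.int32)
        ch.grip_end = np.zeros(n, np.int8)
        ch.bonds = np.empty((0, 2), np.int32)
        ch.bond_class = np.empty(0, np.int8)
        ch.bond_broken = np.empty(0, bool)
        ch.bond_max_extension = np.empty(0)
        ch.angles = np.empty((0, 3), np.int32)
        ch.angle_phi0 = np.empty(0)
        return ch

    def test_equipartition_at_300K(self):
        gas = self._free_gas(1000)
        eng = Engine(gas)
        rng = np.random.default_rng(11)
        st = eng.init_state(T=300.0, rng=rng)
        temps = []
        for k in range(100000):
            eng.step_langevin(st, 10.0, 300.0, 1000.0, rng,
                              want_energy=False)
            if k % 100 == 0 and k > 10000:
                temps.append(kinetic_temperature(st))
        t_mean = float(np.mean(temps))
        assert abs(t_mean - 300.0) / 300.0 < 0.05

    def test_zero_temperature_overdamped_velocity_decay(self):
        gas = self._free_gas(50)
        eng = Engine(gas)
        rng = np.random.default_rng(2)
        st = eng.init_state(T=300.0, rng=rng)
        speeds = [float(np.abs(st.velocities).max())]
        for _ in range(200):
            eng.step_langevin(st, 10.0, 0.0, 20.0, rng, want_energy=False)
            speeds.append(float(np.abs(st.velocities).max()))
        assert speeds[-1] < 1e-6 * speeds[0]
        assert all(b <= a * (1 + 1e-12) for a, b in zip(speeds, speeds[1:]))

    def test_identical_seeds_identical_trajectories(self):
        s = make_fixture("mini7")
        out = []
        for _ in range(2):
            eng = Engine(s.copy())
            rng = np.random.default_rng(42)
            st = eng.init_state(T=300.0, rng=rng)
            for _ in range(50):
                eng.step_langevin(st, 10.0, 300.0, 1000.0, rng,
                                  want_energy=False)
            out.append(st.positions.copy())
        assert np.array_equal(out[0], out[1])

    def test_invalid_parameters_rejected(self):
        s = make_fixture("pair")
        eng = Engine(s)
        st = eng.init_state()
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            eng.step_langevin(st, 10.0, -1.0, 1000.0, rng)
        with pytest.raises(ValueError):
            eng.step_langevin(st, 10.0, 300.0, 0.0, rng)


class TestKineticTemperature:
    def test_zero_velocities_give_zero(self):
        s = make_fixture("pair")
        eng = Engine(s)
        st = eng.init_state()
        assert kinetic_temperature(st) == 0.0

    def test_definition_single_particle(self):
        s = make_fixture("pair")
        eng = Engine(s)
        st = eng.init_state()
        v2 = 3 * KB * 300.0 * FORCE_TO_ACC / 1548.0  # KE = (3/2) kB 300
        st.velocities[0, 0] = np.sqrt(v2)
        assert kinetic_temperature(st, mask=np.array([True, False])) == \
            pytest.approx(300.0)

    def test_quadratic_in_speed(self):
        s = make_fixture("mini7")
        eng = Engine(s)
        st = eng.init_state(T=100.0, rng=np.random.default_rng(0))
        t1 = kinetic_temperature(st)
        st.velocities *= 2.0
        assert kinetic_temperature(st) == pytest.approx(4 * t1)

    def test_no_free_dof_rejected(self):
        s = make_fixture("pair")
        eng = Engine(s)
        st = eng.init_state()
        with pytest.raises(ValueError):
            kinetic_temperature(st, n_constrained_dof=6)


class TestMinimizer:
    def test_already_minimal_takes_no_steps(self):
        s = make_fixture("pair")
        eng = Engine(s)
        st = eng.init_state()
        assert eng.minimize(st, force_tol=1e-6) == 0

    def test_perturbed_bond_returns_to_equilibrium(self):
        s = make_fixture("pair")
        eng = Engine(s)
        st = eng.init_state()
        st.positions[1, 0] += 1.0
        eng.compute_forces(st, allow_breaking=False)
        eng.minimize(st, force_tol=1e-6, max_iter=5000)
        r = st.positions[1, 0] - st.positions[0, 0]
        assert abs(r - 14.0) < 1e-3

    def test_no_breakage_during_minimization(self):
        s = make_fixture("pair")
        eng = Engine(s)
        st = eng.init_state()
        st.positions[1, 0] = 14.0 + 10.0  # beyond r_break if evaluated raw
        eng.minimize(st, force_tol=1e-4, max_iter=5000)
        assert not s.bond_broken.any()
        r = st.positions[1, 0] - st.positions[0, 0]
        assert abs(r - 14.0) < 1e-2

    def test_energy_nonincreasing(self):
        s = small_random_system(4)
        eng = Engine(s)
        st = eng.init_state()
        energies = []
        e = eng.compute_forces(st, allow_breaking=False,
                               cap_bond_extension=True).total
        energies.append(e)
        for _ in range(40):
            eng.minimize(st, force_tol=0.0, max_iter=1)
            energies.append(eng.compute_forces(
                st, allow_breaking=False, cap_bond_extension=True).total)
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))


class TestAxialRescale:
    def _periodic_chain(self):
        cfg = BuildConfig(particles_per_molecule=12,
                          molecules_per_cross_section=1,
                          grip_particles_per_molecule_end=0,
                          periodic_axial=True)
        return build_fibril(cfg)

    def test_requires_periodicity(self):
        s = make_fixture("pair")
        eng = Engine(s)
        st = eng.init_state()
        with pytest.raises(ValueError):
            eng.rescale_box_axial(st)

    def test_prestretched_chain_relaxes_toward_zero_stress(self):
        s = self._periodic_chain()
        eng = Engine(s)
        st = eng.init_state()
        st.positions[:, 0] *= 1.02
        st.box_length *= 1.02
        eng.build_neighbor_list(st)
        stresses = [abs(eng.axial_stress(st))]
        for _ in range(1000):
            eng.rescale_box_axial(st, coupling=1e-3, dt=10.0)
            stresses.append(abs(eng.axial_stress(st)))
        assert stresses[-1] < 0.02 * stresses[0]
        # |stress| decreases monotonically over the relaxation
        coarse = stresses[::100]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(coarse, coarse[1:]))

    def test_zero_stress_means_no_rescale(self):
        s = self._periodic_chain()
        eng = Engine(s)
        st = eng.init_state()
        # built at equilibrium: axial stress ~ 0, strain step ~ 0
        strain = eng.rescale_box_axial(st, coupling=1e-3, dt=10.0)
        assert abs(strain) < 1e-9

    def test_transverse_coordinates_preserved(self):
        s = self._periodic_chain()
        eng = Engine(s)
        st = eng.init_state()
        st.positions[:, 0] *= 1.01
        st.box_length *= 1.01
        eng.build_neighbor_list(st)
        yz0 = st.positions[:, 1:].copy()
        eng.rescale_box_axial(st, coupling=1e-2, dt=10.0)
        assert np.array_equal(st.positions[:, 1:], yz0)
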