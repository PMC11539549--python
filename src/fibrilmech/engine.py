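"""Particle-dynamics engine: neighbor lists, force accumulation,
integrators, thermostat, minimizer.

Real-style units throughout (A, fs, amu, kcal/mol; see
:mod:`fibrilmech.units`).  The engine binds to one
:class:`~fibrilmech.fibril.FibrilSystem`; topology changes (inserting
cross-links, adding mineral) require constructing a new engine.

Non-bonded interactions exclude directly bonded (1-2) pairs; 1-3 pairs
are kept, the angle term already regularizes them and at the default
geometry they lie beyond the pair cutoffs anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels as _kern
from . import force_field as ff_mod
from .fibril import (FibrilSystem, SPECIES_MINERAL,
                     BOND_COLLAGEN, BOND_GRIP, BOND_AGE)
from .force_field import ForceField, default_force_field
from .units import FORCE_TO_ACC, MVV_TO_KCAL, KB

__all__ = ["SimState", "NeighborList", "EnergyBreakdown", "Engine",
           "kinetic_temperature", "maxwell_velocities"]


@dataclass
class SimState:
    """Dynamic state of the particle system."""

    positions: np.ndarray        # (N, 3) A
    velocities: np.ndarray       # (N, 3) A/fs
    forces: np.ndarray           # (N, 3) kcal/mol/A
    masses: np.ndarray           # (N,) amu
    time: float = 0.0            # fs
    box_length: float = 0.0
    periodic_axial: bool = False

    def copy(self) -> "SimState":
        return SimState(self.positions.copy(), self.velocities.copy(),
                        self.forces.copy(), self.masses.copy(), self.time,
                        self.box_length, self.periodic_axial)


@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    pair: float = 0.0

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.pair


@dataclass
class NeighborList:
    """Candidate non-bonded pairs within cutoff+skin at build time."""

    i: np.ndarray
    j: np.ndarray
    pair_class: np.ndarray      # index into the engine's pair-spec table
    skin: float
    ref_positions: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.i.size)


def maxwell_velocities(masses: np.ndarray, T: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocity draw at temperature ``T`` (K)."""
    if T < 0:
        raise ValueError("temperature must be non-negative")
    std = np.sqrt(KB * max(T, 0.0) * FORCE_TO_ACC / masses)
    return rng.normal(size=(masses.size, 3)) * std[:, None]


def kinetic_temperature(state: SimState, n_constrained_dof: int = 0,
                        mask: Optional[np.ndarray] = None) -> float:
    """Instantaneous kinetic temperature 2*KE/(kB*dof), K."""
    if mask is None:
        mask = np.ones(state.masses.size, dtype=bool)
    n = int(np.sum(mask))
    dof = 3 * n - n_constrained_dof
    if dof <= 0:
        raise ValueError("no free degrees of freedom")
    ke = 0.5 * np.sum(state.masses[mask, None]
                      * state.velocities[mask] ** 2) * MVV_TO_KCAL
    return 2.0 * ke / (KB * dof)


class Engine:
    """Force evaluation and time stepping for one fibril system."""

    # species-pair -> pair-spec index (0 col-col, 1 hap-hap, 2 col-hap);
    # grip particles interact as collagen
    _PAIR_CLASS_OF_SPECIES = np.array([[0, 0, 2],
                                       [0, 0, 2],
                                       [2, 2, 1]], dtype=np.int8)

    def __init__(self, system: FibrilSystem,
                 force_field: Optional[ForceField] = None,
                 skin: float = 3.0,
                 use_compiled_kernels: Optional[bool] = None) -> None:
        self.system = system
        self.ff = force_field if force_field is not None else \
            default_force_field()
        self.skin = float(skin)
        self.use_compiled_kernels = _kern.HAVE_NUMBA \
            if use_compiled_kernels is None else bool(use_compiled_kernels)
        n = system.n_particles
        self.free_mask = np.ones(n, dtype=bool)

        self._bond_i = system.bonds[:, 0].astype(np.int64)
        self._bond_j = system.bonds[:, 1].astype(np.int64)
        spec_of = {BOND_COLLAGEN: self.ff.collagen_bond,
                   BOND_GRIP: self.ff.grip_bond,
                   BOND_AGE: self.ff.age}
        self._bond_groups = [
            (spec_of[cls], np.where(system.bond_class == cls)[0])
            for cls in (BOND_COLLAGEN, BOND_GRIP, BOND_AGE)
            if np.any(system.bond_class == cls)]
        # flat per-bond parameter arrays for the hot path
        nb = self._bond_i.size
        self._b_r0 = np.empty(nb)
        self._b_r1 = np.empty(nb)
        self._b_rb = np.empty(nb)
        self._b_k0 = np.empty(nb)
        self._b_k1 = np.empty(nb)
        self._b_a = np.empty(nb)
        self._b_fb = np.empty(nb)
        self._b_cap = np.empty(nb)
        for spec, idx in self._bond_groups:
            self._b_r0[idx] = spec.r0
            self._b_r1[idx] = spec.r1
            self._b_rb[idx] = spec.r_break
            self._b_k0[idx] = spec.k0
            self._b_k1[idx] = spec.k1
            self._b_a[idx] = spec.a
            self._b_fb[idx] = spec.f_break
            self._b_cap[idx] = ff_mod.bond_work_capacity(spec)

        self._ang_i = system.angles[:, 0].astype(np.int64)
        self._ang_j = system.angles[:, 1].astype(np.int64)
        self._ang_k = system.angles[:, 2].astype(np.int64)
        self._ang_phi0 = np.deg2rad(system.angle_phi0)

        self._pair_specs = (self.ff.col_col, self.ff.hap_hap, self.ff.col_hap)
        self._pair_eps = np.array([s.epsilon for s in self._pair_specs])
        self._pair_sigma = np.array([s.sigma for s in self._pair_specs])
        self._pair_lam = np.array([s.lam for s in self._pair_specs])
        self._pair_cut = np.array([s.cutoff for s in self._pair_specs])
        self.max_cutoff = float(self._pair_cut.max())

        # 1-2 exclusions, encoded as i*n + j with i < j
        bi = np.minimum(self._bond_i, self._bond_j)
        bj = np.maximum(self._bond_i, self._bond_j)
        self._excluded = set((bi * n + bj).tolist())

        self.masses = np.where(system.species == SPECIES_MINERAL,
                               self.ff.mass_mineral,
                               self.ff.mass_collagen).astype(float)
        self.nlist: Optional[NeighborList] = None
        self.last_virial_xx = 0.0

    # -- state ------------------------------------------------------------

    def init_state(self, T: float = 0.0,
                   rng: Optional[np.random.Generator] = None) -> SimState:
        if rng is None:
            rng = np.random.default_rng(0)
        v = maxwell_velocities(self.masses, T, rng) if T > 0 else \
            np.zeros((self.masses.size, 3))
        state = SimState(positions=self.system.positions.copy(),
                         velocities=v,
                         forces=np.zeros((self.masses.size, 3)),
                         masses=self.masses.copy(),
                         box_length=self.system.box_length,
                         periodic_axial=self.system.periodic_axial)
        self.compute_forces(state)
        return state

    # -- neighbor list -----------------------------------------------------

    def _min_image(self, d: np.ndarray, box: float) -> np.ndarray:
        d[:, 0] -= box * np.round(d[:, 0] / box)
        return d

    def build_neighbor_list(self, state: SimState) -> NeighborList:
        """All non-excluded pairs within max cutoff + skin, in
        deterministic (lexicographic) order."""
        n = state.positions.shape[0]
        rc = self.max_cutoff + self.skin
        if state.periodic_axial and state.box_length > 0:
            pos = state.positions.copy()
            pos[:, 0] = np.mod(pos[:, 0], state.box_length)
            tl = pos[:, 1:].min(axis=0) - 2 * rc
            pos[:, 1:] -= tl
            boxsize = np.array([state.box_length,
                                pos[:, 1].max() + 2 * rc,
                                pos[:, 2].max() + 2 * rc])
            tree = cKDTree(pos, boxsize=boxsize)
        else:
            tree = cKDTree(state.positions)
        pairs = tree.query_pairs(rc, output_type="ndarray")
        if pairs.size:
            i = np.minimum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
            j = np.maximum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
            code = i * n + j
            keep = np.array([c not in self._excluded for c in code.tolist()])
            i, j = i[keep], j[keep]
            order = np.argsort(i * n + j)
            i, j = i[order], j[order]
        else:
            i = j = np.empty(0, dtype=np.int64)
        cls = self._PAIR_CLASS_OF_SPECIES[self.system.species[i],
                                          self.system.species[j]] \
            .astype(np.int64)
        self.nlist = NeighborList(i=i, j=j, pair_class=cls, skin=self.skin,
                                  ref_positions=state.positions.copy())
        return self.nlist

    def _ensure_neighbors(self, state: SimState) -> None:
        if self.nlist is None:
            self.build_neighbor_list(state)
            return
        disp = state.positions - self.nlist.ref_positions
        if np.max(np.sum(disp * disp, axis=1)) > (0.5 * self.skin) ** 2:
            self.build_neighbor_list(state)

    # -- forces ------------------------------------------------------------

    def compute_forces(self, state: SimState, allow_breaking: bool = True,
                       cap_bond_extension: bool = False,
                       want_energy: bool = True) -> EnergyBreakdown:
        """Accumulate bond + angle + pair forces into ``state.forces``.

        Returns the energy decomposition (zeros unless ``want_energy``)
        and updates the per-bond rupture bookkeeping (unless
        ``allow_breaking`` is false).  ``cap_bond_extension`` evaluates
        bonds at distances clipped just below the breaking distance
        (used during minimization).
        """
        self._ensure_neighbors(state)
        if self.use_compiled_kernels:
            return self._compute_forces_compiled(state, allow_breaking,
                                                 cap_bond_extension)
        sysb = self.system
        x = state.positions
        n = x.shape[0]
        f = np.zeros((n, 3))
        energies = EnergyBreakdown()
        box = state.box_length
        periodic = state.periodic_axial
        virial_xx = 0.0

        # ---- bonds
        bi, bj = self._bond_i, self._bond_j
        if bi.size:
            d = x[bj] - x[bi]
            if periodic:
                d = self._min_image(d, box)
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            if cap_bond_extension:
                r_eval = np.minimum(r, self._b_rb - 1e-6)
            else:
                r_eval = r
            if allow_breaking:
                sysb.bond_broken |= (r >= self._b_rb)
            np.maximum(sysb.bond_max_extension, r,
                       out=sysb.bond_max_extension)
            broken = sysb.bond_broken
            # trilinear law over flat parameter arrays
            fs = np.where(r_eval < self._b_r1,
                          -self._b_k0 * (r_eval - self._b_r0),
                          -(self._b_k0 * (self._b_r1 - self._b_r0)
                            + self._b_k1 * (r_eval - self._b_r1)))
            past = r_eval >= self._b_rb
            if np.any(past):
                ramp = -self._b_fb * (1.0 - (r_eval - self._b_rb) / self._b_a)
                fs = np.where(past,
                              np.where(r_eval < self._b_rb + self._b_a,
                                       ramp, 0.0),
                              fs)
            fs = np.where(broken & (r_eval < self._b_rb), 0.0, fs)
            if want_energy:
                d1 = self._b_r1 - self._b_r0
                e1 = 0.5 * self._b_k0 * (r_eval - self._b_r0) ** 2
                e_r1 = 0.5 * self._b_k0 * d1 * d1
                e2 = (e_r1 + self._b_k0 * d1 * (r_eval - self._b_r1)
                      + 0.5 * self._b_k1 * (r_eval - self._b_r1) ** 2)
                d2 = self._b_rb - self._b_r1
                e_rb = e_r1 + self._b_k0 * d1 * d2 + 0.5 * self._b_k1 * d2 * d2
                s = np.clip(r_eval - self._b_rb, 0.0, self._b_a)
                e_ramp = e_rb + self._b_fb * (s - s * s / (2.0 * self._b_a))
                e = np.where(r_eval < self._b_r1, e1, e2)
                e = np.where(r_eval >= self._b_rb, e_ramp, e)
                e = np.where(broken & (r_eval < self._b_rb), self._b_cap, e)
                if cap_bond_extension:
                    # linear continuation beyond the cap, consistent
                    # with the capped restoring force
                    e = e + np.where(r > r_eval,
                                     self._b_fb * (r - r_eval), 0.0)
                energies.bond = float(np.sum(e))
            u = d / r[:, None]
            fvec = fs[:, None] * u          # force on bj
            for dim in range(3):
                f[:, dim] += np.bincount(bj, fvec[:, dim], minlength=n)
                f[:, dim] -= np.bincount(bi, fvec[:, dim], minlength=n)
            virial_xx += float(np.sum(fs * d[:, 0] ** 2 / r))

        # ---- angles
        ai, aj, ak = self._ang_i, self._ang_j, self._ang_k
        if ai.size:
            r1 = x[ai] - x[aj]
            r2 = x[ak] - x[aj]
            if periodic:
                r1 = self._min_image(r1, box)
                r2 = self._min_image(r2, box)
            n1 = np.linalg.norm(r1, axis=1)
            n2 = np.linalg.norm(r2, axis=1)
            u1 = r1 / n1[:, None]
            u2 = r2 / n2[:, None]
            cosphi = np.clip(np.einsum("ij,ij->i", u1, u2), -1.0, 1.0)
            phi = np.arccos(cosphi)
            sinphi = np.sqrt(np.maximum(1.0 - cosphi * cosphi, 0.0))
            ok = sinphi > 1e-8   # arms anti-/parallel: force undefined -> 0
            dphi = phi - self._ang_phi0
            if want_energy:
                energies.angle = float(0.5 * self.ff.angle.k_bend
                                       * np.sum(dphi * dphi))
            moment = np.where(ok, -self.ff.angle.k_bend * dphi, 0.0)
            inv_sin = np.where(ok, 1.0 / np.where(ok, sinphi, 1.0), 0.0)
            gi = (cosphi[:, None] * u1 - u2) * (inv_sin / n1)[:, None]
            gk = (cosphi[:, None] * u2 - u1) * (inv_sin / n2)[:, None]
            fi = moment[:, None] * gi
            fk = moment[:, None] * gk
            fj = -(fi + fk)
            for dim in range(3):
                f[:, dim] += np.bincount(ai, fi[:, dim], minlength=n)
                f[:, dim] += np.bincount(aj, fj[:, dim], minlength=n)
                f[:, dim] += np.bincount(ak, fk[:, dim], minlength=n)
            # angle virial (axial): sum of F . x over the triple, with
            # displacements taken relative to the apex particle
            virial_xx += float(np.sum(fi[:, 0] * r1[:, 0]
                                      + fk[:, 0] * r2[:, 0]))

        # ---- pairs
        nl = self.nlist
        if nl.n_pairs:
            d = x[nl.j] - x[nl.i]
            if periodic:
                d = self._min_image(d, box)
            r = np.linalg.norm(d, axis=1)
            cut = self._pair_cut[nl.pair_class]
            within = r < cut
            if np.any(within):
                pi, pj = nl.i[within], nl.j[within]
                rw = r[within]
                dw = d[within]
                eps = self._pair_eps[nl.pair_class[within]]
                sig = self._pair_sigma[nl.pair_class[within]]
                lam = self._pair_lam[nl.pair_class[within]]
                cutw = cut[within]
                rcore = lam * sig
                reff = np.maximum(rw, rcore)
                sr6 = (sig / reff) ** 6
                fs = (48.0 * eps * sr6 * sr6 - 24.0 * eps * sr6) / reff
                if want_energy:
                    # energy consistent with the truncated soft-core force
                    sr6c = (sig / cutw) ** 6
                    phi_r = 4.0 * eps * (sr6 * sr6 - sr6)
                    shift = 4.0 * eps * (sr6c * sr6c - sr6c)
                    e = phi_r - shift + np.where(rw < rcore,
                                                 fs * (rcore - rw), 0.0)
                    energies.pair = float(np.sum(e))
                u = dw / rw[:, None]
                fvec = fs[:, None] * u        # force on j (positive repels)
                for dim in range(3):
                    f[:, dim] += np.bincount(pj, fvec[:, dim], minlength=n)
                    f[:, dim] -= np.bincount(pi, fvec[:, dim], minlength=n)
                virial_xx += float(np.sum(fs * dw[:, 0] ** 2 / rw))

        if not np.all(np.isfinite(f)):
            bad = np.where(~np.isfinite(f).any(axis=1))[0]
            raise FloatingPointError(
                f"non-finite force on particles {bad[:5].tolist()}")
        state.forces = f
        self.last_virial_xx = virial_xx
        return energies

    def _compute_forces_compiled(self, state: SimState, allow_breaking: bool,
                                 cap_bond_extension: bool) -> EnergyBreakdown:
        """Numba kernel path; numerically identical to the numpy path."""
        sysb = self.system
        x = state.positions
        n = x.shape[0]
        f = np.zeros((n, 3))
        box = float(state.box_length)
        periodic = bool(state.periodic_axial)
        energies = EnergyBreakdown()
        virial_xx = 0.0
        if self._bond_i.size:
            e, v = _kern.bond_kernel(
                x, self._bond_i, self._bond_j, self._b_r0, self._b_k0,
                self._b_k1, self._b_r1, self._b_rb, self._b_a, self._b_fb,
                self._b_cap, sysb.bond_broken, sysb.bond_max_extension,
                f, box, periodic, allow_breaking, cap_bond_extension)
            energies.bond = float(e)
            virial_xx += v
        if self._ang_i.size:
            e, v = _kern.angle_kernel(
                x, self._ang_i, self._ang_j, self._ang_k, self._ang_phi0,
                float(self.ff.angle.k_bend), f, box, periodic)
            energies.angle = float(e)
            virial_xx += v
        nl = self.nlist
        if nl.n_pairs:
            e, v = _kern.pair_kernel(
                x, nl.i, nl.j, nl.pair_class,
                self._pair_eps, self._pair_sigma, self._pair_lam,
                self._pair_cut, f, box, periodic)
            energies.pair = float(e)
            virial_xx += v
        if not np.all(np.isfinite(f)):
            bad = np.where(~np.isfinite(f).any(axis=1))[0]
            raise FloatingPointError(
                f"non-finite force on particles {bad[:5].tolist()}")
        state.forces = f
        self.last_virial_xx = virial_xx
        return energies

    # -- integrators -------------------------------------------------------

    @property
    def _acc_factor(self) -> np.ndarray:
        if not hasattr(self, "_acc_factor_cache"):
            self._acc_factor_cache = FORCE_TO_ACC / self.masses[:, None]
        return self._acc_factor_cache

    @property
    def _free_f(self) -> np.ndarray:
        """Free mask as a float column (frozen particles multiply to 0)."""
        if getattr(self, "_free_src", None) is not self.free_mask:
            self._free_src = self.free_mask
            self._free_f_cache = self.free_mask.astype(float)[:, None]
        return self._free_f_cache

    def step_nve(self, state: SimState, dt: float,
                 want_energy: bool = True) -> EnergyBreakdown:
        """One velocity-Verlet step (forces must be current)."""
        mf = self._free_f
        kick = state.forces * (self._acc_factor * (0.5 * dt) * mf)
        state.velocities += kick
        state.positions += (dt * mf) * state.velocities
        energies = self.compute_forces(state, want_energy=want_energy)
        state.velocities += state.forces * (self._acc_factor * (0.5 * dt)
                                            * mf)
        state.time += dt
        return energies

    def step_langevin(self, state: SimState, dt: float, T: float,
                      damping: float, rng: np.random.Generator,
                      axial_flow: Optional[np.ndarray] = None,
                      want_energy: bool = False) -> EnergyBreakdown:
        """One BAOAB Langevin step at temperature ``T`` (K) with damping
        time ``damping`` (fs).  Deterministic for a fixed generator
        state.

        ``axial_flow`` (per-particle axial streaming velocity, A/fs)
        makes the thermostat act on the peculiar velocity ``v - u``;
        during steered pulling this prevents the per-particle friction
        from dragging on the imposed deformation flow while still
        damping axial thermal motion.
        """
        if T < 0:
            raise ValueError("temperature must be non-negative")
        if damping <= 0:
            raise ValueError("damping time must be positive")
        mf = self._free_f
        half = self._acc_factor * (0.5 * dt) * mf
        state.velocities += state.forces * half
        state.positions += (0.5 * dt * mf) * state.velocities
        key = (dt, T, damping)
        if getattr(self, "_ou_key", None) != key:
            self._ou_key = key
            self._ou_c1 = float(np.exp(-dt / damping))
            self._ou_sig = (np.sqrt(KB * T * FORCE_TO_ACC / self.masses)
                            [:, None] * np.sqrt(1.0 - self._ou_c1 ** 2))
        c1 = self._ou_c1
        noise = rng.normal(size=(state.masses.size, 3))
        if axial_flow is not None:
            pec = state.velocities.copy()
            pec[:, 0] -= axial_flow
            ou = c1 * pec + self._ou_sig * noise
            ou[:, 0] += axial_flow
        else:
            ou = c1 * state.velocities + self._ou_sig * noise
        state.velocities += (ou - state.velocities) * mf
        state.positions += (0.5 * dt * mf) * state.velocities
        energies = self.compute_forces(state, want_energy=want_energy)
        state.velocities += state.forces * half
        state.time += dt
        return energies

    # -- minimizer ---------------------------------------------------------

    def minimize(self, state: SimState, force_tol: float = 1.0,
                 max_iter: int = 2000, max_step: float = 0.2) -> int:
        """Backtracking steepest descent to max-force <= ``force_tol``.

        Bond extensions are capped just below breaking so that no bond
        can rupture during relaxation; energy is non-increasing across
        accepted steps.  Returns the number of accepted steps.
        """
        free = self.free_mask
        energies = self.compute_forces(state, allow_breaking=False,
                                       cap_bond_extension=True)
        e = energies.total
        alpha = 1e-3          # step scale, A^2 mol / kcal
        accepted = 0
        for _ in range(max_iter):
            fmax = float(np.max(np.abs(state.forces[free]))) \
                if np.any(free) else 0.0
            if fmax <= force_tol:
                break
            f2 = float(np.sum(state.forces[free] ** 2))
            ok = False
            for _try in range(60):
                a_eff = min(alpha, max_step / fmax)
                trial = state.copy()
                trial.positions[free] += a_eff * state.forces[free]
                e_try = self.compute_forces(trial, allow_breaking=False,
                                            cap_bond_extension=True).total
                # Armijo sufficient-decrease along the steepest descent
                if e_try <= e - 1e-4 * a_eff * f2:
                    state.positions = trial.positions
                    state.forces = trial.forces
                    e = e_try
                    alpha = min(alpha * 1.5, 1.0)
                    ok = True
                    accepted += 1
                    break
                alpha *= 0.5
            if not ok:
                break
        if not np.isfinite(e):
            raise FloatingPointError("minimization diverged")
        # refresh forces with the true (uncapped) law
        self.compute_forces(state, allow_breaking=False)
        return accepted

    # -- axial barostat ----------------------------------------------------

    def axial_stress(self, state: SimState) -> float:
        """Axial virial stress P_xx in kcal/mol/A^3 (negative = tension)."""
        self.compute_forces(state)
        from .observables import cross_section_area
        area = cross_section_area(self.system)
        vol = area * state.box_length
        kin = float(np.sum(state.masses * state.velocities[:, 0] ** 2)) \
            * MVV_TO_KCAL
        return (kin + self.last_virial_xx) / vol

    def rescale_box_axial(self, state: SimState,
                          target_axial_stress: float = 0.0,
                          coupling: float = 1e-3, dt: float = 10.0,
                          max_strain_per_step: float = 1e-4) -> float:
        """Berendsen-style axial rescale toward ``target_axial_stress``.

        Returns the applied strain increment.  Transverse coordinates
        are untouched.  Requires axial periodicity.
        """
        if not state.periodic_axial:
            raise ValueError("axial rescale requires a periodic system")
        p_xx = self.axial_stress(state)
        strain = float(np.clip(coupling * dt * (p_xx - target_axial_stress),
                               -max_strain_per_step, max_strain_per_step))
        if strain != 0.0:
            state.positions[:, 0] *= (1.0 + strain)
            state.box_length *= (1.0 + strain)
            self.build_neighbor_list(state)
            self.compute_forces(state)
        return strain
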