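"""Shared fixtures: miniature fibrils, a naive reference force
implementation, and cached mechanism-scale tensile runs."""

from __future__ import annotations

import numpy as np
import pytest

from fibrilmech.fibril import (BuildConfig, CrosslinkSpec, MineralSpec,
                               make_fixture)
from fibrilmech.force_field import (bond_force, pair_force,
                                    default_force_field)
from fibrilmech.fibril import BOND_AGE, BOND_COLLAGEN, BOND_GRIP
from fibrilmech.protocols import (PullSchedule, RunConfig,
                                  preset_build_config, preset_schedule,
                                  run_tensile_pipeline)


@pytest.fixture(scope="session")
def mini7():
    return make_fixture("mini7")


@pytest.fixture()
def pair_system():
    return make_fixture("pair")


@pytest.fixture()
def toy_gap():
    return make_fixture("toy_gap")


def naive_forces(system, positions, ff=None):
    """Per-interaction python-loop force evaluation (reference oracle).

    Slow and scalar on purpose: bonds and pairs through the public
    scalar force laws, angles through an independently written gradient
    of the harmonic bending energy.
    """
    ff = ff or default_force_field()
    n = positions.shape[0]
    f = np.zeros((n, 3))
    spec_of = {BOND_COLLAGEN: ff.collagen_bond, BOND_GRIP: ff.grip_bond,
               BOND_AGE: ff.age}
    for (i, j), cls, broken in zip(system.bonds, system.bond_class,
                                   system.bond_broken):
        d = positions[j] - positions[i]
        r = float(np.linalg.norm(d))
        fs = bond_force(r, spec_of[int(cls)], bool(broken))
        f[j] += fs * d / r
        f[i] -= fs * d / r
    kb = ff.angle.k_bend
    for (i, j, k), phi0 in zip(system.angles, np.deg2rad(system.angle_phi0)):
        a = positions[i] - positions[j]
        b = positions[k] - positions[j]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        ua, ub = a / na, b / nb
        c = float(np.clip(ua @ ub, -1.0, 1.0))
        s = np.sqrt(max(1.0 - c * c, 0.0))
        if s <= 1e-8:
            continue
        phi = np.arccos(c)
        dEdphi = kb * (phi - phi0)
        dphi_di = (c * ua - ub) / (s * na)
        dphi_dk = (c * ub - ua) / (s * nb)
        f[i] += -dEdphi * dphi_di
        f[k] += -dEdphi * dphi_dk
        f[j] += dEdphi * (dphi_di + dphi_dk)
    pair_spec = {(0, 0): ff.col_col, (0, 1): ff.col_col, (1, 1): ff.col_col,
                 (0, 2): ff.col_hap, (1, 2): ff.col_hap, (2, 2): ff.hap_hap}
    bonded = {tuple(sorted(b)) for b in system.bonds.tolist()}
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            spec = pair_spec[tuple(sorted((int(system.species[i]),
                                           int(system.species[j]))))]
            d = positions[j] - positions[i]
            r = float(np.linalg.norm(d))
            if r >= spec.cutoff:
                continue
            fs = pair_force(r, spec)
            f[j] += fs * d / r
            f[i] -= fs * d / r
    return f


# ---------------------------------------------------------------------------
# cached mechanism-scale tensile runs (shared across acceptance tests)

MINI_EQ_FS = 1.0e4
DESK_EQ_FS = 2.0e4


def _mini_run(content=0.0, n_age=0, k1=8.0, pattern="edge", seed=1,
              max_strain=0.85):
    cfg = preset_build_config("mini", seed=seed)
    mineral = MineralSpec(pattern=pattern, content_percent=content) \
        if content else None
    cross = CrosslinkSpec(n_per_molecule=n_age, k1_age=k1) if n_age else None
    run_cfg = RunConfig(equilibration_fs=MINI_EQ_FS, seed=seed)
    sched = PullSchedule(speed=preset_schedule("mini").speed,
                         sample_stride=60, max_strain=max_strain)
    return run_tensile_pipeline(cfg, mineral, cross, run_cfg, sched,
                                seed=seed)


def _desk_run(content=0.0, n_age=0, k1=8.0, pattern="edge", seed=1,
              max_strain=0.9):
    cfg = preset_build_config("desk", seed=seed)
    mineral = MineralSpec(pattern=pattern, content_percent=content) \
        if content else None
    cross = CrosslinkSpec(n_per_molecule=n_age, k1_age=k1) if n_age else None
    run_cfg = RunConfig(equilibration_fs=DESK_EQ_FS, seed=seed)
    sched = PullSchedule(speed=preset_schedule("desk").speed,
                         sample_stride=200, max_strain=max_strain)
    return run_tensile_pipeline(cfg, mineral, cross, run_cfg, sched,
                                seed=seed)


@pytest.fixture(scope="session")
def mini_sweep():
    """Mechanism-scale runs shared by the ordering checks.

    Keys: (pattern, content, n_age, k1, seed) -> (system, TimeSeries).
    """
    runs = {}

    def get(pattern="edge", content=0.0, n_age=0, k1=8.0, seed=1,
            max_strain=0.85):
        key = (pattern, content, n_age, k1, seed)
        if key not in runs:
            runs[key] = _mini_run(content=content, n_age=n_age, k1=k1,
                                  pattern=pattern, seed=seed,
                                  max_strain=max_strain)
        return runs[key]

    return get


@pytest.fixture(scope="session")
def desk_sliding_run():
    """Zero-mineral, zero-AGE desk run (pure sliding reference)."""
    return _desk_run(seed=1)


@pytest.fixture(scope="session")
def desk_t6_runs():
    """Desk runs at c=0, N_AGE=40, k1=8 over three seeds."""
    return [_desk_run(n_age=40, seed=s) for s in (1, 2, 3)]


@pytest.fixture(scope="session")
def desk_t7_runs():
    """Desk mineral sweep for the elastic-insensitivity check."""
    out = {}
    for c in (0.0, 20.0, 40.0, 100.0):
        out[c] = [_desk_run(content=c, seed=s, max_strain=0.4)[1]
                  for s in (1, 2)]
    return out


@pytest.fixture(scope="session")
def desk_c100_runs():
    """Fully mineralized desk fibrils pulled to failure (no AGEs)."""
    return [_desk_run(content=100.0, seed=s) for s in (1, 2)]


@pytest.fixture(scope="session")
def desk_c100_age_runs():
    """Fully mineralized desk fibrils with 40 AGEs/TC (k1=8)."""
    return [_desk_run(content=100.0, n_age=40, seed=s) for s in (1, 2, 3)]


@pytest.fixture(scope="session")
def desk_nucleation_runs():
    """Edge vs center nucleation at an intermediate content."""
    return {pattern: [_desk_run(content=25.0, pattern=pattern, seed=s,
                                max_strain=0.6)[1] for s in (1, 2)]
            for pattern in ("edge", "center")}


@pytest.fixture(scope="session")
def desk_sparse_runs():
    """Sparse (every-second-slot) pattern at the same nominal content
    as the dense edge reference."""
    return [_desk_run(content=40.0, pattern="sparse_half", seed=s,
                      max_strain=0.4)[1] for s in (1, 2)]
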