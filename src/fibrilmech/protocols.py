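"""Simulation campaigns: equilibration and the destructive tensile test.

The pipeline mirrors the physical protocol: build the mineralized
fibril, relax it (minimization followed by thermostatted dynamics at
300 K), insert the AGE cross-links into the *equilibrated*
configuration, then pull the strengthened fibril ends apart at constant
velocity while recording strain, engineering stress, broken-bond counts
and the average gap length.

Grips move symmetrically at +-v/2 and stress is computed from the mean
of the two grip restraint-force magnitudes.  Strain is the imposed
gauge elongation over the initial grip-to-grip gauge length (distance
between the two grip-group centroids).

Presets
-------
``full``  — the full fibril (155 molecules, 218 beads/molecule, 20
            grip beads per end, 0.0001 A/fs pulling).  Buildable, but
            the dynamics are expensive; provided for completeness.
``desk``  — reduced fibril preserving the gap/overlap fractions and all
            force laws: 19 molecules, 58 beads/molecule, 10 grip beads
            per end, 0.001 A/fs pulling.
``mini``  — minimal mechanism-scale fibril for fast property checks:
            7 molecules (all five stagger phases), 33 beads/molecule,
            4 grip beads per end, 0.002 A/fs pulling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .engine import Engine, SimState
from .fibril import (BOND_AGE, BOND_COLLAGEN, BuildConfig, CrosslinkSpec,
                     FibrilSystem, MineralSpec, build_fibril,
                     insert_crosslinks, mineralize)
from .force_field import default_force_field
from .observables import (TimeSeries, average_gap_length,
                          cross_section_area, summarize)

__all__ = ["PullSchedule", "RunConfig", "equilibrate", "tensile_test",
           "run_tensile_pipeline", "run_experiment", "PRESETS",
           "preset_build_config", "preset_schedule"]


@dataclass(frozen=True)
class PullSchedule:
    """Constant-velocity symmetric pulling protocol."""

    speed: float = 0.0001             # A/fs, total separation rate
    max_strain: float = 0.8
    stop_stress_fraction: float = 0.02
    sample_stride: int = 200          # steps between samples
    min_strain_before_stop: float = 0.05

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("pulling speed must be positive")
        if self.max_strain <= 0:
            raise ValueError("max_strain must be positive")
        if not (0 < self.stop_stress_fraction < 1):
            raise ValueError("stop_stress_fraction must be in (0, 1)")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Time stepping and thermostat settings."""

    dt: float = 10.0                  # fs
    temperature: float = 300.0        # K
    equilibration_fs: float = 2.0e4   # scaled down; full scale uses 2e7
    damping_fs: float = 1000.0
    minimize_force_tol: float = 0.5   # kcal/mol/A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("timestep must be positive")
        if self.equilibration_fs < 0:
            raise ValueError("equilibration duration must be >= 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


def _substream(seed: int, tag: str) -> np.random.Generator:
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(tag.encode()) % (2 ** 31)])
    return np.random.default_rng(ss)


def _substream_seed(seed: int, tag: str) -> int:
    import zlib

    ss = np.random.SeedSequence([seed, zlib.crc32(tag.encode()) % (2 ** 31)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def equilibrate(system: FibrilSystem, run_config: RunConfig,
                rng: Optional[np.random.Generator] = None,
                axial_rescale: bool = False,
                force_field=None) -> tuple[Engine, SimState]:
    """Relax a built (optionally mineralized) system.

    Minimization followed by Langevin dynamics at the configured
    temperature for ``equilibration_fs``; zero duration means
    minimization only.  Cross-links must not be present yet — they are
    inserted into the equilibrated configuration.  Any bond breakage
    during equilibration aborts (relaxation must be non-destructive).
    """
    if system.n_age_bonds:
        raise ValueError("cross-links must be inserted after equilibration")
    if rng is None:
        rng = _substream(run_config.seed, "equilibrate")
    engine = Engine(system, force_field=force_field)
    nsteps = int(round(run_config.equilibration_fs / run_config.dt))
    state = engine.init_state(T=run_config.temperature if nsteps else 0.0,
                              rng=rng)
    engine.minimize(state, force_tol=run_config.minimize_force_tol)
    for _ in range(nsteps):
        engine.step_langevin(state, run_config.dt, run_config.temperature,
                             run_config.damping_fs, rng)
        if axial_rescale and system.periodic_axial:
            engine.rescale_box_axial(state, dt=run_config.dt)
    if np.any(system.bond_broken):
        broken = np.where(system.bond_broken)[0]
        raise RuntimeError(
            f"{broken.size} bond(s) broke during equilibration "
            f"(first: bond {broken[0]}); equilibration must be "
            f"non-destructive")
    return engine, state


def tensile_test(system: FibrilSystem, state: SimState,
                 schedule: PullSchedule, run_config: RunConfig,
                 rng: Optional[np.random.Generator] = None,
                 force_field=None) -> TimeSeries:
    """Steered constant-velocity tensile test to failure.

    Grip particles are displaced rigidly along the axis (bottom group
    at -v/2, top group at +v/2; their equations of motion are replaced
    by the ramp).  Samples are taken every ``sample_stride`` steps with
    the grip restraint force time-averaged over the stride.  The run
    terminates at ``max_strain`` or once the (smoothed) stress has
    fallen below ``stop_stress_fraction`` of the running peak after the
    peak.
    """
    bot = np.where(system.grip_end == -1)[0]
    top = np.where(system.grip_end == +1)[0]
    if bot.size == 0 or top.size == 0:
        raise ValueError("tensile test requires grips at both fibril ends")
    if rng is None:
        rng = _substream(run_config.seed, "pull")

    engine = Engine(system, force_field=force_field)
    engine.free_mask = system.grip_end == 0
    st = SimState(positions=state.positions.copy(),
                  velocities=state.velocities.copy(),
                  forces=np.zeros_like(state.forces),
                  masses=engine.masses.copy(),
                  time=0.0,
                  box_length=state.box_length,
                  periodic_axial=False)
    st.velocities[bot] = 0.0
    st.velocities[top] = 0.0
    st.velocities[bot, 0] = -0.5 * schedule.speed
    st.velocities[top, 0] = +0.5 * schedule.speed
    x0_bot = st.positions[bot, 0].copy()
    x0_top = st.positions[top, 0].copy()
    gauge0 = float(np.mean(x0_top) - np.mean(x0_bot))
    area = cross_section_area(system)
    # per-particle streaming-velocity estimate for the peculiar-velocity
    # thermostat: initialized to the affine profile (-v/2 at the lower
    # grip plane, +v/2 at the upper) and relaxed toward each particle's
    # own axial velocity so that the thermostat never drags on the
    # actual deformation flow, even once sliding localizes
    x_mid = 0.5 * (np.mean(x0_bot) + np.mean(x0_top))
    axial_flow = np.clip((st.positions[:, 0] - x_mid) / gauge0,
                         -0.5, 0.5) * schedule.speed
    flow_alpha = run_config.dt / 2000.0   # 2 ps flow-estimate memory

    dt = run_config.dt
    engine.compute_forces(st)
    t_rec, eps_rec, sig_rec = [0.0], [0.0], [0.0]
    col_rec, age_rec = [0], [0]
    gap_rec = [average_gap_length(system, st.positions)]
    n_age_total = system.n_age_bonds
    is_col = system.bond_class == BOND_COLLAGEN
    is_age = system.bond_class == BOND_AGE

    acc_f = 0.0
    acc_n = 0
    sigma_peak = 0.0
    truncated = True
    step = 0
    while True:
        step += 1
        try:
            engine.step_langevin(st, dt, run_config.temperature,
                                 run_config.damping_fs, rng,
                                 axial_flow=axial_flow, want_energy=False)
        except FloatingPointError:
            truncated = True
            break
        axial_flow += flow_alpha * (st.velocities[:, 0] - axial_flow)
        t = st.time
        st.positions[bot, 0] = x0_bot - 0.5 * schedule.speed * t
        st.positions[top, 0] = x0_top + 0.5 * schedule.speed * t
        f_bot = float(np.sum(st.forces[bot, 0]))
        f_top = float(np.sum(st.forces[top, 0]))
        acc_f += 0.5 * (abs(f_bot) + abs(f_top))
        acc_n += 1
        if step % schedule.sample_stride == 0:
            eps = schedule.speed * t / gauge0
            sigma = (acc_f / acc_n) / area
            acc_f, acc_n = 0.0, 0
            t_rec.append(t)
            eps_rec.append(eps)
            sig_rec.append(sigma)
            col_rec.append(int(np.sum(system.bond_broken[is_col])))
            age_rec.append(int(np.sum(system.bond_broken[is_age])))
            gap_rec.append(average_gap_length(system, st.positions))
            smoothed = float(np.mean(sig_rec[-3:]))
            sigma_peak = max(sigma_peak, smoothed)
            if eps >= schedule.max_strain:
                truncated = True
                break
            if (eps > schedule.min_strain_before_stop and sigma_peak > 0
                    and smoothed < schedule.stop_stress_fraction * sigma_peak):
                truncated = False
                break

    return TimeSeries(
        time=np.array(t_rec),
        strain=np.array(eps_rec),
        stress=np.array(sig_rec),
        broken_collagen=np.array(col_rec),
        broken_age=np.array(age_rec),
        avg_gap_length=np.array(gap_rec),
        n_age_total=n_age_total,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# presets


def preset_build_config(name: str, seed: int = 0) -> BuildConfig:
    if name == "full":
        return BuildConfig(seed=seed)
    if name == "desk":
        return BuildConfig(particles_per_molecule=58,
                           molecules_per_cross_section=19,
                           grip_particles_per_molecule_end=10, seed=seed)
    if name == "mini":
        return BuildConfig(particles_per_molecule=33,
                           molecules_per_cross_section=7,
                           grip_particles_per_molecule_end=4, seed=seed)
    raise KeyError(f"unknown preset {name!r}")


def preset_schedule(name: str) -> PullSchedule:
    if name == "full":
        return PullSchedule(speed=0.0001, sample_stride=2000)
    if name == "desk":
        return PullSchedule(speed=0.001, sample_stride=200)
    if name == "mini":
        return PullSchedule(speed=0.002, sample_stride=60)
    raise KeyError(f"unknown preset {name!r}")


PRESETS = {
    "full": {"build": "full", "equilibration_fs": 2.0e7},
    "desk": {"build": "desk", "equilibration_fs": 2.0e4},
    "mini": {"build": "mini", "equilibration_fs": 1.0e4},
    "mineral_sweep_reduced": {
        "build": "desk", "equilibration_fs": 2.0e4,
        "sweep": [{"mineral_content": c}
                  for c in (0, 10, 15, 20, 30, 40, 100)]},
    "age_sweep_reduced": {
        "build": "desk", "equilibration_fs": 2.0e4,
        "sweep": [{"n_age": n, "age_k1": k1}
                  for k1 in (8.0, 16.0) for n in (0, 10, 20, 40)]},
}


def run_tensile_pipeline(build_cfg: BuildConfig,
                         mineral_spec: Optional[MineralSpec] = None,
                         crosslink_spec: Optional[CrosslinkSpec] = None,
                         run_config: Optional[RunConfig] = None,
                         schedule: Optional[PullSchedule] = None,
                         seed: int = 1
                         ) -> tuple[FibrilSystem, TimeSeries]:
    """Build, mineralize, equilibrate, cross-link and pull one fibril.

    All randomness derives from ``seed`` through named substreams
    (equilibration thermostat, cross-link placement, pulling
    thermostat), so identical inputs give identical outputs.
    """
    run_config = run_config or RunConfig(seed=seed)
    if run_config.seed != seed:
        run_config = dataclasses.replace(run_config, seed=seed)
    schedule = schedule or PullSchedule()
    system = build_fibril(build_cfg)
    if mineral_spec is not None and mineral_spec.content_percent > 0:
        system = mineralize(system, mineral_spec)
    k1 = crosslink_spec.k1_age if crosslink_spec is not None else 8.0
    ff = default_force_field(age_k1=k1)
    engine, state = equilibrate(system, run_config, force_field=ff)
    # cross-links bind to the relaxed configuration
    relaxed = system.copy()
    relaxed.positions = state.positions.copy()
    if crosslink_spec is not None and crosslink_spec.n_per_molecule > 0:
        cspec = dataclasses.replace(
            crosslink_spec, seed=_substream_seed(seed, "crosslinks"))
        relaxed = insert_crosslinks(relaxed, cspec)
    series = tensile_test(relaxed, state, schedule, run_config,
                          force_field=ff)
    return relaxed, series


def run_experiment(preset_name: str, overrides: Optional[dict] = None,
                   outdir: str = ".", seed: int = 1) -> list[Path]:
    """Run a preset campaign and write its artifacts to disk.

    Each run writes ``timeseries.csv``, ``summary.json`` and a resolved
    provenance/config record; sweep presets write one subdirectory per
    condition.  Returns the list of run directories.
    """
    from .io import write_timeseries

    if preset_name not in PRESETS:
        raise KeyError(f"unknown preset {preset_name!r}; "
                       f"available: {sorted(PRESETS)}")
    preset = dict(PRESETS[preset_name])
    overrides = dict(overrides or {})
    build_name = preset["build"]
    conditions = preset.get("sweep", [dict()])
    outroot = Path(outdir)
    outroot.mkdir(parents=True, exist_ok=True)
    written = []
    for cond in conditions:
        cond = {**cond, **overrides}
        content = cond.get("mineral_content", 0.0)
        pattern = cond.get("mineral_pattern", "edge")
        n_age = cond.get("n_age", 0)
        k1 = cond.get("age_k1", 8.0)
        build_cfg = preset_build_config(build_name, seed=seed)
        mineral = MineralSpec(pattern=pattern, content_percent=content) \
            if content else None
        cross = CrosslinkSpec(n_per_molecule=n_age, k1_age=k1) \
            if n_age else None
        run_cfg = RunConfig(
            equilibration_fs=cond.get("equilibration_fs",
                                      preset["equilibration_fs"]),
            seed=seed)
        schedule = preset_schedule(build_name)
        system, series = run_tensile_pipeline(
            build_cfg, mineral, cross, run_cfg, schedule, seed=seed)
        tag = f"c{content:g}_n{n_age}_k{k1:g}_s{seed}"
        rundir = outroot / tag if len(conditions) > 1 else outroot
        rundir.mkdir(parents=True, exist_ok=True)
        write_timeseries(series, rundir / "timeseries.csv")
        summary = summarize(series).to_dict()
        summary["condition"] = {"preset": preset_name, "seed": seed, **cond}
        (rundir / "summary.json").write_text(json.dumps(summary, indent=2))
        (rundir / "provenance.json").write_text(
            json.dumps(_jsonify(system.provenance), indent=2))
        written.append(rundir)
    return written


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
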