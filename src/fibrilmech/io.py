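"""File formats and configuration.

Topology is written in LAMMPS data-file style (Masses / Atoms /
Bonds / Angles sections, "molecular" atom style) together with a JSON
sidecar carrying everything the data file cannot express (column ids,
stagger phases, gap table, provenance).  ``write_topology`` followed by
``read_topology`` round-trips coordinates and connectivity exactly.

Time series go to CSV with a versioned header; trajectories to
LAMMPS-dump-style text or XYZ, readable by standard MD viewers.

Run configuration is a single YAML file with strict section schemas
(unknown keys are rejected); an empty file yields the tabulated
defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .fibril import (BuildConfig, CrosslinkSpec, FibrilSystem, MineralSpec,
                     make_fixture)
from .observables import TimeSeries
from .protocols import PullSchedule, RunConfig

__all__ = ["ProjectConfig", "read_config", "write_topology", "read_topology",
           "write_timeseries", "read_timeseries", "write_dump", "write_xyz",
           "write_checkpoint", "read_checkpoint", "make_fixture"]

TIMESERIES_SCHEMA_VERSION = 1
_TS_COLUMNS = ["time_fs", "strain", "stress_kcal_molA3", "stress_GPa",
               "n_broken_col", "n_broken_age", "avg_gap_A"]


@dataclass(frozen=True)
class ProjectConfig:
    """Resolved run configuration (defaults filled in)."""

    build: BuildConfig = field(default_factory=BuildConfig)
    mineral: Optional[MineralSpec] = None
    crosslinks: Optional[CrosslinkSpec] = None
    run: RunConfig = field(default_factory=RunConfig)
    pull: PullSchedule = field(default_factory=PullSchedule)
    seed: int = 0
    outdir: str = "."


def _build_section(cls, data: dict, path: str, section: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"{path}: unknown key(s) {sorted(unknown)} in "
                         f"section '{section}' (allowed: {sorted(fields)})")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid section '{section}': {exc}") from exc


def read_config(path) -> ProjectConfig:
    """Read and validate a YAML run configuration.

    Missing sections and keys take the tabulated defaults; unknown keys
    are rejected with the offending section named.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    known = {"build", "mineral", "crosslinks", "run", "pull", "seed", "outdir"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    if "build" in raw:
        kwargs["build"] = _build_section(BuildConfig, raw["build"] or {},
                                         str(path), "build")
    if "mineral" in raw and raw["mineral"] is not None:
        kwargs["mineral"] = _build_section(MineralSpec, raw["mineral"],
                                           str(path), "mineral")
    if "crosslinks" in raw and raw["crosslinks"] is not None:
        kwargs["crosslinks"] = _build_section(CrosslinkSpec,
                                              raw["crosslinks"],
                                              str(path), "crosslinks")
    if "run" in raw:
        kwargs["run"] = _build_section(RunConfig, raw["run"] or {},
                                       str(path), "run")
    if "pull" in raw:
        kwargs["pull"] = _build_section(PullSchedule, raw["pull"] or {},
                                        str(path), "pull")
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "outdir" in raw:
        kwargs["outdir"] = str(raw["outdir"])
    return ProjectConfig(**kwargs)


# ---------------------------------------------------------------------------
# topology

_SPECIES_MASS = {0: 1548.0, 1: 1548.0, 2: 1324.0}


def write_topology(system: FibrilSystem, path) -> Path:
    """LAMMPS-data-style topology plus a JSON provenance sidecar."""
    path = Path(path)
    x = system.positions
    lines = ["# fibrilmech topology v1", ""]
    lines.append(f"{system.n_particles} atoms")
    lines.append(f"{len(system.bonds)} bonds")
    lines.append(f"{len(system.angles)} angles")
    lines.append("3 atom types")
    lines.append("3 bond types")
    lines.append("1 angle types")
    lines.append("")
    lines.append(f"{0.0:.17g} {system.box_length:.17g} xlo xhi")
    for dim, tag in ((1, "ylo yhi"), (2, "zlo zhi")):
        lo = float(x[:, dim].min()) - 50.0
        hi = float(x[:, dim].max()) + 50.0
        lines.append(f"{lo:.17g} {hi:.17g} {tag}")
    lines.append("")
    lines.append("Masses")
    lines.append("")
    for t in (0, 1, 2):
        lines.append(f"{t + 1} {_SPECIES_MASS[t]}")
    lines.append("")
    lines.append("Atoms  # molecular")
    lines.append("")
    for i in range(system.n_particles):
        mol = int(system.molecule_id[i]) + 1
        lines.append(f"{i + 1} {mol} {int(system.species[i]) + 1} "
                     f"{x[i, 0]:.17g} {x[i, 1]:.17g} {x[i, 2]:.17g}")
    if len(system.bonds):
        lines.append("")
        lines.append("Bonds")
        lines.append("")
        for b, (i, j) in enumerate(system.bonds):
            lines.append(f"{b + 1} {int(system.bond_class[b]) + 1} "
                         f"{int(i) + 1} {int(j) + 1}")
    if len(system.angles):
        lines.append("")
        lines.append("Angles")
        lines.append("")
        for a, (i, j, k) in enumerate(system.angles):
            lines.append(f"{a + 1} 1 {int(i) + 1} {int(j) + 1} {int(k) + 1}")
    lines.append("")
    path.write_text("\n".join(lines))

    sidecar = {
        "format": "fibrilmech-topology-sidecar-v1",
        "periodic_axial": bool(system.periodic_axial),
        "box_length": float(system.box_length),
        "column_id": system.column_id.tolist(),
        "stagger_phase": system.stagger_phase.tolist(),
        "backbone_index": system.backbone_index.tolist(),
        "grip_end": system.grip_end.tolist(),
        "column_yz": system.column_yz.tolist(),
        "column_ij": system.column_ij.tolist(),
        "column_phase": system.column_phase.tolist(),
        "angle_phi0": system.angle_phi0.tolist(),
        "bond_broken": system.bond_broken.tolist(),
        "bond_max_extension": system.bond_max_extension.tolist(),
        "gap_lower": system.gap_lower.tolist(),
        "gap_upper": system.gap_upper.tolist(),
        "gap_column": system.gap_column.tolist(),
        "gap_length_built": system.gap_length_built.tolist(),
        "gap_wrapped": system.gap_wrapped.tolist(),
        "mineral_content_achieved": float(system.mineral_content_achieved),
        "provenance": _plain(system.provenance),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_topology(path) -> FibrilSystem:
    """Parse a topology file written by :func:`write_topology`."""
    path = Path(path)
    text = path.read_text().splitlines()
    counts = {}
    box_length = 0.0
    idx = 0
    section = None
    atoms, bonds, angles = [], [], []
    for line in text:
        s = line.split("#")[0].strip()
        if not s:
            continue
        parts = s.split()
        if parts[-1] in ("atoms", "bonds", "angles") and len(parts) == 2:
            counts[parts[-1]] = int(parts[0])
            continue
        if s.endswith("types"):
            continue
        if s.endswith("xlo xhi"):
            box_length = float(parts[1]) - float(parts[0])
            continue
        if s.endswith(("ylo yhi", "zlo zhi")):
            continue
        if s in ("Masses", "Atoms", "Bonds", "Angles"):
            section = s
            continue
        if section == "Atoms":
            atoms.append(parts)
        elif section == "Bonds":
            bonds.append(parts)
        elif section == "Angles":
            angles.append(parts)
        idx += 1
    n = counts.get("atoms", len(atoms))
    if len(atoms) != n:
        raise ValueError(f"{path}: expected {n} atoms, found {len(atoms)}")
    order = np.argsort([int(a[0]) for a in atoms])
    atoms = [atoms[k] for k in order]
    positions = np.array([[float(a[3]), float(a[4]), float(a[5])]
                          for a in atoms])
    molecule_id = np.array([int(a[1]) - 1 for a in atoms], dtype=np.int32)
    species = np.array([int(a[2]) - 1 for a in atoms], dtype=np.int8)
    bond_arr = np.array([[int(b[2]) - 1, int(b[3]) - 1] for b in bonds],
                        dtype=np.int32).reshape(-1, 2)
    bond_cls = np.array([int(b[1]) - 1 for b in bonds], dtype=np.int8)
    angle_arr = np.array([[int(a[2]) - 1, int(a[3]) - 1, int(a[4]) - 1]
                          for a in angles], dtype=np.int32).reshape(-1, 3)

    side = json.loads(_sidecar_path(path).read_text())
    return FibrilSystem(
        positions=positions,
        species=species,
        molecule_id=molecule_id,
        column_id=np.array(side["column_id"], dtype=np.int32),
        stagger_phase=np.array(side["stagger_phase"], dtype=np.int8),
        backbone_index=np.array(side["backbone_index"], dtype=np.int32),
        grip_end=np.array(side["grip_end"], dtype=np.int8),
        bonds=bond_arr,
        bond_class=bond_cls,
        bond_broken=np.array(side["bond_broken"], dtype=bool),
        bond_max_extension=np.array(side["bond_max_extension"], dtype=float),
        angles=angle_arr,
        angle_phi0=np.array(side["angle_phi0"], dtype=float),
        box_length=float(side["box_length"]),
        periodic_axial=bool(side["periodic_axial"]),
        column_yz=np.array(side["column_yz"], dtype=float).reshape(-1, 2),
        column_ij=np.array(side["column_ij"], dtype=np.int32).reshape(-1, 2),
        column_phase=np.array(side["column_phase"], dtype=np.int8),
        gap_lower=np.array(side["gap_lower"], dtype=np.int32),
        gap_upper=np.array(side["gap_upper"], dtype=np.int32),
        gap_column=np.array(side["gap_column"], dtype=np.int32),
        gap_length_built=np.array(side["gap_length_built"], dtype=float),
        gap_wrapped=np.array(side["gap_wrapped"], dtype=bool),
        mineral_content_achieved=float(side["mineral_content_achieved"]),
        provenance=side["provenance"],
    )


# ---------------------------------------------------------------------------
# time series & trajectories


def write_timeseries(series: TimeSeries, path) -> Path:
    path = Path(path)
    df = series.to_dataframe()
    with open(path, "w") as fh:
        fh.write(f"# fibrilmech timeseries schema v{TIMESERIES_SCHEMA_VERSION}"
                 f" n_age_total={series.n_age_total}"
                 f" truncated={int(series.truncated)}\n")
        df.to_csv(fh, index=False)
    return path


def read_timeseries(path) -> TimeSeries:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh)
    meta = dict(tok.split("=") for tok in header.split()if "=" in tok)
    if list(df.columns) != _TS_COLUMNS:
        raise ValueError(f"{path}: unexpected column schema {list(df.columns)}")
    return TimeSeries(
        time=df["time_fs"].to_numpy(),
        strain=df["strain"].to_numpy(),
        stress=df["stress_kcal_molA3"].to_numpy(),
        broken_collagen=df["n_broken_col"].to_numpy(),
        broken_age=df["n_broken_age"].to_numpy(),
        avg_gap_length=df["avg_gap_A"].to_numpy(),
        n_age_total=int(meta.get("n_age_total", 0)),
        truncated=bool(int(meta.get("truncated", 1))),
    )


def write_dump(positions: np.ndarray, species: np.ndarray, path,
               timestep: int = 0, append: bool = False,
               box_length: float = 0.0) -> Path:
    """One LAMMPS-dump-style frame (id / type / x y z)."""
    path = Path(path)
    n = positions.shape[0]
    lo = positions.min(axis=0) - 1.0
    hi = positions.max(axis=0) + 1.0
    lines = ["ITEM: TIMESTEP", str(timestep), "ITEM: NUMBER OF ATOMS", str(n),
             "ITEM: BOX BOUNDS pp ss ss" if box_length else
             "ITEM: BOX BOUNDS ss ss ss"]
    bx = (0.0, box_length) if box_length else (lo[0], hi[0])
    lines.append(f"{bx[0]:.8g} {bx[1]:.8g}")
    lines.append(f"{lo[1]:.8g} {hi[1]:.8g}")
    lines.append(f"{lo[2]:.8g} {hi[2]:.8g}")
    lines.append("ITEM: ATOMS id type x y z")
    for i in range(n):
        lines.append(f"{i + 1} {int(species[i]) + 1} "
                     f"{positions[i, 0]:.8g} {positions[i, 1]:.8g} "
                     f"{positions[i, 2]:.8g}")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def write_checkpoint(state, path) -> Path:
    """Portable JSON+array checkpoint of a dynamic state."""
    path = Path(path)
    payload = {
        "format": "fibrilmech-checkpoint-v1",
        "time": float(state.time),
        "box_length": float(state.box_length),
        "periodic_axial": bool(state.periodic_axial),
        "positions": state.positions.tolist(),
        "velocities": state.velocities.tolist(),
        "masses": state.masses.tolist(),
    }
    path.write_text(json.dumps(payload))
    return path


def read_checkpoint(path):
    """Restore a :class:`~fibrilmech.engine.SimState` written by
    :func:`write_checkpoint` (forces are recomputed on first use)."""
    from .engine import SimState

    data = json.loads(Path(path).read_text())
    pos = np.array(data["positions"], dtype=float)
    return SimState(positions=pos,
                    velocities=np.array(data["velocities"], dtype=float),
                    forces=np.zeros_like(pos),
                    masses=np.array(data["masses"], dtype=float),
                    time=float(data["time"]),
                    box_length=float(data["box_length"]),
                    periodic_axial=bool(data["periodic_axial"]))


_SPECIES_LABEL = {0: "C", 1: "G", 2: "M"}


def write_xyz(positions: np.ndarray, species: np.ndarray, path,
              comment: str = "", append: bool = False) -> Path:
    """XYZ frame with species labels C (collagen), G (grip), M (mineral)."""
    path = Path(path)
    lines = [str(positions.shape[0]), comment]
    for i in range(positions.shape[0]):
        lines.append(f"{_SPECIES_LABEL[int(species[i])]} "
                     f"{positions[i, 0]:.8g} {positions[i, 1]:.8g} "
                     f"{positions[i, 2]:.8g}")
    with open(path, "a" if append else "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
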