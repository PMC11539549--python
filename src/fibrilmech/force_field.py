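"""Interaction laws of the coarse-grained fibril model.

Three kinds of interactions act between mesoscale particles:

* breakable *trilinear* springs for the bonds inside tropocollagen (TC)
  molecules and for AGE cross-links.  The force-extension law has an
  initial slope ``k0`` up to the critical hyperelastic distance ``r1``,
  a stiffer slope ``k1`` up to the breaking distance ``r_break``, and a
  short linear regularization ramp of width ``a = z*(r_break - r1)``
  that takes the force continuously to zero.  Rupture is irreversible:
  once a bond has been stretched past ``r_break`` it never carries load
  below ``r_break`` again.
* harmonic bending on every triple of consecutive backbone particles.
* a soft-core Lennard-Jones pair potential between non-bonded
  particles; below ``lam*sigma`` the force is capped at its value at
  ``lam*sigma``, which removes the near-field singularity.

All functions are vectorized over ``r`` and use the sign convention
that the returned scalar is the radial force on the pair: negative
pulls the particles together (restoring at extension), positive pushes
them apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "BondSpec",
    "AngleSpec",
    "PairSpec",
    "BondState",
    "ForceField",
    "COLLAGEN_BOND",
    "GRIP_BOND",
    "age_bond",
    "COL_COL_PAIR",
    "HAP_HAP_PAIR",
    "COL_HAP_PAIR",
    "DEFAULT_ANGLE",
    "default_force_field",
    "bond_force",
    "bond_energy",
    "bond_work_capacity",
    "angle_force",
    "pair_force",
    "pair_energy",
    "mark_broken",
    "tabulate_force_laws",
]


@dataclass(frozen=True)
class BondSpec:
    """Parameters of a breakable trilinear bond.

    Lengths in Angstrom, stiffnesses in kcal/mol/A^2.  ``z`` is the
    dimensionless regularization factor; the ramp width is
    ``a = z * (r_break - r1)``.
    """

    r0: float
    r1: float
    r_break: float
    k0: float
    k1: float
    z: float
    bond_class: str = "collagen"

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 < self.r_break):
            raise ValueError("require r0 < r1 < r_break")
        if self.k0 <= 0 or self.k1 <= 0:
            raise ValueError("stiffnesses must be positive")
        if not (0 < self.z < 1):
            raise ValueError("regularization factor z must be in (0, 1)")

    @property
    def a(self) -> float:
        """Width of the post-break regularization ramp, A."""
        return self.z * (self.r_break - self.r1)

    @property
    def f_break(self) -> float:
        """Force magnitude carried just before rupture, kcal/mol/A."""
        return self.k0 * (self.r1 - self.r0) + self.k1 * (self.r_break - self.r1)


@dataclass(frozen=True)
class AngleSpec:
    """Harmonic bending between three consecutive particles.

    ``phi0`` is the equilibrium angle in degrees (180 = straight chain);
    ``k_bend`` the bending stiffness in kcal/mol/rad^2.
    """

    phi0: float = 180.0
    k_bend: float = 14.98

    def __post_init__(self) -> None:
        if not (0 < self.phi0 <= 180.0):
            raise ValueError("phi0 must be in (0, 180] degrees")
        if self.k_bend < 0:
            raise ValueError("k_bend must be non-negative")


@dataclass(frozen=True)
class PairSpec:
    """Soft-core Lennard-Jones parameters for one species pair."""

    epsilon: float
    sigma: float
    lam: float
    cutoff: float
    pair_class: str = "col-col"

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("epsilon and sigma must be positive")
        if not (0 < self.lam < 1):
            raise ValueError("soft-core parameter lam must be in (0, 1)")
        if self.cutoff <= 2.0 ** (1.0 / 6.0) * self.sigma:
            raise ValueError("cutoff must exceed the potential minimum 2^(1/6)*sigma")

    @property
    def r_min(self) -> float:
        """Location of the potential minimum, 2^(1/6)*sigma."""
        return 2.0 ** (1.0 / 6.0) * self.sigma


@dataclass
class BondState:
    """Rupture bookkeeping for a single bond."""

    broken: bool = False
    max_extension_reached: float = 0.0


# Table of mesoscale parameters (collagen backbone, strengthened grip
# bonds, glucosepane-like AGE cross-links, mineral pair interactions).
COLLAGEN_BOND = BondSpec(r0=14.00, r1=18.20, r_break=21.00, k0=17.13, k1=97.66,
                         z=0.05, bond_class="collagen")
#: Strengthened bonds in the gripped fibril ends: collagen parameters
#: with the breaking distance pushed out to 70 A so they never rupture
#: during a tensile test.
GRIP_BOND = replace(COLLAGEN_BOND, r_break=70.00, bond_class="grip")

AGE_K1_RANGE = (8.0, 16.0)


def age_bond(k1: float = 8.0) -> BondSpec:
    """AGE cross-link bond spec; ``k1`` in [8, 16] kcal/mol/A^2.

    Doubling ``k1`` from 8 to 16 represents a stiffer cross-link type.
    """
    return BondSpec(r0=18.52, r1=22.72, r_break=31.72, k0=0.1, k1=k1,
                    z=0.05, bond_class="age")


COL_COL_PAIR = PairSpec(epsilon=6.87, sigma=14.72, lam=0.9, cutoff=20.0,
                        pair_class="col-col")
HAP_HAP_PAIR = PairSpec(epsilon=106.7, sigma=10.28, lam=0.9, cutoff=13.85,
                        pair_class="hap-hap")
COL_HAP_PAIR = PairSpec(epsilon=137.1, sigma=9.88, lam=0.9, cutoff=20.00,
                        pair_class="col-hap")
DEFAULT_ANGLE = AngleSpec(phi0=180.0, k_bend=14.98)

#: Mesoscale particle masses, amu.
MASS_COLLAGEN = 1548.0
MASS_MINERAL = 1324.0


@dataclass(frozen=True)
class ForceField:
    """Complete parameter set: bonds by class, bending, pairs by class."""

    collagen_bond: BondSpec = COLLAGEN_BOND
    grip_bond: BondSpec = GRIP_BOND
    age: BondSpec = field(default_factory=age_bond)
    angle: AngleSpec = DEFAULT_ANGLE
    col_col: PairSpec = COL_COL_PAIR
    hap_hap: PairSpec = HAP_HAP_PAIR
    col_hap: PairSpec = COL_HAP_PAIR
    mass_collagen: float = MASS_COLLAGEN
    mass_mineral: float = MASS_MINERAL

    def bond_spec(self, bond_class: str) -> BondSpec:
        return {"collagen": self.collagen_bond, "grip": self.grip_bond,
                "age": self.age}[bond_class]

    def pair_spec(self, pair_class: str) -> PairSpec:
        return {"col-col": self.col_col, "hap-hap": self.hap_hap,
                "col-hap": self.col_hap}[pair_class]


def default_force_field(age_k1: float = 8.0) -> ForceField:
    """Force field with the tabulated mesoscale defaults."""
    return ForceField(age=age_bond(age_k1))


def force_field_to_dict(ff: ForceField) -> dict:
    """Serialize a parameter set to plain nested dicts (YAML/JSON-able)."""
    import dataclasses

    out = {}
    for f in dataclasses.fields(ff):
        v = getattr(ff, f.name)
        out[f.name] = dataclasses.asdict(v) if dataclasses.is_dataclass(v) \
            else v
    return out


def force_field_from_dict(data: dict) -> ForceField:
    """Inverse of :func:`force_field_to_dict`; missing sections keep
    the tabulated defaults."""
    kwargs = {}
    for key, cls in (("collagen_bond", BondSpec), ("grip_bond", BondSpec),
                     ("age", BondSpec), ("angle", AngleSpec),
                     ("col_col", PairSpec), ("hap_hap", PairSpec),
                     ("col_hap", PairSpec)):
        if key in data:
            kwargs[key] = cls(**data[key])
    for key in ("mass_collagen", "mass_mineral"):
        if key in data:
            kwargs[key] = float(data[key])
    return ForceField(**kwargs)


def _check_positive_r(r: np.ndarray) -> None:
    if np.any(r <= 0):
        raise ValueError("interparticle distance r must be positive")


def bond_force(r: ArrayLike, spec: BondSpec,
               broken: ArrayLike = False) -> ArrayLike:
    """Radial force of a trilinear breakable bond, kcal/mol/A.

    ``broken`` marks bonds that have already ruptured; they carry no
    load below ``r_break`` but still follow the regularization ramp if
    currently inside it.
    """
    r_arr = np.asarray(r, dtype=float)
    _check_positive_r(r_arr)
    broken_arr = np.asarray(broken, dtype=bool)
    rb, a = spec.r_break, spec.a
    f1 = -spec.k0 * (r_arr - spec.r0)
    f2 = -(spec.k0 * (spec.r1 - spec.r0) + spec.k1 * (r_arr - spec.r1))
    f_at_break = -spec.f_break
    ramp = f_at_break * (1.0 - (r_arr - rb) / a)
    f = np.where(r_arr < spec.r1, f1, f2)
    f = np.where(r_arr >= rb, np.where(r_arr < rb + a, ramp, 0.0), f)
    f = np.where(broken_arr & (r_arr < rb), 0.0, f)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(f)
    return f


def bond_energy(r: ArrayLike, spec: BondSpec,
                broken: ArrayLike = False) -> ArrayLike:
    """Stretching energy of a bond relative to ``r0``, kcal/mol.

    Closed-form piecewise quadratic, equal to minus the integral of
    :func:`bond_force` from ``r0``.  A fully ruptured bond retains its
    total work capacity (the energy has been dissipated).
    """
    r_arr = np.asarray(r, dtype=float)
    _check_positive_r(r_arr)
    broken_arr = np.asarray(broken, dtype=bool)
    d1 = spec.r1 - spec.r0
    d2 = spec.r_break - spec.r1
    rb, a = spec.r_break, spec.a
    e_r1 = 0.5 * spec.k0 * d1 * d1
    e_rb = e_r1 + spec.k0 * d1 * d2 + 0.5 * spec.k1 * d2 * d2
    fb = spec.f_break
    e1 = 0.5 * spec.k0 * (r_arr - spec.r0) ** 2
    e2 = e_r1 + spec.k0 * d1 * (r_arr - spec.r1) + 0.5 * spec.k1 * (r_arr - spec.r1) ** 2
    s = np.clip(r_arr - rb, 0.0, a)
    e_ramp = e_rb + fb * (s - s * s / (2.0 * a))
    e = np.where(r_arr < spec.r1, e1, e2)
    e = np.where(r_arr >= rb, e_ramp, e)
    e = np.where(broken_arr & (r_arr < rb), bond_work_capacity(spec), e)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(e)
    return e


def bond_work_capacity(spec: BondSpec) -> float:
    """Loading energy capacity of one bond: area under |f|(r) from
    equilibrium to full rupture including the ramp tail, kcal/mol."""
    d1 = spec.r1 - spec.r0
    d2 = spec.r_break - spec.r1
    f1 = spec.k0 * d1
    return (0.5 * spec.k0 * d1 * d1 + f1 * d2 + 0.5 * spec.k1 * d2 * d2
            + 0.5 * spec.f_break * spec.a)


def angle_force(phi_degrees: ArrayLike, spec: AngleSpec) -> ArrayLike:
    """Harmonic restoring moment -k_bend*(phi - phi0), kcal/mol/rad.

    ``phi`` is the bending angle in degrees; the deviation is converted
    to radians before multiplying by the stiffness.
    """
    phi = np.asarray(phi_degrees, dtype=float)
    if np.any((phi <= 0) | (phi > 180.0)):
        raise ValueError("phi must be in (0, 180] degrees")
    m = -spec.k_bend * np.deg2rad(phi - spec.phi0)
    if np.isscalar(phi_degrees) or np.ndim(phi_degrees) == 0:
        return float(m)
    return m


def pair_force(r: ArrayLike, spec: PairSpec) -> ArrayLike:
    """Soft-core Lennard-Jones radial force, kcal/mol/A.

    Standard 12-6 force for ``lam*sigma <= r < cutoff``; constant
    plateau value below ``lam*sigma``; zero at and beyond the cutoff.
    Positive values are repulsive.
    """
    r_arr = np.asarray(r, dtype=float)
    _check_positive_r(r_arr)

    def _lj(rr: np.ndarray) -> np.ndarray:
        sr6 = (spec.sigma / rr) ** 6
        return (48.0 * spec.epsilon * sr6 * sr6 - 24.0 * spec.epsilon * sr6) / rr

    rcore = spec.lam * spec.sigma
    f = _lj(np.maximum(r_arr, rcore))
    f = np.where(r_arr >= spec.cutoff, 0.0, f)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(f)
    return f


def pair_energy(r: ArrayLike, spec: PairSpec) -> ArrayLike:
    """Pair potential consistent with :func:`pair_force` (energy whose
    negative radial derivative is the force), shifted to zero at the
    cutoff.  Linear in ``r`` inside the soft core."""
    r_arr = np.asarray(r, dtype=float)
    _check_positive_r(r_arr)

    def _phi(rr: np.ndarray) -> np.ndarray:
        sr6 = (spec.sigma / rr) ** 6
        return 4.0 * spec.epsilon * (sr6 * sr6 - sr6)

    rcore = spec.lam * spec.sigma
    shift = _phi(np.asarray(spec.cutoff))
    e_core = _phi(np.asarray(rcore)) + pair_force(rcore, spec) * (rcore - r_arr)
    e = np.where(r_arr < rcore, e_core, _phi(np.maximum(r_arr, rcore))) - shift
    e = np.where(r_arr >= spec.cutoff, 0.0, e)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(e)
    return e


def mark_broken(state: BondState, r: float, spec: BondSpec) -> BondState:
    """Update rupture bookkeeping after observing extension ``r``.

    Breakage triggers the first time ``r >= r_break`` and is never
    undone.
    """
    return BondState(broken=state.broken or r >= spec.r_break,
                     max_extension_reached=max(state.max_extension_reached, r))


def tabulate_force_laws(ff: ForceField, n: int = 400):
    """Dump all force laws on a distance grid as a DataFrame (for
    plotting and external validation)."""
    import pandas as pd

    frames = []
    for name, spec in [("collagen", ff.collagen_bond), ("grip", ff.grip_bond),
                       ("age", ff.age)]:
        r = np.linspace(0.5 * spec.r0, spec.r_break + 2 * spec.a, n)
        frames.append(pd.DataFrame({"law": f"bond:{name}", "r_A": r,
                                    "force": bond_force(r, spec),
                                    "energy": bond_energy(r, spec)}))
    for name, spec in [("col-col", ff.col_col), ("hap-hap", ff.hap_hap),
                       ("col-hap", ff.col_hap)]:
        r = np.linspace(0.5 * spec.lam * spec.sigma, spec.cutoff * 1.1, n)
        frames.append(pd.DataFrame({"law": f"pair:{name}", "r_A": r,
                                    "force": pair_force(r, spec),
                                    "energy": pair_energy(r, spec)}))
    return pd.concat(frames, ignore_index=True)
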