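"""Unit system of the simulation (LAMMPS-style "real" units).

Lengths are Angstrom, time femtoseconds, masses atomic mass units and
energies kcal/mol.  In this system a force of 1 kcal/mol/A acting on a
1 amu particle produces an acceleration of 4.184e-4 A/fs^2, because
1 kcal = 4184 J and 1 J = 1e-7 amu A^2/fs^2 per molecule of a mole.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Avogadro constant, 1/mol.
AVOGADRO = 6.02214076e23

#: Acceleration per (force/mass): A/fs^2 per (kcal/mol/A)/amu.
FORCE_TO_ACC = 4.184e-4

#: 1 amu*A^2/fs^2 expressed in kcal/mol (used for kinetic energy / virial).
MVV_TO_KCAL = 1.0 / FORCE_TO_ACC

#: Boltzmann constant, kcal/mol/K.
KB = 1.9872041e-3

#: 1 kcal/mol/A^3 in GPa: 4184 J/mol / (Avogadro * 1e-30 m^3) / 1e9.
STRESS_TO_GPA = 4184.0 / (AVOGADRO * 1e-30) / 1e9

#: 1 A/fs in m/s.
VELOCITY_TO_MS = 1e5


@dataclass(frozen=True)
class UnitConstants:
    """Fixed conversion factors of the real-unit system."""

    force_to_acceleration: float = FORCE_TO_ACC
    boltzmann: float = KB
    stress_to_gpa: float = STRESS_TO_GPA
    velocity_to_m_per_s: float = VELOCITY_TO_MS


def unit_constants() -> UnitConstants:
    """Return the conversion table of the unit system."""
    return UnitConstants()
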