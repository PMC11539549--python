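"""Mechanical metrics of the tensile test.

All summary quantities are pure functions of the recorded time series
(strain, engineering stress, broken-bond counts, average gap length).
Stress is carried both in simulation units (kcal/mol/A^3) and in GPa;
the stress-strain curve is analyzed for peak stress, post-failure work
(the integral of stress over strain from the peak down to effective
zero), sawtooth stress-drop events characteristic of stick-slip
intermolecular sliding, the initial elastic modulus and the onset of
large-strain stiffening.

"Effective zero" stress and the sawtooth drop threshold are quantified
as configurable fractions of the peak stress (defaults 2% and 5%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .fibril import FibrilSystem, SPECIES_COLLAGEN
from .units import STRESS_TO_GPA

__all__ = [
    "TimeSeries", "MechanicalSummary", "engineering_stress",
    "cross_section_area", "average_gap_length", "peak_stress",
    "post_failure_work", "sawtooth_events", "elastic_modulus",
    "stiffening_onset", "tangent_stiffening_ratio", "summarize",
    "elastic_agreement_strain",
]


@dataclass
class TimeSeries:
    """Per-sample record of one tensile test."""

    time: np.ndarray                  # fs
    strain: np.ndarray
    stress: np.ndarray                # kcal/mol/A^3
    broken_collagen: np.ndarray       # cumulative counts
    broken_age: np.ndarray
    avg_gap_length: np.ndarray        # A (nan if the system has no gaps)
    n_age_total: int = 0
    truncated: bool = False           # stopped at max strain, not at failure

    def __post_init__(self) -> None:
        n = self.time.size
        for name in ("strain", "stress", "broken_collagen", "broken_age",
                     "avg_gap_length"):
            if getattr(self, name).size != n:
                raise ValueError("time-series arrays must have equal length")

    @property
    def stress_gpa(self) -> np.ndarray:
        return self.stress * STRESS_TO_GPA

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_fs": self.time,
            "strain": self.strain,
            "stress_kcal_molA3": self.stress,
            "stress_GPa": self.stress_gpa,
            "n_broken_col": self.broken_collagen,
            "n_broken_age": self.broken_age,
            "avg_gap_A": self.avg_gap_length,
        })


@dataclass
class MechanicalSummary:
    """Headline mechanical quantities of one run."""

    sigma_peak: float                 # kcal/mol/A^3
    sigma_peak_gpa: float
    eps_peak: float
    eps_pf0: float                    # strain at effective-zero stress
    w_pf: float                       # post-failure work, kcal/mol/A^3
    sawtooth_count: int
    stiffening_onset_strain: Optional[float]
    elastic_modulus: float            # kcal/mol/A^3 per unit strain
    elastic_modulus_gpa: float
    broken_collagen: int
    broken_age: int
    broken_age_fraction: Optional[float]

    def to_dict(self) -> dict:
        return {k: (None if v is None or (isinstance(v, float) and np.isnan(v))
                    else v)
                for k, v in self.__dict__.items()}


def engineering_stress(grip_force: float, area: float) -> float:
    """Engineering stress = restraint force / initial cross-section.

    ``grip_force`` in kcal/mol/A, ``area`` in A^2; result in
    kcal/mol/A^3 (multiply by ``units.STRESS_TO_GPA`` for GPa).
    """
    if area <= 0:
        raise ValueError("area must be positive")
    return grip_force / area


def cross_section_area(system: FibrilSystem) -> float:
    """Initial cross-sectional area: one hexagonal lattice cell
    (sqrt(3)/2 * a^2) per molecule column."""
    a = system.provenance.get("build", {}).get("lattice_spacing")
    if a is None:
        if system.n_columns > 1:
            d = [np.linalg.norm(system.column_yz[i] - system.column_yz[j])
                 for i in range(system.n_columns)
                 for j in range(i + 1, system.n_columns)]
            a = float(np.min(d))
        else:
            a = 2.0 ** (1.0 / 6.0) * 14.72
    return system.n_columns * (np.sqrt(3.0) / 2.0) * a * a


def average_gap_length(system: FibrilSystem,
                       positions: Optional[np.ndarray] = None) -> float:
    """Mean Euclidean distance between the two terminal collagen beads
    flanking each gap.  ``positions`` defaults to the built geometry.
    Returns nan when the system records no gaps."""
    if system.gap_lower.size == 0:
        return float("nan")
    x = system.positions if positions is None else positions
    d = x[system.gap_upper] - x[system.gap_lower]
    if system.periodic_axial and system.box_length > 0:
        d[:, 0] -= system.box_length * np.round(d[:, 0] / system.box_length)
    return float(np.mean(np.linalg.norm(d, axis=1)))


def peak_stress(series: TimeSeries) -> tuple[float, float]:
    """Maximum stress and its strain (first occurrence on ties)."""
    if series.n_samples == 0:
        raise ValueError("empty time series")
    k = int(np.argmax(series.stress))
    return float(series.stress[k]), float(series.strain[k])


def _eps_pf0_index(series: TimeSeries, zero_threshold_fraction: float
                   ) -> tuple[int, int, bool]:
    """Index of the peak and of the first post-peak sample at or below
    the effective-zero threshold; flag marks threshold-not-reached."""
    sp, _ = peak_stress(series)
    kp = int(np.argmax(series.stress))
    thresh = zero_threshold_fraction * sp
    post = np.where(series.stress[kp:] <= thresh)[0]
    if post.size:
        return kp, kp + int(post[0]), False
    return kp, series.n_samples - 1, True


def post_failure_work(series: TimeSeries,
                      zero_threshold_fraction: float = 0.02) -> float:
    """Trapezoidal integral of stress over strain from the peak to the
    first strain where stress falls to the effective-zero threshold.

    An immediate drop (the very next sample is already at effective
    zero) counts as zero work.  If the threshold is never reached the
    integral runs to the end of the series (the series' ``truncated``
    flag marks such runs).
    """
    kp, kz, _ = _eps_pf0_index(series, zero_threshold_fraction)
    if kz <= kp + 1:
        return 0.0
    return float(np.trapezoid(series.stress[kp:kz + 1],
                              series.strain[kp:kz + 1]))


def sawtooth_events(series: TimeSeries, drop_fraction: float = 0.05) -> int:
    """Number of stress drops of at least ``drop_fraction * sigma_peak``
    from a local maximum before the next rise, counted between the
    first sample and the effective-zero strain."""
    if series.n_samples < 2:
        return 0
    sp, _ = peak_stress(series)
    _, kz, _ = _eps_pf0_index(series, 0.02)
    s = series.stress[:kz + 1]
    thresh = drop_fraction * sp
    count = 0
    run_max = s[0]
    armed = True
    for v in s[1:]:
        if v > run_max:
            run_max = v
            armed = True
        elif armed and run_max - v >= thresh:
            count += 1
            armed = False
            run_max = v
        elif not armed and v < run_max:
            run_max = min(run_max, v)
    return count


def elastic_modulus(series: TimeSeries,
                    strain_window: tuple[float, float] = (0.01, 0.05)
                    ) -> float:
    """Least-squares slope of stress vs strain on ``strain_window``."""
    lo, hi = strain_window
    m = (series.strain >= lo) & (series.strain <= hi)
    if np.sum(m) < 2:
        raise ValueError("fewer than 2 samples in the strain window")
    slope = np.polyfit(series.strain[m], series.stress[m], 1)[0]
    return float(slope)


def _windowed_slopes(strain: np.ndarray, stress: np.ndarray,
                     window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, slopes = [], []
    for k in range(0, strain.size - window):
        s = np.polyfit(strain[k:k + window], stress[k:k + window], 1)[0]
        centers.append(0.5 * (strain[k] + strain[k + window - 1]))
        slopes.append(s)
    return np.array(centers), np.array(slopes)


def stiffening_onset(series: TimeSeries, window: Optional[int] = None,
                     rise_factor: float = 1.2, min_strain: float = 0.05,
                     persist_fraction: float = 0.9) -> Optional[float]:
    """Onset strain of large-strain stiffening, or None.

    The smoothed tangent modulus (moving-window least-squares slope) is
    scanned up to the stress peak; the onset is the smallest strain
    after ``min_strain`` where the modulus exceeds ``rise_factor``
    times its running minimum *and keeps exceeding it* — the mean
    modulus over the remainder of the pre-peak curve stays above the
    threshold and at least ``persist_fraction`` of the remaining
    windows lie above the reference.  The persistence requirement
    separates genuine stiffening (which by construction lasts until the
    peak) from noise bumps.  Invariant under uniform stress rescaling.

    Designed for reasonably smooth curves; on short, thermally noisy
    records the result is indicative only.
    """
    kp = int(np.argmax(series.stress))
    strain = series.strain[:kp + 1]
    stress = series.stress[:kp + 1]
    n = strain.size
    smooth_w = max(3, n // 40)
    if window is None:
        window = max(7, n // 25)
    if n < window + 6:
        return None
    kern = np.ones(smooth_w) / smooth_w
    smoothed = np.convolve(stress, kern, mode="same")
    centers, slopes = _windowed_slopes(strain, smoothed, window)
    keep = centers >= min_strain
    centers, slopes = centers[keep], slopes[keep]
    if centers.size < 6:
        return None
    scale = np.percentile(np.abs(slopes), 90)
    for k in range(1, centers.size - 3):
        ref = max(float(np.min(slopes[:k])), 0.02 * scale)
        rest = slopes[k:]
        if (slopes[k] >= rise_factor * ref
                and np.mean(rest) >= rise_factor * ref
                and np.mean(rest >= ref) >= persist_fraction):
            return float(centers[k])
    return None


def tangent_stiffening_ratio(series: TimeSeries,
                             early_window: tuple[float, float] = (0.01, 0.08),
                             late_window: tuple[float, float] = (0.25, 0.40)
                             ) -> float:
    """Ratio of the late-strain to early-strain tangent modulus.

    A robust scalar indicator of large-strain stiffening for noisy
    curves: > 1 means the curve is steeper late than in its initial
    elastic response.
    """
    early = elastic_modulus(series, early_window)
    late = elastic_modulus(series, late_window)
    return late / early


def summarize(series: TimeSeries,
              zero_threshold_fraction: float = 0.02,
              drop_fraction: float = 0.05,
              modulus_window: tuple[float, float] = (0.01, 0.05)
              ) -> MechanicalSummary:
    """All headline metrics of one run."""
    sp, ep = peak_stress(series)
    kp, kz, truncated = _eps_pf0_index(series, zero_threshold_fraction)
    try:
        e_mod = elastic_modulus(series, modulus_window)
    except ValueError:
        e_mod = float("nan")
    frac = (float(series.broken_age[-1]) / series.n_age_total
            if series.n_age_total else None)
    return MechanicalSummary(
        sigma_peak=sp,
        sigma_peak_gpa=sp * STRESS_TO_GPA,
        eps_peak=ep,
        eps_pf0=float(series.strain[kz]),
        w_pf=post_failure_work(series, zero_threshold_fraction),
        sawtooth_count=sawtooth_events(series, drop_fraction),
        stiffening_onset_strain=stiffening_onset(series),
        elastic_modulus=e_mod,
        elastic_modulus_gpa=e_mod * STRESS_TO_GPA,
        broken_collagen=int(series.broken_collagen[-1]),
        broken_age=int(series.broken_age[-1]),
        broken_age_fraction=frac,
    )


def elastic_agreement_strain(reference: TimeSeries, others: list[TimeSeries],
                             rel_tol: float = 0.10,
                             floor_fraction: float = 0.02,
                             smooth: int = 5,
                             grid: Optional[np.ndarray] = None) -> float:
    """Largest strain up to which all curves agree with the reference
    within ``rel_tol`` relative deviation.

    Curves are lightly smoothed (moving average over ``smooth`` samples)
    and compared on a common strain grid.  The denominator is floored at
    ``floor_fraction`` of the reference peak stress, since the relative
    deviation is undefined where the stress itself vanishes.
    """
    def smoothed(ts: TimeSeries) -> tuple[np.ndarray, np.ndarray]:
        kern = np.ones(smooth) / smooth
        s = np.convolve(ts.stress, kern, mode="same")
        return ts.strain, s

    ref_e, ref_s = smoothed(reference)
    if grid is None:
        emax = min([reference.strain[-1]] + [o.strain[-1] for o in others])
        grid = np.linspace(0.0, emax, 400)
    ref_on = np.interp(grid, ref_e, ref_s)
    sp, _ = peak_stress(reference)
    floor = floor_fraction * sp
    agree_to = grid[-1]
    for o in others:
        oe, os_ = smoothed(o)
        o_on = np.interp(grid, oe, os_)
        dev = np.abs(o_on - ref_on) / np.maximum(np.abs(ref_on), floor)
        bad = np.where(dev > rel_tol)[0]
        if bad.size:
            agree_to = min(agree_to, grid[bad[0]])
    return float(agree_to)
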