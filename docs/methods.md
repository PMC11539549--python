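# Methods

`fibrilmech` simulates the tensile mechanics of a single mineralized,
glycation-cross-linked collagen fibril with a coarse-grained bead-spring
model and steered molecular dynamics.  This note records the model, its
parameters, the numerical choices, what the reduced-scale simulations
emulate, and the known limitations.

## Model

### Geometry

A tropocollagen (TC) molecule is a straight string of beads at the bond
equilibrium spacing r₀ = 14 Å (218 beads at full scale, so the molecule
is L = 217·14 Å ≈ 304 nm long).  Molecules sit on a hexagonal transverse
lattice with spacing 2^{1/6}·σ_col ≈ 16.52 Å (the collagen–collagen
pair-potential minimum) and follow the collagen-specific five-fold
stagger: each lattice column carries one molecule per axial period,
shifted by s·D with stagger phase s ∈ {0..4}, where the period D is
*derived* from the bead geometry,

    D = L / (5 − g),      g = 0.6 (gap fraction),

so that each column shows one gap of length g·D and an overlap of
(1−g)·D per 5D axial cell, with every bond starting at equilibrium.
(The experimental constraints r₀ = 14 Å, 218 beads, D = 67 nm and
gap = 0.6·D are mutually inconsistent by ≈3%; spacing and bead count
are taken as primary, giving D ≈ 69 nm.)  Phases are assigned as
s = (i + 2j) mod 5 on integer lattice coordinates, which guarantees
that transverse neighbors differ in phase.

Molecules crossing the axial cell boundary are split into two chain
segments that keep the molecule identity — equivalently, the finite
fibril is cut flat at both ends and the truncated remainder of each
molecule appears at the opposite end.  In non-periodic (tensile) builds
every chain end lying at a fibril boundary is extended with grip beads
(20 per end at full scale) whose bonds use the strengthened breaking
distance r_break = 70 Å; grips are the beads displaced during pulling.
The column whose gap abuts the boundary (phase 0) is gripped at one end
only: bonding its single molecule to both grips would make pure
intermolecular sliding geometrically impossible, contradicting the
observed sliding failure mode of unmineralized, uncross-linked fibrils.
Periodic builds (for equilibration of an effectively infinite fibril)
have no grips and bond the split segments across the seam.

### Mineral

Mineral is represented by unbonded beads (hydroxyapatite-like, mass
1324 amu) laid along the column axis inside the gap zones, first bead
at the collagen–mineral pair minimum (2^{1/6}·σ_col-HAP ≈ 11.09 Å) from
the flanking terminal bead, subsequent beads at the mineral–mineral
minimum (2^{1/6}·σ_HAP ≈ 11.54 Å).  Patterns: `edge` (grow inward from
both gap transitions — the reference), `center` (grow outward from the
gap midpoint), `sparse_half` (edge slot grid with every second slot
empty; content measures the spanned extent), `double_row` (edge plus a
parallel row offset transversely by one mineral spacing, direction
chosen per column to maximize clearance from neighboring columns).
The mineral content c = m/l·100% is the fraction of the gap length l
occupied; slot quantization means the achieved content is the largest
attainable value not exceeding the request, and it is recorded.  At
desk scale the slot granularity is coarse (each slot ≈ 10% of the gap).

### Cross-links

AGE (advanced glycation end-product) cross-links are extra breakable
bonds inserted *after* equilibration, N_AGE per TC molecule: a donor
bead is drawn uniformly from the central 95% of the molecule's backbone
(the helical region), and the partner is the nearest central-region
bead of a different molecule on a transversely neighboring column
within the eligibility cutoff (the AGE critical distance, 22.72 Å).
Because the nearest-neighbor relation is symmetric, opposing molecules
contend for the same pairs; when the nearest pair already exists the
next-nearest eligible partner is used, keeping the per-molecule count
exact.  Glucosepane-like parameters are used; the stiffness k₁ may be
doubled (8 → 16 kcal/mol/Å²) to represent a stiffer cross-link type.

### Interactions

* **Bonds** (collagen backbone, grip, AGE): continuous trilinear
  springs — slope k₀ to the critical distance r₁, slope k₁ to the
  breaking distance r_break, then a linear regularization ramp of width
  a = z·(r_break − r₁) down to zero.  Rupture is irreversible: past
  r_break a bond never again carries load below r_break.  (The ramp
  width is read as z·(r_break − r₁); the printed form z·r_break − r₁
  is negative at the tabulated values.)
* **Bending**: harmonic in the angle over every three consecutive
  chain beads, k_B = 14.98 kcal/mol/rad², equilibrium angle 180° by
  default (per-angle values accepted from configuration).
* **Non-bonded pairs**: 12-6 Lennard-Jones force with a soft core —
  below λσ (λ = 0.9) the force is capped at its λσ value — truncated at
  the cutoff.  Species pairs col–col (ε 6.87, σ 14.72), HAP–HAP
  (ε 106.7, σ 10.28, cutoff 13.85) and col–HAP (ε 137.1, σ 9.88,
  cutoff 20.0).  The col–col cutoff is not tabulated in the source
  parameter set; 20.0 Å is used (same cutoff class as col–HAP) and is
  configurable.  Directly bonded (1–2) pairs are excluded; 1–3 pairs
  are kept (they lie beyond the cutoffs at the default geometry).

Masses: 1548 amu for collagen and grip beads, 1324 amu for mineral.
Units are LAMMPS-style "real" units (Å, fs, amu, kcal/mol);
1 kcal·mol⁻¹·Å⁻³ = 6.9477 GPa, 0.0001 Å/fs = 10 m/s.

## Protocols

**Equilibration.**  Armijo-backtracked steepest-descent minimization
(bond extensions capped just below r_break so relaxation cannot break
bonds, with the capped energy continued linearly so the line search
stays consistent), then BAOAB Langevin dynamics at 300 K, Δt = 10 fs,
damping time 1 ps.  The full-scale protocol equilibrates 20 ns in an
NPT ensemble; here NPT is approximated by
minimization + NVT with an optional Berendsen-style axial box rescale
(periodic builds only, per-step strain clamped at 10⁻⁴).  Desk-scale
runs equilibrate 20 ps — long enough to thermalize the small fibril,
chosen as the package's routine verification scale.  Any bond breakage
during equilibration aborts the run.

**Tensile test.**  Grip beads move rigidly and symmetrically at ±v/2
along the axis (their equations of motion are replaced by the ramp).
Strain is the imposed gauge elongation over the initial grip-centroid
separation; engineering stress is the mean of the two grip
restraint-force magnitudes (time-averaged over each sampling stride)
divided by the initial cross-section, N_columns·(√3/2)·a² with a the
lattice spacing.  During pulling the Langevin thermostat acts on the
*peculiar* velocity v − u: per-particle friction on absolute velocities
would exert a rate-proportional drag on the imposed deformation flow
(≈ m·v/τ per bead — comparable to the sliding stress at the desk
pulling rate), an artifact a global-rescale NVT thermostat does not
have.  The streaming estimate u is a per-particle exponential moving
average (2 ps memory) of the axial velocity, initialized to the affine
profile; a static affine profile would re-introduce drag once sliding
localizes.  The run samples strain, stress, cumulative broken
collagen/AGE bond counts and the average gap length (mean Euclidean
distance between the terminal beads flanking each gap), and stops at
max strain or once the smoothed stress falls below 2% of the running
peak ("effective zero", which also defines ε_PF0 for the post-failure
work integral W_PF = ∫σ dε from the peak to ε_PF0).

**Presets.**  `full` (155 molecules × 218 beads, v = 0.0001 Å/fs) is
buildable and runnable but expensive; `desk` (19 × 58, grips 10/end,
v = 0.001 Å/fs) preserves the gap/overlap fractions and all force laws
and is the acceptance scale; `mini` (7 × 33, v = 0.002 Å/fs) is the
smallest geometry with all five stagger phases, used for fast property
checks.

## Analysis choices

"σ ≈ 0" is quantified as 2% of the peak stress; the sawtooth counter
registers drops ≥5% of the peak from a local maximum before the next
rise; the elastic modulus is the least-squares slope on ε ∈
[0.01, 0.05].  The stiffening-onset detector smooths the pre-peak
curve, computes moving-window tangent moduli, and reports the first
strain (after 0.05) where the modulus exceeds 1.2× its running minimum
*and persists above it for the remainder of the pre-peak curve* — the
persistence requirement separates genuine stiffening from noise bumps;
on short noisy records the scalar late/early tangent-modulus ratio is
the more robust stiffening indicator and is used for ordering
comparisons.  The mineral-insensitivity strain (target t7) compares
seed-averaged, lightly smoothed curves on a common strain grid against
the zero-mineral reference with a 10% relative tolerance, the
denominator floored at 5% of the reference peak because a relative
deviation is undefined where the stress itself vanishes.

## What the reduced scale does and does not show

The desk and mini fibrils preserve the architecture (stagger, gap
fraction, grips) and every interaction law, and they reproduce the
central mechanisms: pure sliding failure with zero broken collagen
bonds and stick-slip sawtooth at zero mineral/cross-links, monotone
strengthening with mineral content, AGE-induced strengthening and
stiffening that grows with cross-link stiffness.

Two quantities do *not* survive the reduction, because they depend on
ratios that change with molecule length and cross-section:

* **Distributed cross-link rupture.**  With N_AGE fixed per molecule,
  shortening molecules from 218 to 58 beads multiplies the per-length
  AGE density by 3.75.  A Griffith-type peel estimate (the backbone
  tension required to rupture cross-links sequentially,
  T ≈ √(2·k₀·sp²·W_AGE·ρ_AGE)) then reaches ≈340 kcal/mol/Å — the
  backbone rupture force itself (345) — so failure localizes onto a
  single surface through a handful of backbone bonds and only the
  cross-links at that surface break (≈6–13% over seeds).  At full
  scale the peel tension is ≈175, molecules peel off their cross-links
  progressively, and the majority of cross-links is expected to
  rupture.  Reduced runs with 218-bead
  molecules and a 19-column cross-section still localize (≈19%),
  so the full cross-section appears necessary as well.
* **Early-response mineral insensitivity.**  An edge-pattern mineral
  row bridges the gap with stiff pair contacts, adding a direct tensile
  path per column whose stiffness is set by the *molecule* compliance
  in series with the bridge.  Relative to the fibril modulus this
  contribution scales inversely with molecule length; at 58 beads it
  adds tens of percent to the early response (a dimensional estimate
  puts the full-scale contribution near 10%), so mineralized desk
  curves separate from the zero-mineral reference well before strain
  0.1.

Both effects are reported as measured; the acceptance checks tied to
them are expected to fail at desk scale and the failure is analyzed
rather than hidden.  Three orderings are likewise sensitive to the
reduction: center-of-gap nucleation measures slightly *weaker* than
edge nucleation at low content (center rows do not touch the gap
flanks in the pristine reduced geometry, removing the direct load
path); the broken-AGE decrease with mineral content is only marginal
because the localized failure surface breaks few AGEs at any mineral
content; and full mineralization does not produce broken collagen
bonds at desk scale (0 over four seeds) — the axial anchor a mineral
row offers one column (a few pair contacts, tens of kcal/mol/Å) is an
order of magnitude below the backbone rupture force, and the extra
sliding resistance mineral provides scales with molecule length and
cross-section, both of which the reduction shrinks.

Other idealizations shared with the source model: no water, pH effects,
enzymatic cross-links or extrafibrillar mineral; straight backbones
(no helical substructure); a single pulling rate per run; AGE
placement random within the helical region.  The weakest-link example
(a single chain pulled to rupture) idealizes further: all bonds of a
uniform chain reach criticality together, so rupture is a small
localized burst rather than literally one bond.

## Numerical notes

* Velocity-Verlet (NVE) and BAOAB (Langevin) integrators; Δt = 10 fs
  throughout.  NVE energy drift < 10⁻⁴ relative over 10⁴ steps on a
  bonded chain; equipartition at 300 K within 5% on a dilute gas.
* Neighbor lists from a k-d tree with 3 Å skin, rebuilt on half-skin
  displacement; exact pair enumeration verified against brute force.
* Force kernels exist twice: a vectorized numpy reference path and
  numba-compiled loops (identical to machine precision, ~6× faster);
  tests compare both against an independent per-interaction python
  loop.
* Breakage is evaluated every step on the stretched distance; the
  bond-state arrays (broken flag, maximum extension reached) live with
  the topology and are serialized with it.
* Determinism: every pipeline stage draws from named substreams of one
  master seed; identical configuration + seed gives identical output
  files.
* Degenerate inputs: anti-parallel angle arms get zero bending force;
  empty neighbor lists, zero-duration equilibration (minimization
  only) and zero-content mineralization are all well-defined.
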