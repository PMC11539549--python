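# fibrilmech

Coarse-grained molecular dynamics of mineralized, AGE-cross-linked
collagen fibrils under destructive tension.

Mineralized collagen fibrils are the basic mechanical unit of bone.
Their behavior is set by three ingredients: the staggered tropocollagen
(TC) molecules themselves, the mineral deposited in the gap zones of
the D-periodic structure, and sugar-derived cross-links (advanced
glycation end-products, AGEs — elevated in diabetes) that tie
neighboring molecules together.  `fibrilmech` builds such fibrils as
bead-spring systems, pulls them apart with steered dynamics, and
measures how mineral content/morphology and cross-link density/
stiffness shift the failure mechanism between intermolecular *sliding*
(tough, sawtooth stick-slip) and *bond rupture* (strong, brittle).

It is aimed at researchers in bone/collagen nanomechanics who want a
desk-scale, fully scriptable re-implementation of this class of model:
every force law, the fibril architecture, and the loading protocol are
exposed as plain Python objects.

## Model in brief

A TC molecule is a chain of beads (spacing r₀ = 14 Å, 218 beads at
full scale) on a hexagonal lattice with the collagen 5-fold stagger:
period D = L/(5 − 0.6), one gap of 0.6·D per column per 5D cell.
Interactions:

* bonds (collagen, strengthened grip ends, AGE cross-links):
  continuous trilinear springs, force −k₀(r−r₀) up to r₁, then slope
  k₁ up to r_break, then a regularization ramp of width
  a = z(r_break−r₁) to zero — rupture is irreversible;
* harmonic bending (k_B = 14.98 kcal/mol/rad²) on consecutive triples;
* soft-core 12-6 Lennard-Jones between non-bonded beads (force capped
  below λσ, λ = 0.9) for collagen–collagen, mineral–mineral and
  collagen–mineral pairs.

Mineral beads are unbonded and laid equidistantly into the gap zones
(edge/center nucleation, sparse and double-row morphologies); content
c = m/l·100% is the occupied fraction of the gap.  AGEs are inserted
per molecule between the central 95% helical regions, after
equilibration.  The tensile test moves the strengthened fibril ends
apart at constant velocity (0.0001 Å/fs = 10 m/s at full scale) in a
300 K NVT ensemble, Δt = 10 fs, and records engineering stress
σ = F_grip/A₀, strain, broken-bond counts and the average gap length;
summaries report σ_peak, ε_peak, the post-failure work
W_PF = ∫σ dε (peak → effective zero), sawtooth counts, the elastic
modulus and the stiffening onset.

See `docs/methods.md` for the full parameter table, protocol details
and the limitations of the reduced problem sizes.

## Worked example

Build a small fibril (7 molecules × 33 beads), mineralize 40% of the
gaps, insert 10 AGEs per molecule, equilibrate briefly and pull to
failure:

```python
from fibrilmech import (BuildConfig, MineralSpec, CrosslinkSpec, RunConfig,
                        PullSchedule, run_tensile_pipeline, summarize)

build = BuildConfig(particles_per_molecule=33, molecules_per_cross_section=7,
                    grip_particles_per_molecule_end=4)
mineral = MineralSpec(pattern="edge", content_percent=40)
cross = CrosslinkSpec(n_per_molecule=10, k1_age=8.0)
run_cfg = RunConfig(equilibration_fs=1.0e4, seed=1)
schedule = PullSchedule(speed=0.002, sample_stride=60, max_strain=0.85)

system, series = run_tensile_pipeline(build, mineral, cross, run_cfg,
                                      schedule, seed=1)
s = summarize(series)
```

prints (via the obvious f-strings):

```
particles:        295
mineral content:  36.3 %
AGE cross-links:  70
peak stress:      2.74 GPa at strain 0.43
post-failure work: 0.1114 GPa (stress x strain)
broken bonds:     1 collagen, 17/70 AGE
sawtooth events:  1
elastic modulus:  4.2 GPa
```

The requested 40% mineral content quantizes to 36.3% (mineral beads
occupy discrete slots in each gap).  The cross-links strengthen the
fibril well past the sliding stress of the bare geometry (~0.35 GPa)
and make failure abrupt: one collagen bond and a quarter of the AGEs
break at the failure surface.  `series.to_dataframe()` gives the full
stress–strain/rupture record for plotting
(`fibrilmech.plotting.plot_run_overview`).

The same pipeline is available from the shell:

```
fibrilmech build --config fibril.yaml --out fibril.data
fibrilmech pull  --config fibril.yaml --out run/
fibrilmech analyze run/timeseries.csv
fibrilmech sweep mineral_sweep_reduced --out sweeps/ --seed 1
```

Topologies are LAMMPS-data-style text (plus a JSON sidecar), time
series are versioned CSV, trajectories XYZ / LAMMPS dump; all are
readable by standard MD tooling (the test-suite round-trips them
through MDAnalysis).

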