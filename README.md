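# inhibikit

Analytics for affinity-based enzyme-inhibitor discovery from natural-product
extracts, built around the tyrosinase workflow: a crude plant extract is
incubated with the enzyme, enzyme-bound metabolites are removed by
ultrafiltration, and binders reveal themselves as peak-area losses in the
unbound LC-MS fraction.  The surviving candidates are then characterised by
exact-mass annotation, enzyme kinetics (including slow-binding analysis),
docking-pose post-processing, and MD contact analysis.

The package is a library first — `import inhibikit` and call the modules —
with an `examples/` directory of narrative scripts and a thin `inhibikit`
CLI for shell use.  Because raw instrument, docking-engine and MD-engine
outputs are not portable, a seeded synthetic-data module
(`inhibikit.synthdata`) emulates every input with known ground truth, so the
whole pipeline is testable end to end.

## What it computes

**Ultrafiltration screen** (`ufscreen`): peaks are matched across control
and enzyme-incubated runs (retention time ± 0.1 min, m/z ± 10 ppm), the
binding degree is the percent area reduction
`100 × (1 − area_treated / area_control)`, and hits are called above a
configurable threshold (default 35%).

**Mass annotation** (`msannot`): calculated deprotonated ions
`[M − H]⁻ = M_mono − m(H)`, signed ppm errors
`(m_det − m_calc)/m_calc × 10⁶`, neutral-loss assignment (glucose residue
162.0528 Da, 114 Da ring cleavage), and the 3:1 M/M+2 chlorine-cluster test.

**Kinetics** (`kinetics`):

- dose-response `Activity(%) = 100 / (1 + [I]/IC₅₀)` (Hill slope 1);
- Michaelis–Menten `v = V_max S / (K_m + S)`, initialised from the
  Lineweaver–Burk double-reciprocal line;
- inhibition-mode classification from per-[I] Lineweaver–Burk lines, with
  K_i from a global competitive refit and from the Dixon-plot intersection;
- slow-binding analysis under the enzyme-isomerisation model
  Enz + I ⇌ Enz·I → Enz*·I: progress curves
  `A(t) = A₀ + v_s t + (v_i − v_s)(1 − e^{−k_obs t})/k_obs`, velocity decay
  `v/v₀ = e^{−k_obs t}`, and the secondary plot
  `k_obs = k₆ + k₅[I]/(K_i^app + [I])`.

**Docking post-processing** (`dockrank`): deterministic leader clustering
of poses by centre of mass, per-group occupancy and energy statistics,
active-site assignment relative to the binuclear copper pair, compound
ranking, and geometric hydrogen-bond detection (donor–acceptor < 4 Å,
donor–H–acceptor > 120°).

**MD contact analysis** (`mdtraj`): Kabsch-superposition RMSD, per-residue
C-alpha RMSF, radius of gyration, and ring-COG-to-residue distance profiles
with a 10 Å contact limit driving bound/dissociated verdicts.

## Worked example

```sh
python examples/01_ultrafiltration_screen.py
```

```
peak    control    treated  reduction  hit
   4      16481       2886      82.5%  *
   2      10677       3852      63.9%  *
   8        976        465      52.4%  *
   6      44999      22171      50.7%  *
   1     112306      61907      44.9%  *
   7      12844       8093      37.0%  *
   5      17798      12194      31.5%
   9      15756      11932      24.3%
   3      26121      21250      18.6%

6 binder(s) at >= 35% area reduction: peaks 1, 2, 4, 6, 7, 8
```

Six of the nine extract metabolites lose more than a third of their
unbound-fraction area after enzyme incubation — these are the binders the
downstream stages characterise.  `examples/03_enzyme_kinetics.py` then
prints the kinetic fits for the lead compound:

```
IC50 fit: 31.2 uM (generating 31.2)
Km fit:   180.0 uM (generating 180.0); Vmax 1.000
mode:     competitive; Ki 5.10 uM (Dixon 5.10 uM)
slow binding: k5 0.04496 1/s, k6 1.103e-05 1/s, Ki_app 2.402 mM, R^2 1.0000
mechanism verdict: enzyme isomerisation (slow-binding)
```

Each value is recovered by refitting synthetic data generated at the stated
parameters; the saturating k_obs-vs-[I] curve is the kinetic signature of
two-step (isomerising) slow binding.  The remaining examples cover mass
annotation, pose ranking with hydrogen-bond detection, MD contacts, and the
full study (`examples/06_full_study.py`, which also runs 12 ground-truth
recovery checks).

## Layout

```
src/inhibikit/       library (ufscreen, msannot, kinetics, dockrank,
                     mdtraj, synthdata, pdbio, pipeline, cli)
src/inhibikit/data/  packaged nine-iridoid reference peak table (CSV)
examples/            one narrative script per capability
tests/               pytest suite (unit, property and acceptance tests)
docs/methods.md      models, assumptions, numerical choices, limitations
```
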