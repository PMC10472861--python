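# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical choices a maintainer would want to know about.  No number
here is asserted beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Differential ultrafiltration screen

The screen compares integrated LC-MS peak areas of the unbound fraction
between an enzyme-free control run and an enzyme-incubated run.  A
metabolite sequestered by the enzyme is depleted from the unbound fraction,
so its binding degree is quantified as `100 × (1 − area_treated /
area_control)`; negative values (area increases) are legitimate output and
flag matrix or matching problems rather than being clipped.

*Peak matching* is greedy nearest-retention-time within a tR window
(default ± 0.1 min, a UPLC peak-width scale) and an m/z window (default
± 10 ppm, a QTOF accuracy scale); ties on tR fall back to the smaller m/z
difference, and every peak is used at most once.  Unmatched peaks are
reported, never dropped — a peak present only in the control is itself
evidence of complete sequestration and belongs in the audit trail.

*Hit threshold.* The field's "significantly reduced" is not a quantity, so
the package fixes a default of 35% reduction: on the packaged reference
screen this separates the cluster of strong binders (37–82% reduction)
from the marginal non-binders (below 32%).  It is configuration, not a
constant, and single-area tables support thresholding only — replicate
statistics would need replicate areas, which this screen format does not
carry.

## Exact-mass annotation

Masses are sums of most-abundant-isotope masses (¹²C 12 exactly, ¹H
1.0078250, ¹⁴N 14.0030740, ¹⁶O 15.9949146, ³²S 31.9720707, ³⁵Cl
34.9688527).  The calculated deprotonated ion is the neutral monoisotopic
mass minus the mass of a hydrogen **atom**.  The physically complete
convention would subtract a proton and add an electron mass (≈ 0.55 mDa
difference), but the hydrogen-atom convention is what common instrument
software prints and is what reproduces the packaged reference ions to all
four printed decimals, so it is the package default and is stated in the
API documentation.  Reporting precision follows the instrument convention:
masses to 4 decimals, ppm errors to 1 decimal.

The neutral-loss library is deliberately tiny and user-extensible: the
glucose residue (C₆H₁₀O₅, 162.0528 Da, matched on exact mass within a
10 mDa default tolerance) and the 114 Da iridoid ring cleavage (two
aldehyde groups plus a 28 Da ring fragment), which is catalogued by nominal
mass only because no exact composition is assigned to it.  Unmatched losses
are returned unlabelled rather than suppressed.

The chlorine test flags a single Cl atom when the M/M+2 intensity ratio is
within 25% (relative) of the natural ³⁵Cl/³⁷Cl ratio of ~3.13 ≈ 3:1; a
missing M+2 peak means "no chlorine", not an error.

One packaged reference row (the C₂₄H₃₀O₁₃ glycoside) prints a calculated
ion of 525.1613 that is arithmetically inconsistent with its own formula
(which gives 525.1608); the row is retained in the data file but excluded
from the mass-regression test, and the discrepancy is left visible rather
than silently corrected.

## Kinetics

All fits are unweighted nonlinear least squares (lmfit/least-squares), each
initialised from the analytic linearisation of its model, with both the
linearised and the refined estimates reported where the linearisation is a
standard plot (Lineweaver–Burk).

- **Dose-response** is the one-parameter logistic
  `Activity = 100/(1 + [I]/IC₅₀)` with Hill slope fixed at 1 — the model
  the assay convention prescribes.  A four-parameter option would absorb
  baseline effects but is intentionally not the default.  Data entirely
  above 95% or below 5% activity cannot pin the midpoint and are flagged
  `poorly_determined` rather than refused.
- **Michaelis–Menten** needs ≥ 3 distinct substrate levels; the
  Lineweaver–Burk line supplies (K_m/V_max, 1/V_max) starting values, with
  a scale heuristic fallback when the line is pathological.
- **Mode classification** fits one double-reciprocal line per inhibitor
  level and compares: competitive inhibition leaves the y-intercept
  (1/V_max) fixed while slopes grow with [I]; uncompetitive leaves the
  slope; noncompetitive leaves the x-intercept (−1/K_m); anything else is
  mixed.  "Agree" means a spread below 10% of the mean — plots, not a
  rule, are the field's standard here, so the tolerance is explicit
  configuration.  K_i then comes from a global refit of the classified
  rate law, and independently from the Dixon construction: the 1/v-vs-[I]
  lines at fixed S intersect at [I] = −K_i, located here as the
  least-squares common intersection over all lines (a 2-unknown linear
  problem), which degrades gracefully to a parallel-lines warning for
  uncompetitive patterns.
- **Slow binding.**  Progress curves follow
  `A(t) = A₀ + v_s t + (v_i − v_s)(1 − e^{−k_obs t})/k_obs`, with the
  analytic limit `A₀ + v_i t` at k_obs = 0 (no epsilon tricks).
  Initialisation: early-window slope for v_i, late-window slope for v_s,
  and a transient rate scaled to the observation window.  Near-linear data
  yield v_i ≈ v_s with an explicit `kobs_unidentifiable` flag: a transient
  decaying less than ~5% over the window is indistinguishable from a
  straight line.  The preincubation decay `v/v₀ = e^{−k_obs t}` is fitted
  through the fixed point (0, 1) with a log-linear start.  The secondary
  plot `k_obs = k₆ + k₅[I]/(K_i^app + [I])` needs ≥ 4 inhibitor levels
  spanning K_i^app; the mechanism verdict ("enzyme isomerisation" vs
  "simple reversible") requires the hyperbola to beat a straight line by
  ΔR² ≥ 0.01 **and** a residual-sum-of-squares F-ratio ≥ 2, because a line
  is the K_i^app → ∞ limit of the hyperbola and R² alone cannot separate
  them on noisy data.

Units are fixed at the interface: µM for dose-response, Michaelis–Menten
and Dixon work; mM for the slow-binding secondary plot; seconds for time;
dopachrome absorbance at 475 nm in arbitrary units.  V_max is arbitrary
because every reported quantity is either V_max-free or trivially scales.

## Docking post-processing

*Clustering* is a leader algorithm on pose centres of mass: poses are
visited in ascending energy order (ties broken by run order, making the
procedure fully deterministic), each joining the first group whose
running-mean centroid lies within the cutoff, else founding a new group.
The default cutoff is 3.5 Å; clustering quality is judged against planted
ground truth in tests, where well-separated clouds (≥ 30 Å apart, ~1 Å
spread) are recovered exactly at a 5 Å cutoff.  A leader scheme was chosen
over hierarchical/k-means because it is single-parameter, order-stable and
deterministic — properties the audit trail needs more than optimal cluster
shapes.

*Active-site assignment* labels a group "active" when its centroid lies
strictly within 8 Å of the midpoint of the two catalytic copper ions —
large enough to enclose the catalytic pocket, small enough to exclude
surface sites.  *Ranking* reports, per compound, its best active-site
group if any (else its overall best), ordered by (lowest energy ↑,
occupancy ↓, mean energy ↑).

*Hydrogen bonds* use strict geometric criteria: donor–acceptor distance
< 4 Å and donor–hydrogen–acceptor angle > 120°, both strict inequalities,
with the distance measured donor-to-acceptor (not hydrogen-to-acceptor).
Donors are N/O atoms with a hydrogen inferred covalent by distance
(< 1.2 Å), because pose files carry no bond table; acceptors are all N/O
atoms; both molecular directions are scanned.  Missing explicit hydrogens
empty the donor list with a warning instead of silently finding nothing.

## Trajectory analysis

Superposition uses the Kabsch solution (via scipy's rotation alignment).
Two RMSD notions are exposed deliberately: `rmsd` compares coordinates as
given (the closed-form checks in the tests use this), while
`kabsch_superpose` returns the RMSD after optimal fitting — the two differ
whenever the optimal transform is not the identity, and conflating them is
a classic source of irreproducible numbers.  RMSF is computed per atom
about the time-mean structure with two-pass alignment (align to frame 0,
form the mean, re-align to the mean); the alignment selection can be
decoupled from the analysis selection so that a rigid anchor region can
define the frame — otherwise the alignment itself absorbs part of the
motion being measured.  R_g is mass-weighted (the standard definition)
while ring centres are unweighted geometric means (centres of geometry),
matching how contact profiles are defined.

Contact analysis measures, per frame, the distance from each ligand-ring
COG to the C-alpha of each profiled pocket residue.  A ring is "bound"
when at least 90% of frames keep its minimum-over-residues distance below
the 10 Å limit; the compound is bound when any ring (the anchor) is.  Both
limit and fraction are configuration.

## Synthetic data

The generators produce inputs with the statistical structure each stage
assumes, carrying their ground truth (true parameters, binder sets,
cluster labels, planted bonds, bound/escape labels) so recovery is
assertable.  Design choices:

- **Noise models**: multiplicative unit-mean log-normal for peak areas
  (areas stay positive under any CV), additive Gaussian with
  value-proportional SD for activities/velocities/absorbances.  Default
  area CV is 2%, a typical UPLC repeatability for well-integrated major
  peaks.
- **Seeding**: one integer seed per call via `numpy.random.default_rng`;
  no global state.  Identical seeds give bit-identical output.
- **Screen scenario defaults** reproduce the packaged reference screen
  (nine peaks, six binders, per-peak reductions derived from the reference
  areas).  Incubation time and enzyme amount are metadata labels only: no
  quantitative time/enzyme dependence is modelled because the screen data
  format carries none.
- **Kinetic scenario defaults** are the reference inhibitor's parameters
  (K_m 180 µM, K_i 5.1 µM, IC₅₀ 31.2 µM, k₅ 0.04496 s⁻¹, k₆ 1.103×10⁻⁵
  s⁻¹, K_i^app 2.402 mM).
- **Pose clouds** are isotropic Gaussians with per-cluster energy
  distributions — the simplest model with controllable overlap for
  clustering tests.  No docking physics is simulated.
- **Hydrogen-bond scenes** plant true bonds with donor–acceptor distance
  in [2.6, 3.4] Å and DHA angle in [150°, 180°] (the hydrogen is placed by
  root-finding so the planted angle is exact), and decoys violating
  exactly one criterion (distance ≥ 4.5 Å or angle ≤ 110°); sites sit on a
  12 Å grid so cross-site contacts are geometrically impossible.
- **Trajectories** combine a static pocket scaffold (eight pocket residues
  with backbone atoms, plus the copper pair) with a three-ring ligand.
  Bound runs confine the ligand's drift within 3 Å of the pocket anchor;
  escaping runs translate the ligand at least 25 Å away from the escape
  frame onwards, which guarantees every ring clears the 10 Å limit.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: chromatographic peak-shape and integration
artefacts, retention-time drift beyond simple jitter, ion-suppression and
matrix effects, substrate depletion in progress curves, anisotropic or
multi-modal pose distributions, force-field physics, correlated thermal
motion, and solvent.  Absolute docking energies and hydrogen-bond counts
on real receptors depend on an external docking engine and an experimental
structure, so they are validated only as properties (planted-geometry
recovery, invariances), never as numbers.

## Pipeline and reproducibility

The pipeline layer validates every threshold against its documented range,
fails before computation when an enabled stage lacks inputs, and embeds
the full configuration in the report so no threshold is silent.  Report
JSON is deterministic for a given configuration and seed (wall-clock
timing is kept outside the serialised payload).  `demo_study` runs every
stage on synthetic inputs at the default scenarios — the screen stage
reproduces the reference areas exactly (zero area CV) since those areas
already embody one measured realisation — and records 12 ground-truth
recovery checks; it completes in seconds on one CPU.  Test problem sizes
(50–300 trajectory frames, 50 noisy replicates, 60-pose clouds) were
chosen as the smallest sizes at which the statistical assertions are
stable.

## Known limitations

- Single-area screens cannot support significance testing; the hit call is
  a threshold, and the threshold is a judgement exposed as configuration.
- The mode classifier assumes clean Lineweaver–Burk behaviour; cooperative
  or substrate-inhibited kinetics will land in "mixed".
- Progress-curve fitting is per-curve; no global fit across inhibitor
  concentrations is attempted (the secondary k_obs plot plays that role).
- The PDB layer reads coordinates only; occupancy, altlocs and insertion
  codes are ignored, and pose energies are taken from per-model remark
  lines in the Vina dialect.
- Leader clustering is order-stable but cutoff-sensitive for overlapping
  clouds; the cutoff is a first-class parameter for that reason.
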