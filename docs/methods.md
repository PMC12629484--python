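# Methods

## Scope

`atriacal` reproduces, as a tested pipeline, a multiscale simulation study of
loss-of-function *CACNA1C* (Cav1.2) mutations in the human atria: a
biophysically detailed atrial myocyte model with graded L-type Ca²⁺ current
(I_CaL) deficiency, and the cell-, cable- and sheet-level protocols that turn
it into arrhythmia-relevant biomarkers — action-potential duration (APD₉₀),
amplitude (APA), maximal upstroke velocity (MUV), resting potential (RMP),
effective refractory period (ERP), conduction velocity (CV), wavelength
(WL = CV·ERP), excitation threshold (EXT), vulnerable window (VW), and 2D
re-entry metrics (tip meander area, lifespan, dominant frequency).  3D
anatomically realistic simulations are out of scope (the anatomical mesh and
fibre fields are not distributable); the pseudo-ECG and spectral operators
are written mesh-generically so a 3D mesh could be plugged in later.

## Ionic model

The base cell is the Courtemanche–Ramirez–Nattel (CRN) human atrial model:
12 membrane currents (I_Na, I_K1, I_to, I_Kur, I_Kr, I_Ks, I_CaL, I_NaCa,
I_NaK, I_pCa and two background currents), Hodgkin–Huxley gating, and a
two-compartment sarcoplasmic-reticulum Ca²⁺ subsystem, 21 state variables in
all.  Two modifications follow the lineage of regional human-atria models
built on CRN:

* the transient-outward current gating uses the Maleckar r/s kinetics
  (conductance unchanged at 0.1652 nS/pF, numerically equal to Maleckar's
  8.25 nS / 50 pF);
* the Ca-dependent inactivation gate of I_CaL (here `hCa`) relaxes to the
  CRN steady state `1/(1 + [Ca²⁺]ᵢ/0.35 µM)` with a fixed 2.0 ms time
  constant.

The I_Kur reformulation cited in that lineage could not be recovered from
any distributable source; the CRN I_Kur is retained and the parameter
manifest says so.  Every constant lives in
`src/atriacal/data/model_parameters.yaml`; a SHA-256 of that file is embedded
in every result record so deviations are auditable.

### Mutant I_CaL as a conductance mixture

Heterologous-expression data for the A39V and G490R variants show a large
reduction of peak I_CaL with no shift of the I–V peak potential, so the
mutations are modelled as pure maximal-conductance scalings.  A cell carries
a mixture of wild-type and mutant channels with shared gating:

    I_CaL' = [(1 − f) + f·s_mut] · g_CaL · d · h · hCa · (Vm − ECa)

with mixing fraction `f ∈ [0, 1]` (0 wild type, 0.5 the conventional
heterozygous assumption, 1 homozygous) and relative mutant conductance
`s_mut` (G490R 0.07, A39V exon 8A 0.13, A39V exon 8 0.20).  `ECa` is the CRN
fixed 65 mV reversal.  Because gating is shared, the mixture is exactly
equivalent to a single conductance scale — a machine-precision invariant in
the test suite.

### Regional heterogeneity

Ten atrial cell types (RA, CT, BB, PM, AVR, RAA, AS, LA, LAA, PV) are
encoded as per-current maximal-conductance multipliers relative to the
right-atrial cell (all 1.0 by definition).  The original study's scaling
table is in a supplement that is not distributed; the table shipped here is
a reconstruction from the regional-heterogeneity literature that study
builds on (crista terminalis/Bachmann's bundle with augmented I_CaL,
atrioventricular ring with reduced I_CaL and augmented I_Kr, left atrium
with augmented I_Kr, pulmonary-vein sleeves with reduced I_CaL/I_K1/I_to and
augmented I_Kr).  Junction-level quantities (the vulnerable windows) inherit
this uncertainty directly; their qualitative behaviour is the robust output.

## Numerics

* Forward explicit Euler for Vm and the concentration ODEs, Rush–Larsen
  exponential updates for all gates; dt = 0.01 ms at cell and cable level
  (0.025 ms for the desk-scale 2D runs).
* Production integrators tabulate every voltage-dependent quantity (gate
  steady states, Rush–Larsen decay factors at the run's dt, I_K1/I_Kur/I_Kr/
  I_NaK/I_NaCa voltage factors) on a 0.02 mV grid over −150…+200 mV with
  linear interpolation (numba-jitted); nodes driven outside the tabulated
  range by strong stimuli fall back to the exact scalar update.  Agreement
  of the whole scheme with an adaptive stiff reference solve (LSODA,
  rtol 1e-9) of the same right-hand side is enforced by tests: < 0.5 mV
  unpaced over 1 s, < 1 mV over a paced beat away from the upstroke, with
  the upstroke time itself matched to < 0.2 ms (at ~200 V/s a microsecond
  phase shift masquerades as millivolts, so the instants are compared
  separately).
* Monodomain tissue: 5-point (1D: 3-point) Laplacian, zero-flux boundaries
  via mirrored neighbours, D = 0.21 mm²/ms, dx = 0.25 mm; the explicit-FDM
  stability bound is checked before every run.  A uniform resting strand
  stays uniform to < 1e−10 mV (conservation test).
* Concentrations are never clipped; divergence raises an error naming the
  offending variable.
* No randomness exists anywhere in the default pipeline; the acceptance
  script's `--seed` is recorded for provenance only.

## Protocols and measurement conventions

Conventions the source study does not restate are declared here and fixed:

* **Stimuli**: 2-ms rectangular pulses; 20 pA/pF for single cells, 80 pA/pF
  at the strand/sheet pacing site.  The strand electrode is the first two
  nodes (0.5 mm); EXT uses the same two-node electrode, a declared
  convention to which thresholds are sensitive (a 1-node electrode nearly
  doubles EXT, a 3-node electrode lowers it by a third).
* **Steady state**: 50 pre-beats per cycle length (100 below BCL 400 ms).
  The base model drifts slowly for hundreds of beats (WT APD₉₀ 261→206 ms
  from 50→800 beats) with no fixed point on this timescale, so "steady" is
  necessarily a convention; all tabulated values use this one.
* **Biomarkers**: RMP just before the stimulus; APA to the peak; MUV the
  maximal upstroke dVm/dt; APD₉₀ from the MUV instant to the first drop
  below RMP + 0.1·APA after the peak.
* **Cell ERP**: shortest S1–S2 interval whose S2 response reaches 80 % of
  the S1 amplitude; bisection to 1 ms (linear-scan cross-check in tests).
* **CV**: −40 mV upstroke-crossing delay between the 25th and 75th strand
  nodes; conduction failure is recorded as CV = 0.
* **Strand ERP / EXT**: S1-conditioned (5 beats at BCL 1000 ms) snapshot;
  each trial re-delivers its own S1 and the premature S2; success =
  activation reaching the 75th node.  EXT bisected to 1 pA/pF, capped at
  600 pA/pF.  The critical SI is found by a coarse 16-ms descent bracketed
  with single-amplitude probes (does 250 pA/pF capture? does 400?) and a
  1-ms walk inside the bracket — equivalent to the full descending scan for
  a monotone capture boundary, at a fraction of the cost.
* **Vulnerable window**: junction strands are 100 nodes, 50 per region, S2
  spanning the six junction-straddling nodes; outcomes classified by
  activation at probes near both ends (unidirectional = exactly one side);
  edges bisected to 0.1 ms after a coarse scan across the junction's
  repolarisation span.
* **2D re-entry**: cross-field S1–S2; the S2 quarter is fired into the S1
  tail.  Unidirectional block requires the recovery boundary to sit inside
  the quarter at S2 time — a window a few ms wide — so the coupling interval
  is searched over a small offset set around (quarter-top activation +
  strand ERP); an attempt is accepted when a phase singularity persists
  250 ms after S2.  When the tissue wavelength exceeds the sheet diagonal
  no timing can produce a surviving rotor and a single mid-window S2 is
  applied instead (flagged).  Lifespan = time from S2 to the last frame with
  any node above −40 mV; quiescent runs are cut short chunk-wise (the
  metric is unaffected).
* **Tips, meander, DF**: phase by time-delay embedding
  atan2(V(t)−V*, V(t−τ)−V*) with τ = 5 ms, V* = −40 mV; singularities where
  the plaquette winding is ±2π; greedy nearest-neighbour linking capped at
  2 mm/frame; meander area = convex hull of the longest-lived track, in
  cm².  DF = largest spectral peak of the mean-subtracted integrated Vm in
  0.5–20 Hz, first 1 s excluded.  The tracker is validated to sub-grid
  accuracy on analytic rigid rotors, the DF operator to one bin on
  synthetic sinusoids, and the pseudo-ECG operator against the analytic
  dipole far field (1/r² scaling along the dipole axis; exactly zero for a
  uniform field).

## Problem sizes

Cell and cable results use the study's native sizes (single node; 100-node
strand at 0.25 mm).  The 2D analyses in the test suite and default analysis
scripts keep the study's 100 × 100 mm sheet but discretise it at 150 × 150
nodes (dx ≈ 0.67 mm, dt 0.025 ms, 3 s).  The physical domain must stay at
100 mm: a rotor can only form if the tissue to the right of the S2 quarter
exceeds roughly half the tissue wavelength, and shrinking the domain to
37.5 mm makes re-entry geometrically impossible for every condition.
Coarsening dx instead slows CV by roughly a quarter (a known property of
coarse explicit grids) but preserves the qualitative contrast the sheet
experiments are about: sustained re-entry with a fast, compact rotor under
severe I_CaL deficiency versus early self-termination in wild type.  The
study-scale job (400 × 400 at 0.25 mm, 8 s, all seven f-levels) is the
opt-in `analysis/07_sheet_reentry.py --full`.

## What the synthetic inputs do and do not capture

All inputs are generated: region-labelled strands, junction cables, analytic
rotors, canned configs.  They emulate idealised, isotropic, homogeneous (or
two-region) tissue with the study's geometry, not real atria: no fibre
anisotropy, no anatomical obstacles, no electrotonic loading by
neighbouring structures, no beat-to-beat variability.  Passing tests
therefore demonstrate correctness of the model and protocols under the
study's idealisations, not clinical fidelity.

## Known limitations and deviations

* The base model is CRN + Maleckar Ito with CRN I_Kur; the source study's
  exact baseline (including its I_Kur reformulation) is not recoverable, and
  its published wild-type RMP (−75.6 mV) differs from CRN's (−81 mV).
  Consequences, measured not hidden: WT APD₉₀ 261 vs 247.4 ms (+5.5 %); the
  homozygous APD₉₀ is 113 vs 41.7 ms — with 7 % of I_CaL this baseline
  repolarises far more slowly in the −30…−60 mV range than the study's.
  Orderings (APD/ERP/WL monotone in f, secondary-effect directions, DF
  rise, sustained-vs-terminating re-entry) all reproduce; several absolute
  mutant-condition values do not, and the corresponding acceptance tests
  are left failing rather than re-tuned.
* The regional scaling table is a literature reconstruction; vulnerable-
  window widths shift with it, and the f-dependence patterns at the two
  junctions differ from the published ones under this table.
* No Markov channel models, no temperature correction of heterologous-cell
  kinetics, no mechanics, no persistent/late Na⁺ current (absent from the
  base model too).
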