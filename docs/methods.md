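# Methods

## The measurement model

The package models the readout of a PeT-class voltage-sensitive
membrane dye.  Emission is affine in membrane potential,

    F(Vm, a, r) = F0 · (1 + s · (Vm − Vrest)/100) · a · r,

with baseline `F0` (default 100 a.u.), sensitivity `s = 0.25` per
100 mV, resting potential `Vrest = −40 mV` and dead-cell potential
0 mV.  `a ≥ 1` is the membrane surface-area amplification (bleb
formation folds additional labelled membrane into the optical plane
without growing the cell's projected footprint) and `r ∈ (0, 1]` the
fraction of dye still attached.  Anything beyond this linear
sensitivity — photochemistry, bleaching, wavelength effects — is out
of scope.  A voltage far below rest would drive the affine form
negative; the model clamps at zero and warns, since such inputs are
outside its validity.

External-potassium calibration maps K⁺ concentration to Vm by monotone
piecewise-linear interpolation through anchor points measured in
neurons: (15 mM, −56 mV), (30, −26), (40, −19).  Beyond the anchors
the mapping extrapolates linearly and clamps at the dead potential.  A
baseline anchor (5 mM, Vrest) is prepended only when the configured
resting potential lies below −56 mV, because the anchor table must be
strictly increasing in both columns; for the −40 mV cell lines the
assay targets, the neuron anchors are used alone and whether they
transfer quantitatively to other cell types is an open question the
calibration table leaves to the user (the table is a plain argument).

## Fate archetypes and the synthetic cohorts

Each death archetype prescribes Vm, `a` and `r` over a normalized
death phase `u ∈ [0, 1]` from commitment (point of no return) to
lysis.  Committed cells depolarize to 0 mV within the first 5–10 % of
the phase — permanent loss of the membrane barrier is the event the
assay measures, and it is fast relative to the morphological
programme.  Two death phenotypes are generated by default:

* **spike-then-fall** (`apoptotic`): surface factor ramps 1 → 2 over
  the first 30 % of the phase; retention collapses linearly to 0.1
  over the last 40 %.  Intensity rises well above baseline and ends
  below it.
* **slow decline** (`necrotic`): a constant 1.3× swelling/dye-loading
  factor from commitment, with retention decaying as `exp(−6u)`.
  Intensity is non-increasing from commitment and spends only a brief
  fraction of the phase near the viable band.

A third archetype (`ferroptotic`, mild surface growth with late
retention loss) is available but not part of the default mixture.  The
default death mixture is 25 % spike / 75 % decline: observed dead-cell
trajectories show both trends, and when the decline trend dominates
the dead-value distribution sits mostly on one side of the viable
band, giving the strong viable-vs-dead rank separation the assay
reports.  With a spike-dominant mixture the high and low dead values
nearly cancel in rank terms and the Mann–Whitney test becomes only
marginally significant — a behaviour seen in macrophage-line data and
reproducible here by overriding `pathway_mix`.  Surface-amplification
magnitudes are not quantified anywhere authoritative; the defaults are
free parameters chosen to place dying cells clearly outside the gate
for most of the death phase, consistent with the assay's reported
accuracy.

Cohorts: each cell independently commits to death with probability
`toxin_effect`, with onset uniform over the 24 h exposure window and
duration uniform on [2, 48] h (death pathways take 2–48 h).  Alive
cells divide with per-24 h probability `division_rate` (default 0.3);
a dividing cell shows a +20 mV excursion during the ~1 h mitotic
window — the documented false-positive channel — and carries 2×
DNA-stain content.  Asynchronous cultures occupy G1/S/G2M at
60/25/15 % with DNA content 1, uniform(1, 2), and 2.  Time-lapse
tracks sample every 12 h to 80 h; a division ends the parent track and
spawns two daughters; cells are absent from all samplings at or after
the true lysis instant, and the recorded `lysis_time` is the first
frame at which the cell is observed absent.  Cytometry acquisitions
take the unlysed cells at `measure_time` (default 24 h) and again 1 h
later as duplicate 2, with the mitotic draw made independently per
duplicate so division-linked depolarizations do not persist across the
pair.  Total intensity scales with a per-cell lognormal size factor
(CV 0.2) times the dye density `F(Vm, a, r)`; the dye footprint equals
the projected cell area, so compensation (total/area) cancels size
exactly and the compensated control CV equals the measurement noise
CV.  Measurement noise is multiplicative lognormal (CV 0.03) on
intensities and additive Gaussian (2 % of level) on microscope
backgrounds — fluorescence noise is scale-dependent, and at CV 0.03
the lognormal is indistinguishable from Gaussian for gate purposes.

What the generator does **not** emulate: pixel-level segmentation
errors, debris/doublet events, spectral bleed-through, instrument
drift between duplicates, dye toxicity, and any biochemical pathway
kinetics (archetypes are phenomenological; the pipeline never claims
pathway identification).  Passing tests therefore show the analysis
logic is correct under the stated measurement model, not that the
assay performs identically on real instruments.

## Analysis conventions

* Background normalization (time-lapse): value = cell ROI intensity /
  background ROI intensity; non-positive backgrounds are invalid
  measurements.
* Labeling: values of a cell up to its observed division are viable
  (division proves viability); values within 48 h before an observed
  lysis are dead; everything else — including all values of cells with
  no decisive event — is discarded.  The dead window is inclusive at
  `L − 48 h` and the lysis timestamp convention is the first-absent
  frame (both exposed as parameters).  A track with a division and a
  lysis at the same timestamp is rejected as inconsistent.
* Viable range: arithmetic mean ± k × sample SD (n−1 denominator;
  control sets can be small), k = 2, bounds inclusive — "outside the
  range" is read as strict exteriority.  At k = 2 a calibrated gate
  classifies 2(1 − Φ(2)) ≈ 4.55 % of genuinely viable cells dead; this
  is the assay's designed false-positive floor.
* Cytometry gating: compensated intensity = total FV intensity / FV
  dye area.  DNA exclusion removes events above 1.5× the sample-median
  stain intensity (separating 1× G1 from 2× G2/M content with margin)
  before both range building and scoring.  Ranges are built per
  replicate group from both control duplicates pooled; if the control
  duplicates themselves fail the permanence check the range falls back
  to duplicate 1 with a warning.
* Permanence: Chi-squared on the 2×2 duplicate × classification table;
  permanent if p ≥ 0.01, transient otherwise, untestable below 20
  events per duplicate.  Degenerate all-viable (or all-dead) identical
  duplicates are permanent by construction.
* Count adjustment: viability × n_sample/n_control, clamped to [0, 1],
  with event counts averaged over duplicates; a formula is not
  prescribed anywhere authoritative, and the multiplicative form is
  the minimal model that scores fully-lysed samples near 0.
* Mann–Whitney: exact two-sided p by full enumeration of group
  labelings for pooled samples up to 14 (valid under ties); normal
  approximation with midrank tie correction above that.  Identical
  constant samples return p = 1 with a warning.  Chi-squared: Pearson,
  1 df, no continuity correction; zero rows/columns are degenerate.
  No multiple-testing correction is applied across groups.

## Comparator assays

Cell count: survivors counted 48 h after the exposure window closes
(t = 72 h, by which time every committed cell has lysed), binomially
subsampled by volume (default 20 of 50 µL) and rescaled.  PI at 24 h:
positive iff membrane integrity is lost, plus a false-positive channel
in which G2/M-content cells admit the dye with probability 0.1; cells
lysed before staining are invisible, which is why PI overestimates
viability under fast-lysing insults.  MTT at 24 h: per-cell metabolic
activity 1 (alive), ramping linearly to 0 over the death duration
(committed), 0 (lysed); summed activity passes through a response
that is exactly linear below 25 000 active-cell equivalents and
saturates smoothly above (exponential plateau with scale half the
saturation count).  All benchmark viabilities, the membrane-potential
assay's included, are reported relative to the untreated control, as
viability percentages conventionally are; PI positivity is driven by
the simulator's membrane-integrity state, not by the dye intensity, so
the two assays' error modes stay independent.

## Numerical and design notes

* All randomness flows through one `numpy.random.Generator`; identical
  config + seed gives bitwise-identical tables.  The orchestrator
  derives per-stage child seeds as `SeedSequence([seed, stage_index])`
  reduced below 2³¹.
* Problem sizes in the test suite (cohorts of 1 500 cells for gating
  studies, 160 tracked cells for time-lapse replicates, 10⁴/10⁵ events
  for gate calibration) are chosen to put Monte-Carlo error well below
  the effect sizes under test while keeping the full suite under a
  minute.
* Degenerate inputs: empty event sets, all-excluded samples,
  insufficient controls (< 2 values), zero/negative areas and
  backgrounds, non-monotone calibration tables and simultaneous
  division+lysis events all raise informative errors rather than
  propagating NaNs.
* The FCS export is a minimal list-mode float32 FCS 3.1 writer with a
  matching reader for round-trip tests; delimited text remains the
  canonical format, and proprietary imaging-cytometer containers are
  not read.

## Known limitations

* The ±10 % swing available from depolarization alone (25 %/100 mV
  over a 40 mV range) is comparable to 2 SD of a 3 % CV measurement;
  detection of dying cells rests materially on the morphology factors
  (surface amplification, dye loss), whose magnitudes are free
  parameters here.
* Cells committed immediately before acquisition (death phase u ≈ 0)
  are physically indistinguishable from viable cells; sensitivity can
  never reach 1 under this model.
* The dead-labeled sample in the time-lapse arm deliberately includes
  pre-commitment values (the 48 h window is wider than most death
  durations), diluting the viable-vs-dead contrast exactly as it does
  in real data.
* Duplicate permanence uses event counts only; paired per-cell
  tracking across duplicates is not modeled.
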