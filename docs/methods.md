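# Methods

This note documents the models behind `oslet`, the defaults and why they were
chosen, what the synthetic data do and do not emulate, and the numerical
choices that matter when interpreting test results.

## Phantom and fraction scenarios

The anthropomorphic head-and-neck phantom is reduced to parametric primitives
on a regular voxel grid (default 2 mm spacing, 200×220×160 mm): an
ellipsoidal soft-tissue body (ρ = 1.00 g/cm³), two box-shaped nasal cavities
along the beam paths that are either filled with mucus-equivalent material
(ρ = 1.00) or drained to air (ρ = 0.0012), a cylindrical tissue-equivalent
rod channel carrying the detectors, and surrounding air. CT imaging and
Hounsfield calibration are not modeled — the scoring and detector chain
consume only mass density. The CTV is a box posterior to the cavities; the
PTV is its exact 2 mm isotropic dilation (euclidean distance transform on
voxel centers).

Fraction scenarios reproduce the five-fraction structure of an adaptive
validation experiment:

| fraction | change | delivery modes | measured |
|---|---|---|---|
| FX1 | none (replicates planning geometry) | NA | NA |
| FX2 | 1 cm fat shell around the neck + rigid repositioning error | NA, DAPT | both |
| FX3 | 1 cm lateral shift | NA, DAPT | DAPT |
| FX4 | posterior half of cavity fillings removed | NA, DAPT | DAPT |
| FX5 | cavities empty | NA, DAPT | DAPT |

Fat density is 0.92 g/cm³ (standard reference value). Rigid moves resample
density with trilinear interpolation and masks with nearest-neighbor;
"registration" between reference and daily geometry is the known scenario
transform applied to contours exactly, so no image-registration solver is
involved.

The fat-layer fraction's repositioning error is the one genuinely open
design choice: the shell is added around the neck (the inferior quarter of
the body), and the head pivots on the neck — modeled as a 6 mm lateral +
4 mm anterior offset with a 3° roll about the anterior–posterior axis,
pivoted at the body's inferior end. The magnitudes were set so that the
induced displacement at the detector plane (~10 mm, mostly lateral) is
comparable to and slightly exceeds the lateral-shift fraction, which is what
an asymmetric thick shell under a fixation mask produces and what makes the
non-adapted delivery of this fraction the worst case of the suite. Lateral
displacement is the component that the range-robust margin cannot absorb;
depth (anterior) offsets are largely covered by the ±3 % range margin.

## Proton transport

A condensed-history pencil-beam engine, protons only (no nuclear
interactions, no secondaries, no delta rays — a stated limitation: total
dose is exactly primary-proton dose here).

* **Range–energy**: Bragg–Kleeman, `R = α·E^p` in water with
  α = 2.2×10⁻³ cm·MeV⁻ᵖ, p = 1.77, accurate to a few percent across the
  therapeutic range and exactly invertible — every depth/energy oracle in
  the tests is closed-form. Relative stopping power of a voxel is ρ/ρ_water.
* **Stepping**: step = min(voxel crossing, 1 mm, 2 % of residual range), with
  a 0.05 mm floor so track ends don't fragment into thousands of records.
  Per step, the energy loss is taken from exact CSDA range bookkeeping
  (`E' = ((R_res − ρ_rel·s)/α)^(1/p)`), which places the Bragg peak exactly at
  the closed-form range; the recorded dE/dx uses the actual geometric step
  length, matching the step-wise definition used for LET scoring. Below
  e_min = 0.5 MeV the remainder is deposited locally.
* **Straggling**: Gaussian smearing of each proton's initial range,
  σ = 1.2 % of R — one parameter reproducing the SOBP-relevant distal
  falloff. There is no per-step energy straggling.
* **Scattering**: Highland-type small-angle kicks per step
  (14.1 MeV/pv · √(s/X₀), X₀ = 36.08 cm scaled by density) without the
  logarithmic step-size correction, so the accumulated angular variance is
  step-size independent and the analytic Fermi–Eyges lateral spread used by
  the planning kernel integrates the *same* scattering power.
* Near-vacuum voxels (ρ < 0.05) are crossed in whole-voxel steps; energy loss
  there is negligible but still recorded, keeping per-history energy books
  exact (Σ dE + E_exit = E₀ to float32 rounding, < 10⁻⁶ relative).

The engine runs in a numba kernel; with a fixed seed the step log is
bit-identical between runs and between the record-steps and
accumulate-only paths.

## Scoring

Dose is Σ dE·1.602×10⁻¹⁰/(ρ·V) Gy; LET_D is the energy-deposit-weighted mean
of the step-wise dE/dx, water-referred ((ρ_water/ρ_v)·⟨dE/dx⟩, reported in
keV/µm). The printed form of the per-field scoring equation is dimensionally
ambiguous about where ρ_water sits; we implement the water-referred
dose-averaged mass stopping power, consistent with reporting "keV/µm in
water". LET_D is NaN, never zero, where no dose was scored; the 0.2 Gy(RBE)
and 0.5 keV/µm display cutoffs exist only in the renderer. Statistical
uncertainty is estimated from history batches (round-robin assignment,
default 8); the transport stopping rule is the mean relative dose
uncertainty over the PTV falling below 1 %, with a hard cap of 2×10⁵
histories per field (at the default geometry the cap binds first: the mean
PTV uncertainty at the cap is ≈3 %, so deliveries run the full cap).

## Planning

Spots are laid on a 4 mm lateral grid over each field's beam's-eye view of
the PTV (σ = 4 mm spots, one-pitch lateral margin), with energy layers every
4 mm water-equivalent spanning the PTV's WEPL extent widened by the ±3 %
range-robustness margin. The influence matrix for optimization is an
analytic pencil kernel: Bragg–Kleeman depth dose averaged exactly over the
voxel's water-equivalent thickness (the mean of S(E(z)) over a slab is an
energy difference divided by the slab width — essential on a 2 mm grid,
where point-sampling the peak under-predicts it by ~30 %), Gauss–Hermite
smearing over the range-straggling distribution, and a lateral Gaussian
whose variance is the spot size plus the Fermi–Eyges multiple-scattering
spread. Spot weights minimize Σ(A·w − D_phys)² subject to w ≥ 0 via an
accelerated projected-gradient (FISTA) iteration on the normal equations
with a final active-set polish; scipy's reference NNLS serves as the
independent oracle in the tests. Organ-at-risk objectives are omitted — the
validation surface is target dose and LET only.

Delivered dose is always re-computed with the Monte Carlo engine (the
analytic kernel is used for optimization only), mirroring the analytic-plan
/ MC-recompute split of daily-adaptive workflows. With these defaults the
closed loop closes well: the nominal delivery's PTV mean lands within ~0.1 %
of the 1.818 Gy prescription (2.0 Gy(RBE)/1.1), with a voxel-wise ripple of
≈3.8 % SD (optimizer residual ~0.2 %; the rest is kernel-vs-MC model
difference plus MC statistics).

## Detector model

Parametric stand-ins for the two calibration curves are pinned to the
stated operating constraints rather than to unpublished data points:
η(L) = (1+a·L_ref)/(1+a·L) with a = 0.01357 (keV/µm)⁻¹ — η(6.0) ≈ 0.93, so
quenching corrections stay below 10 % across proton SOBP LET values, and a
10 % LET error moves the correction by only ~0.4 % (the logarithmic
sensitivity a·L/(1+a·L) ≈ 0.04 at 3 keV/µm); r(L) = r₀(1+c·L/(1+L/L_sat))
with r₀ = 0.3, c = 2.0 (keV/µm)⁻¹, L_sat = 50 keV/µm — strictly increasing
and invertible on (0, 41.3] keV/µm with a log–log slope of ≈0.8 at 3 keV/µm.
The dose calibration is linear (validity 0–5 Gy). UV-band quenching is not
modeled separately; only the ratio is ever used.

Noise: per-chip sensitivity N(1, 3 %) shared by both bands; independent
multiplicative N(0, 0.3 %) per band and per the reference exposure.
Calibration exposures at varying LET additionally carry a N(0, 3.7 %)
delivery factor common to both bands (position/delivery error — it cancels
in the ratio but not in the efficiency points) and a N(0, 1.7 %) scatter on
the ratio only (the uncertainty of the LET reference). These magnitudes were
chosen so the three fitted calibrations reproduce the experimentally stated
residual spreads: ≈0.45 % (dose line, < the stated 0.6 %), ≈3.7 %
(efficiency), ≈1.8 % (ratio curve). A per-detector effective LET is the
dose-weighted mean over the 3 mm disk, computed with supersampled
area-overlap weights (boolean disk masks hold only 1–2 voxels at 2 mm and
mis-sample the ~5 %/mm LET gradient).

The LET-calibration systematic enters the analysis as a single per-suite
scale factor 1 + N(0, 1.8 %) on the ratio curve used for inversion. The
fitted ratio curve's own scatter is the *measurement* of that uncertainty,
not an additional error source, so the inversion does not stack both.

## Fraction suite and comparison statistics

Each suite: fit calibrations from synthetic exposures, draw the systematic,
then for every delivery score dose/LET_D, read out the seven detectors,
invert, and compare the detector mean against the unweighted voxel mean over
the single-slice OSLD contour (a disk of radius 7.5 mm enclosing all seven
detectors; SDs are population SDs, coverage factor k = 1). The suite-average
error is the mean absolute relative error over the six measured deliveries
(FX1 NA, FX2 NA, FX2–FX5 DAPT), with the Monte Carlo value as denominator.
Uncertainty propagation is first-order in log space:
u_L/L = √(u_ratio² + u_cal²)/|d ln r/d ln L| and
u_D/D = √(u_readout² + (S_k·u_L/L)²) — at 3 keV/µm with the default curves
this gives ≈2.3 % (k=1) for LET and ≈1 % for dose.

## Problem sizes and runtimes

Defaults: 2 mm grid, 2×10⁵ histories per field, ~3 100 spots across three
fields. One measured-only suite (six deliveries) runs in ≈4 minutes on one
core; `scripts/acceptance.py` reuses the deterministic geometry/plans across
3 replicate seeds and reports the median suite-average errors, ~15 minutes
total. The test suite runs reduced sizes (6×10⁴ histories for the
noisy-suite agreement checks) where the quantity being tested is not
statistics-limited.

## What the synthetic data do not show

* The transport omits nuclear interactions and secondaries, so absolute
  dose and the LET_D spectrum lack the few-percent secondary-proton
  component of a real beamline; agreement figures here validate the
  *chain*, not beam-model fidelity.
* Calibration curves are parametric stand-ins constrained by stated
  precisions, not the (unpublished) measured curves; LET inversions are
  exact only relative to this family.
* Detector fading, readout-protocol timing, and reader hardware are not
  modeled; the reference irradiation is an independent post-readout
  exposure.
* Anatomy is rigid; no deformation, no imaging or registration error beyond
  the known scenario transforms.

## Known limitations / honest numbers

At the 2 mm default grid, the zero-noise closed loop (all detector noise
off) does not reach arbitrary precision: the seven 3 mm disks sample the
plan's voxel-scale dose ripple (~2 % structural + MC statistics) and the
in-plane LET gradient differently from the 44-voxel contour average, leaving
suite-average residuals of ≈0.6–0.9 % in dose and ≈0.8–1.4 % in LET_D at
2×10⁵ histories per field. This is a sampling property of the stated study
geometry (3 mm detectors, 2 mm voxels, single-slice contour), not an
inversion defect — the analysis chain is machine-exact at a point, which the
unit tests verify. The acceptance tests assert the tighter 0.5 % figure and
therefore flag this resolution limit.
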