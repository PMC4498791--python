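# Methods

## Scope and design

The package has two layers. The *clinical-table layer* recomputes paired
statistics from the transcribed tables of a 12-patient ¹¹C-Choline vs
¹⁸F-FDG GTV study (checksummed CSV fixtures shipped with the package). The
*phantom layer* rebuilds the full measurement chain — acquisition, SUV,
fusion, segmentation, observer contouring, overlap, statistics — on
synthetic data with exact ground truth, so every operator is testable
without clinical images and the mechanism behind the inter-modality effect
(tracer contrast) can be studied in isolation.

## Phantom model

A phantom is a rectangular field of view containing a uniform warm
background (default 5 kBq/mL) and one or more spherical lesions at a
lesion-to-background contrast ratio. The simulated PET volume is the ideal
piecewise-constant activity sampled at voxel centers, convolved with an
isotropic Gaussian PSF (FWHM in mm; models scanner resolution loss and the
partial-volume effect), then degraded by additive zero-mean Gaussian noise
whose SD is a stated fraction of the background activity. The PSF is
applied before noise, mirroring acquisition order: resolution loss happens
in the scanner, statistical noise in the counts. Gaussian (rather than
Poisson) noise keeps a single interpretable amplitude knob, which is all
the DSC-degradation studies need; it does not model the signal-dependent
variance of real reconstructions.

The CT volume is uniform soft tissue (40 HU) with lesions isointense —
deliberately invisible — so segmentation must rely on the PET signal, the
situation that makes tracer contrast decisive in advanced NPC near the
skull base.

Ground-truth masks rasterize each sphere on the CT grid: a voxel belongs
iff its center lies within the closed ball. The closed convention matters:
a sphere centered on a voxel center has lattice points exactly on its
surface, and excluding them biases the voxel count by several percent
(515 vs 485 against an analytic 523.6 for a 20 mm sphere on a 2 mm grid).
Truth volumes converge to the analytic sphere volume as spacing shrinks.

Default grids follow clinical practice: PET 4 × 4 × 4.25 mm, CT
0.98 × 0.98 × 2 mm, exercising realistic anisotropy. Voxel-center world
coordinates are LPS, indices 0-based.

## Observer simulation

A simulated manual contour perturbs the truth mask through its signed
distance field: the new contour is the zero level of
`sd(truth) − boundary_shift − field`, where `boundary_shift` (mm) models
systematic over-/under-contouring and `field` is a smooth zero-mean
Gaussian random field (default correlation length 8 mm) scaled to a stated
SD (mm), modeling idiosyncratic boundary wobble. Zero parameters give the
identity exactly.

The signed distance uses the Euclidean distance transform with the
standard half-sample correction (half the mean voxel spacing subtracted
from center-to-center distances, magnitude floored at a quarter of the
minimum spacing so the sign still encodes membership). Without the
correction, a shift smaller than one voxel spacing cannot erode at all;
with it, a +2 mm shift of a 20 mm sphere reproduces the analytic dilated
volume ratio (12/10)³ to within ~3.5% on a 0.5 mm grid, with the residual
shrinking as the grid is refined. This is a boundary-quantization error
inherent to voxel EDTs, not a parameter.

This simulation is a stand-in for human contouring, not a model of
oncologist behavior: it has no slice-wise structure, no anatomical
priors, and its difficulty scaling (below) is an explicit assumption.

## Segmentation

* **Percent-of-maximum threshold**: the local maximum is taken over an
  explicit user ROI box (replacing the oncologist-supplied context with a
  logged, reproducible region); the mask is `SUV ≥ fraction·max`, reduced
  to the 26-connected component containing the maximum voxel. Components
  are pruned because disconnected speckle would never be contoured.
* **Fixed threshold** (`SUV ≥ 2.5` classically): largest 26-connected
  component; an empty mask is a legitimate outcome (low-uptake lesion).
* **Region growing**: breadth-first growth from a seed (by default the ROI
  maximum), admitting neighbors with `SUV ≥ inclusion_fraction ·
  SUV(seed)` (default 0.5), 26-connectivity, capped at 10× the ROI volume;
  hitting the cap flags suspected leakage into adjacent uptake. The
  admission rule, seed choice and connectivity are this package's
  decisions — simple, deterministic, and consistent with limited human
  interaction; absolute DSC values from other implementations of "region
  growing" are not expected to transfer.

No hole-filling or smoothing is applied by default: the operators stay
minimal and exactly testable (on noiseless, blur-free phantoms with
contrast above `1/fraction`, both the 40% threshold and region growing
recover the truth mask voxel-for-voxel).

A noteworthy interaction, visible in the test suite's noise sweep: with a
PSF (or coarse-grid interpolation), the noiseless percent-of-max contour is
*oversized* because blur lowers the local maximum; adding noise raises the
observed maximum, shrinking the contour back toward truth, so mean DSC can
*increase* with noise. The monotone noise-degradation property therefore
holds — and is tested — under matched blur-free grids, where the noiseless
contour is exact and any loss is attributable to noise alone.

## Fusion

PET is resampled onto the CT grid by trilinear interpolation at each CT
voxel-center's physical position (SimpleITK, identity transform — alignment
comes entirely from stored header geometry, as in hardware-fused PET/CT;
no registration optimization). Out-of-extent positions fill with 0, keeping
downstream SUV thresholds conservative. Masks resample nearest-neighbor to
stay binary. Alignment screening intersects the axis-aligned physical
bounding boxes and flags pairs whose overlap covers less than 95% of the CT
box — a quantitative stand-in for the visual "conspicuous head movement"
exclusion; the threshold is exposed in the API and CLI.

## Statistics

Student's paired-sample t-test throughout: d = x − y, sample SD (n−1
denominator), t = mean/(SD/√n), two-sided p with df = n−1, 95% CI
mean ± t₀.₉₇₅·SD/√n. Bands: p < 0.05 significant, 0.05 ≤ p < 0.10 "near"
(tendency), else not significant. No multiple-testing correction is
applied (a known limitation, matching the original analysis design).
Degenerate inputs are explicit: zero-variance differences give p = 1 when
the mean is also zero and a floating-point-floor p otherwise; the DSC of
two empty masks raises rather than defaulting to 0 or 1, because silent
conventions corrupt phantom sweeps.

Recomputation from the fixtures confirms the published two-sided,
n−1 conventions: mean ± SD 18.21 ± 8.19 for the reference-volume
differences, p = 0.0025 (df 3), p = 0.00014 (df 5, printed as 0.0001), and
CI (−0.290, 0.025). One rounding note: the semi-automatic comparison
recomputes to p = 0.0755, which the source prints as 0.076; the
reproduction report compares that statistic at one unit in the last
printed digit, all others at half a unit.

## Study sweep

`run_study` emulates the clinical design at desk scale: 12 cases (lesion
diameters cycling 10–30 mm, centered in an 80 mm field of view), two tracer
profiles — FDG-like at 2:1 contrast, Choline-like at 4:1, the contrast
difference being the package's model of the tracers' distinguishability
near brain tissue — four observers and five segmentation methods per case.
Background activity (5 kBq/mL) and the nominal injection (370 MBq, 74 kg,
no uptake delay) place the background at SUV 1.0, so lesion SUV equals the
contrast ratio and the classical 2.5 cutoff is meaningful. Defaults: 7 mm
PSF, 10% noise, 1.5 mm observer deformation SD.

Observer deformation is scaled by (max contrast / tracer contrast) by
default: contouring low-contrast images is harder, so the FDG-like profile
draws observers with twice the boundary wobble. This is the mechanism
under study expressed as an assumption; it can be disabled
(`observer_difficulty_scaling=False`), in which case simulated observers
become modality-independent and the inter-modality observer comparison is
degenerate by construction.

All randomness descends from one master seed through
`numpy.random.SeedSequence` spawning (per-case, per-tracer, per-observer
children, reduced below 2³¹); reports are written with fixed float
formatting, so a rerun with the same configuration is byte-identical. The
default sweep runs in well under a minute on one CPU; problem sizes (80 mm
field of view, 12 cases) were chosen so the whole chain, including the
fine-CT-grid fusion, stays desk-scale while still exercising the clinical
voxel anisotropy.

## What the phantom results do and do not show

Phantom DSC values are not comparable to the published clinical DSC tables:
real NPC lesions are non-spherical and textured, real backgrounds
heterogeneous, real observers anatomy-aware, and the clinical image volumes
behind those tables are not available. What the phantom layer establishes
is internal validity — exact recovery where recovery is provable, monotone
degradation with noise, determinism — and the directional contrast effect:
higher lesion-to-surround contrast yields higher and more stable DSC for
every semi-automatic method, the same direction the clinical tables report.
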