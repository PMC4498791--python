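# petgtv

Variability analysis of gross-tumor-volume (GTV) delineation on PET/CT,
with a phantom simulation pipeline for studying how tracer contrast, image
noise and voxel size drive inter-observer and inter-modality disagreement.

## The problem

For radiotherapy of nasopharyngeal carcinoma (NPC), the tumor must be
contoured on images before treatment planning. PET/CT fusion is attractive
because it aligns functional (PET) and anatomical (CT) information in
hardware, but the choice of tracer matters: with ¹⁸F-FDG, normal brain
tissue takes up nearly as much tracer as tumor, so skull-base and
intracranial invasion — common in advanced NPC — is poorly separated from
its surroundings. ¹¹C-Choline gives a much higher lesion-to-surround
contrast at those sites. This package provides the quantitative machinery
for comparing GTV contours across observers and across tracers:

* **SUV**: body-weight standardized uptake value,
  `SUV(v) = C(v)·W / D(t)`, with activity concentration `C` in kBq/mL, body
  weight `W` in g and injected dose `D` in kBq decay-corrected to the
  acquisition start with the isotope half-life (¹⁸F 6586.2 s, ¹¹C 1221.8 s).
* **Fusion**: trilinear resampling of the PET volume (typically
  4 × 4 × 4.25 mm) onto the CT grid (0.98 × 0.98 × 2 mm) using the physical
  coordinates stored in the image headers, with a bounding-box overlap check
  that flags misaligned pairs for exclusion.
* **Segmentation**: the standard semi-automatic families — SUV ≥ x% of the
  local maximum (x ∈ {15, 30, 40}), fixed cutoff SUV ≥ 2.5, and seeded
  region growing.
* **Overlap**: voxel confusion counts TP/FP/FN/TN and the Dice similarity
  coefficient `DSC = 2·TP / ((FP+TP) + (TP+FN))` between a contour and a
  reference, plus pairwise observer DSC matrices.
* **Statistics**: Student's paired-sample t-test with 95% CI; p < 0.05
  significant, 0.05 ≤ p < 0.10 a "near"-significant tendency.
* **Phantoms**: IEC-style digital phantoms — spherical lesions of known
  position and size in a warm background, at configurable contrast ratio,
  Gaussian PSF, noise level and voxel size — with exact ground-truth masks,
  plus simulated imperfect observer contours.

The packaged fixtures transcribe the published clinical tables of a
12-patient paired ¹¹C-Choline / ¹⁸F-FDG NPC study (reference GTV volumes,
manual-contouring DSC, semi-automatic DSC), and the stats layer recomputes
every derived statistic those tables support.

## Worked example

```bash
$ petgtv reproduce-tables
Reproduction of published table statistics:
  [ok ] table1_mean_diff: computed 18.2058 ~ printed 18.21
  [ok ] table1_sd_diff: computed 8.19058 ~ printed 8.19
  [ok ] table1_p: computed 9.37787e-06 < printed 0.0001
  [ok ] table2_reference_p: computed 0.00251222 ~ printed 0.0025
  [ok ] table2_observer_pairs_p: computed 0.000139739 ~ printed 0.0001
  [ok ] table3_p: computed 0.0754653 ~ printed 0.076
  [ok ] table3_ci_lower: computed -0.290224 ~ printed -0.29
  [ok ] table3_ci_upper: computed 0.0252238 ~ printed 0.025
```

Reading: across the 12 paired cases the Choline reference GTVs are on
average 18.21 cm³ larger than the FDG GTVs (SD 8.19, p < 0.0001); observers
agree with the reference significantly better on Choline than on FDG
volumes (p = 0.0025), and likewise with each other (p = 0.0001); the
semi-automatic methods show a near-significant tendency to do better on
Choline (p ≈ 0.075, 95% CI −0.29 to 0.025 for the FDG − CH DSC difference).

The same comparison at phantom scale:

```bash
$ petgtv run-study --seed 77 --out study_out
```

runs 12 phantom cases through the full chain (phantom → SUV → fusion → four
observers + five segmentation methods → DSC → paired tests), emulating FDG
as a 2:1 and Choline as a 4:1 contrast profile, and writes per-contour rows,
mean DSC matrices and the aggregate paired tests. In the default sweep the
high-contrast profile beats the low-contrast one on every method (mean DSC
advantage ≈ 0.42), the direction the clinical tables show.

Library use mirrors the CLI:

```python
from petgtv import load_table, paired_t

t1 = load_table("table1_reference_gtv")
print(paired_t(t1.ch_cm3, t1.fdg_cm3))
# n=12 mean=18.21 sd=8.191 t(11)=7.700 p=9.378e-06 CI95=(13, 23.41) [significant]
```

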