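# Methods

`vrsquant` quantifies enlarged Virchow-Robin (perivascular) spaces — thin,
CSF-bright tubular structures — in the white matter at and above the level
of the lateral ventricle bodies on axial T2-weighted MRI, and ships a
synthetic cohort generator so the full analysis can run with no patient
data. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## Measurement pipeline

Given a T2 volume (axes `(x, y, z)`, axial slice = last axis, spacing in
mm):

1. **Brain extraction** — Otsu threshold on the intensity histogram,
   per-slice hole filling, largest connected component. This is a
   phantom-grade stand-in for clinical skull stripping; it assumes a
   dark background and a single bright head region.
2. **Tissue segmentation** — deterministic 3-class 1-D k-means on the
   within-brain intensities (seeds at 1/6, 3/6, 5/6 of the
   percentile-clipped intensity range; Lloyd iterations on a 512-bin
   histogram). On T2 the darkest class is white matter, the middle grey
   matter, the brightest CSF. Ventricles are interior CSF components:
   connected CSF regions that do not touch the brain boundary and exceed
   a volume floor (default 100 mm³). The floor is needed because
   perivascular spaces themselves are small interior CSF-bright
   components; without it they would masquerade as ventricle and corrupt
   the ventricular-level rule. The WM mask is hole-filled per slice
   (minus ventricles) so CSF-bright specks *inside* WM — the structures
   we are trying to count — remain part of the WM mask and hence the ROI.
   If a label volume is available it is used verbatim.
3. **Supraventricular ROI** — the "level of the ventricle bodies" is
   operationalised as the superior-most axial slice whose ventricle
   cross-section is at least `roi_min_area_mm2` (default 10 mm²); the ROI
   is every WM voxel on that slice and above. The area threshold is a
   declared convention for an anatomically fuzzy phrase and is exposed in
   the configuration.
4. **Vesselness** — 2-D multiscale Frangi filtering per axial slice
   (slices are 4 mm thick and strongly anisotropic, so no 3-D Hessian is
   used). For each scale σ the scale-normalised Hessian is computed with
   Gaussian-derivative filters (γ = 2 normalisation, derivatives w.r.t.
   mm); with eigenvalues ordered |λ₁| ≤ |λ₂| the response is

       V = exp(−R_B²/(2β²)) · (1 − exp(−S²/(2c²))),
       R_B = λ₁/λ₂,  S = √(λ₁² + λ₂²),

   zero wherever λ₂ > 0 (bright polarity). β = 0.5 and c = half the
   per-slice maximum structureness (classic defaults; the auto-c maximum
   is taken over the evaluation region, i.e. the ROI dilated by one
   voxel, so background never sets the sensitivity). Responses are
   maximised over scales.
5. **Segmentation and quantification** — voxels with V ≥ 0.25 inside the
   ROI, 3-D 26-connected components, components with fewer than 2 or more
   than 200 voxels discarded; count = number of components, volume =
   labeled voxels × voxel volume. Counting is volumetric (3-D), so a tube
   visible on consecutive slices is counted once.

### Parameter defaults and rationale

| parameter | default | why |
|---|---|---|
| scales σ | {0.5, 0.75} mm | spans visible-VRS radii at 0.75 mm pixels. Scales ≥ 1 mm (σ ≥ 1.3 px) blur sub-millimetre tubes into ridges 2–3 px wide and inflate the segmented cross-section about two-fold, breaking volume recovery against ground truth; they are left to the configuration for coarser data. |
| β | 0.5 | classic blobness sensitivity; gives the e⁻² blob suppression factor. |
| c | auto (half max S per slice, per scale) | makes the response contrast-invariant; verified to keep noise-only slices quiet as long as each ROI slice contains at least one true tube (the generator distributes tubes over all ROI slices). |
| threshold | 0.25 | with the scale set above, the V ≥ 0.25 footprint of a planted tube equals its rendered footprint voxel-for-voxel in the noise-free case. |
| min/max size | 2 / 200 voxels | removes single-voxel noise specks and sheet-like artefacts (e.g. tissue-boundary ridges) that are far larger than any plausible single VRS. |
| γ | 2 | standard scale normalisation for second-order structure. |

Sub-voxel scales (σ < spacing/2) trigger an under-resolved warning. At
σ = 0.5 mm (0.67 px) the discrete Gaussian-derivative kernel deviates
from the continuous closed form by ~10% in amplitude; this affects
absolute Hessian values, not the normalised vesselness ordering, and the
closed-form accuracy test therefore pins scales ≥ 1 px.

## Synthetic cohort generator

The generator emulates a three-group pediatric cohort — simple febrile
seizures (SFS, n = 26), epilepsy (n = 33), controls (n = 28) — with the
published group-level summaries as its packaged defaults: VRS counts
442.42 ± 74.58 / 629.94 ± 106.55 / 354.14 ± 106.58; VRS volumes
6228.18 ± 570.74 / 9684.84 ± 7292.66 / 4007.22 ± 118.86 mm³; brain and
WM volumes per group; seizure duration 2.54 ± 1.45 and 5.61 ± 2.59 min;
course after seizure onset 3.69 ± 1.38 and 3.42 ± 1.43 days; age, sex
and gestational age distributions.

**Geometry.** A 256 × 256 × 32 grid at (0.75, 0.75, 4.0) mm — the
in-plane spacing of a 240 mm FOV / 320 matrix acquisition with 4 mm
slices, matrix reduced to keep desk-scale runtime. Anatomy is schematic:
concentric ellipsoids for brain, cortical ribbon and white matter, plus
two fixed ellipsoidal lateral ventricles. Tissue baselines are WM 100,
GM 140, CSF 200 (arbitrary units, T2 ordering), tubules WM + 90.
Per-subject brain and WM sizes are scaled isotropically so the rendered
masks match the drawn brain/WM volume targets within voxelisation error.

**Covariate coupling.** (duration, course, count) are drawn from a joint
Gaussian with the configured correlation matrix (a Gaussian copula with
normal marginals). The reported couplings (e.g. r = 0.807 for
duration–count and −0.964 for course–count in SFS) are *infeasible* if
duration and course were independent: positive semi-definiteness forces
corr(duration, course) into a strictly negative interval, computed in
closed form (`correlation_feasible_interval`). The empirical
duration–course correlation is nowhere reported, so the default sits
near the midpoint of the feasible interval: −0.78 (SFS), −0.73
(epilepsy). Counts are rounded and redrawn (not clipped) when negative,
preserving the mean; durations/courses are clipped at a 0.1 floor —
clipping the ~4% negative tail attenuates the configured correlation by
well under 0.01, whereas joint redraws would shave several hundredths.

**Burden rendering.** The per-subject total volume is drawn from the
group volume distribution, quantised to whole voxels, and split across
`count` tubules of 3–24 voxels each (the bounds keep every tubule
resolvable by the filter and below the ventricle-area rule; when the
drawn volume implies out-of-range tubule sizes the volume is silently
bounded, which mostly affects the extreme tails of the very wide
epilepsy volume distribution). Each tubule is a digital line 1–2 voxels
wide with a voxel-exact footprint. Tubules are grid-axis aligned (one
random axis per subject): a digital line along a grid axis occupies
exactly its nominal width, whereas an oblique staircase is optically
wider than its voxel count, which would bias the declared ground truth;
the filter's rotation invariance is verified separately on analytic
oblique tubes. Placement uses rows 10 voxels apart with a half-pitch
offset between adjacent slices and a 4-voxel along-row gap, so distinct
tubules are always ≥ 2 empty voxels apart in-plane and can never touch
across slices under 26-connectivity; positions directly above/below the
ventricles are excluded so no tubule can 3-D-merge with the ventricle
and shift the apparent ventricular level. Placement is deterministic given the seed; when a
subject's burden is large relative to its white matter the layout is
tightened stepwise (row pitch 10 -> 8, along-row gap 4 -> 2, edge margin
2 -> 0, all still honouring the two-voxel separation), and at sampling
time an analytic capacity estimate redraws the WM volume (never the
burden, so count marginals and the covariate coupling are untouched)
when a drawn combination could not be rendered at all; a genuinely
impossible burden raises a placement error.

**Noise.** Additive Gaussian noise, σ = 4 (2% of the CSF intensity),
applied last; ground-truth masks are noise-free. The contrast regime is
high-SNR, so a Rician model would differ negligibly.

**Determinism.** Identical (config, seed) reproduces cohorts, phantoms
and manifests bit-for-bit (NIfTI files are gzipped deterministically).
In the pipeline all randomness derives from one global seed; subject i
is rendered from the seed sequence (seed, i).

## Statistical layer

Group summaries are reported as mean ± SD (mirroring the study's own
tables) while between-group tests are two-sided Mann-Whitney U tests: the
exact p-value (full enumeration of rank assignments, via scipy) when
min(n, m) ≤ 8 with no ties, otherwise the normal approximation with
continuity and tie correction. Significance uses the Bonferroni-corrected
threshold α/m with α = 0.05, m = 3 pairwise comparisons (reported
rounded to 0.017). Correlations of VRS count/volume with seizure duration
and course after onset are Pearson product-moment coefficients with
t-transform p-values (n − 2 df), computed within each seizure group;
control rows carry no correlation entries. Pearson on modest n with
possibly skewed metrics is a deliberate reproduction of the study
convention, not a recommendation.

## What the synthetic validation shows — and does not

Passing tests demonstrate that the measurement chain recovers the burden
that the generator plants (counts exactly in the noise-free case, within
a few per mille under default noise; volumes within quantisation), that
the group-level summaries and coupling structure propagate through the
full pipeline, and that the statistical layer reproduces textbook exact
values. The phantoms deliberately omit cortical folding, partial-volume
effects at 4 mm slices, bias fields, motion, age-dependent myelination
contrast, and VRS mimics (lacunes, white-matter hyperintensities). Real
clinical performance is therefore *not* established here; on clinical
data the skull-strip and tissue stand-ins should be replaced by
dedicated tools, and the scale set revisited against the acquisition's
resolution.

## Problem sizes used in validation

The acceptance script averages the per-group burden means over 5 seeded
replicates of each full cohort (26/33/28 subjects), runs 100 seeded
replicates of the epilepsy-vs-control Mann-Whitney test, and averages
the SFS duration-count correlation over 60 seeded cohorts of 26 subjects
each — about 2,000 full phantom renders and measurements in total,
chosen to keep the whole recomputation in the tens of minutes on one
CPU while leaving Monte-Carlo error far below the comparison
tolerances (the standard error of the mean correlation at 60 replicates
is ≈ 0.01 against a ±0.1 band). The test suite uses the same study-scale
cohorts for the burden and separation checks and a 25-seed version of
the correlation check, plus a shrunken 128 × 128 × 24 phantom for unit
tests.
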