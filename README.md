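# vrsquant

Automated quantification of enlarged **Virchow-Robin spaces** (VRS,
perivascular spaces) in supraventricular white matter on axial
T2-weighted MRI — with a seeded synthetic phantom cohort generator so the
entire analysis runs, end to end, without any patient data.

Enlarged perivascular spaces appear on T2 as thin, bright, roughly
straight tubular structures inside dark white matter and are used as an
imaging proxy for glymphatic (brain waste-clearance) function. Pediatric
seizure studies compare the per-subject VRS *count* and total *volume*
between groups — e.g. simple febrile seizures (SFS), epilepsy, controls —
and correlate them with seizure duration and with the time between
seizure onset and the MRI scan. `vrsquant` reimplements that measurement
chain as a tested Python package for neuroimaging researchers who want a
transparent, reproducible VRS pipeline or a controlled test bed for one.

## The method

For each subject the pipeline computes, on a T2 volume with spacing
`(0.75, 0.75, 4.0)` mm:

1. **Brain mask** — Otsu threshold, hole filling, largest component.
2. **Tissue masks** — deterministic 3-class intensity clustering
   (T2 ordering: CSF > GM > WM); ventricles = large interior CSF
   components.
3. **Supraventricular ROI** — white matter on slices at and above the
   superior-most slice with ≥ 10 mm² of ventricle cross-section.
4. **2-D multiscale Frangi vesselness** per axial slice. With Hessian
   eigenvalues |λ₁| ≤ |λ₂| at scale σ:

   V = exp(−R_B²/2β²) · (1 − exp(−S²/2c²)),  R_B = λ₁/λ₂,  S = √(λ₁²+λ₂²)

   V = 0 where λ₂ > 0 (bright structures only); β = 0.5; c = half the
   per-slice maximum S; response maximised over σ ∈ {0.5, 0.75} mm.
5. **Quantification** — threshold V ≥ 0.25 inside the ROI, 3-D
   26-connected components, size filter 2–200 voxels; VRS count =
   number of components, VRS volume = labeled voxels × 2.25 mm³.

The statistics layer reports mean ± SD per group, pairwise two-sided
Mann-Whitney U tests (exact by enumeration for small samples) at the
Bonferroni-corrected threshold 0.05/3 ≈ 0.017, and Pearson correlations
of the VRS metrics with seizure duration and course after onset.

The synthetic generator renders ellipsoidal three-tissue brain phantoms
with two lateral ventricles and plants bright tubules in supraventricular
WM. Per-subject burdens and covariates are drawn from a Gaussian copula
whose marginals and correlations default to the published summaries of a
26/33/28-subject SFS/epilepsy/control cohort. See `docs/methods.md` for
the model, assumptions and limitations.

## Worked example

```python
import dataclasses
from vrsquant import default_config, sample_cohort
from vrsquant.pipeline import RunConfig, measure_cohort
from vrsquant.stats import build_report

cfg = default_config()                       # packaged study conditions
rc = RunConfig(cohort=cfg, seed=1)
records = sample_cohort(cfg, seed=1)         # 87 subjects: 26 SFS, 33 epilepsy, 28 control
df = measure_cohort(records, rc)             # render + segment every subject (~25 s)

for g in ("SFS", "epilepsy", "control"):
    s = df[df.group == g]
    print(f"{g:9s} count {s.vrs_count.mean():6.1f}  volume {s.vrs_volume_mm3.mean():8.1f} mm3")

report = build_report(df)
print("corrected threshold:", report.threshold_rounded)
for c in report.correlations:
    if c.pair[1] == "vrs_count":
        print(c.pair, f"r={c.r:.3f} p={c.p:.2g}")
```

Output from this exact run:

```
SFS       count  431.3  volume   6217.7 mm3
epilepsy  count  605.2  volume  10041.1 mm3
control   count  359.1  volume   4013.0 mm3
corrected threshold: 0.017
('SFS:seizure_duration_min', 'vrs_count') r=0.886 p=1.7e-09
('SFS:course_days', 'vrs_count') r=-0.976 p=2e-17
('epilepsy:seizure_duration_min', 'vrs_count') r=0.833 p=1.9e-09
('epilepsy:course_days', 'vrs_count') r=-0.972 p=3.6e-21
```

The measured group means sit on the configured burdens (442 / 630 / 354
counts; 6228 mm³ SFS volume) up to the sampling noise of one seeded
cohort, the seizure groups separate from controls far below the 0.017
threshold, and the planted duration-count coupling survives the full
measurement chain.

The same pipeline is available from the shell:

```bash
vrsquant all --seed 1 --out runs/demo           # simulate -> segment -> stats
vrsquant simulate --seed 1 --group-sizes 2 2 2 --out runs/tiny
vrsquant segment --cohort runs/tiny --out runs/tiny_seg
vrsquant stats --metrics runs/tiny_seg/metrics.csv \
               --covariates runs/tiny/covariates.csv --out runs/tiny_stats
```

`simulate` writes one T2 NIfTI + one label NIfTI per subject, a
`covariates.csv` and a `manifest.json` with content hashes; reruns with
the same seed are bit-identical.

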