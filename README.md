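# somasearch

Searchlight decoding, pattern-dissimilarity mapping and permutation/TFCE
inference for volumetric brain statistic maps.

## What this is for

Studies of observed somatosensory experience (watching a hand being
painfully stimulated, gently touched, or approached without contact)
produce one standard-space z-statistic volume per participant and
condition, plus per-participant trait questionnaires such as the
Interpersonal Reactivity Index (IRI) with its four subscales — Fantasy
(FS), Empathic Concern (EC), Perspective Taking (PT) and Personal Distress
(PD). `somasearch` implements the multivariate analysis chain for such
data:

1. **Cross-participant decoding searchlight.** At every brain voxel, the
   z-values inside a sphere (radius r voxels, default 3) form a feature
   vector per participant × condition. Three pairwise linear SVMs
   (one-against-one: pain–touch, pain–control, touch–control) are scored by
   leave-one-subject-out cross-validation; the accuracy over all
   n_subjects × 3 predictions (chance 1/3) is mapped to the sphere center.
2. **Accuracy thresholding.** Multiple comparisons use a resel-wise
   Bonferroni correction: α_corr = α / R, with R the number of
   non-overlapping spheres fitting in the brain mask. The corrected alpha
   becomes a critical accuracy through the exact binomial inverse CDF,
   k* = F⁻¹(1 − α_corr; n, ⅓). For the reference design (n = 210
   classifications, R = 725, α = 0.05) this gives α_corr ≈ 6.90×10⁻⁵ and
   k* = 97, i.e. 46%.
3. **Dissimilarity searchlight.** Within each subject, the Euclidean
   distance between unit-normalised sphere patterns of each condition pair,
   d = ‖v̂₁ − v̂₂‖ = √(2 − 2cos θ) ∈ [0, 2], yields three contrast maps per
   subject (0 identical, √2 orthogonal, 2 antipodal patterns).
4. **Brain–behaviour inference.** Per-subject maps are regressed voxelwise
   on a demeaned trait subscale; the slope t-map is enhanced with
   threshold-free cluster enhancement, TFCE(v) = Σ_h e(h,v)^E · h^H · dh
   (E = 0.5, H = 2), and tested against a max-statistic permutation null
   (trait vector shuffled across subjects). Results are family-wise-error
   corrected 1−p maps; positive and negative correlations are separate
   one-sided analyses, run for all 3 contrasts × 4 subscales × 2
   directions.

A seeded synthetic-cohort generator produces z-map-like volumes (smoothed
unit-variance noise plus multivoxel condition patterns in chosen regions,
optionally with the pattern separation of one contrast coupled linearly to
a trait subscale), so every stage can be exercised end-to-end with known
ground truth.

## Worked example

`examples/02_decoding_searchlight.py` builds a 12-subject cohort on a
16³ grid with one 125-voxel signal region at per-voxel SNR 1, runs the
decoding searchlight and thresholds it:

```
reference design: corrected alpha 6.90e-05, critical count 97/210 = 46%

searchlight: radius 2 voxels, 33 voxels per sphere, 1328 centers
scaled design: 40 resels, corrected alpha 1.25e-03, critical accuracy 21/36 = 58.3%
peak accuracy inside the seeded region: 100.0% (chance 33.3%)
voxels above threshold: 350, of which inside the region or its shell: 343
```

The reference numbers are the full-scale design (70 subjects × 3
conditions, 725 resels); the scaled numbers show the same machinery
re-derived for the small cohort, and the seeded region is recovered far
above its corrected threshold. `examples/04_trait_inference.py` shows the
selective brain–behaviour recovery: with only the pain-vs-control
separation coupled to EC, the (pain_vs_control, EC, positive) analysis
reaches max FWE 1−p = 0.987 (p < 0.05) inside the region while its
negative mirror and all uncoupled combinations stay at chance.

The same pipeline runs from the shell:

```bash
somasearch simulate --out cohort/ --seed 1
somasearch classify --in cohort/ --out clf/ --seed 1
somasearch dissim   --in cohort/ --out dis/
somasearch correlate --in cohort/ --out cor/ --n-perm 1000 --seed 1
somasearch report   --in clf/
```

## Layout

- `src/somasearch/volumes.py` — grids, masks, NIfTI I/O, sphere geometry
- `src/somasearch/synthetic.py` — seeded cohort and trait generation
- `src/somasearch/searchlight.py` — the generic per-sphere engine
- `src/somasearch/classification.py` — LOSO one-against-one SVM decoding
- `src/somasearch/thresholding.py` — resels, Bonferroni, binomial threshold
- `src/somasearch/dissimilarity.py` — Euclidean pattern distances, peaks
- `src/somasearch/inference.py` — voxelwise correlation, TFCE, permutation FWE
- `src/somasearch/cli.py` — thin command-line wrapper
- `docs/methods.md` — modelling choices, defaults and limitations
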