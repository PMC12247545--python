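"""Brain-behaviour inference: permutation TFCE on trait-coupled dissimilarity.

A cohort is generated in which only the pain-vs-control pattern separation
in one region tracks the Empathic Concern (EC) subscale. The voxelwise
slope t of dissimilarity on the demeaned trait is TFCE-enhanced and tested
against a max-statistic permutation null; results are FWE-corrected 1-p
maps (1 = most significant).
"""

import numpy as np

import somasearch as ss

coupling = ss.TraitCoupling(
    roi=0, contrast="pain_vs_control", subscale="EC",
    slope=0.25, base_separation=3.0,
)
cfg = ss.default_config(
    n_subjects=16, shape=(16, 16, 16), roi_halfwidth=2,
    amplitude=1.0, noise_sd=0.2, couplings=(coupling,),
    subject_sd=0.05, seed=104,
)
maps, traits = ss.generate_cohort(cfg)
by_contrast = ss.cohort_dissimilarity(maps, ss.sphere_offsets(2), cfg.grid)

results = ss.run_empathy_correlations(
    by_contrast, traits, cfg.grid, n_perm=300, seed=105,
    contrasts=("pain_vs_control", "pain_vs_touch"), subscales=("EC", "PT"),
)

roi = cfg.signal_rois[0].voxels
roi_mask = np.zeros(cfg.grid.shape, dtype=bool)
roi_mask[roi[:, 0], roi[:, 1], roi[:, 2]] = True

print(f"{'contrast':18s} {'trait':5s} {'dir':8s}  max FWE 1-p in region")
for (contrast, subscale, direction), res in sorted(results.items()):
    flag = "  <-- significant (FWE p < 0.05)" if res.max_inv_p(roi_mask) > 0.95 else ""
    print(f"{contrast:18s} {subscale:5s} {direction:8s}  {res.max_inv_p(roi_mask):.3f}{flag}")
print()
print("Only the coupled (pain_vs_control, EC, positive) combination should")
print("reach significance; its mirrored negative contrast and the uncoupled")
print("combinations stay at chance level.")
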