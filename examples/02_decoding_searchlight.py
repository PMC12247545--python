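"""Cross-participant decoding searchlight with binomial thresholding.

At every brain voxel, a sphere of z-values per subject and condition feeds
three pairwise linear SVMs (one-against-one); leave-one-subject-out
accuracy is mapped to the sphere center. Significance uses a resel-wise
Bonferroni alpha converted to a critical accuracy by the exact binomial
inverse CDF.
"""

import numpy as np

import somasearch as ss

# the reference full-scale design: 70 participants x 3 conditions,
# alpha 0.05 over 725 resels
alpha_c = ss.bonferroni_alpha(0.05, 725)
k, acc, _ = ss.binomial_threshold(210, 1 / 3, alpha_c)
print(f"reference design: corrected alpha {alpha_c:.2e}, "
      f"critical count {k}/210 = {100 * acc:.0f}%")
print()

# a scaled-down cohort with one seeded signal region at per-voxel SNR 1
cfg = ss.default_config(
    n_subjects=12, shape=(16, 16, 16), roi_halfwidth=2,
    amplitude=float(np.sqrt(125)), noise_sd=1.0, seed=7,
)
maps, _ = ss.generate_cohort(cfg)
sphere = ss.sphere_offsets(2)
print(f"searchlight: radius {sphere.radius_voxels:g} voxels, "
      f"{sphere.n_offsets} voxels per sphere, {cfg.grid.n_mask_voxels} centers")
acc_map = ss.classification_searchlight(maps, sphere, cfg.grid)

spec = ss.build_threshold_spec(cfg.grid.mask, sphere, n_classifications=len(maps))
sig = ss.threshold_accuracy_map(acc_map, spec)
roi = cfg.signal_rois[0].voxels
roi_peak = np.nanmax(acc_map.values[roi[:, 0], roi[:, 1], roi[:, 2]])

print(f"scaled design: {spec.resel_count} resels, corrected alpha "
      f"{spec.alpha_corrected:.2e}, critical accuracy "
      f"{spec.k_critical}/{spec.n_classifications} = {100 * spec.accuracy_critical:.1f}%")
print(f"peak accuracy inside the seeded region: {100 * roi_peak:.1f}% "
      f"(chance 33.3%)")
print(f"voxels above threshold: {int(sig.sum())}, "
      f"of which inside the region or its shell: "
      f"{int(sig[roi[:, 0].min() - 2 : roi[:, 0].max() + 3, roi[:, 1].min() - 2 : roi[:, 1].max() + 3, roi[:, 2].min() - 2 : roi[:, 2].max() + 3].sum())}")
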