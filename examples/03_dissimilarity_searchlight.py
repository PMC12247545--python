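"""Within-subject pattern-dissimilarity searchlight.

For each subject, the three condition maps yield three contrast maps of
Euclidean distances between unit-normalised sphere patterns, bounded in
[0, 2]: 0 = identical patterns, sqrt(2) ~ 1.414 = orthogonal (unrelated),
2 = antipodal. Group means are thresholded at 1.5 to report the most
dissimilar regions.
"""

import numpy as np

import somasearch as ss

cfg = ss.default_config(
    n_subjects=8, shape=(16, 16, 16), roi_halfwidth=2,
    amplitude=float(np.sqrt(125)), noise_sd=1.0, seed=21,
)
maps, _ = ss.generate_cohort(cfg)
sphere = ss.sphere_offsets(2)
by_contrast = ss.cohort_dissimilarity(maps, sphere, cfg.grid)

roi = cfg.signal_rois[0].voxels
for contrast in ss.CONTRASTS:
    mean = ss.group_mean_dissimilarity(by_contrast[contrast])
    in_roi = np.nanmean(mean[roi[:, 0], roi[:, 1], roi[:, 2]])
    out = mean[cfg.grid.mask]
    print(f"{contrast:18s}: region mean {in_roi:.3f}, "
          f"whole-mask range [{np.nanmin(out):.3f}, {np.nanmax(out):.3f}]")

mean = ss.group_mean_dissimilarity(by_contrast["pain_vs_control"])
peaks = ss.report_peaks(mean, cfg.grid, threshold=1.5)
print()
print(f"pain_vs_control peaks above 1.5: {len(peaks)}")
if len(peaks):
    print(peaks.head(5).to_string(index=False))
print()
print("With orthogonal condition templates the designed in-region distance")
print("approaches sqrt(2) ~ 1.414 as SNR grows; noise pushes values toward")
print("sqrt(2) from either side elsewhere.")
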