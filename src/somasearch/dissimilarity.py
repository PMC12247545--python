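"""Pattern-dissimilarity searchlight.

For each subject, the three condition volumes yield three contrast maps
(pain–touch, pain–control, touch–control): at every mask voxel the sphere's
pattern vector is extracted from each condition map, and the Euclidean
distance between each pair of vectors is written to the center voxel.

Pattern vectors are scaled to unit Euclidean norm before distancing by
default, which bounds the distance by [0, 2]: identical patterns give 0,
antipodal give 2, orthogonal give √2 (the closed form is
d = √(2 − 2·cosθ) with θ the angle between patterns). The raw
(un-normalised) distance is available via ``normalize=False``. All-zero
patterns are degenerate under normalisation and map to NaN so that
downstream inference can exclude them.

Dissimilarity is computed within each subject — no cross-subject pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DatasetError, InvalidParameterError
from .searchlight import SearchlightResult, run_searchlight
from .synthetic import CONTRASTS, CONTRAST_PAIRS
from .volumes import CONDITIONS, ConditionMap, SphereSpec, VolumeGrid

__all__ = [
    "DissimilarityMap",
    "pattern_distance",
    "dissimilarity_searchlight",
    "cohort_dissimilarity",
    "group_mean_dissimilarity",
    "report_peaks",
]


@dataclass(frozen=True)
class DissimilarityMap:
    """One subject's Euclidean pattern-distance volume for one contrast."""

    subject_id: str
    contrast: str
    values: np.ndarray
    grid: VolumeGrid
    normalized: bool = True

    def __post_init__(self):
        if self.contrast not in CONTRASTS:
            raise InvalidParameterError(f"contrast must be one of {CONTRASTS}")
        values = self.grid.check_volume(self.values)
        if self.normalized:
            inm = values[self.grid.mask]
            inm = inm[np.isfinite(inm)]
            if inm.size and (inm.min() < -1e-9 or inm.max() > 2 + 1e-9):
                raise InvalidParameterError("normalized dissimilarities must lie in [0, 2]")
        object.__setattr__(self, "values", values)


def pattern_distance(v1: np.ndarray, v2: np.ndarray, normalize: bool = True) -> float:
    """Euclidean distance between two pattern vectors.

    With ``normalize`` (default) each vector is scaled to unit norm first,
    so the result lies in [0, 2]; a zero-norm vector is degenerate and
    yields NaN. Without normalisation the raw distance is returned.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.ndim != 1 or v1.size == 0:
        raise InvalidParameterError("patterns must be 1D vectors of equal nonzero length")
    if normalize:
        n1 = np.linalg.norm(v1)
        n2 = np.linalg.norm(v2)
        if n1 == 0 or n2 == 0:
            return float("nan")
        v1 = v1 / n1
        v2 = v2 / n2
    return float(np.linalg.norm(v1 - v2))


def dissimilarity_searchlight(
    subject_maps: Sequence[ConditionMap],
    sphere: SphereSpec,
    grid: VolumeGrid,
    normalize: bool = True,
    n_jobs: int = 1,
) -> dict[str, DissimilarityMap]:
    """One subject's three contrast maps from their three condition maps.

    Uses the same searchlight geometry (clipped spheres, inclusive radius)
    as the decoding searchlight. Returns ``{contrast: DissimilarityMap}``.
    """
    by_cond = {m.condition: m for m in subject_maps}
    if sorted(by_cond) != sorted(CONDITIONS):
        raise DatasetError(
            f"need exactly one map per condition {CONDITIONS}, got {sorted(by_cond)}"
        )
    sids = {m.subject_id for m in subject_maps}
    if len(sids) != 1:
        raise DatasetError(f"maps from multiple subjects passed: {sorted(sids)}")
    sid = sids.pop()
    ordered = [by_cond[c] for c in CONDITIONS]
    cond_idx = {c: i for i, c in enumerate(CONDITIONS)}
    pairs = [(cond_idx[a], cond_idx[b]) for a, b in (CONTRAST_PAIRS[k] for k in CONTRASTS)]

    def stat(patterns: np.ndarray) -> np.ndarray:
        return np.array(
            [pattern_distance(patterns[i], patterns[j], normalize) for i, j in pairs]
        )

    results = run_searchlight(
        ordered, stat, sphere, grid, statistic_name="euclidean_dissimilarity", n_jobs=n_jobs
    )
    return {
        contrast: DissimilarityMap(sid, contrast, res.values, grid, normalized=normalize)
        for contrast, res in zip(CONTRASTS, results)
    }


def cohort_dissimilarity(
    maps: Sequence[ConditionMap],
    sphere: SphereSpec,
    grid: VolumeGrid,
    normalize: bool = True,
    n_jobs: int = 1,
) -> dict[str, list[DissimilarityMap]]:
    """Per-subject dissimilarity maps for a whole cohort.

    Returns ``{contrast: [DissimilarityMap per subject]}`` with subjects in
    first-appearance order of ``maps``.
    """
    subjects = list(dict.fromkeys(m.subject_id for m in maps))
    out: dict[str, list[DissimilarityMap]] = {c: [] for c in CONTRASTS}
    for sid in subjects:
        sub = [m for m in maps if m.subject_id == sid]
        res = dissimilarity_searchlight(sub, sphere, grid, normalize=normalize, n_jobs=n_jobs)
        for c in CONTRASTS:
            out[c].append(res[c])
    return out


def group_mean_dissimilarity(maps: Sequence[DissimilarityMap]) -> np.ndarray:
    """Voxelwise mean across subjects of one contrast's maps (NaN-aware)."""
    if len(maps) == 0:
        raise DatasetError("need at least one subject's dissimilarity map")
    contrasts = {m.contrast for m in maps}
    if len(contrasts) != 1:
        raise DatasetError(f"maps mix contrasts {sorted(contrasts)}")
    stack = np.stack([m.values for m in maps])
    import warnings

    with warnings.catch_warnings():
        # voxels outside the mask are all-NaN by construction
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stack, axis=0)


def report_peaks(
    volume: np.ndarray,
    grid: VolumeGrid,
    threshold: float = 1.5,
    min_distance_voxels: int = 2,
) -> pd.DataFrame:
    """Local maxima above ``threshold`` as a (x, y, z, x_mm, y_mm, z_mm, value) table.

    A peak is a voxel that attains the maximum of its (2d+1)³ neighbourhood
    (d = ``min_distance_voxels``) and exceeds the threshold; rows are sorted
    by descending value. The default threshold of 1.5 targets the top of
    the [0, 2] normalised-distance range.
    """
    vol = np.asarray(volume, dtype=float)
    filled = np.where(np.isfinite(vol) & grid.mask, vol, -np.inf)
    size = 2 * min_distance_voxels + 1
    local_max = ndimage.maximum_filter(filled, size=size, mode="constant", cval=-np.inf)
    is_peak = (filled == local_max) & (filled > threshold)
    coords = np.argwhere(is_peak)
    rows = []
    for c in coords:
        world = grid.voxel_to_world(c)
        rows.append(
            {
                "x": int(c[0]),
                "y": int(c[1]),
                "z": int(c[2]),
                "x_mm": world[0],
                "y_mm": world[1],
                "z_mm": world[2],
                "value": float(vol[tuple(c)]),
            }
        )
    df = pd.DataFrame(rows, columns=["x", "y", "z", "x_mm", "y_mm", "z_mm", "value"])
    return df.sort_values("value", ascending=False).reset_index(drop=True)
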