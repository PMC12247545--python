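"""Voxelwise brain–behaviour inference with permutation TFCE and
max-statistic family-wise error correction.

Per-subject volumes (dissimilarity maps, or raw condition/contrast maps for
the analogous univariate analysis) are correlated voxelwise with a demeaned
trait score across subjects. The per-voxel statistic is the slope
t-statistic of the regression of map values on the demeaned trait — a
monotone transform of Pearson's r. Statistic maps are enhanced with
threshold-free cluster enhancement (TFCE), which integrates cluster extent
and height over all thresholds:

    TFCE(v) = Σ_{h = dh, 2dh, … ≤ stat(v)}  e(h, v)^E · h^H · dh

with e(h, v) the size of the connected supra-threshold component containing
v at height h. The null distribution is built by randomly permuting the
trait vector across subjects (Fisher–Pitman scheme; the design has no
nuisance covariates), recording the volume-wide maximum TFCE value of each
permutation. The FWE-corrected p-value at a voxel is the fraction of
permutation maxima (plus the observed map, the "+1" convention) that reach
its observed TFCE value; results are reported as 1 − p, where 1 is most
significant.

Positive and negative correlations are separate one-sided analyses; the
negative direction enhances the negated statistic map.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _all_permutations
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import AlignmentError, DegenerateCovariateError, InvalidParameterError
from .synthetic import CONTRASTS, SUBSCALES, TraitScores
from .volumes import VolumeGrid

__all__ = [
    "TFCEParams",
    "StatResult",
    "voxelwise_correlation",
    "tfce_enhance",
    "permutation_fwe",
    "run_empathy_correlations",
]

T_CAP = 100.0  # ceiling for |t| at perfect correlation (r -> ±1)
DIRECTIONS = ("positive", "negative")


@dataclass(frozen=True)
class TFCEParams:
    """TFCE parameters.

    E and H are the standard published defaults for 3D volumetric data
    (extent 0.5, height 2.0). ``dh`` is the integration step in statistic
    units; None selects an adaptive step of (max statistic)/100 with a
    floor of 0.01. Connectivity of the supra-threshold components is 26
    (vertex), 18 (edge) or 6 (face).
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    connectivity: int = 26

    def __post_init__(self):
        if self.E < 0 or self.H < 0:
            raise InvalidParameterError("TFCE exponents must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise InvalidParameterError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise InvalidParameterError("connectivity must be 6, 18 or 26")

    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


@dataclass(frozen=True)
class StatResult:
    """Observed statistic, TFCE map and FWE-corrected 1−p map."""

    stat: np.ndarray
    tfce: np.ndarray
    fwe_inv_p: np.ndarray
    direction: str
    n_perm: int
    seed: int
    contrast: str | None = None
    subscale: str | None = None

    def max_inv_p(self, mask: np.ndarray | None = None) -> float:
        v = self.fwe_inv_p if mask is None else self.fwe_inv_p[mask]
        v = v[np.isfinite(v)]
        return float(v.max()) if v.size else float("nan")


def _stack_mask_matrix(maps: Sequence, grid: VolumeGrid) -> np.ndarray:
    rows = []
    for m in maps:
        v = getattr(m, "values", m)
        rows.append(grid.check_volume(np.asarray(v, dtype=float))[grid.mask])
    return np.asarray(rows)


def _tstats(V: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Slope t-statistics of each column of V regressed on demeaned x."""
    n = len(x)
    xc = x - x.mean()
    Vc = V - V.mean(axis=0)
    good = np.isfinite(Vc).all(axis=0)
    Vc = np.where(good[None, :], Vc, 0.0)
    num = xc @ Vc
    ssx = float(xc @ xc)
    ssv = (Vc**2).sum(axis=0)
    denom = np.sqrt(ssx * ssv)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    t = np.clip(np.nan_to_num(t, nan=0.0, posinf=T_CAP, neginf=-T_CAP), -T_CAP, T_CAP)
    return np.where(good, t, 0.0)


def voxelwise_correlation(
    maps: Sequence,
    trait: np.ndarray,
    grid: VolumeGrid,
    demean: bool = True,
) -> np.ndarray:
    """Per-voxel slope t-statistic of map values regressed on the trait.

    ``maps`` holds one volume per subject, aligned with ``trait``. The
    covariate is demeaned by default (a no-op for the t-statistic itself,
    but kept explicit to mirror the analysis design). Voxels with zero map
    variance or non-finite values get statistic 0; |t| is capped at 100.
    Returns a volume (NaN outside the mask).
    """
    trait = np.asarray(trait, dtype=float)
    if len(maps) != len(trait):
        raise AlignmentError(f"{len(maps)} maps vs {len(trait)} trait values")
    if len(trait) < 3:
        raise InvalidParameterError("need at least 3 subjects for a correlation")
    if np.ptp(trait) == 0:
        raise DegenerateCovariateError("trait covariate has zero variance")
    x = trait - trait.mean() if demean else trait
    V = _stack_mask_matrix(maps, grid)
    t = _tstats(V, x)
    out = np.full(grid.shape, np.nan)
    out[grid.mask] = t
    return out


def tfce_enhance(stat: np.ndarray, params: TFCEParams, mask: np.ndarray) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of ``stat``.

    Voxels with stat ≤ 0 (and voxels outside the mask) get TFCE 0. The
    Riemann sum runs over thresholds dh, 2dh, … up to the map maximum.
    """
    stat = np.asarray(stat, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    pos = np.where(mask & np.isfinite(stat) & (stat > 0), stat, 0.0)
    out = np.zeros_like(pos)
    vmax = float(pos.max())
    if vmax <= 0:
        return out
    dh = params.dh if params.dh is not None else max(vmax / 100.0, 0.01)
    struct = params.structure()
    # work on the bounding box of the positive support
    idx = np.argwhere(pos > 0)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    box = tuple(slice(l, h_) for l, h_ in zip(lo, hi))
    p = pos[box]
    acc = np.zeros_like(p)
    h = dh
    while h <= vmax * (1 + 1e-12):
        supra = p >= h
        labels, n = ndimage.label(supra, structure=struct)
        if n == 0:
            break
        sizes = np.bincount(labels.ravel())
        acc[supra] += (sizes[labels[supra]].astype(float) ** params.E) * (h**params.H) * dh
        h += dh
    out[box] = acc
    return out


def permutation_fwe(
    maps: Sequence,
    trait: np.ndarray,
    grid: VolumeGrid,
    params: TFCEParams = TFCEParams(),
    n_perm: int = 1000,
    seed: int = 0,
    direction: str = "positive",
    demean: bool = True,
) -> StatResult:
    """Permutation TFCE inference with max-statistic FWE correction.

    The trait vector is randomly permuted across subjects ``n_perm`` times;
    each permutation's statistic map is TFCE-enhanced and its volume-wide
    maximum recorded. FWE p at voxel v is
    ``(1 + #{perm maxima ≥ observed TFCE(v)}) / (n_perm + 1)`` and the
    returned map holds 1 − p. If ``n_perm`` meets or exceeds n! the n!
    distinct permutations are enumerated exhaustively instead (with a
    warning) and p becomes the exact Fisher–Pitman tail fraction.
    Reproducible from ``seed``.
    """
    if direction not in DIRECTIONS:
        raise InvalidParameterError(f"direction must be one of {DIRECTIONS}")
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    trait = np.asarray(trait, dtype=float)
    n = len(trait)
    if len(maps) != n:
        raise AlignmentError(f"{len(maps)} maps vs {n} trait values")
    if np.ptp(trait) == 0:
        raise DegenerateCovariateError("trait covariate has zero variance")
    sign = 1.0 if direction == "positive" else -1.0

    V = _stack_mask_matrix(maps, grid)
    # canonicalise subject order (trait value, then map content) before any
    # reduction over subjects, so the Monte-Carlo null — and hence the
    # p-maps — are invariant to a consistent relabeling of subjects
    digests = [hashlib.sha1(np.ascontiguousarray(row).tobytes()).hexdigest() for row in V]
    order = sorted(range(n), key=lambda i: (trait[i], digests[i]))
    trait = trait[order]
    V = V[order]
    x = trait - trait.mean() if demean else trait.copy()
    vol = np.zeros(grid.shape)

    def tfce_of(xperm: np.ndarray) -> np.ndarray:
        t = sign * _tstats(V, xperm)
        vol[grid.mask] = t
        return tfce_enhance(vol, params, grid.mask)

    tfce_obs = tfce_of(x)

    n_exhaustive = math.factorial(n) if n <= 13 else None
    if n_exhaustive is not None and n_perm >= n_exhaustive:
        warnings.warn(
            f"n_perm={n_perm} >= {n}! = {n_exhaustive}; enumerating all permutations exactly",
            stacklevel=2,
        )
        maxima = np.array([tfce_of(np.asarray(p)).max() for p in _all_permutations(x)])
        sorted_max = np.sort(maxima)
        # count of permutation maxima >= observed TFCE at each voxel
        exceed = len(maxima) - np.searchsorted(sorted_max, tfce_obs, side="left")
        p = exceed / n_exhaustive  # observed is the identity permutation
        n_used = n_exhaustive
    else:
        rng = np.random.default_rng(seed)
        maxima = np.empty(n_perm)
        for i in range(n_perm):
            maxima[i] = tfce_of(rng.permutation(x)).max()
        sorted_max = np.sort(maxima)
        exceed = n_perm - np.searchsorted(sorted_max, tfce_obs, side="left")
        p = (1.0 + exceed) / (n_perm + 1.0)
        n_used = n_perm

    stat_map = np.full(grid.shape, np.nan)
    stat_map[grid.mask] = sign * _tstats(V, x)
    inv_p = np.full(grid.shape, np.nan)
    inv_p[grid.mask] = 1.0 - p[grid.mask]
    tfce_map = np.where(grid.mask, tfce_obs, np.nan)
    return StatResult(
        stat=stat_map,
        tfce=tfce_map,
        fwe_inv_p=inv_p,
        direction=direction,
        n_perm=int(n_used),
        seed=int(seed),
    )


def run_empathy_correlations(
    dissim: dict,
    traits: TraitScores,
    grid: VolumeGrid,
    params: TFCEParams = TFCEParams(),
    n_perm: int = 1000,
    seed: int = 0,
    contrasts: Sequence[str] = CONTRASTS,
    subscales: Sequence[str] = SUBSCALES,
    directions: Sequence[str] = DIRECTIONS,
) -> dict:
    """All (contrast × subscale × direction) permutation analyses.

    ``dissim`` maps contrast name to the list of per-subject
    :class:`~somasearch.dissimilarity.DissimilarityMap`; subject ids must
    match the trait table exactly. With the defaults this yields
    3 × 4 × 2 = 24 independently seeded :class:`StatResult` objects keyed
    by ``(contrast, subscale, direction)``.
    """
    results = {}
    rng = np.random.default_rng(seed)
    for contrast in contrasts:
        maps = dissim[contrast]
        map_ids = [m.subject_id for m in maps]
        if map_ids != traits.subject_ids:
            raise AlignmentError(
                "subject ids of dissimilarity maps and trait table must match exactly"
            )
        for subscale in subscales:
            trait = traits.subscale(subscale)
            for direction in directions:
                sub_seed = int(rng.integers(2**31))
                res = permutation_fwe(
                    maps,
                    trait,
                    grid,
                    params=params,
                    n_perm=n_perm,
                    seed=sub_seed,
                    direction=direction,
                )
                results[(contrast, subscale, direction)] = StatResult(
                    stat=res.stat,
                    tfce=res.tfce,
                    fwe_inv_p=res.fwe_inv_p,
                    direction=direction,
                    n_perm=res.n_perm,
                    seed=sub_seed,
                    contrast=contrast,
                    subscale=subscale,
                )
    return results
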