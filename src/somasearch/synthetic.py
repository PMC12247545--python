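"""Synthetic multi-subject, three-condition volumetric cohorts.

The generator emulates the statistical structure of first-level z-statistic
maps: spatially smooth Gaussian noise everywhere, plus condition-specific
multivoxel patterns inside designated signal regions. Optionally, the
*separation* between two conditions' patterns in a region is coupled
linearly to one trait subscale, so that individual-differences inference
(dissimilarity ~ trait) has a known ground truth.

Model per subject i, condition c, inside a signal region:

    values = amplitude · T_c  +  Σ_couplings ±½ s_i · u  +  noise

where T_c are mutually orthogonal unit-norm condition templates, u is a
fixed unit direction orthogonal to all templates (one per coupled
contrast), and the separation scalar

    s_i = base_separation + slope · (trait_i − mean trait) + N(0, subject_sd).

The two conditions of the coupled contrast receive +½s_i·u and −½s_i·u, so
their raw pattern distance is |s_i| at zero noise while the third condition
is untouched — coupling is contrast-selective. Outside regions the volume
is smoothed Gaussian noise rescaled to unit variance (mimicking smoothed
z-maps), scaled by ``noise_sd``.

Everything is reproducible bit-for-bit from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, InvalidParameterError
from .volumes import (
    CONDITIONS,
    ConditionMap,
    VolumeGrid,
    ellipsoid_mask_grid,
    write_volume,
)

SUBSCALES = ("FS", "EC", "PT", "PD")
CONTRASTS = ("pain_vs_touch", "pain_vs_control", "touch_vs_control")
CONTRAST_PAIRS = {
    "pain_vs_touch": ("pain", "touch"),
    "pain_vs_control": ("pain", "control"),
    "touch_vs_control": ("touch", "control"),
}

# Default questionnaire scale: four subscales, each the sum of 6 items
# scored 0..5, hence legal range [0, 30]. Default means/SDs are plausible
# adult values for fantasy, empathic concern, perspective taking and
# personal distress sum scores on that scale.
DEFAULT_TRAIT_MEANS = {"FS": 17.0, "EC": 20.0, "PT": 19.0, "PD": 12.0}
DEFAULT_TRAIT_SDS = {"FS": 5.0, "EC": 4.5, "PT": 4.5, "PD": 5.0}

__all__ = [
    "SUBSCALES",
    "CONTRASTS",
    "CONTRAST_PAIRS",
    "TraitScores",
    "SignalROI",
    "TraitCoupling",
    "SyntheticConfig",
    "generate_traits",
    "generate_cohort",
    "default_config",
    "write_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class TraitScores:
    """Per-subject trait empathy scores: four subscales (FS, EC, PT, PD).

    Wraps a DataFrame with columns ``subject_id, FS, EC, PT, PD``; subject
    ids are unique and each subscale lies in [0, n_items·item_max].
    """

    table: pd.DataFrame
    item_max: float = 5.0
    n_items: int = 6

    def __post_init__(self):
        df = self.table
        missing = [c for c in ("subject_id", *SUBSCALES) if c not in df.columns]
        if missing:
            raise InvalidParameterError(f"trait table missing columns {missing}")
        if df["subject_id"].duplicated().any():
            raise InvalidParameterError("duplicate subject_ids in trait table")
        hi = self.item_max * self.n_items
        for s in SUBSCALES:
            v = df[s].to_numpy(dtype=float)
            if (v < 0).any() or (v > hi).any():
                raise InvalidParameterError(f"subscale {s} outside [0, {hi}]")
        df = df.reset_index(drop=True)
        object.__setattr__(self, "table", df)

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.table["subject_id"]]

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def subscale(self, name: str) -> np.ndarray:
        if name not in SUBSCALES:
            raise InvalidParameterError(f"unknown subscale {name!r}; expected one of {SUBSCALES}")
        return self.table[name].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "TraitScores":
        return cls(pd.read_csv(path, dtype={"subject_id": str}), **kw)


@dataclass(frozen=True)
class SignalROI:
    """A set of mask voxels carrying condition-specific patterns.

    ``voxels`` is an (n, 3) integer array; ``amplitude`` scales the
    unit-norm condition templates (so amplitude/noise_sd is the pattern
    SNR). ``templates`` maps condition name to a length-n vector; if None,
    mutually orthogonal unit-norm random templates are drawn from the
    cohort seed.
    """

    voxels: np.ndarray
    amplitude: float = 1.0
    templates: dict | None = None

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.voxels, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3 or len(v) == 0:
            raise ConfigError("ROI voxels must be a non-empty (n, 3) integer array")
        object.__setattr__(self, "voxels", v)
        if self.templates is not None:
            for c, t in self.templates.items():
                if c not in CONDITIONS:
                    raise ConfigError(f"unknown condition {c!r} in ROI templates")
                if len(np.asarray(t)) != len(v):
                    raise ConfigError(
                        f"template for {c!r} has length {len(np.asarray(t))}, ROI has {len(v)} voxels"
                    )

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass(frozen=True)
class TraitCoupling:
    """Couples one contrast's pattern separation in one ROI to a subscale."""

    roi: int  # index into SyntheticConfig.signal_rois
    contrast: str  # e.g. "pain_vs_control"
    subscale: str  # e.g. "EC"
    slope: float  # separation units per trait unit
    base_separation: float = 1.0

    def __post_init__(self):
        if self.contrast not in CONTRASTS:
            raise ConfigError(f"unknown contrast {self.contrast!r}")
        if self.subscale not in SUBSCALES:
            raise ConfigError(f"unknown subscale {self.subscale!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full recipe for a synthetic cohort; the seed makes it reproducible."""

    n_subjects: int
    grid: VolumeGrid
    signal_rois: tuple = ()
    trait_couplings: tuple = ()
    noise_sd: float = 1.0
    smooth_fwhm_voxels: float = 2.0
    subject_sd: float = 0.0
    seed: int = 0
    trait_means: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_MEANS))
    trait_sds: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_SDS))

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be positive")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.smooth_fwhm_voxels < 0 or self.subject_sd < 0:
            raise ConfigError("smooth_fwhm_voxels and subject_sd must be >= 0")
        object.__setattr__(self, "signal_rois", tuple(self.signal_rois))
        object.__setattr__(self, "trait_couplings", tuple(self.trait_couplings))
        for roi in self.signal_rois:
            v = roi.voxels
            inb = ((v >= 0) & (v < np.asarray(self.grid.shape)[None, :])).all(axis=1)
            if not inb.all():
                raise ConfigError("ROI voxels outside grid bounds")
            if not self.grid.mask[v[:, 0], v[:, 1], v[:, 2]].all():
                raise ConfigError("ROI voxels outside the brain mask")
        for cp in self.trait_couplings:
            if not 0 <= cp.roi < len(self.signal_rois):
                raise ConfigError(f"coupling references ROI {cp.roi}, have {len(self.signal_rois)}")


def generate_traits(
    n_subjects: int,
    means: dict | None = None,
    sds: dict | None = None,
    seed: int = 0,
    item_max: float = 5.0,
    n_items: int = 6,
) -> TraitScores:
    """Draw per-subject subscale sums from truncated normals.

    Each subscale is drawn independently from N(mean, sd) truncated to the
    legal range [0, n_items·item_max]. ``sds=0`` gives every subject the
    mean score.
    """
    means = {**DEFAULT_TRAIT_MEANS, **(means or {})}
    sds = {**DEFAULT_TRAIT_SDS, **(sds or {})}
    if any(sds[s] < 0 for s in SUBSCALES):
        raise InvalidParameterError("trait sds must be >= 0")
    rng = np.random.default_rng(seed)
    hi = item_max * n_items
    cols = {"subject_id": [f"sub-{i + 1:03d}" for i in range(n_subjects)]}
    for s in SUBSCALES:
        if sds[s] == 0:
            cols[s] = np.full(n_subjects, float(np.clip(means[s], 0, hi)))
        else:
            # rejection sampling from the truncated normal; reproducible and
            # free of scipy's ppf edge cases at sd -> 0
            out = np.empty(n_subjects)
            need = np.ones(n_subjects, dtype=bool)
            while need.any():
                draw = rng.normal(means[s], sds[s], size=int(need.sum()))
                ok = (draw >= 0) & (draw <= hi)
                idx = np.flatnonzero(need)[ok]
                out[idx] = draw[ok]
                need[idx] = False
            cols[s] = out
    return TraitScores(pd.DataFrame(cols), item_max=item_max, n_items=n_items)


def _smooth_noise(rng, grid: VolumeGrid, fwhm: float) -> np.ndarray:
    """Unit-variance spatially smooth Gaussian field on the full grid."""
    noise = rng.standard_normal(grid.shape)
    if fwhm > 0:
        sigma = fwhm / np.sqrt(8.0 * np.log(2.0))
        noise = ndimage.gaussian_filter(noise, sigma=sigma)
        noise /= noise.std()
    return noise


def _orthonormal_vectors(rng, n: int, k: int) -> list[np.ndarray]:
    """k mutually orthogonal unit-norm vectors of length n (n >= k)."""
    if n < k:
        raise ConfigError(f"ROI with {n} voxels cannot host {k} orthogonal templates")
    mat = rng.standard_normal((n, k))
    q, _ = np.linalg.qr(mat)
    return [np.ascontiguousarray(q[:, j]) for j in range(k)]


def generate_cohort(config: SyntheticConfig):
    """Generate ``n_subjects × 3`` condition maps plus trait scores.

    Returns ``(maps, traits)`` with maps in subject-major, condition-minor
    order (pain, touch, control per subject). Identical seeds give
    bit-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    traits = generate_traits(
        config.n_subjects,
        config.trait_means,
        config.trait_sds,
        seed=rng.integers(2**31),
    )

    # Per-ROI templates: user-supplied, or orthogonal unit-norm random,
    # plus one extra orthogonal direction per coupled contrast.
    roi_templates: list[dict] = []
    coupling_dirs: list[np.ndarray] = []
    for r, roi in enumerate(config.signal_rois):
        n_extra = sum(cp.roi == r for cp in config.trait_couplings)
        basis = _orthonormal_vectors(rng, roi.n_voxels, 3 + n_extra)
        if roi.templates is not None:
            tmpl = {c: np.asarray(roi.templates[c], dtype=float) for c in CONDITIONS}
        else:
            tmpl = dict(zip(CONDITIONS, basis[:3]))
        roi_templates.append(tmpl)
        # direction vectors for this ROI's couplings, in coupling order
        extra = iter(basis[3:])
        for cp in config.trait_couplings:
            if cp.roi == r:
                if roi.templates is not None:
                    u = np.asarray(next(extra))
                    # re-orthogonalise against user templates
                    for t in tmpl.values():
                        nt = np.linalg.norm(t)
                        if nt > 0:
                            u = u - (u @ t) / nt**2 * t
                    nu = np.linalg.norm(u)
                    if nu == 0:
                        raise ConfigError("cannot build separation direction orthogonal to templates")
                    u = u / nu
                else:
                    u = next(extra)
                coupling_dirs.append(u)

    # Per-subject separation scalars s_i for each coupling (subject noise
    # drawn before the volume noise so map generation order is stable).
    separations = []
    for cp in config.trait_couplings:
        t = traits.subscale(cp.subscale)
        s = cp.base_separation + cp.slope * (t - t.mean())
        s = s + rng.normal(0.0, config.subject_sd, size=config.n_subjects)
        separations.append(s)

    dir_by_coupling = {}
    k = 0
    for r, _ in enumerate(config.signal_rois):
        for ci, cp in enumerate(config.trait_couplings):
            if cp.roi == r:
                dir_by_coupling[ci] = coupling_dirs[k]
                k += 1

    maps = []
    for i, sid in enumerate(traits.subject_ids):
        for c in CONDITIONS:
            vol = config.noise_sd * _smooth_noise(rng, config.grid, config.smooth_fwhm_voxels)
            for r, roi in enumerate(config.signal_rois):
                v = roi.voxels
                signal = roi.amplitude * roi_templates[r][c]
                for ci, cp in enumerate(config.trait_couplings):
                    if cp.roi != r:
                        continue
                    c1, c2 = CONTRAST_PAIRS[cp.contrast]
                    if c == c1:
                        signal = signal + 0.5 * separations[ci][i] * dir_by_coupling[ci]
                    elif c == c2:
                        signal = signal - 0.5 * separations[ci][i] * dir_by_coupling[ci]
                vol[v[:, 0], v[:, 1], v[:, 2]] += signal
            maps.append(ConditionMap(subject_id=sid, condition=c, values=vol, grid=config.grid))
    return maps, traits


def default_config(
    n_subjects: int = 20,
    shape: Sequence[int] = (24, 24, 24),
    roi_halfwidth: int = 2,
    amplitude: float = 1.0,
    noise_sd: float = 1.0,
    smooth_fwhm_voxels: float = 2.0,
    couplings: Sequence[TraitCoupling] = (),
    subject_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticConfig:
    """Desk-scale cohort: ellipsoid brain mask with one cubic signal ROI
    at the mask centre (side 2·halfwidth+1)."""
    grid = ellipsoid_mask_grid(shape=shape)
    c = np.asarray(shape) // 2
    rng = range(-roi_halfwidth, roi_halfwidth + 1)
    vox = np.array([[c[0] + i, c[1] + j, c[2] + k] for i in rng for j in rng for k in rng])
    roi = SignalROI(voxels=vox, amplitude=amplitude)
    return SyntheticConfig(
        n_subjects=n_subjects,
        grid=grid,
        signal_rois=(roi,),
        trait_couplings=tuple(couplings),
        noise_sd=noise_sd,
        smooth_fwhm_voxels=smooth_fwhm_voxels,
        subject_sd=subject_sd,
        seed=seed,
    )


def write_cohort(maps, traits: TraitScores, grid: VolumeGrid, outdir) -> None:
    """Write a cohort as ``<subject>_<condition>.nii.gz`` volumes, a
    ``mask.nii.gz`` and a ``traits.csv`` table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for m in maps:
        write_volume(m.values, outdir / f"{m.subject_id}_{m.condition}.nii.gz", grid)
    write_volume(grid.mask.astype(float), outdir / "mask.nii.gz", grid)
    traits.to_csv(outdir / "traits.csv")


def load_cohort(indir, grid: VolumeGrid):
    """Load a cohort written by :func:`write_cohort`."""
    from .volumes import read_volume

    indir = Path(indir)
    traits = TraitScores.from_csv(indir / "traits.csv")
    maps = []
    for sid in traits.subject_ids:
        for c in CONDITIONS:
            path = indir / f"{sid}_{c}.nii.gz"
            if not path.exists():
                raise ConfigError(f"missing condition volume {path}")
            vals, _ = read_volume(path, grid)
            maps.append(ConditionMap(subject_id=sid, condition=c, values=vals, grid=grid))
    return maps, traits
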