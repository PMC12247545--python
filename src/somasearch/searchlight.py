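"""Generic searchlight engine.

A searchlight applies a per-sphere statistic at every brain-mask voxel: the
values of all input volumes within the sphere centred at a voxel are passed
to the statistic, and its result is written back to that center voxel. The
engine is statistic-agnostic so the condition-decoding searchlight and the
pattern-dissimilarity searchlight share one implementation and identical
sphere geometry.

Work is chunked over center voxels; serial and parallel execution merge
chunks deterministically, so results are bit-identical regardless of the
degree of parallelism for deterministic statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from joblib import Parallel, delayed

from .errors import DegenerateSphereError, SomasearchError
from .volumes import SphereSpec, VolumeGrid, sphere_index_table

__all__ = ["SearchlightResult", "run_searchlight"]


@dataclass(frozen=True)
class SearchlightResult:
    """A statistic volume produced by a searchlight run.

    ``values`` is finite exactly at mask voxels (unless the statistic itself
    produced NaN there, e.g. for a flagged degenerate sphere) and NaN
    outside the mask. Multi-output statistics produce a tuple of results,
    one per output component.
    """

    values: np.ndarray
    statistic_name: str
    radius_voxels: float
    grid: VolumeGrid


def _stack_maps(maps, grid: VolumeGrid) -> np.ndarray:
    vols = []
    for m in maps:
        v = getattr(m, "values", m)
        v = np.asarray(v, dtype=float)
        vols.append(grid.check_volume(v).ravel())
    return np.asarray(vols)


def _run_chunk(flat_maps, indices, centers, lo, hi, statistic):
    out = []
    for i in range(lo, hi):
        idx = indices[i]
        idx = idx[idx >= 0]
        patterns = flat_maps[:, idx]
        try:
            out.append(statistic(patterns))
        except SomasearchError:
            raise
        except Exception as exc:  # attach the center coordinate for debugging
            c = tuple(int(x) for x in centers[i])
            raise DegenerateSphereError(f"statistic failed at sphere center {c}: {exc}") from exc
    return out


def run_searchlight(
    maps: Sequence,
    statistic: Callable[[np.ndarray], float | np.ndarray],
    sphere: SphereSpec,
    grid: VolumeGrid,
    statistic_name: str = "statistic",
    n_jobs: int = 1,
    chunk_size: int = 512,
):
    """Apply ``statistic`` to every mask voxel's sphere patterns.

    Parameters
    ----------
    maps
        Volumes (arrays or objects with ``.values``) sharing ``grid``.
    statistic
        Callable receiving an ``(n_maps, k)`` array of the sphere's pattern
        vectors (k ≤ number of sphere offsets after clipping at mask/grid
        edges) and returning either a scalar or a fixed-length 1D array.
    sphere, grid
        Sphere geometry and the shared grid/mask.
    n_jobs
        joblib workers; output is identical for any value.

    Returns
    -------
    SearchlightResult, or a tuple of them when the statistic returns a
    vector (one result per output component).
    """
    flat_maps = _stack_maps(maps, grid)
    centers, indices = sphere_index_table(grid, sphere)
    M = len(centers)
    bounds = [(lo, min(lo + chunk_size, M)) for lo in range(0, M, chunk_size)]
    if n_jobs == 1 or len(bounds) <= 1:
        chunks = [_run_chunk(flat_maps, indices, centers, lo, hi, statistic) for lo, hi in bounds]
    else:
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(_run_chunk)(flat_maps, indices, centers, lo, hi, statistic)
            for lo, hi in bounds
        )
    flat_out = [v for chunk in chunks for v in chunk]

    first = np.asarray(flat_out[0], dtype=float)
    if first.ndim == 0:
        vol = np.full(grid.shape, np.nan)
        vol[centers[:, 0], centers[:, 1], centers[:, 2]] = np.asarray(flat_out, dtype=float)
        return SearchlightResult(vol, statistic_name, sphere.radius_voxels, grid)
    n_out = first.shape[0]
    arr = np.asarray(flat_out, dtype=float).reshape(M, n_out)
    results = []
    for j in range(n_out):
        vol = np.full(grid.shape, np.nan)
        vol[centers[:, 0], centers[:, 1], centers[:, 2]] = arr[:, j]
        results.append(
            SearchlightResult(vol, f"{statistic_name}[{j}]", sphere.radius_voxels, grid)
        )
    return tuple(results)
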