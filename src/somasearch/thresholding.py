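"""Significance machinery for decoding-accuracy maps.

Multiple comparisons are handled with a resel-wise Bonferroni correction:
the brain mask is divided into "resels" — the number of non-overlapping
searchlight spheres that fit inside it — and the nominal alpha is divided
by that count. The corrected alpha is converted to a minimum number of
correct classifications via the exact binomial null (n classifications at
chance 1/3), i.e. the binomial inverse cumulative distribution function.

On the full-resolution standard brain with a 3-voxel-radius sphere the
reference resel count is ~725, giving corrected alpha 0.05/725 ≈ 6.89e-5
and, for 210 classifications, a critical count of 97 (46%). The resel
count is always a reportable, overridable input, since the packing rule
used to derive ~725 on a particular mask is not uniquely defined; two
deterministic estimators are provided.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import InvalidParameterError
from .searchlight import SearchlightResult
from .volumes import SphereSpec

__all__ = [
    "ThresholdSpec",
    "resel_count",
    "bonferroni_alpha",
    "binomial_threshold",
    "threshold_accuracy_map",
    "build_threshold_spec",
]

REFERENCE_RESELS_FULL_BRAIN = 725  # documented reference value for the standard-brain mask


@dataclass(frozen=True)
class ThresholdSpec:
    """All numbers defining the accuracy-significance threshold.

    ``accuracy_critical = k_critical / n_classifications``; a map voxel is
    significant when accuracy ≥ accuracy_critical (inclusive, so the
    critical count itself passes). ``attainable`` is False when no count
    ≤ n reaches the corrected alpha (then k_critical = n + 1).
    """

    alpha_nominal: float
    resel_count: int
    alpha_corrected: float
    n_classifications: int
    chance_p: float
    k_critical: int
    accuracy_critical: float
    attainable: bool = True

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def resel_count(mask: np.ndarray, sphere: SphereSpec, method: str = "volume") -> int:
    """Number of non-overlapping spheres fitting in the mask.

    ``"volume"`` (default): floor(mask voxels / sphere voxel count).
    ``"cube"``: packs bounding cubes, floor(mask voxels / (2⌊r⌋+1)³).
    Both are deterministic; neither reproduces a particular published count
    exactly on an arbitrary mask, so the result should be reported with any
    thresholded map.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise InvalidParameterError("mask is empty")
    if method == "volume":
        per = sphere.n_offsets
    elif method == "cube":
        side = 2 * int(np.floor(sphere.radius_voxels)) + 1
        per = side**3
    else:
        raise InvalidParameterError(f"unknown resel estimator {method!r}")
    return max(1, n // per)


def bonferroni_alpha(alpha_nominal: float, resels: int) -> float:
    """Resel-wise Bonferroni corrected alpha = alpha / resel count."""
    if not 0 < alpha_nominal < 1:
        raise InvalidParameterError(f"alpha must be in (0,1), got {alpha_nominal}")
    if resels < 1:
        raise InvalidParameterError("resel count must be >= 1")
    return alpha_nominal / resels


def binomial_threshold(n: int, chance_p: float, alpha_corrected: float, convention: str = "inverse_cdf"):
    """Critical classification count under the exact binomial null.

    X ~ Binomial(n, chance_p). Two conventions are in circulation:

    ``"inverse_cdf"`` (default)
        k = smallest count with CDF(k) ≥ 1 − alpha — the value returned by
        the binomial inverse cumulative distribution function (binoinv /
        ppf), the standard recipe for converting a corrected alpha into an
        accuracy threshold. For 210 classifications at chance 1/3 and
        alpha 0.05/725 this gives the reference k = 97 (46%).
    ``"tail"``
        k = smallest count with upper tail P(X ≥ k) ≤ alpha, which is one
        more than the inverse-CDF value whenever the tail at the
        inverse-CDF count slightly exceeds alpha (k = 98 in the reference
        design); this variant strictly guarantees the tail bound at k.

    Returns ``(k_critical, accuracy_critical, attainable)``; when even
    k = n fails the criterion (possible only under ``"tail"``), returns
    ``(n + 1, (n + 1)/n, False)``.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if not 0 < chance_p < 1:
        raise InvalidParameterError("chance_p must be in (0,1)")
    if not 0 < alpha_corrected <= 1:
        raise InvalidParameterError("alpha_corrected must be in (0,1]")
    k = np.arange(0, n + 1)
    # P(X >= k) = sf(k-1); sf computes the regularised incomplete beta, which
    # is exact to double precision for these tails
    tails = stats.binom.sf(k - 1, n, chance_p)
    if convention == "tail":
        ok = np.flatnonzero(tails <= alpha_corrected)
        if len(ok) == 0:
            return n + 1, (n + 1) / n, False
        k_crit = int(k[ok[0]])
    elif convention == "inverse_cdf":
        # smallest k with P(X > k) <= alpha, i.e. CDF(k) >= 1 - alpha
        ok = np.flatnonzero(tails[1:] <= alpha_corrected)  # tails[k+1] = P(X > k)
        k_crit = int(ok[0]) if len(ok) else n
    else:
        raise InvalidParameterError(f"unknown threshold convention {convention!r}")
    return k_crit, k_crit / n, True


def build_threshold_spec(
    mask: np.ndarray,
    sphere: SphereSpec,
    n_classifications: int,
    chance_p: float = 1.0 / 3.0,
    alpha_nominal: float = 0.05,
    resel_override: int | None = None,
    resel_method: str = "volume",
    convention: str = "inverse_cdf",
) -> ThresholdSpec:
    """Assemble the full threshold spec for an accuracy map."""
    resels = resel_override if resel_override is not None else resel_count(mask, sphere, resel_method)
    alpha_c = bonferroni_alpha(alpha_nominal, resels)
    k_crit, acc_crit, attainable = binomial_threshold(n_classifications, chance_p, alpha_c, convention)
    return ThresholdSpec(
        alpha_nominal=alpha_nominal,
        resel_count=int(resels),
        alpha_corrected=alpha_c,
        n_classifications=int(n_classifications),
        chance_p=chance_p,
        k_critical=k_crit,
        accuracy_critical=acc_crit,
        attainable=attainable,
    )


def threshold_accuracy_map(acc, spec: ThresholdSpec) -> np.ndarray:
    """Boolean volume: True where accuracy ≥ the critical accuracy.

    NaN voxels (outside the mask) are False.
    """
    values = acc.values if isinstance(acc, SearchlightResult) else np.asarray(acc, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(values, nan=-np.inf) >= spec.accuracy_critical
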