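"""Cross-participant condition decoding within searchlight spheres.

Each sphere's feature set is the z-values of its voxels, one pattern per
subject × condition. Decoding is three-way (pain / touch / control) via the
one-against-one scheme: three binary linear SVMs (pain–touch, pain–control,
touch–control) whose majority vote labels a sample. Accuracy is assessed by
leave-one-subject-out cross-validation: train on all other subjects'
patterns, predict the held-out subject's three patterns; the fraction of
correct predictions over all folds (n_subjects × 3 predictions, chance 1/3)
is mapped to the sphere's center voxel.

The SVM regularisation constant is set from the data scale,
C = 1 / mean(‖x‖²) over training samples by default (``c_norm="sqnorm"``;
``"norm"`` divides by the mean Euclidean norm instead). This makes accuracy
invariant to a common rescaling of all features. One-against-one vote ties
are broken deterministically by fixed label order pain < touch < control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .errors import DatasetError, DegenerateSphereError
from .searchlight import SearchlightResult, run_searchlight
from .volumes import CONDITIONS, ConditionMap, SphereSpec, VolumeGrid

__all__ = ["DecodingDataset", "loso_accuracy", "classification_searchlight", "svm_c_heuristic"]

_LABEL_ORDER = {c: i for i, c in enumerate(CONDITIONS)}  # pain < touch < control


@dataclass(frozen=True)
class DecodingDataset:
    """Pattern samples indexed by (subject, condition).

    ``samples`` is (n_samples, n_features); ``labels`` and ``groups`` give
    each sample's condition and subject. Every subject must contribute
    exactly one sample per condition, and there must be at least two
    subjects (otherwise leave-one-subject-out folds cannot be formed).
    """

    samples: np.ndarray
    labels: tuple
    groups: tuple

    def __post_init__(self):
        X = np.asarray(self.samples, dtype=float)
        labels = tuple(self.labels)
        groups = tuple(str(g) for g in self.groups)
        if X.ndim != 2 or len(X) != len(labels) or len(X) != len(groups):
            raise DatasetError("samples, labels and groups must have matching first dimension")
        subjects = sorted(set(groups))
        if len(subjects) < 2:
            raise DatasetError("need at least 2 subjects for leave-one-subject-out folds")
        for s in subjects:
            conds = sorted(l for l, g in zip(labels, groups) if g == s)
            if conds != sorted(CONDITIONS):
                raise DatasetError(f"subject {s} does not have exactly one sample per condition")
        object.__setattr__(self, "samples", X)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "groups", groups)

    @property
    def subjects(self) -> list[str]:
        return sorted(set(self.groups))


def svm_c_heuristic(X: np.ndarray, mode: str = "sqnorm") -> float:
    """Data-scale regularisation constant for the linear SVM.

    ``"sqnorm"``: C = 1 / mean(‖x‖²); ``"norm"``: C = 1 / mean(‖x‖).
    Either choice makes decoding invariant to a common affine rescaling of
    the features.
    """
    norms = np.linalg.norm(X, axis=1)
    if mode == "sqnorm":
        denom = float(np.mean(norms**2))
    elif mode == "norm":
        denom = float(np.mean(norms))
    else:
        raise DatasetError(f"unknown C heuristic {mode!r}")
    if denom <= 0:
        return 1.0
    return 1.0 / denom


def _ovo_predict(Xtr, ytr, Xte, C):
    """One-against-one majority vote over the three binary linear SVMs.

    Implemented as a single libsvm multiclass fit: libsvm trains the three
    pairwise classifiers internally and labels by majority vote, breaking
    cyclic 1-1-1 ties in favour of the first class — i.e. the fixed order
    pain < touch < control given our integer label encoding. Equivalent to
    fitting the three binary SVMs explicitly (checked against that
    construction in the test suite) but substantially faster.
    """
    clf = SVC(kernel="linear", C=C)
    clf.fit(Xtr, ytr)
    return clf.predict(Xte).astype(int)


def loso_accuracy(dataset: DecodingDataset, c_mode: str = "sqnorm") -> float:
    """Leave-one-subject-out decoding accuracy in [0, 1].

    For each fold, the three pairwise linear SVMs are trained on every
    other subject's patterns (with C from :func:`svm_c_heuristic` on the
    fold's training data) and the held-out subject's three patterns are
    labelled by majority vote. Returns total correct / total predictions.
    """
    X = dataset.samples
    if X.shape[1] == 0:
        raise DegenerateSphereError("empty pattern vectors (0 features) in this sphere")
    y = np.array([_LABEL_ORDER[l] for l in dataset.labels])
    groups = np.array(dataset.groups)
    correct = 0
    total = 0
    for s in dataset.subjects:
        test = groups == s
        Xtr, ytr = X[~test], y[~test]
        C = svm_c_heuristic(Xtr, c_mode)
        pred = _ovo_predict(Xtr, ytr, X[test], C)
        correct += int((pred == y[test]).sum())
        total += int(test.sum())
    return correct / total


def _as_dataset(maps: Sequence[ConditionMap], patterns: np.ndarray) -> DecodingDataset:
    return DecodingDataset(
        samples=patterns,
        labels=tuple(m.condition for m in maps),
        groups=tuple(m.subject_id for m in maps),
    )


def classification_searchlight(
    maps: Sequence[ConditionMap],
    sphere: SphereSpec,
    grid: VolumeGrid,
    c_mode: str = "sqnorm",
    n_jobs: int = 1,
) -> SearchlightResult:
    """Whole-brain decoding searchlight: LOSO accuracy at every mask voxel.

    ``maps`` must contain exactly one map per subject per condition. The
    returned volume holds accuracies in [0, 1] at mask voxels and NaN
    elsewhere.
    """
    labels = tuple(m.condition for m in maps)
    groups = tuple(m.subject_id for m in maps)
    # validate the subject x condition design once, not per sphere
    probe = DecodingDataset(
        samples=np.zeros((len(maps), 1)), labels=labels, groups=groups
    )

    def stat(patterns: np.ndarray) -> float:
        ds = DecodingDataset.__new__(DecodingDataset)
        object.__setattr__(ds, "samples", patterns)
        object.__setattr__(ds, "labels", labels)
        object.__setattr__(ds, "groups", groups)
        return loso_accuracy(ds, c_mode)

    return run_searchlight(
        maps, stat, sphere, grid, statistic_name="loso_accuracy", n_jobs=n_jobs
    )
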