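"""Subject classification from similarity maps with a linear SVM.

Each subject contributes 12 similarity maps (3 repetition pairs x 2
languages x 2 phases) restricted to a common mask. The maps are voxelwise
averaged into one map per subject (a concatenation mode is also provided),
mean-centered using training-fold statistics only, and classified with a
binary linear SVM (C = 1) under leave-one-subject-out cross-validation.
Significance is assessed by full-label permutation with an add-one
corrected p-value, and the final weight map (from a fit on all subjects) is
thresholded at 30% of the maximum absolute weight with a 100-voxel cluster
extent, keeping the sign of each surviving weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.svm import SVC

N_SIMILARITY_MAPS = 12
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class FeatureSet:
    """Per-subject stacks of similarity maps restricted to a mask.

    ``maps`` has shape (n_subjects, 12, n_mask_voxels); ``labels`` is a
    binary group label per subject; ``mask`` is the 3D boolean mask shared
    by all subjects.
    """

    maps: np.ndarray
    labels: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.maps.ndim != 3:
            raise ValueError("maps must be (n_subjects, n_maps, n_voxels)")
        if self.maps.shape[1] != N_SIMILARITY_MAPS:
            raise ValueError(f"expected {N_SIMILARITY_MAPS} similarity maps per subject")
        if self.maps.shape[2] != int(self.mask.sum()):
            raise ValueError("map length does not match mask size")
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) != 2 or (counts < 3).any():
            raise ValueError("need two classes with at least 3 subjects each")


@dataclass
class ClassifierResult:
    accuracy: float
    predictions: np.ndarray
    labels: np.ndarray
    weights: np.ndarray  # in-mask weight vector from the all-subject fit
    permutation_p: float | None = None
    permutation_accuracies: np.ndarray | None = None
    threshold_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")


def assemble_features(feature_set: FeatureSet, mode: str = "average") -> np.ndarray:
    """Collapse the 12 maps into one feature vector per subject.

    ``mode="average"`` (default) voxelwise-averages the maps;
    ``mode="concatenate"`` stacks them. Mean-centering is *not* applied
    here: it uses training-fold means only, inside cross-validation.
    """
    if mode == "average":
        return feature_set.maps.mean(axis=1)
    if mode == "concatenate":
        return feature_set.maps.reshape(feature_set.maps.shape[0], -1)
    raise ValueError("mode must be 'average' or 'concatenate'")


def _loso_accuracy(features: np.ndarray, labels: np.ndarray, C: float = 1.0):
    """Pooled LOSO predictions with training-fold mean-centering."""
    n = features.shape[0]
    preds = np.empty(n, dtype=labels.dtype)
    skipped = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        y_tr = labels[train]
        if len(np.unique(y_tr)) < 2:
            warnings.warn(f"fold {i}: single-class training set, skipped", RuntimeWarning)
            skipped.append(i)
            preds[i] = labels[i]  # placeholder, excluded from accuracy
            continue
        mu = features[train].mean(axis=0)
        clf = SVC(kernel="linear", C=C)
        clf.fit(features[train] - mu, y_tr)
        preds[i] = clf.predict((features[i] - mu)[None, :])[0]
    valid = np.ones(n, dtype=bool)
    valid[skipped] = False
    classes = np.unique(labels)
    per_class = [
        (preds[valid & (labels == c)] == c).mean() for c in classes if (valid & (labels == c)).any()
    ]
    return float(np.mean(per_class)), preds


def loso_svm(features: np.ndarray, labels, C: float = 1.0) -> ClassifierResult:
    """Leave-one-subject-out linear SVM.

    Accuracy is the balanced accuracy of the pooled held-out predictions
    (mean of per-class accuracies). The reported weight vector comes from a
    final fit on all subjects (centered on the full-sample mean).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must be binary")
    accuracy, preds = _loso_accuracy(features, labels, C=C)
    clf = SVC(kernel="linear", C=C)
    clf.fit(features - features.mean(axis=0), labels)
    weights = np.asarray(clf.coef_).ravel()
    return ClassifierResult(
        accuracy=accuracy, predictions=preds, labels=labels, weights=weights
    )


def permutation_test(
    features: np.ndarray, labels, n_perm: int = 1000, seed: int = 0, C: float = 1.0
) -> tuple[float, np.ndarray, float]:
    """Permutation p-value for the LOSO accuracy.

    Labels are fully shuffled ``n_perm`` times and the LOSO accuracy
    recomputed; p = (1 + #{perm >= observed}) / (n_perm + 1).

    Returns (p, permuted accuracies, observed accuracy).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    observed, _ = _loso_accuracy(features, labels, C=C)
    rng = np.random.default_rng(seed)
    perm_acc = np.empty(n_perm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(n_perm):
            perm_acc[i], _ = _loso_accuracy(features, rng.permutation(labels), C=C)
    p = (1.0 + float((perm_acc >= observed).sum())) / (n_perm + 1.0)
    return p, perm_acc, observed


def threshold_weight_map(
    weights: np.ndarray,
    mask: np.ndarray | None = None,
    fraction: float = 0.30,
    min_cluster: int = 100,
) -> np.ndarray:
    """Threshold a weight map at a fraction of the maximum absolute weight.

    Voxels with |w| >= fraction * max|w| are kept with their sign; clusters
    (26-connectivity, computed on the kept voxels regardless of sign)
    smaller than ``min_cluster`` voxels are removed.
    """
    weights = np.asarray(weights, dtype=float)
    if not np.isfinite(weights).all():
        raise ValueError("weights must be finite")
    if mask is not None:
        vol = np.zeros(mask.shape)
        vol[np.asarray(mask, dtype=bool)] = weights
    else:
        vol = weights
    if vol.ndim != 3:
        raise ValueError("provide a 3D weight map or a mask to embed the vector")
    wmax = np.abs(vol).max()
    if wmax == 0:
        warnings.warn("all-zero weight map", RuntimeWarning)
        return np.zeros_like(vol)
    keep = np.abs(vol) >= fraction * wmax
    labeled, n = ndimage.label(keep, structure=CONNECTIVITY_26)
    if n:
        sizes = np.bincount(labeled.ravel())
        small = np.flatnonzero(sizes < min_cluster)
        keep &= ~np.isin(labeled, small[small > 0])
    out = np.where(keep, vol, 0.0)
    return out
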