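"""Cross-task pattern classification.

The core computation: pairwise linear SVMs (C = 1) are trained on
search-task beta patterns from the cue or delay period and tested on
1-back-task patterns, under four cross-classification schemes:

===========  ==================  ======================  =============
scheme       train period        test period             test modality
===========  ==================  ======================  =============
cue_face     search cue          1-back sample stimulus  face
cue_scene    search cue          1-back sample stimulus  scene
delay_face   search delay        1-back delay            face
delay_scene  search delay        1-back delay            scene
===========  ==================  ======================  =============

Training samples are always labeled by the cued face (1..4). For scene
schemes each test sample's scene category is mapped to the face id it is
associated with (the learned face-scene bijection), so that e.g. a delay
pattern trained on "cue was face 2" should generalize to the 1-back
pattern of face 2's associated scene. Accuracy is the mean over the six
pairwise classifiers.

Patterns are normalized per voxel (z-scoring) using statistics estimated
from the training set only; the identical transform is applied to the
test set, so no test information leaks into training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import svm as _svm
from .roi import PatternSet

__all__ = [
    "CrossClassScheme",
    "SCHEMES",
    "LabelMap",
    "PairwiseClassifierBank",
    "AccuracyResult",
    "normalize_patterns",
    "train_pairwise",
    "cross_classify",
    "decode",
]


@dataclass(frozen=True)
class CrossClassScheme:
    name: str
    train_period: str
    test_period: str
    test_modality: str


SCHEMES = {
    "cue_face": CrossClassScheme("cue_face", "cue", "stim", "face"),
    "cue_scene": CrossClassScheme("cue_scene", "cue", "stim", "scene"),
    "delay_face": CrossClassScheme("delay_face", "delay", "oneback_delay",
                                   "face"),
    "delay_scene": CrossClassScheme("delay_scene", "delay", "oneback_delay",
                                    "scene"),
}


def get_scheme(name) -> CrossClassScheme:
    if isinstance(name, CrossClassScheme):
        return name
    if name not in SCHEMES:
        raise ValueError(f"unknown scheme {name!r}; valid schemes are "
                         f"{sorted(SCHEMES)}")
    return SCHEMES[name]


class LabelMap:
    """Bijection between face ids and associated scene categories."""

    def __init__(self, face_to_scene: dict):
        if sorted(face_to_scene) != [1, 2, 3, 4] \
                or sorted(face_to_scene.values()) != [1, 2, 3, 4]:
            raise ValueError("label map must be a bijection on {1..4}")
        self.face_to_scene = dict(face_to_scene)
        self.scene_to_face = {v: k for k, v in face_to_scene.items()}

    def faces_for_scenes(self, scenes):
        try:
            return np.array([self.scene_to_face[int(s)] for s in scenes])
        except KeyError as e:
            raise ValueError(f"unmapped scene category {e.args[0]!r}") from None

    def permuted(self, perm: dict) -> "LabelMap":
        """Label map after relabeling faces by ``perm`` (face -> new id)."""
        return LabelMap({perm[f]: s for f, s in self.face_to_scene.items()})


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_patterns(train: PatternSet, test: PatternSet,
                       method: str = "zscore"):
    """Center and scale each voxel using training-set statistics only.

    ``zscore``: per-voxel mean/sd over training samples (sd 0 -> voxel
    mapped to 0 in both sets). ``sample_center``: subtract each sample's
    own mean across voxels (the alternative reading of removing univariate
    condition differences).
    """
    if train.n_voxels != test.n_voxels:
        raise ValueError("train and test voxel counts differ")
    if method == "zscore":
        mu = train.X.mean(axis=0)
        sd = train.X.std(axis=0, ddof=0)
        good = sd > 0
        scale = np.where(good, sd, 1.0)
        Xtr = np.where(good, (train.X - mu) / scale, 0.0)
        Xte = np.where(good, (test.X - mu) / scale, 0.0)
    elif method == "sample_center":
        Xtr = train.X - train.X.mean(axis=1, keepdims=True)
        Xte = test.X - test.X.mean(axis=1, keepdims=True)
    else:
        raise ValueError("method must be 'zscore' or 'sample_center'")
    return replace(train, X=Xtr), replace(test, X=Xte)


# ---------------------------------------------------------------------------
# training and cross-classification
# ---------------------------------------------------------------------------

@dataclass
class PairwiseClassifierBank:
    """One soft-margin linear rule per unordered condition pair.

    ``weights[k]``, ``biases[k]`` belong to ``pairs[k] = (lo, hi)``; the
    decision score w.x + b predicts ``hi`` when > 0 and ``lo`` otherwise
    (ties toward the smaller id).
    """

    pairs: np.ndarray            # (n_pairs, 2)
    weights: np.ndarray          # (n_pairs, n_voxels)
    biases: np.ndarray           # (n_pairs,)
    cost: float

    @property
    def n_pairs(self):
        return self.pairs.shape[0]


def train_pairwise(train: PatternSet, cost: float = 1.0,
                   tol: float = 1e-4) -> PairwiseClassifierBank:
    """Train one binary linear SVM per unordered condition pair, each on
    that pair's samples only."""
    if cost <= 0:
        raise ValueError("cost must be positive")
    conds = train.conditions
    uniq, counts = np.unique(conds, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two conditions to train")
    if counts.min() < 2:
        bad = uniq[counts < 2]
        raise ValueError(
            f"conditions {bad.tolist()} have fewer than 2 samples")
    pairs = np.asarray(_svm.condition_pairs(conds), dtype=np.int64)
    W = np.empty((pairs.shape[0], train.n_voxels))
    b = np.empty(pairs.shape[0])
    X = np.ascontiguousarray(train.X, dtype=np.float64)
    for k, (lo, hi) in enumerate(pairs):
        sel = (conds == lo) | (conds == hi)
        y = np.where(conds[sel] == hi, 1.0, -1.0)
        W[k], b[k] = _svm.svc_fit(np.ascontiguousarray(X[sel]), y,
                                  float(cost), float(tol))
    return PairwiseClassifierBank(pairs=pairs, weights=W, biases=b,
                                  cost=float(cost))


@dataclass
class AccuracyResult:
    scheme: str
    roi_label: str
    accuracy: float              # mean of the pairwise accuracies
    pair_accuracies: np.ndarray
    pairs: np.ndarray
    n_train: int
    n_test: int
    subject: int | None = None


def cross_classify(scheme, bank: PairwiseClassifierBank, test: PatternSet,
                   label_map: LabelMap | None = None) -> AccuracyResult:
    """Score a trained bank on cross-task test patterns.

    For face schemes test labels are the face ids; for scene schemes each
    test sample's scene category is first mapped to its associated face id
    so the face-trained classifiers can score it.
    """
    scheme = get_scheme(scheme)
    if test.n_samples == 0:
        raise ValueError("empty test set")
    if scheme.test_modality == "scene":
        if label_map is None:
            raise ValueError("scene schemes require a label map")
        labels = label_map.faces_for_scenes(test.conditions)
    else:
        labels = test.conditions
    accs = np.empty(bank.n_pairs)
    for k in range(bank.n_pairs):
        lo, hi = bank.pairs[k]
        sel = (labels == lo) | (labels == hi)
        if not sel.any():
            accs[k] = np.nan
            continue
        score = test.X[sel] @ bank.weights[k] + bank.biases[k]
        pred = np.where(score > 0, hi, lo)
        accs[k] = np.mean(pred == labels[sel])
    return AccuracyResult(scheme=scheme.name, roi_label=test.roi_label,
                          accuracy=float(np.nanmean(accs)),
                          pair_accuracies=accs, pairs=bank.pairs,
                          n_train=0, n_test=int(test.n_samples))


def decode(train: PatternSet, test: PatternSet, scheme,
           label_map: LabelMap | None = None, cost: float = 1.0,
           normalization: str = "zscore", tol: float = 1e-4) -> AccuracyResult:
    """Full single-subject chain: normalize -> train pairwise -> cross-test."""
    tr, te = normalize_patterns(train, test, method=normalization)
    bank = train_pairwise(tr, cost=cost, tol=tol)
    res = cross_classify(scheme, bank, te, label_map=label_map)
    res.n_train = int(train.n_samples)
    return res
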