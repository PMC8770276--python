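"""Classifier training/evaluation and the ablation harness.

Four classifiers are compared: k-nearest-neighbour with Euclidean or
cosine distance, and support-vector machines with RBF or polynomial
kernels. Evaluation follows a repeated, stratified, shuffled 10-fold
cross-validation of the pooled segments: per fold, features are
z-scored by the training-fold mean/sd (never the test fold), the model
is fit on nine folds and scored on the held-out fold as
accuracy = 100 * n_correct / n_total, and the reported figure is the
arithmetic mean over all repetitions x folds.

Pooling means sub-segments of one 8-s epoch can land in both the
training and the test side of a split; ``group_by_epoch=True`` keeps
each epoch's segments together (grouped stratified folds), which is
the leakage-free — and typically lower-scoring — variant.

Ablations re-run the same protocol on channel-region subsets, on
single frequency bands, and on named feature configurations, all with
identical fold partitions (same seed and row order) so comparisons are
paired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedGroupKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ClassBalanceError, ParameterError
from .features import FeatureTable, build_feature_table, default_bands
from .preprocess import SegmentSet
from .recording import Montage

logger = logging.getLogger(__name__)

_VARIANTS = {"knn": ("euclidean", "cosine"), "svm": ("rbf", "poly")}


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier configuration.

    ``family`` is ``knn`` or ``svm``; ``variant`` the distance (knn:
    euclidean/cosine) or kernel (svm: rbf/poly). Hyperparameters: ``k``
    (odd, default 5) for knn; ``C`` (1.0), ``gamma`` ("scale"),
    ``degree`` (3) for svm.
    """

    family: str
    variant: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in _VARIANTS:
            raise ParameterError(f"unknown classifier family {self.family!r}")
        if self.variant not in _VARIANTS[self.family]:
            raise ParameterError(
                f"variant {self.variant!r} not valid for {self.family!r}")
        k = self.hyperparams.get("k", 5)
        if self.family == "knn" and (k < 1 or k % 2 == 0):
            raise ParameterError("knn k must be odd and >= 1")

    @property
    def name(self) -> str:
        return f"{self.family}-{self.variant}"

    def build(self):
        if self.family == "knn":
            k = self.hyperparams.get("k", 5)
            return KNeighborsClassifier(n_neighbors=k, metric=self.variant)
        return SVC(kernel=self.variant,
                   C=self.hyperparams.get("C", 1.0),
                   gamma=self.hyperparams.get("gamma", "scale"),
                   degree=self.hyperparams.get("degree", 3))


def default_classifiers() -> tuple[ClassifierSpec, ...]:
    """The four compared classifiers: KNN(E), KNN(C), SVM(R), SVM(P)."""
    return (ClassifierSpec("knn", "euclidean"), ClassifierSpec("knn", "cosine"),
            ClassifierSpec("svm", "rbf"), ClassifierSpec("svm", "poly"))


@dataclass
class EvalResult:
    """Per-fold accuracies (%) for one configuration; ``mean_accuracy``
    is the arithmetic mean of the reps x folds matrix."""

    config: dict
    fold_accuracies: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def to_dict(self) -> dict:
        return {"config": self.config,
                "fold_accuracies": self.fold_accuracies.tolist(),
                "mean_accuracy": self.mean_accuracy}


def accuracy(n_correct: int, n_total: int) -> float:
    """Classification accuracy in percent: 100 * n_correct / n_total."""
    if n_total <= 0:
        raise ParameterError("n_total must be positive")
    if not 0 <= n_correct <= n_total:
        raise ParameterError("need 0 <= n_correct <= n_total")
    return 100.0 * n_correct / n_total


def _partitions(labels: np.ndarray, folds: int, rep_seed: int, groups=None):
    """One repetition's stratified shuffled fold partition; re-drawn (up
    to 10 times, logged) if any training side is single-class."""
    for attempt in range(10):
        seed = rep_seed + attempt * 7919
        if groups is None:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            splits = list(splitter.split(np.zeros(len(labels)), labels))
        else:
            splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                            random_state=seed)
            splits = list(splitter.split(np.zeros(len(labels)), labels, groups))
        if all(len(np.unique(labels[tr])) == 2 for tr, _ in splits):
            return splits
        logger.warning("degenerate single-class training fold; re-drawing partition")
    raise ClassBalanceError("could not draw a partition with both classes "
                            "in every training fold after 10 attempts")


def cross_validate(features: FeatureTable, spec: ClassifierSpec,
                   folds: int = 10, reps: int = 10, seed: int = 0,
                   group_by_epoch: bool = False) -> EvalResult:
    """Repeated stratified k-fold evaluation of one classifier on one
    feature table. Returns the reps x folds accuracy matrix."""
    y = features.labels
    if len(np.unique(y)) < 2:
        raise ClassBalanceError("both classes required for cross-validation")
    if features.n_segments < folds:
        raise ParameterError("fewer rows than folds")
    X = features.values
    groups = None
    if group_by_epoch:
        groups = np.array([f"{m[0]}/{m[1]}" for m in features.meta])

    acc = np.empty((reps, folds))
    for rep in range(reps):
        splits = _partitions(y, folds, seed + 1000 * rep, groups)
        for fi, (train, test) in enumerate(splits):
            scaler = StandardScaler().fit(X[train])
            clf = spec.build()
            clf.fit(scaler.transform(X[train]), y[train])
            pred = clf.predict(scaler.transform(X[test]))
            acc[rep, fi] = accuracy(int((pred == y[test]).sum()), len(test))
    return EvalResult(config={"classifier": spec.name, **spec.hyperparams},
                      fold_accuracies=acc)


def _evaluate_config(segments: SegmentSet, family: str, spec: ClassifierSpec,
                     montage: Montage, *, channels=None, bands=None, indices=None,
                     folds=10, reps=10, seed=0, group_by_epoch=False,
                     label=None) -> EvalResult:
    ft = build_feature_table(segments, family, channels=channels, bands=bands,
                             montage=montage, indices=indices)
    res = cross_validate(ft, spec, folds=folds, reps=reps, seed=seed,
                         group_by_epoch=group_by_epoch)
    res.config.update({"family": family, "channels": channels, "bands": bands,
                       "name": label})
    return res


def ablate_regions(segments: SegmentSet, family: str, spec: ClassifierSpec,
                   montage: Montage | None = None, folds: int = 10,
                   reps: int = 10, seed: int = 0,
                   group_by_epoch: bool = False) -> dict[str, EvalResult]:
    """Evaluate each scalp region's channel subset plus the whole head
    (key ``all``). All runs share fold partitions for paired
    comparison."""
    montage = montage or segments.montage
    out: dict[str, EvalResult] = {}
    for region, chans in montage.regions.items():
        if not chans:
            raise ParameterError(f"region {region!r} has no channels")
        out[region] = _evaluate_config(segments, family, spec, montage,
                                       channels=list(chans), folds=folds,
                                       reps=reps, seed=seed,
                                       group_by_epoch=group_by_epoch, label=region)
    out["all"] = _evaluate_config(segments, family, spec, montage, folds=folds,
                                  reps=reps, seed=seed,
                                  group_by_epoch=group_by_epoch, label="all")
    return out


def ablate_bands(segments: SegmentSet, family: str, spec: ClassifierSpec,
                 bands=None, folds: int = 10, reps: int = 10, seed: int = 0,
                 group_by_epoch: bool = False) -> dict[str, EvalResult]:
    """Evaluate each single frequency band plus the all-band fusion
    (key ``all``), with shared partitions."""
    bandset = bands or default_bands()
    montage = segments.montage
    out: dict[str, EvalResult] = {}
    for bname in bandset.names:
        out[bname] = _evaluate_config(segments, family, spec, montage,
                                      bands=bandset.subset([bname]), folds=folds,
                                      reps=reps, seed=seed,
                                      group_by_epoch=group_by_epoch, label=bname)
    out["all"] = _evaluate_config(segments, family, spec, montage, bands=bandset,
                                  folds=folds, reps=reps, seed=seed,
                                  group_by_epoch=group_by_epoch, label="all")
    return out


def default_feature_configs(montage: Montage) -> list[dict]:
    """The eight named feature configurations of the feature-family
    comparison: whole-head PSD/Hjorth/DE tables, the three 2-channel
    frontal indices, and the choice index on 2 channels (F3/F4) and on
    16 channels (the eight non-reference left/right pairs; TP9/TP10 are
    the offline reference and are excluded)."""
    pairs_16 = [p for p in montage.lr_pairs if p != ("TP9", "TP10")]
    chans_16 = [c for pair in pairs_16 for c in pair]
    return [
        {"name": "psd-all", "family": "psd"},
        {"name": "aw-2ch", "family": "asymmetry", "channels": ["F3", "F4"],
         "indices": ["aw"], "bands": ["alpha"]},
        {"name": "effort-2ch", "family": "asymmetry", "channels": ["F3", "F4"],
         "indices": ["effort"], "bands": ["theta"]},
        {"name": "valence-2ch", "family": "asymmetry", "channels": ["F3", "F4"],
         "indices": ["valence"], "bands": ["alpha", "beta"]},
        {"name": "choice-2ch", "family": "asymmetry", "channels": ["F3", "F4"],
         "indices": ["choice"]},
        {"name": "choice-16ch", "family": "asymmetry", "channels": chans_16,
         "indices": ["choice"]},
        {"name": "hjorth-all", "family": "hjorth"},
        {"name": "de-all", "family": "de"},
    ]


def compare_features(segments: SegmentSet, spec: ClassifierSpec,
                     configs: list[dict] | None = None,
                     montage: Montage | None = None, folds: int = 10,
                     reps: int = 10, seed: int = 0,
                     group_by_epoch: bool = False) -> dict[str, EvalResult]:
    """Evaluate each named feature configuration with shared partitions."""
    montage = montage or segments.montage
    configs = configs if configs is not None else default_feature_configs(montage)
    out: dict[str, EvalResult] = {}
    for cfg in configs:
        out[cfg["name"]] = _evaluate_config(
            segments, cfg["family"], spec, montage,
            channels=cfg.get("channels"), bands=cfg.get("bands"),
            indices=cfg.get("indices"), folds=folds, reps=reps, seed=seed,
            group_by_epoch=group_by_epoch, label=cfg["name"])
    return out


def results_summary(results: dict[str, EvalResult]) -> "pd.DataFrame":  # noqa: F821
    """Flat one-row-per-configuration summary (for CSV export)."""
    import pandas as pd

    rows = [{"name": name, "classifier": r.config.get("classifier"),
             "family": r.config.get("family"),
             "mean_accuracy": r.mean_accuracy,
             "sd_accuracy": float(np.std(r.fold_accuracies))}
            for name, r in results.items()]
    return pd.DataFrame(rows)
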