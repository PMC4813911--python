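"""Training/validation harness, classifier sweep and performance metrics.

The classification design mirrors the published experiment: per feature
matrix, 30 % of segments train and 70 % validate (stratified by class),
repeated 20 times with fresh seeded splits, for each of three classifiers —
a CART decision tree, 1-nearest-neighbour with Euclidean distance, and an
RBF-kernel SVM extended to three classes one-vs-rest (a binary machine per
class, combined by argmax of the decision values; exact ties resolve to the
lowest class index).

Metrics are computed from the pooled 3×3 confusion matrix with exact
rational arithmetic (`fractions.Fraction`) so identities such as RT + ET = 1
and FA_d = 1 − Sp_d hold exactly: recognition/error rate RT/ET; per class d
sensitivity S_d, specificity Sp_d (the recognition rate among samples whose
true class is not d), accuracy A_d (precision), false-alarm FA_d = 1 − Sp_d,
and the likelihood-style quotients PP_d = S_d/(1 − Sp_d) and
NP_d = (1 − S_d)/Sp_d, flagged as undefined (None) where the denominator
vanishes rather than propagated as NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix, QSAConfig, extract_features
from .sessions import ChannelBlock, ConfigError, EEGSession

logger = logging.getLogger(__name__)

CLASSES = (0, 1, 2)
CLASSIFIER_KINDS = ("dt", "knn", "svm")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Train/validation split design: fraction, repeats, seed, stratification."""

    train_fraction: float = 0.30
    repeats: int = 20
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )
        if self.repeats < 1:
            raise ConfigError(f"repeats must be >= 1, got {self.repeats}")


def _split_rng(spec: SplitSpec, repeat_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(repeat_index,))
    )


def split(
    features: FeatureMatrix | tuple[np.ndarray, np.ndarray],
    spec: SplitSpec,
    repeat_index: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One seeded train/validation split; returns (train_idx, val_idx).

    All three classes must be present; under stratification the train
    fraction is rounded per class with a minimum of one training segment per
    class.  Train and validation indices are disjoint and exhaustive.
    """
    labels = (
        features.labels if isinstance(features, FeatureMatrix) else np.asarray(features[1])
    )
    present = set(np.unique(labels).tolist())
    missing = set(CLASSES) - present
    if missing:
        raise ConfigError(
            f"class(es) {sorted(missing)} absent from the feature matrix; "
            "every class must have at least one segment"
        )
    rng = _split_rng(spec, repeat_index)
    if spec.stratified:
        train_parts = []
        for cls in sorted(present):
            idx = np.flatnonzero(labels == cls)
            n_train = max(1, int(round(spec.train_fraction * idx.size)))
            n_train = min(n_train, idx.size - 1)  # keep >=1 validation segment
            train_parts.append(rng.permutation(idx)[:n_train])
        train_idx = np.sort(np.concatenate(train_parts))
    else:
        perm = rng.permutation(labels.size)
        n_train = max(1, int(round(spec.train_fraction * labels.size)))
        train_idx = np.sort(perm[:n_train])
        if set(np.unique(labels[train_idx]).tolist()) != present:
            raise ConfigError(
                f"non-stratified split at repeat {repeat_index} lost a class "
                "from the training set; use stratified=True"
            )
    mask = np.zeros(labels.size, dtype=bool)
    mask[train_idx] = True
    val_idx = np.flatnonzero(~mask)
    return train_idx, val_idx


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier kind plus kind-specific hyperparameters.

    Defaults follow the published setup's stated defaults: CART with Gini
    impurity and unlimited depth; KNN with k = 1 and Euclidean distance; SVM
    with a Gaussian RBF kernel at unit kernel scale and unit regularisation,
    one-vs-rest.
    """

    kind: str
    hyperparams: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        kind = self.kind.lower()
        if kind not in CLASSIFIER_KINDS:
            raise ConfigError(
                f"classifier kind must be one of {CLASSIFIER_KINDS}, got {self.kind!r}"
            )
        object.__setattr__(self, "kind", kind)
        allowed = {
            "dt": {"criterion", "max_depth"},
            "knn": {"n_neighbors", "metric"},
            "svm": {"kernel_scale", "c"},
        }[kind]
        unknown = set(self.hyperparams) - allowed
        if unknown:
            raise ConfigError(
                f"unrecognised hyperparameter(s) {sorted(unknown)} for "
                f"{kind!r}; allowed: {sorted(allowed)}"
            )


def ovr_combine(decision_values: np.ndarray) -> np.ndarray:
    """Fuse one-vs-rest decision values into class predictions.

    Implements the codeword scheme — class 0 ↔ (1 0 0), class 1 ↔ (0 1 0),
    class 2 ↔ (0 0 1) — by argmax of the continuous decision values, which
    also resolves the multi-hot and zero-hot sign patterns; exact ties go to
    the lowest class index.
    """
    values = np.atleast_2d(np.asarray(decision_values, dtype=float))
    if values.shape[1] != len(CLASSES):
        raise ValueError(
            f"expected {len(CLASSES)} decision values per sample, "
            f"got shape {values.shape}"
        )
    return np.argmax(values, axis=1)


class OneVsRestRbfSVM:
    """Three binary RBF-SVMs (class d vs rest) fused by :func:`ovr_combine`.

    ``kernel_scale`` follows the K(u, v) = exp(−‖u−v‖²/s²) convention, i.e.
    gamma = 1/s².
    """

    def __init__(self, kernel_scale: float = 1.0, c: float = 1.0) -> None:
        if kernel_scale <= 0 or c <= 0:
            raise ConfigError("kernel_scale and c must be positive")
        self.kernel_scale = float(kernel_scale)
        self.c = float(c)
        self._machines: list[SVC] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OneVsRestRbfSVM":
        gamma = 1.0 / self.kernel_scale**2
        self._machines = []
        for cls in CLASSES:
            machine = SVC(kernel="rbf", gamma=gamma, C=self.c)
            machine.fit(X, (np.asarray(y) == cls).astype(int))
            self._machines.append(machine)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([m.decision_function(X) for m in self._machines])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return ovr_combine(self.decision_function(X))


def make_classifier(spec: ClassifierSpec, seed: int = 0):
    """Instantiate the estimator for a :class:`ClassifierSpec`."""
    hp = dict(spec.hyperparams)
    if spec.kind == "dt":
        return DecisionTreeClassifier(
            criterion=str(hp.get("criterion", "gini")),
            max_depth=hp.get("max_depth"),
            random_state=seed,
        )
    if spec.kind == "knn":
        return KNeighborsClassifier(
            n_neighbors=int(hp.get("n_neighbors", 1)),
            metric=str(hp.get("metric", "euclidean")),
        )
    return OneVsRestRbfSVM(
        kernel_scale=float(hp.get("kernel_scale", 1.0)),
        c=float(hp.get("c", 1.0)),
    )


# ---------------------------------------------------------------------------
# Train / evaluate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainEvalResult:
    acc_train: float
    acc_val: float
    confusion: np.ndarray  # 3x3 counts, rows = true class, cols = predicted


def train_eval(
    features: FeatureMatrix | tuple[np.ndarray, np.ndarray],
    clf: ClassifierSpec,
    split_indices: tuple[np.ndarray, np.ndarray],
    seed: int = 0,
) -> TrainEvalResult:
    """Fit on the train rows, predict the validation rows.

    Accuracies are the plain fraction of matching labels; the confusion
    matrix counts validation predictions (rows = true, columns = predicted).
    """
    if isinstance(features, FeatureMatrix):
        X, y = features.M, features.labels
    else:
        X, y = np.asarray(features[0], dtype=float), np.asarray(features[1])
    train_idx, val_idx = split_indices
    y_train = y[train_idx]
    if np.unique(y_train).size < 2:
        raise ConfigError(
            "degenerate training set: a single class cannot be trained on"
        )
    model = make_classifier(clf, seed=seed)
    model.fit(X[train_idx], y_train)
    pred_train = np.asarray(model.predict(X[train_idx]))
    pred_val = np.asarray(model.predict(X[val_idx]))
    y_val = y[val_idx]
    cm = _sk_confusion(y_val, pred_val, labels=list(CLASSES))
    return TrainEvalResult(
        acc_train=float(np.mean(pred_train == y_train)),
        acc_val=float(np.mean(pred_val == y_val)),
        confusion=cm,
    )


def repeated_eval(
    features: FeatureMatrix | tuple[np.ndarray, np.ndarray],
    clf: ClassifierSpec,
    split_spec: SplitSpec,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Run all repeats of the split design for one classifier.

    Returns a per-repeat frame (repeat, seed, acc_train, acc_val) and the
    confusion matrix pooled over the repeats' validation predictions.
    """
    rows = []
    pooled = np.zeros((len(CLASSES), len(CLASSES)), dtype=int)
    for rep in range(split_spec.repeats):
        idx = split(features, split_spec, rep)
        seed = derive_seed(split_spec.seed, rep)
        res = train_eval(features, clf, idx, seed=seed)
        pooled += res.confusion
        rows.append(
            {
                "repeat": rep,
                "seed": seed,
                "acc_train": res.acc_train,
                "acc_val": res.acc_val,
            }
        )
    return pd.DataFrame(rows), pooled


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsReport:
    """Exact-rational performance metrics of one 3×3 confusion matrix.

    All values are `Fraction` (convert with ``float()``); per-class tuples
    are indexed by class d ∈ {0, 1, 2}; an entry is None where the defining
    ratio has a zero denominator (flagged undefined, never NaN).
    """

    rt: Fraction
    et: Fraction
    sensitivity: tuple[Fraction | None, ...]
    specificity: tuple[Fraction | None, ...]
    accuracy: tuple[Fraction | None, ...]
    false_alarm: tuple[Fraction | None, ...]
    positive_likelihood: tuple[Fraction | None, ...]
    negative_likelihood: tuple[Fraction | None, ...]

    def to_series(self) -> "pd.Series":
        """Flat (measure → float-or-None) view shaped like a report column."""
        out: dict[str, float | None] = {
            "RT": float(self.rt),
            "ET": float(self.et),
        }
        names = {
            "S": self.sensitivity,
            "Sp": self.specificity,
            "A": self.accuracy,
            "FA": self.false_alarm,
            "PP": self.positive_likelihood,
            "NP": self.negative_likelihood,
        }
        for prefix, values in names.items():
            for d, v in enumerate(values):
                out[f"{prefix}_{d}"] = None if v is None else float(v)
        return pd.Series(out)


def compute_metrics(cm: np.ndarray, weighted_lr: bool = False) -> MetricsReport:
    """Metrics of a confusion matrix (rows = true class d, cols = predicted).

    ``weighted_lr=True`` additionally multiplies PP_d/NP_d by the class
    prevalence odds n_d/(N − n_d) (resp. its reciprocal) — an exploratory
    re-weighting, off by default.
    """
    cm = np.asarray(cm)
    if cm.shape != (len(CLASSES), len(CLASSES)):
        raise ValueError(f"expected a 3x3 confusion matrix, got shape {cm.shape}")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be nonnegative counts")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")

    correct = int(np.trace(cm))
    rt = Fraction(correct, total)
    et = 1 - rt

    sens: list[Fraction | None] = []
    spec: list[Fraction | None] = []
    acc: list[Fraction | None] = []
    fa: list[Fraction | None] = []
    pp: list[Fraction | None] = []
    np_: list[Fraction | None] = []
    for d in range(len(CLASSES)):
        n_d = int(cm[d].sum())
        pred_d = int(cm[:, d].sum())
        n_not_d = total - n_d
        correct_not_d = correct - int(cm[d, d])

        s_d = Fraction(int(cm[d, d]), n_d) if n_d else None
        sp_d = Fraction(correct_not_d, n_not_d) if n_not_d else None
        a_d = Fraction(int(cm[d, d]), pred_d) if pred_d else None
        fa_d = 1 - sp_d if sp_d is not None else None

        odds = Fraction(n_d, n_not_d) if (weighted_lr and n_not_d and n_d) else None
        pp_d: Fraction | None = None
        if s_d is not None and sp_d is not None and sp_d != 1:
            pp_d = s_d / (1 - sp_d)
            if odds is not None:
                pp_d *= odds
        np_d: Fraction | None = None
        if s_d is not None and sp_d is not None and sp_d != 0:
            np_d = (1 - s_d) / sp_d
            if odds is not None:
                np_d /= odds

        sens.append(s_d)
        spec.append(sp_d)
        acc.append(a_d)
        fa.append(fa_d)
        pp.append(pp_d)
        np_.append(np_d)

    return MetricsReport(
        rt=rt,
        et=et,
        sensitivity=tuple(sens),
        specificity=tuple(spec),
        accuracy=tuple(acc),
        false_alarm=tuple(fa),
        positive_likelihood=tuple(pp),
        negative_likelihood=tuple(np_),
    )


# ---------------------------------------------------------------------------
# Sweep
# ---------------------------------------------------------------------------

def derive_seed(master_seed: int, *keys: int) -> int:
    """Deterministic 31-bit child seed from a master seed and integer keys."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SweepResult:
    """Per-cell sweep rows plus the published-table-shaped aggregations."""

    frame: pd.DataFrame

    def by_dt(self) -> pd.DataFrame:
        """max/mean/min validation accuracy per (classifier, dt)."""
        ok = self.frame[self.frame["error"] == ""]
        return (
            ok.groupby(["classifier", "dt"])["acc_val"]
            .agg(["max", "mean", "min"])
            .reset_index()
        )

    def block_best(self) -> pd.DataFrame:
        """Best validation accuracy per (classifier, block)."""
        ok = self.frame[self.frame["error"] == ""]
        return (
            ok.groupby(["classifier", "block"])["acc_val"].max().reset_index()
        )

    def block_mean(self) -> pd.DataFrame:
        """Mean validation accuracy per (classifier, block)."""
        ok = self.frame[self.frame["error"] == ""]
        return (
            ok.groupby(["classifier", "block"])["acc_val"].mean().reset_index()
        )

    def by_session(self) -> pd.DataFrame:
        """Mean validation accuracy per (classifier, session)."""
        ok = self.frame[self.frame["error"] == ""]
        return (
            ok.groupby(["classifier", "session"])["acc_val"].mean().reset_index()
        )


def run_sweep(
    sessions: Sequence[tuple[str, EEGSession]],
    blocks: Sequence[ChannelBlock],
    dts: Sequence[int],
    classifiers: Sequence[ClassifierSpec],
    split_spec: SplitSpec,
    qsa_config: QSAConfig | None = None,
) -> SweepResult:
    """The full grid: sessions × blocks × dts × classifiers × repeats.

    Features are extracted once per (session, block, dt) cell and reused
    across classifiers and repeats.  Every cell's seed derives
    deterministically from the split seed and the cell coordinates; a
    failing cell is recorded in its row's ``error`` column and the sweep
    continues.
    """
    if not (len(sessions) and len(blocks) and len(dts) and len(classifiers)):
        raise ConfigError("sweep grids must be non-empty")
    base = qsa_config if qsa_config is not None else QSAConfig()
    rows = []
    for si, (sid, session) in enumerate(sessions):
        for block in blocks:
            for di, dt in enumerate(dts):
                feats: FeatureMatrix | None = None
                feat_error = ""
                try:
                    cfg = QSAConfig(
                        dt=int(dt),
                        rotation_mode=base.rotation_mode,
                        feature_set=base.feature_set,
                        boundary_policy=base.boundary_policy,
                        pure_q=base.pure_q,
                    )
                    feats = extract_features(session, block, cfg)
                except Exception as exc:  # noqa: BLE001 - recorded per row
                    feat_error = f"{type(exc).__name__}: {exc}"
                for ci, clf in enumerate(classifiers):
                    for rep in range(split_spec.repeats):
                        seed = derive_seed(
                            split_spec.seed, si, block.block_id, int(dt), ci, rep
                        )
                        row = {
                            "session": sid,
                            "block": block.block_id,
                            "dt": int(dt),
                            "classifier": clf.kind,
                            "repeat": rep,
                            "seed": seed,
                            "acc_train": np.nan,
                            "acc_val": np.nan,
                            "error": feat_error,
                        }
                        if feats is not None:
                            try:
                                idx = split(feats, split_spec, rep)
                                res = train_eval(feats, clf, idx, seed=seed)
                                row["acc_train"] = res.acc_train
                                row["acc_val"] = res.acc_val
                            except Exception as exc:  # noqa: BLE001
                                row["error"] = f"{type(exc).__name__}: {exc}"
                        rows.append(row)
    logger.info("sweep finished: %d cells", len(rows))
    return SweepResult(frame=pd.DataFrame(rows))
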