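"""Training and cross-validation of the threat-status networks.

Two label schemes are supported: the five ordinal Red List classes
(LC < NT < VU < EN < CR) and the binary grouping into possibly
threatened (VU, EN, CR) versus not threatened (LC, NT), which trades
class resolution for balance. Two heads are supported: a softmax
classifier and a regression on the ordinal index whose predictions are
rounded to the nearest class. Performance is estimated by stratified
fivefold cross-validation, with each held-out fold doubling as the
early-stopping validation set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .features import FeatureMatrix, apply_normalization, fit_normalization
from .nn import MLP

FIVE_CLASSES = ("LC", "NT", "VU", "EN", "CR")
BINARY_CLASSES = ("not_threatened", "possibly_threatened")
#: LC and NT fold into "not threatened", VU/EN/CR into "possibly threatened".
BINARY_GROUPING = {"LC": 0, "NT": 0, "VU": 1, "EN": 1, "CR": 1}
EXCLUDED_CATEGORIES = ("DD",)  # Data Deficient: treated as unlabeled


@dataclass(frozen=True)
class LabelScheme:
    mode: str = "binary"  # 'five_class' | 'binary'

    def __post_init__(self):
        if self.mode not in ("five_class", "binary"):
            raise ValueError(f"unknown label scheme {self.mode!r}")

    @property
    def classes(self) -> tuple[str, ...]:
        return FIVE_CLASSES if self.mode == "five_class" else BINARY_CLASSES

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def encode_one(self, category: str) -> int:
        if category not in FIVE_CLASSES:
            raise KeyError(category)
        if self.mode == "five_class":
            return FIVE_CLASSES.index(category)
        return BINARY_GROUPING[category]


@dataclass(frozen=True)
class ModelSpec:
    hidden_layers: tuple = (100, 60, 20)
    dropout_rate: float = 0.1
    mode: str = "classifier"  # 'classifier' | 'regression'
    seed: int = 0
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 1000
    patience: int = 100


def encode_labels(labels: pd.DataFrame, scheme: LabelScheme) -> tuple[pd.Series, list[str]]:
    """Map a (species, category) table to integer targets.

    DD species are excluded (returned in the excluded list) — they are
    treated as unlabeled downstream. Unknown category strings raise,
    naming the offending species.
    """
    targets: dict[str, int] = {}
    excluded: list[str] = []
    for sp, cat in zip(labels["species"], labels["category"]):
        if cat in EXCLUDED_CATEGORIES:
            excluded.append(sp)
            continue
        try:
            targets[sp] = scheme.encode_one(cat)
        except KeyError:
            raise ValueError(f"species {sp!r} has unknown Red List category {cat!r}") from None
    return pd.Series(targets, dtype=int, name="target"), excluded


def make_folds(targets: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified k-fold assignment: within each class, shuffled indices are
    dealt cyclically across folds (per-class fold sizes differ by <= 1).
    Classes with fewer than k members are distributed the same way but
    cannot be present in every fold; a warning is emitted."""
    targets = np.asarray(targets)
    n = targets.size
    if n < k:
        raise ValueError(f"need at least k={k} labeled instances, got {n}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    offset = 0
    for cls in np.unique(targets):
        idx = np.flatnonzero(targets == cls)
        if idx.size < k:
            warnings.warn(f"class {cls} has {idx.size} < k={k} members; not stratifiable", stacklevel=2)
        idx = rng.permutation(idx)
        folds[idx] = (np.arange(idx.size) + offset) % k
        offset += idx.size  # stagger classes so small classes don't pile into fold 0
    return folds


@dataclass
class TrainedModel:
    net: MLP
    spec: ModelSpec
    scheme: LabelScheme
    norm_params: dict | None = None
    history: dict = field(default_factory=dict)

    def predict_point(self, features: np.ndarray):
        """Deterministic prediction (dropout off): class-probability rows
        (classifier) or real scores (regression)."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.net.n_in:
            raise ValueError(f"expected {self.net.n_in} features, got {features.shape[1]}")
        if self.spec.mode == "classifier":
            return self.net.predict_proba(features)
        return self.net.predict_score(features)

    def predict_class(self, features: np.ndarray) -> np.ndarray:
        out = self.predict_point(features)
        if self.spec.mode == "classifier":
            # np.argmax takes the first maximum: ties resolve to the
            # less-threatened class (classes are ordered by severity)
            return np.argmax(out, axis=1)
        return scores_to_classes(out, self.scheme.n_classes)

    # -- checkpointing ---------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = {
            "spec": self.spec.__dict__ | {"hidden_layers": list(self.spec.hidden_layers)},
            "scheme": self.scheme.mode,
            "norm_params": self.norm_params,
            "network": self.net.to_dict(),
        }
        (directory / "model.json").write_text(json.dumps(payload))

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        payload = json.loads((Path(directory) / "model.json").read_text())
        spec_d = payload["spec"]
        spec_d["hidden_layers"] = tuple(spec_d["hidden_layers"])
        return cls(
            net=MLP.from_dict(payload["network"]),
            spec=ModelSpec(**spec_d),
            scheme=LabelScheme(payload["scheme"]),
            norm_params=payload["norm_params"],
        )


def scores_to_classes(scores: np.ndarray, n_classes: int) -> np.ndarray:
    """Regression scores -> classes: round half up, clip to [0, K-1]."""
    return np.clip(np.floor(np.asarray(scores) + 0.5).astype(int), 0, n_classes - 1)


def train(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    X_val: np.ndarray,
    y_val: np.ndarray,
    scheme: LabelScheme,
    norm_params: dict | None = None,
) -> TrainedModel:
    """Fit one network on normalized features and encoded targets, with
    early stopping on the supplied validation set."""
    X = np.asarray(X, dtype=float)
    net = MLP(
        n_in=X.shape[1],
        n_out=scheme.n_classes,
        hidden=spec.hidden_layers,
        mode=spec.mode,
        dropout_rate=spec.dropout_rate,
        seed=spec.seed,
    )
    history = net.fit(
        X,
        np.asarray(y),
        np.asarray(X_val, dtype=float),
        np.asarray(y_val),
        learning_rate=spec.learning_rate,
        batch_size=spec.batch_size,
        max_epochs=spec.max_epochs,
        patience=spec.patience,
        seed=spec.seed + 1,
    )
    return TrainedModel(net=net, spec=spec, scheme=scheme, norm_params=norm_params, history=history)


@dataclass
class CVResult:
    fold_ids: np.ndarray
    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: np.ndarray  # pooled over held-out predictions, rows = truth
    classes: tuple[str, ...]
    oof_pred: np.ndarray  # held-out predicted class per instance
    targets: np.ndarray
    models: list[TrainedModel]
    species: list[str] | None = None

    def per_class_accuracy(self) -> np.ndarray:
        row_sums = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.diag(self.confusion) / row_sums
        return np.where(row_sums > 0, acc, np.nan)


def cross_validate(
    features,
    targets: np.ndarray,
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
    species: list[str] | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation.

    In each fold the other k-1 folds train the network and the held-out
    fold serves as the validation set for early stopping, then receives
    predictions — the 80/20 usage of fivefold CV. ``features`` may be a
    :class:`FeatureMatrix` (normalization is then fitted on each fold's
    training rows only) or an already normalized array.
    """
    if isinstance(features, FeatureMatrix):
        raw = features.raw
        columns = features.columns
        if species is None:
            species = features.species
        prenormalized = None
    else:
        raw = np.asarray(features, dtype=float)
        columns = None
        prenormalized = raw

    targets = np.asarray(targets)
    scheme = LabelScheme("binary" if targets.max() <= 1 else "five_class")
    folds = make_folds(targets, k=k, seed=seed)
    n = targets.size
    oof_pred = np.full(n, -1, dtype=int)
    fold_accuracies: list[float] = []
    models: list[TrainedModel] = []
    for f in range(k):
        val = folds == f
        tr = ~val
        if prenormalized is not None:
            X_tr, X_val = prenormalized[tr], prenormalized[val]
            norm_params = None
        else:
            norm_params = fit_normalization(raw[tr], columns)
            X_tr = apply_normalization(raw[tr], norm_params)
            X_val = apply_normalization(raw[val], norm_params)
        fold_spec = ModelSpec(**{**spec.__dict__, "seed": spec.seed + f})
        model = train(X_tr, targets[tr], fold_spec, X_val, targets[val], scheme, norm_params)
        pred = model.predict_class(X_val)
        oof_pred[val] = pred
        fold_accuracies.append(float(np.mean(pred == targets[val])))
        models.append(model)

    conf = confusion_matrix(targets, oof_pred, labels=np.arange(scheme.n_classes))
    fold_sizes = np.bincount(folds, minlength=k)
    mean_accuracy = float(np.average(fold_accuracies, weights=fold_sizes))
    return CVResult(
        fold_ids=folds,
        fold_accuracies=fold_accuracies,
        mean_accuracy=mean_accuracy,
        confusion=conf,
        classes=scheme.classes,
        oof_pred=oof_pred,
        targets=targets,
        models=models,
        species=species,
    )


def per_class_accuracy(cv: CVResult) -> np.ndarray:
    return cv.per_class_accuracy()


def adjacent_misclassification_fraction(confusion: np.ndarray) -> float:
    """Fraction of off-diagonal (misclassified) mass in cells one class away
    from the truth. With ordinal signal, most confusion is adjacent."""
    conf = np.asarray(confusion, dtype=float)
    off = conf.sum() - np.trace(conf)
    if off == 0:
        return float("nan")
    i, j = np.indices(conf.shape)
    return float(conf[np.abs(i - j) == 1].sum() / off)
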