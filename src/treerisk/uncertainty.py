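"""MC-dropout prediction and target-accuracy threshold calibration.

Repeating the forward pass with dropout active turns the network into an
approximate Bayesian predictor: the spread of the replicate outputs
measures the model's uncertainty. The per-species confidence is the mean
softmax probability of the predicted class (classifier) or the fraction
of replicates agreeing with the modal class (regression). Given labeled
predictions, a confidence threshold can be calibrated so that species
predicted with confidence at or above it reach a target accuracy, while
the rest remain unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import apply_normalization
from .model import CVResult, TrainedModel, scores_to_classes


@dataclass
class McPredictions:
    """MC-dropout predictions for a batch of species."""

    mean_probs: np.ndarray  # (n, K); for regression, replicate class frequencies
    predicted_class: np.ndarray  # (n,)
    confidence: np.ndarray  # (n,), in (1/K, 1]
    n_replicates: int
    seed: int
    species: list[str] | None = None

    def to_frame(self, class_names=None) -> pd.DataFrame:
        k = self.mean_probs.shape[1]
        names = class_names or [f"class_{i}" for i in range(k)]
        df = pd.DataFrame(self.mean_probs, columns=[f"prob_{n}" for n in names])
        df.insert(0, "confidence", self.confidence)
        df.insert(0, "predicted_class", [names[c] for c in self.predicted_class])
        if self.species is not None:
            df.insert(0, "species", self.species)
        return df


def mc_predict(
    model: TrainedModel,
    features: np.ndarray,
    n_replicates: int = 100,
    seed: int = 0,
    species: list[str] | None = None,
) -> McPredictions:
    """Run ``n_replicates`` stochastic forward passes with dropout active.

    Classifier: the mean of the replicate softmax vectors is the
    predictive distribution; the prediction is its argmax and the
    confidence its maximum. Regression: each replicate's score is rounded
    to a class; the prediction is the modal class and the confidence the
    modal fraction. Deterministic given ``seed``.
    """
    if model.spec.dropout_rate <= 0.0:
        raise ValueError("MC dropout requires a model trained with dropout_rate > 0")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    rng = np.random.default_rng(seed)
    K = model.scheme.n_classes
    if model.spec.mode == "classifier":
        acc = np.zeros((X.shape[0], K))
        for _ in range(n_replicates):
            acc += model.net.stochastic_forward(X, rng)
        mean_probs = acc / n_replicates
        predicted = np.argmax(mean_probs, axis=1)
        confidence = mean_probs[np.arange(len(predicted)), predicted]
    else:
        counts = np.zeros((X.shape[0], K))
        for _ in range(n_replicates):
            cls = scores_to_classes(model.net.stochastic_forward(X, rng), K)
            counts[np.arange(len(cls)), cls] += 1
        mean_probs = counts / n_replicates
        predicted = np.argmax(mean_probs, axis=1)
        confidence = mean_probs[np.arange(len(predicted)), predicted]
    return McPredictions(
        mean_probs=mean_probs,
        predicted_class=predicted,
        confidence=confidence,
        n_replicates=n_replicates,
        seed=seed,
        species=species,
    )


@dataclass
class ThresholdResult:
    target_accuracy: float
    threshold: float  # NaN when unattainable
    retained_accuracy: float
    n_unclassified: int
    fraction_unclassified: float
    attainable: bool


def find_threshold(confidence: np.ndarray, correct: np.ndarray, target_accuracy: float) -> ThresholdResult:
    """Smallest confidence threshold whose retained set (confidence >= t)
    reaches the target accuracy.

    Candidates are the sorted unique confidence values; if even the most
    confident subset cannot reach the target, ``attainable`` is False.
    """
    confidence = np.asarray(confidence, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if confidence.size == 0:
        raise ValueError("empty evaluation set")
    n = confidence.size
    for t in np.unique(confidence):  # ascending
        retained = confidence >= t
        acc = float(correct[retained].mean())
        if acc >= target_accuracy:
            return ThresholdResult(
                target_accuracy=target_accuracy,
                threshold=float(t),
                retained_accuracy=acc,
                n_unclassified=int(n - retained.sum()),
                fraction_unclassified=float((n - retained.sum()) / n),
                attainable=True,
            )
    return ThresholdResult(
        target_accuracy=target_accuracy,
        threshold=float("nan"),
        retained_accuracy=float(correct[confidence >= confidence.max()].mean()),
        n_unclassified=n,
        fraction_unclassified=1.0,
        attainable=False,
    )


def apply_threshold(predictions: McPredictions, threshold: float):
    """Partition predictions by confidence >= threshold.

    Returns (retained mask, composition) where composition counts the
    predicted classes inside the retained set — used to check that the
    threatened fraction is stable under thresholding.
    """
    retained = predictions.confidence >= threshold
    k = predictions.mean_probs.shape[1]
    composition = np.bincount(predictions.predicted_class[retained], minlength=k)
    return retained, composition


def mc_oof_predictions(cv: CVResult, raw_features: np.ndarray, n_replicates: int = 100, seed: int = 0) -> McPredictions:
    """Pooled held-out MC-dropout predictions across all CV folds.

    Each fold's model predicts its own held-out rows (normalized with
    that fold's training statistics), giving one out-of-fold prediction
    per labeled species — the calibration set for ``find_threshold``.
    """
    n = cv.fold_ids.size
    K = len(cv.classes)
    mean_probs = np.zeros((n, K))
    predicted = np.zeros(n, dtype=int)
    confidence = np.zeros(n)
    for f, model in enumerate(cv.models):
        val = cv.fold_ids == f
        X = raw_features[val]
        if model.norm_params is not None:
            X = apply_normalization(X, model.norm_params)
        mc = mc_predict(model, X, n_replicates=n_replicates, seed=seed + f)
        mean_probs[val] = mc.mean_probs
        predicted[val] = mc.predicted_class
        confidence[val] = mc.confidence
    return McPredictions(
        mean_probs=mean_probs,
        predicted_class=predicted,
        confidence=confidence,
        n_replicates=n_replicates,
        seed=seed,
        species=cv.species,
    )


def calibrate_threshold(
    cv: CVResult, raw_features: np.ndarray, target_accuracy: float, n_replicates: int = 100, seed: int = 0
) -> tuple[ThresholdResult, McPredictions]:
    """Calibrate the target-accuracy threshold on pooled out-of-fold
    MC-dropout predictions."""
    mc = mc_oof_predictions(cv, raw_features, n_replicates=n_replicates, seed=seed)
    result = find_threshold(mc.confidence, mc.predicted_class == cv.targets, target_accuracy)
    return result, mc
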