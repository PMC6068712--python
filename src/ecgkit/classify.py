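"""Classifier training and the balanced / unbalanced evaluation protocols.

Two classifier kinds are supported for every stage: a binary decision tree
(Gini impurity, unlimited depth) and a linear support vector machine with
C = 1.  SVM features are standardised on the training split only; trees are
left unscaled.

Two evaluation protocols:

* **unbalanced** - the pooled dataset is randomly split in half into train
  and test, five times; mean +/- std of accuracy / sensitivity /
  specificity over the five trials is reported.
* **balanced** - the majority class is randomly subsampled to the minority
  size B (5 outer draws); each balanced pool of 2B is then split into B
  training and B testing samples (5 inner splits), yielding 25 results
  which are averaged.

Degenerate splits (a training half containing one class) are re-drawn
rather than failing the whole protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import EcgKitError

__all__ = [
    "LabeledDataset",
    "EvalResult",
    "train",
    "evaluate",
    "protocol_unbalanced",
    "protocol_balanced",
    "model_to_dict",
    "model_from_dict",
]


@dataclass
class LabeledDataset:
    """Feature matrix with binary labels (1 = positive class)."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2 or self.features.shape[0] != self.labels.size:
            raise EcgKitError("features must be N x d with N labels")
        if not np.isfinite(self.features).all():
            raise EcgKitError("dataset contains non-finite feature values")

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class EvalResult:
    """Accuracy / sensitivity / specificity in percent, mean +/- std over trials."""

    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_std: float = 0.0
    sensitivity_std: float = 0.0
    specificity_std: float = 0.0
    trials: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    @classmethod
    def from_trials(cls, trials: list[tuple[float, float, float]]) -> "EvalResult":
        t = np.asarray(trials, dtype=float)
        mean, std = t.mean(axis=0), t.std(axis=0)
        return cls(accuracy=mean[0], sensitivity=mean[1], specificity=mean[2],
                   accuracy_std=std[0], sensitivity_std=std[1], specificity_std=std[2],
                   trials=t)


def train(data: LabeledDataset, kind: str = "bdt", seed: int = 0):
    """Fit a classifier of the given ``kind`` ('bdt' or 'svm') on the dataset."""
    classes = np.unique(data.labels)
    if classes.size < 2:
        raise EcgKitError("training data must contain both classes")
    if kind == "bdt":
        model = DecisionTreeClassifier(criterion="gini", random_state=seed)
    elif kind == "svm":
        model = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="linear", C=1.0, random_state=seed)),
        ])
    else:
        raise EcgKitError(f"unknown classifier kind {kind!r}")
    model.fit(data.features, data.labels)
    return model


def evaluate(pred, truth, positive_class: int = 1) -> EvalResult:
    """Accuracy, sensitivity (TP rate), specificity (TN rate), in percent."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise EcgKitError("prediction and truth must have equal length")
    pos = truth == positive_class
    tp = int(np.sum(pos & (pred == positive_class)))
    fn = int(np.sum(pos & (pred != positive_class)))
    tn = int(np.sum(~pos & (pred != positive_class)))
    fp = int(np.sum(~pos & (pred == positive_class)))
    acc = 100.0 * (tp + tn) / truth.size
    sens = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    spec = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return EvalResult(accuracy=acc, sensitivity=sens, specificity=spec,
                      trials=np.array([[acc, sens, spec]]))


def _split_half(rng: np.random.Generator, labels: np.ndarray, idx: np.ndarray,
                max_redraws: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Random half/half split whose training half contains both classes."""
    for _ in range(max_redraws):
        perm = rng.permutation(idx)
        half = perm.size // 2
        tr, te = perm[:half], perm[half:]
        if np.unique(labels[tr]).size == 2 and np.unique(labels[te]).size == 2:
            return tr, te
    raise EcgKitError("could not draw a non-degenerate split")


def _run_trial(data: LabeledDataset, kind: str, tr, te, seed: int) -> tuple[float, float, float]:
    sub = LabeledDataset(data.features[tr], data.labels[tr], data.feature_names)
    model = train(sub, kind=kind, seed=seed)
    res = evaluate(model.predict(data.features[te]), data.labels[te])
    return res.accuracy, res.sensitivity, res.specificity


def protocol_unbalanced(data: LabeledDataset, kind: str = "bdt",
                        n_trials: int = 5, seed: int = 0) -> EvalResult:
    """Five random half/half splits of the pooled dataset; mean +/- std."""
    if len(data) < 4:
        raise EcgKitError("need at least 4 samples")
    rng = np.random.default_rng(seed)
    idx = np.arange(len(data))
    trials = []
    for t in range(n_trials):
        tr, te = _split_half(rng, data.labels, idx)
        trials.append(_run_trial(data, kind, tr, te, seed + t))
    return EvalResult.from_trials(trials)


def protocol_balanced(data: LabeledDataset, kind: str = "bdt",
                      n_outer: int = 5, n_inner: int = 5, seed: int = 0) -> EvalResult:
    """Subsample the majority class to the minority size, then split; 25 trials."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(data.labels, return_counts=True)
    if classes.size != 2:
        raise EcgKitError("balanced protocol requires exactly two classes")
    minority = classes[np.argmin(counts)]
    majority = classes[1] if minority == classes[0] else classes[0]
    b = int(counts.min())
    if b < 4:
        raise EcgKitError("minority class must hold at least 4 samples")
    min_idx = np.flatnonzero(data.labels == minority)
    maj_idx = np.flatnonzero(data.labels == majority)
    trials = []
    for outer in range(n_outer):
        chosen_maj = rng.choice(maj_idx, size=b, replace=False)
        pool = np.concatenate([min_idx, chosen_maj])
        for inner in range(n_inner):
            tr, te = _split_half(rng, data.labels, pool)
            trials.append(_run_trial(data, kind, tr, te, seed + outer * n_inner + inner))
    return EvalResult.from_trials(trials)


# ---------------------------------------------------------------------------
# portable JSON model serialization (decision tree arrays / SVM weights)

def model_to_dict(model) -> dict:
    """Serialize a fitted classifier to a JSON-compatible dict."""
    if isinstance(model, DecisionTreeClassifier):
        t = model.tree_
        return {
            "kind": "bdt",
            "children_left": t.children_left.tolist(),
            "children_right": t.children_right.tolist(),
            "feature": t.feature.tolist(),
            "threshold": t.threshold.tolist(),
            "leaf_class": [int(model.classes_[int(np.argmax(v))]) for v in t.value],
        }
    if isinstance(model, Pipeline):
        scale, svm = model.named_steps["scale"], model.named_steps["svm"]
        return {
            "kind": "svm",
            "mean": scale.mean_.tolist(),
            "scale": scale.scale_.tolist(),
            "coef": svm.coef_.ravel().tolist(),
            "intercept": float(svm.intercept_[0]),
            "classes": svm.classes_.tolist(),
        }
    raise EcgKitError(f"cannot serialize model of type {type(model).__name__}")


class _PortableModel:
    """Numpy-only predictor reconstructed from :func:`model_to_dict` output."""

    def __init__(self, spec: dict):
        self.spec = spec

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        s = self.spec
        if s["kind"] == "bdt":
            left = np.asarray(s["children_left"])
            right = np.asarray(s["children_right"])
            feat = np.asarray(s["feature"])
            thr = np.asarray(s["threshold"])
            leaf = np.asarray(s["leaf_class"])
            out = np.empty(X.shape[0], dtype=int)
            for i, row in enumerate(X):
                node = 0
                while left[node] != -1:
                    node = left[node] if row[feat[node]] <= thr[node] else right[node]
                out[i] = leaf[node]
            return out
        if s["kind"] == "svm":
            z = (X - np.asarray(s["mean"])) / np.asarray(s["scale"])
            score = z @ np.asarray(s["coef"]) + s["intercept"]
            classes = np.asarray(s["classes"])
            return np.where(score > 0, classes[1], classes[0])
        raise EcgKitError(f"unknown portable model kind {s.get('kind')!r}")


def model_from_dict(spec: dict) -> _PortableModel:
    """Rebuild a predictor from a serialized model dict."""
    return _PortableModel(spec)
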