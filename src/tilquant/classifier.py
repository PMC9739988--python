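"""Multilayer-perceptron cell classification over TUMOR/IMMUNE/STROMA/IGNORE.

A small fully connected neural network is trained on labelled example cells
(feature rows from :mod:`tilquant.features`) and then applied to every
detected cell. Features are z-standardized with statistics computed from the
training rows only. Training is deterministic given the configured seed.

The network is fitted with scikit-learn's MLPClassifier (lbfgs solver) behind
this module's interface; the held-out confusion matrix reported after
training comes from a stratified 80/20 split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "TrainedCellClassifier",
    "TrainingError",
    "train_classifier",
    "classify_cells",
    "evaluate_classifier",
]

DEFAULT_CLASSES = ("TUMOR", "IMMUNE", "STROMA", "IGNORE")


class TrainingError(ValueError):
    """Raised when the training set cannot support a classifier fit."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Configuration of the cell classifier.

    ``hidden_layout`` gives the widths of the hidden layers. The default is a
    single hidden layer of 8 units; :meth:`eight_layer_preset` provides the
    alternative reading of an "eight hidden layers" network. ``max_iterations``
    bounds the optimizer (default 1000).
    """

    hidden_layout: tuple[int, ...] = (8,)
    max_iterations: int = 1000
    tolerance: float = 1e-5
    alpha: float = 1e-4  # L2 penalty
    classes: tuple[str, ...] = DEFAULT_CLASSES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.hidden_layout:
            raise ValueError("hidden_layout must be non-empty")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")

    @classmethod
    def eight_layer_preset(cls, **kwargs) -> "ClassifierConfig":
        """Eight hidden layers of 8 units each."""
        return cls(hidden_layout=(8,) * 8, **kwargs)


@dataclass
class TrainedCellClassifier:
    """A fitted cell classifier with its standardization statistics."""

    config: ClassifierConfig
    feature_names: list[str]
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    model: MLPClassifier
    training_class_counts: dict[str, int]
    holdout_confusion: pd.DataFrame

    def _standardize(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in table.columns]
        if missing:
            raise KeyError(f"feature table is missing columns: {missing}")
        x = table[self.feature_names].to_numpy(dtype=float)
        return (x - self.feature_mean) / self.feature_scale

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Class probabilities, columns in config class order."""
        proba = self.model.predict_proba(self._standardize(table))
        # model.classes_ are integer codes into config.classes, sorted, so
        # columns already follow the configured class order.
        return proba

    def save(self, path: str | Path) -> None:
        """Serialize to a single portable JSON file."""
        payload = {
            "format": "tilquant-cell-classifier-v1",
            "config": {
                "hidden_layout": list(self.config.hidden_layout),
                "max_iterations": self.config.max_iterations,
                "tolerance": self.config.tolerance,
                "alpha": self.config.alpha,
                "classes": list(self.config.classes),
                "seed": self.config.seed,
            },
            "feature_names": self.feature_names,
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "coefs": [w.tolist() for w in self.model.coefs_],
            "intercepts": [b.tolist() for b in self.model.intercepts_],
            "model_classes": self.model.classes_.tolist(),
            "training_class_counts": self.training_class_counts,
            "holdout_confusion": {
                "index": list(self.holdout_confusion.index),
                "columns": list(self.holdout_confusion.columns),
                "values": self.holdout_confusion.to_numpy().tolist(),
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedCellClassifier":
        d = json.loads(Path(path).read_text())
        if d.get("format") != "tilquant-cell-classifier-v1":
            raise ValueError("unrecognized classifier file format")
        cfg = ClassifierConfig(
            hidden_layout=tuple(d["config"]["hidden_layout"]),
            max_iterations=d["config"]["max_iterations"],
            tolerance=d["config"]["tolerance"],
            alpha=d["config"]["alpha"],
            classes=tuple(d["config"]["classes"]),
            seed=d["config"]["seed"],
        )
        model = _make_mlp(cfg)
        coefs = [np.asarray(w, dtype=float) for w in d["coefs"]]
        intercepts = [np.asarray(b, dtype=float) for b in d["intercepts"]]
        n_features = coefs[0].shape[0]
        classes = np.asarray(d["model_classes"])
        # Minimal fit to build the internal structure, then overwrite weights.
        x0 = np.zeros((len(classes), n_features))
        y0 = classes
        model.partial_fit = None  # type: ignore[assignment]
        model = _make_mlp(cfg)
        model.fit(x0, y0)
        model.coefs_ = coefs
        model.intercepts_ = intercepts
        model.classes_ = classes
        conf = pd.DataFrame(
            np.asarray(d["holdout_confusion"]["values"]),
            index=d["holdout_confusion"]["index"],
            columns=d["holdout_confusion"]["columns"],
        )
        return cls(
            config=cfg,
            feature_names=list(d["feature_names"]),
            feature_mean=np.asarray(d["feature_mean"], dtype=float),
            feature_scale=np.asarray(d["feature_scale"], dtype=float),
            model=model,
            training_class_counts=dict(d["training_class_counts"]),
            holdout_confusion=conf,
        )


def _make_mlp(config: ClassifierConfig) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=config.hidden_layout,
        solver="lbfgs",
        alpha=config.alpha,
        max_iter=config.max_iterations,
        tol=config.tolerance,
        random_state=config.seed,
    )


def train_classifier(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray | list,
    config: ClassifierConfig | None = None,
) -> TrainedCellClassifier:
    """Train the cell classifier on labelled feature rows.

    Requires at least 10 examples per class. Feature columns with zero
    variance in the training rows are dropped with a warning. A stratified
    80/20 split (deterministic, keyed on sorted cell ids per class) reserves
    the held-out rows for the reported confusion matrix; the model and the
    z-standardization statistics are fitted on the training rows only.
    """
    config = config or ClassifierConfig()
    y = pd.Series(list(labels), index=table.index, dtype=object)
    unknown = sorted(set(y) - set(config.classes))
    if unknown:
        raise TrainingError(f"labels not in configured class list: {unknown}")
    counts = y.value_counts()
    if len(counts) < 2:
        raise TrainingError(
            f"training requires >= 2 classes, got only {counts.index.tolist()}"
        )
    small = counts[counts < 10]
    if len(small):
        raise TrainingError(
            "classes with fewer than 10 examples: "
            + ", ".join(f"{c} ({n})" for c, n in small.items())
        )

    # Deterministic stratified 80/20 split keyed on cell ids (not row
    # positions): within each class, ids are sorted and the last 20% held
    # out. The deployed weights and the standardization statistics depend on
    # the training rows only — reordering or altering held-out rows cannot
    # change them.
    holdout_ids: list = []
    for cls in config.classes:
        ids = sorted(y.index[y == cls])
        if not ids:
            continue
        n_ho = max(1, int(round(0.2 * len(ids))))
        holdout_ids.extend(ids[-n_ho:])
    train_ids = sorted(set(y.index) - set(holdout_ids))
    holdout_ids = sorted(holdout_ids)

    numeric = table.select_dtypes(include=[np.number])
    variances = numeric.loc[train_ids].var(axis=0, ddof=0)
    dropped = variances[variances == 0].index.tolist()
    if dropped:
        logger.warning("dropping zero-variance feature columns: %s", dropped)
    feature_names = [c for c in numeric.columns if c not in dropped]
    if not feature_names:
        raise TrainingError("no informative feature columns remain")

    x_tr = numeric.loc[train_ids, feature_names].to_numpy(dtype=float)
    mean = x_tr.mean(axis=0)
    scale = x_tr.std(axis=0)
    scale[scale == 0] = 1.0
    codes = {i: config.classes.index(c) for i, c in y.items()}
    y_tr = np.array([codes[i] for i in train_ids])
    model = _make_mlp(config)
    model.fit((x_tr - mean) / scale, y_tr)

    x_ho = numeric.loc[holdout_ids, feature_names].to_numpy(dtype=float)
    y_ho = np.array([codes[i] for i in holdout_ids])
    pred_ho = model.predict((x_ho - mean) / scale)
    k = len(config.classes)
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(y_ho, pred_ho):
        conf[t, p] += 1
    confusion = pd.DataFrame(conf, index=list(config.classes), columns=list(config.classes))
    return TrainedCellClassifier(
        config=config,
        feature_names=feature_names,
        feature_mean=mean,
        feature_scale=scale,
        model=model,
        training_class_counts={c: int(counts.get(c, 0)) for c in config.classes},
        holdout_confusion=confusion,
    )


def classify_cells(
    classifier: TrainedCellClassifier, table: pd.DataFrame
) -> tuple[pd.Series, pd.DataFrame]:
    """Apply a trained classifier to a feature table.

    Returns ``(labels, probabilities)``: predicted class per cell (argmax,
    ties broken by class-list order) and the per-class probability table.
    """
    proba = classifier.predict_proba(table)
    present = [classifier.config.classes[i] for i in classifier.model.classes_]
    prob_df = pd.DataFrame(proba, index=table.index, columns=present)
    # argmax returns the first maximal column, i.e. class-list order.
    labels = prob_df.columns[np.argmax(prob_df.to_numpy(), axis=1)]
    return pd.Series(labels, index=table.index, name="class_label"), prob_df


def evaluate_classifier(
    classifier: TrainedCellClassifier,
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray | list,
) -> dict:
    """Confusion matrix (rows = truth), per-class precision/recall, accuracy."""
    y_true = pd.Series(list(labels), index=table.index, dtype=object)
    y_pred, _ = classify_cells(classifier, table)
    classes = list(classifier.config.classes)
    k = len(classes)
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[classes.index(t), classes.index(p)] += 1
    confusion = pd.DataFrame(conf, index=classes, columns=classes)
    precision = {}
    recall = {}
    for i, c in enumerate(classes):
        col = conf[:, i].sum()
        row = conf[i, :].sum()
        precision[c] = conf[i, i] / col if col else float("nan")
        recall[c] = conf[i, i] / row if row else float("nan")
    total = conf.sum()
    accuracy = conf.trace() / total if total else float("nan")
    return {
        "confusion": confusion,
        "precision": precision,
        "recall": recall,
        "accuracy": float(accuracy),
    }
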