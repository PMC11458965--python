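"""Coral / non-coral classification on depth-invariant index features.

Ground-truth percent-cover rows are binarized (coral vs everything else),
class imbalance is removed by stratified undersampling, and an RBF-kernel
support vector machine is tuned by grid search over (gamma, cost) with
stratified cross-validation. The fitted model carries its own feature
standardization so it can be applied to scenes from other sites without
touching their statistics.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .synthetic import GT_CATEGORIES
from .water_column import DIIStack

NODATA_CLASS = -1  # class-raster value for invalid pixels


@dataclass
class LabeledSamples:
    """Feature matrix + binary labels with site and pixel provenance."""

    X: np.ndarray  # (n, n_features) DII values
    y: np.ndarray  # bool, True = coral
    site: np.ndarray  # str per sample
    rows: np.ndarray
    cols: np.ndarray
    feature_names: list[str]

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "LabeledSamples":
        return LabeledSamples(
            X=self.X[idx],
            y=self.y[idx],
            site=self.site[idx],
            rows=self.rows[idx],
            cols=self.cols[idx],
            feature_names=self.feature_names,
        )

    @staticmethod
    def concat(parts: list["LabeledSamples"]) -> "LabeledSamples":
        names = parts[0].feature_names
        if any(p.feature_names != names for p in parts):
            raise ValueError("feature sets differ between sample collections")
        return LabeledSamples(
            X=np.vstack([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            site=np.concatenate([p.site for p in parts]),
            rows=np.concatenate([p.rows for p in parts]),
            cols=np.concatenate([p.cols for p in parts]),
            feature_names=names,
        )


@dataclass(frozen=True)
class ClassifierSpec:
    """RBF-SVM tuning grid and cross-validation settings."""

    gamma_grid: tuple[float, ...] = tuple(2.0**k for k in range(-7, 4))
    cost_grid: tuple[float, ...] = tuple(2.0**k for k in range(-3, 8))
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.gamma_grid or not self.cost_grid:
            raise ValueError("tuning grids must be non-empty")
        if self.folds < 2:
            raise ValueError("need at least 2 cross-validation folds")


@dataclass
class TrainedClassifier:
    """Fitted RBF-SVM with its standardization constants and provenance."""

    svc: SVC
    scaler: StandardScaler
    gamma: float
    cost: float
    cv_accuracy: float
    feature_names: list[str]
    train_sites: tuple[str, ...]

    def predict_proba_coral(self, X: np.ndarray) -> np.ndarray:
        """Posterior coral probability for raw (unstandardized) features."""
        Xs = self.scaler.transform(X)
        coral_col = list(self.svc.classes_).index(True)
        return self.svc.predict_proba(Xs)[:, coral_col]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump(self, fh)
        return path

    @staticmethod
    def load(path: str | Path) -> "TrainedClassifier":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TrainedClassifier):
            raise TypeError(f"{path} does not contain a TrainedClassifier")
        return model


# ------------------------------------------------------------ ground truth


def binarize_ground_truth(
    table: pd.DataFrame, rule: str = "plurality", threshold: float = 50.0
) -> np.ndarray:
    """Binary coral labels from percent-cover rows.

    ``rule="plurality"``: coral iff Coral's percent is >= every other
    category's (ties labelled coral). ``rule="threshold"``: coral iff
    Coral >= ``threshold`` percent.
    """
    covers = table[list(GT_CATEGORIES)].to_numpy(dtype=float)
    if np.any(covers.sum(axis=1) == 0):
        bad = int(np.flatnonzero(covers.sum(axis=1) == 0)[0])
        raise ValueError(f"ground-truth row {bad} has all-zero percent covers")
    coral = covers[:, GT_CATEGORIES.index("coral")]
    if rule == "plurality":
        return coral >= covers.max(axis=1)
    if rule == "threshold":
        return coral >= threshold
    raise ValueError(f"unknown binarization rule {rule!r}")


def build_labeled_samples(
    table: pd.DataFrame,
    dii: DIIStack,
    site: str | None = None,
    rule: str = "plurality",
    threshold: float = 50.0,
) -> LabeledSamples:
    """Join a ground-truth table with DII features; drop invalid pixels."""
    rows = table["row"].to_numpy(dtype=int)
    cols = table["col"].to_numpy(dtype=int)
    nr, nc = dii.shape
    if np.any((rows < 0) | (rows >= nr) | (cols < 0) | (cols >= nc)):
        raise ValueError("ground-truth positions fall outside the raster")
    y = binarize_ground_truth(table, rule=rule, threshold=threshold)
    X = dii.features(rows, cols)
    ok = np.all(np.isfinite(X), axis=1)
    sites = (
        np.full(len(table), site)
        if site is not None
        else table["site"].to_numpy(dtype=str)
    )
    return LabeledSamples(
        X=X[ok],
        y=y[ok],
        site=sites[ok],
        rows=rows[ok],
        cols=cols[ok],
        feature_names=dii.feature_names(),
    )


def stratified_balanced_sample(
    samples: LabeledSamples, seed: int = 0, n_per_class: int | None = None
) -> LabeledSamples:
    """Equal coral / non-coral counts by undersampling the majority class."""
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(samples.y)
    neg = np.flatnonzero(~samples.y)
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            f"both classes required: {pos.size} coral, {neg.size} non-coral"
        )
    k = min(pos.size, neg.size) if n_per_class is None else n_per_class
    if k > min(pos.size, neg.size):
        raise ValueError(f"cannot draw {k} per class from {pos.size}/{neg.size}")
    keep = np.concatenate(
        [
            pos if pos.size == k else rng.choice(pos, size=k, replace=False),
            neg if neg.size == k else rng.choice(neg, size=k, replace=False),
        ]
    )
    rng.shuffle(keep)
    return samples.subset(keep)


# ----------------------------------------------------------------- training


def effective_folds(y: np.ndarray, requested: int) -> int:
    """Fold count for stratified CV: small evaluation sets (field surveys
    can run to a few dozen points) cap the folds at the minority count."""
    counts = np.bincount(np.asarray(y).astype(int), minlength=2)
    smallest = int(counts[counts > 0].min())
    if smallest < 2:
        raise ValueError(f"minority class has only {smallest} sample(s)")
    return max(2, min(requested, smallest))


def tune_and_train(
    samples: LabeledSamples, spec: ClassifierSpec | None = None
) -> TrainedClassifier:
    """Grid-search (gamma, cost) by stratified CV accuracy, refit on all.

    Ties are broken toward smaller cost, then smaller gamma, so the chosen
    model is the least flexible among the best scorers. Features are
    z-scored with training-set statistics stored on the returned model.
    """
    spec = spec or ClassifierSpec()
    X, y = samples.X, samples.y
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    folds = effective_folds(y, spec.folds)
    if len(y) < 2 * folds:
        raise ValueError(f"{len(y)} samples cannot fill {folds} stratified folds")
    if np.any(np.std(X, axis=0) == 0):
        dead = [samples.feature_names[i] for i in np.flatnonzero(np.std(X, axis=0) == 0)]
        raise ValueError(f"zero-variance features: {dead}")

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    splits = list(skf.split(Xs, y))

    best = (-np.inf, None, None)
    for cost in sorted(spec.cost_grid):
        for gamma in sorted(spec.gamma_grid):
            accs = []
            for tr, te in splits:
                clf = SVC(kernel="rbf", C=cost, gamma=gamma)
                clf.fit(Xs[tr], y[tr])
                accs.append(np.mean(clf.predict(Xs[te]) == y[te]))
            score = float(np.mean(accs))
            if score > best[0]:  # strict: first (smallest cost, gamma) wins ties
                best = (score, cost, gamma)
    cv_acc, cost, gamma = best
    svc = SVC(kernel="rbf", C=cost, gamma=gamma, probability=True, random_state=spec.seed)
    svc.fit(Xs, y)
    return TrainedClassifier(
        svc=svc,
        scaler=scaler,
        gamma=gamma,
        cost=cost,
        cv_accuracy=cv_acc,
        feature_names=samples.feature_names,
        train_sites=tuple(sorted(set(samples.site.tolist()))),
    )


# --------------------------------------------------------------- prediction


def predict_posterior(model: TrainedClassifier, dii: DIIStack) -> np.ndarray:
    """Per-pixel coral posterior probability raster (NaN = invalid)."""
    if dii.feature_names() != model.feature_names:
        raise ValueError(
            f"DII layers {dii.feature_names()} do not match training "
            f"features {model.feature_names}"
        )
    out = np.full(dii.shape, np.nan)
    rr, cc = np.nonzero(dii.valid)
    if rr.size:
        out[rr, cc] = model.predict_proba_coral(dii.features(rr, cc))
    return out


def threshold_class(probability: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Coral (1) iff probability >= threshold; 0 otherwise, -1 nodata."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    prob = np.asarray(probability, dtype=float)
    out = np.where(prob >= threshold, 1, 0).astype(np.int8)
    out[~np.isfinite(prob)] = NODATA_CLASS
    return out
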