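"""Wrapper fitness: feature mask -> cross-validated ELM accuracy.

The selector proposes binary feature masks; the evaluator scores each mask
by training the extreme learning machine on the masked columns under fixed
stratified splits and returning the mean validation accuracy.  Splits and
the ELM's hidden seed are frozen per evaluator so fitness is a
deterministic function of the mask (otherwise the metaheuristic chases
classifier noise), and scores are cached by mask so revisited subsets cost
nothing.

Search-time fitness uses a cheap inner scheme (3-fold by default); the
definitive report for a chosen mask comes from :func:`final_evaluate`,
a repeated stratified 10-fold cross-validation.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data import Dataset
from .elm import elm_predict, elm_train
from .metrics import ConfusionMatrix, accuracy, kappa, precision_recall

__all__ = ["FitnessEvaluator", "final_evaluate", "exhaustive_search"]


class FitnessEvaluator:
    """Scores binary feature masks on one dataset with fixed splits.

    Parameters
    ----------
    scheme : {"kfold", "holdout"}
        Inner validation scheme; 3-fold stratified CV by default.
    elm_L : int or None
        Hidden-layer width; None picks min(100, 2 * n_train).
    elm_seed, split_seed : int
        Freeze the classifier's random feature map and the splits.
    """

    def __init__(self, dataset: Dataset, scheme: str = "kfold", k: int = 3,
                 holdout_fraction: float = 0.3, elm_L: int | None = None,
                 elm_activation: str = "sigmoid", elm_seed: int = 0,
                 split_seed: int = 0):
        if scheme not in ("kfold", "holdout"):
            raise ValueError("scheme must be 'kfold' or 'holdout'")
        self.dataset = dataset
        self.scheme = scheme
        self.k = int(k)
        self.holdout_fraction = float(holdout_fraction)
        self.elm_L = elm_L
        self.elm_activation = elm_activation
        self.elm_seed = int(elm_seed)
        self.split_seed = int(split_seed)
        self.cache: dict[bytes, float] = {}
        self.n_trainings = 0
        self.n_cache_hits = 0
        self._y = dataset.labels
        self._splits = self._make_splits()

    def _make_splits(self) -> list[tuple[np.ndarray, np.ndarray]]:
        y = self.dataset.encoded_labels()
        idx = np.arange(len(y))
        if self.scheme == "holdout":
            tr, te = train_test_split(idx, test_size=self.holdout_fraction,
                                      stratify=y, random_state=self.split_seed)
            return [(tr, te)]
        k = self.k
        smallest = int(np.bincount(y).min())
        if smallest < k:
            warnings.warn(
                f"smallest class has {smallest} members; reducing folds "
                f"from {k} to {smallest}"
            )
            k = smallest
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=self.split_seed)
        return [(tr, te) for tr, te in skf.split(idx, y)]

    # ------------------------------------------------------------------
    def evaluate_mask(self, mask) -> float:
        """Mean validation accuracy of the ELM on the masked columns.

        The all-zero mask scores 0.0 (worst possible) without touching the
        classifier; the escape/rebirth machinery moves wolves off it.
        """
        mask = np.asarray(mask)
        if mask.shape != (self.dataset.n_features,):
            raise ValueError(
                f"mask length {mask.shape} does not match "
                f"n_features = {self.dataset.n_features}"
            )
        mask = mask.astype(bool)
        key = np.packbits(mask).tobytes()
        if key in self.cache:
            self.n_cache_hits += 1
            return self.cache[key]
        if not mask.any():
            self.cache[key] = 0.0
            return 0.0
        X = self.dataset.features[:, mask]
        y = self._y
        accs = []
        for tr, te in self._splits:
            model = elm_train(X[tr], y[tr], L=self.elm_L,
                              activation=self.elm_activation,
                              seed=self.elm_seed)
            self.n_trainings += 1
            pred = elm_predict(model, X[te])
            accs.append(float(np.mean(pred == y[te])))
        score = float(np.mean(accs))
        self.cache[key] = score
        return score

    __call__ = evaluate_mask


def exhaustive_search(evaluator: FitnessEvaluator, max_features: int = 16
                      ) -> tuple[np.ndarray, float]:
    """Enumerate every nonempty mask and return the best (mask, fitness).

    Feasible only at tiny dimension (2^p - 1 evaluations); serves as the
    ground-truth optimum that the swarm selectors are measured against.
    """
    p = evaluator.dataset.n_features
    if p > max_features:
        raise ValueError(f"exhaustive search over {p} features is infeasible")
    best_mask, best_fit = None, -np.inf
    for code in range(1, 2**p):
        mask = np.array([(code >> j) & 1 for j in range(p)], dtype=np.int8)
        fit = evaluator.evaluate_mask(mask)
        if fit > best_fit:
            best_mask, best_fit = mask, fit
    return best_mask, float(best_fit)


def final_evaluate(dataset: Dataset, mask, folds: int = 10, repeats: int = 10,
                   seed: int = 0, averaging: str = "weighted") -> dict:
    """Repeated stratified k-fold CV report for one selected mask.

    Each repeat reshuffles the folds with a distinct seed, pools the
    out-of-fold predictions into one confusion matrix and scores accuracy,
    kappa, precision and recall; the report maps each metric to its
    (mean, sd) over repeats.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != (dataset.n_features,):
        raise ValueError("mask length does not match dataset")
    if not mask.any():
        raise ValueError("cannot evaluate an empty feature mask")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y_enc = dataset.encoded_labels()
    smallest = int(np.bincount(y_enc).min())
    if smallest < folds:
        warnings.warn(
            f"smallest class has {smallest} members; reducing folds "
            f"from {folds} to {smallest}"
        )
        folds = smallest
    X = dataset.features[:, mask]
    y = dataset.labels
    classes = dataset.classes

    per_repeat: dict[str, list[float]] = {
        "accuracy": [], "kappa": [], "precision": [], "recall": []
    }
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=(int(seed) + rep) % (2**31))
        y_pred = np.empty(len(y), dtype=object)
        for tr, te in skf.split(X, y_enc):
            model = elm_train(X[tr], y[tr], seed=int(seed))
            y_pred[te] = elm_predict(model, X[te])
        cm = ConfusionMatrix.from_labels(y, y_pred, class_order=classes)
        prec, rec = precision_recall(cm, averaging=averaging)
        per_repeat["accuracy"].append(accuracy(cm))
        per_repeat["kappa"].append(kappa(cm))
        per_repeat["precision"].append(prec)
        per_repeat["recall"].append(rec)

    return {
        name: (float(np.mean(vals)), float(np.std(vals)))
        for name, vals in per_repeat.items()
    }
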