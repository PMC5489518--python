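"""Labeled tabular datasets and selection results.

A :class:`Dataset` is the object every selector, evaluator and classifier in
this package consumes: a dense ``n_samples x n_features`` real matrix, a
vector of opaque class labels, and unique feature names.  Loaders are
provided for the formats gene-expression benchmarks commonly ship in
(CSV/TSV with a header, ARFF with a nominal class attribute, libsvm sparse
text); results round-trip through JSON.

Labels are kept as opaque identifiers; code that needs integer classes maps
them to ``0..K-1`` in order of first appearance (deterministic and
independent of label lexicography).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import arff as _scipy_arff
from sklearn.datasets import dump_svmlight_file, load_svmlight_file

__all__ = [
    "Dataset",
    "SelectionResult",
    "load_dataset",
    "save_dataset",
    "save_result",
    "load_result",
]

_FORMATS = ("csv", "tsv", "arff", "libsvm")


@dataclass
class Dataset:
    """A labeled samples-by-features matrix.

    Parameters
    ----------
    features : ndarray of shape (n_samples, n_features)
        Dense real-valued matrix; must be finite.
    labels : ndarray of shape (n_samples,)
        Opaque class identifiers (strings or integers); at least two
        distinct classes are required for classification use.
    feature_names : list of str
        Unique column names, length ``n_features``.
    name : str
        Free-form dataset name used in logs and reports.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    name: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.feature_names = [str(n) for n in self.feature_names]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, p = self.features.shape
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if len(self.labels) != n:
            raise ValueError("labels length does not match n_samples")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match n_features")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature_names must be unique")
        if not np.all(np.isfinite(self.features)):
            i, j = np.argwhere(~np.isfinite(self.features))[0]
            raise ValueError(
                f"non-finite value at row {i}, column '{self.feature_names[j]}'"
            )
        if len(self.classes) < 2:
            raise ValueError(
                f"labels contain a single class ({self.classes[0]!r}); "
                "classification needs at least two"
            )

    # -- views ------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> list:
        """Distinct class identifiers in order of first appearance."""
        seen: dict = {}
        for lab in self.labels.tolist():
            seen.setdefault(lab, None)
        return list(seen)

    def encoded_labels(self) -> np.ndarray:
        """Labels mapped to ``0..K-1`` in first-appearance order."""
        index = {c: k for k, c in enumerate(self.classes)}
        return np.array([index[lab] for lab in self.labels.tolist()], dtype=int)

    def subset_rows(self, idx: np.ndarray, name: str | None = None) -> "Dataset":
        return Dataset(
            self.features[idx],
            self.labels[idx],
            list(self.feature_names),
            name if name is not None else self.name,
        )


# ---------------------------------------------------------------------------
# loading / saving datasets
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext in ("csv",):
        return "csv"
    if ext in ("tsv", "tab"):
        return "tsv"
    if ext in ("arff",):
        return "arff"
    if ext in ("libsvm", "svm", "svmlight"):
        return "libsvm"
    raise ValueError(
        f"cannot infer format from extension '.{ext}'; pass format= explicitly"
    )


def _check_feature_frame(df: pd.DataFrame, impute_missing: bool) -> np.ndarray:
    """Coerce a feature frame to a finite float matrix or fail loudly."""
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        if impute_missing:
            arr = numeric.to_numpy(dtype=float, na_value=np.nan)
            arr[~np.isfinite(arr)] = np.nan
            col_means = np.nanmean(arr, axis=0)
            col_means = np.where(np.isfinite(col_means), col_means, 0.0)
            ii, jj = np.where(np.isnan(arr))
            arr[ii, jj] = col_means[jj]
            return arr
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric or missing value at row {i}, column '{df.columns[j]}' "
            f"(value {df.iat[i, j]!r}); pass impute_missing=True to mean-impute"
        )
    return numeric.to_numpy(dtype=float)


def _resolve_label_col(columns, label_col) -> str:
    if isinstance(label_col, int):
        if not 0 <= label_col < len(columns):
            raise ValueError(f"label column index {label_col} out of range")
        return columns[label_col]
    if label_col not in columns:
        raise ValueError(
            f"label column {label_col!r} not found; columns are {list(columns)}"
        )
    return label_col


def load_dataset(
    path,
    format: str | None = None,
    label_col="class",
    impute_missing: bool = False,
    name: str | None = None,
) -> Dataset:
    """Load a labeled dataset from CSV/TSV, ARFF or libsvm text.

    ``label_col`` selects the class column by name or 0-based position for
    the header-based formats; libsvm carries its labels intrinsically.
    Missing or non-numeric feature cells are a hard error unless
    ``impute_missing`` requests column-mean imputation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    ds_name = name if name is not None else path.stem

    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t")
        label = _resolve_label_col(list(df.columns), label_col)
        labels = df[label].to_numpy()
        feats = df.drop(columns=[label])
        X = _check_feature_frame(feats, impute_missing)
        return Dataset(X, labels, list(feats.columns), ds_name)

    if fmt == "arff":
        data, meta = _scipy_arff.loadarff(str(path))
        df = pd.DataFrame(data)
        # scipy returns nominal attributes as bytes
        for col in df.columns:
            if df[col].dtype == object:
                df[col] = df[col].str.decode("utf-8")
        label = _resolve_label_col(list(df.columns), label_col)
        labels = df[label].to_numpy()
        feats = df.drop(columns=[label])
        X = _check_feature_frame(feats, impute_missing)
        return Dataset(X, labels, list(feats.columns), ds_name)

    # libsvm sparse text
    X, y = load_svmlight_file(str(path))
    X = np.asarray(X.todense(), dtype=float)
    names = [f"f{j}" for j in range(X.shape[1])]
    labels = y.astype(int) if np.all(y == np.round(y)) else y
    return Dataset(X, labels, names, ds_name)


def save_dataset(dataset: Dataset, path, format: str | None = None,
                 label_col: str = "class") -> None:
    """Write a dataset in any supported format (inverse of :func:`load_dataset`)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("csv", "tsv"):
        df = pd.DataFrame(dataset.features, columns=dataset.feature_names)
        df[label_col] = dataset.labels
        # repr-exact floats so read-back reproduces the matrix bit for bit
        df.to_csv(path, index=False, sep="," if fmt == "csv" else "\t",
                  float_format=lambda v: repr(float(v)))
        return
    if fmt == "arff":
        classes = dataset.classes
        with open(path, "w") as fh:
            fh.write(f"@relation {dataset.name or 'dataset'}\n")
            for fname in dataset.feature_names:
                fh.write(f"@attribute {fname} numeric\n")
            fh.write(f"@attribute {label_col} {{{','.join(str(c) for c in classes)}}}\n")
            fh.write("@data\n")
            for row, lab in zip(dataset.features, dataset.labels.tolist()):
                fh.write(",".join(repr(float(v)) for v in row) + f",{lab}\n")
        return
    if fmt == "libsvm":
        y = dataset.encoded_labels()
        dump_svmlight_file(dataset.features, y, str(path), zero_based=True)
        return
    raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# selection results
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of one feature-selection run.

    ``fitness_history`` is the best-so-far wrapper fitness per iteration and
    is therefore non-decreasing.  ``dimension_pct`` is the selected subset
    size as a percentage of the full feature count.  ``trace`` optionally
    carries per-iteration search diagnostics (weight sums, gamma/sigma,
    memory size) for inspection and invariant checks.
    """

    mask: np.ndarray
    selected_count: int
    dimension_pct: float
    fitness_history: list[float]
    final_metrics: dict
    config_echo: dict
    seed: int
    trace: list | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.int8)
        self.fitness_history = [float(v) for v in self.fitness_history]
        self.validate()

    def validate(self) -> None:
        if self.mask.ndim != 1 or self.mask.size == 0:
            raise ValueError("mask must be a non-empty 1-D binary vector")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        if int(self.mask.sum()) != self.selected_count:
            raise ValueError("selected_count does not match mask")
        expect = 100.0 * self.selected_count / self.mask.size
        if abs(expect - self.dimension_pct) > 1e-12:
            raise ValueError("dimension_pct inconsistent with mask")
        hist = self.fitness_history
        if any(b < a for a, b in zip(hist, hist[1:])):
            raise ValueError("fitness_history must be non-decreasing (best-so-far)")

    @classmethod
    def from_mask(cls, mask, fitness_history, final_metrics, config_echo,
                  seed, trace=None) -> "SelectionResult":
        mask = np.asarray(mask, dtype=np.int8)
        count = int(mask.sum())
        return cls(mask, count, 100.0 * count / mask.size,
                   list(fitness_history), dict(final_metrics),
                   dict(config_echo), int(seed), trace)

    def __eq__(self, other) -> bool:  # array field needs an explicit rule
        if not isinstance(other, SelectionResult):
            return NotImplemented
        return (
            np.array_equal(self.mask, other.mask)
            and self.selected_count == other.selected_count
            and self.dimension_pct == other.dimension_pct
            and self.fitness_history == other.fitness_history
            and self.final_metrics == other.final_metrics
            and self.config_echo == other.config_echo
            and self.seed == other.seed
            and self.trace == other.trace
        )

    def to_dict(self) -> dict:
        d = {
            "mask": self.mask.astype(int).tolist(),
            "selected_count": self.selected_count,
            "dimension_pct": self.dimension_pct,
            "fitness_history": self.fitness_history,
            "final_metrics": self.final_metrics,
            "config_echo": self.config_echo,
            "seed": self.seed,
        }
        if self.trace is not None:
            d["trace"] = self.trace
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        return cls(
            np.asarray(d["mask"], dtype=np.int8),
            int(d["selected_count"]),
            float(d["dimension_pct"]),
            d["fitness_history"],
            d["final_metrics"],
            d["config_echo"],
            int(d["seed"]),
            d.get("trace"),
        )


def save_result(result: SelectionResult, path) -> None:
    """Serialize a validated :class:`SelectionResult` to JSON."""
    result.validate()
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_result(path) -> SelectionResult:
    with open(path) as fh:
        return SelectionResult.from_dict(json.load(fh))
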