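"""Dataset loading, min-max normalization and synthetic data generation.

The datasets this toolchain targets are gene-expression-style tables:
far more features than samples (D >> n), two class labels, continuous
measurements.  The loader accepts delimited text (comma default, tab
auto-detected) with one header row and one label column.  The synthetic
generator plants a small number of class-informative Gaussian mean-shift
features among standard-normal noise features, returning the planted
indices as ground truth so selection quality can be scored directly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class Dataset:
    """An instances-by-features matrix with binary labels.

    ``y`` holds 0/1 codes; ``positive_label`` records which original
    label was mapped to 1.  ``normalized`` flags that every feature
    column has been min-max scaled into [0, 1].
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list
    normalized: bool = False
    positive_label: Optional[str] = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on the number of instances")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must equal the feature count")
        classes = np.unique(self.y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError(f"labels must contain both classes 0 and 1, got {classes}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a planted-feature two-class dataset.

    Defaults mirror the study conditions used throughout the test suite:
    62 instances (a typical small microarray cohort) with 50 features of
    which 5 are informative, the class means on informative features
    separated by 2 within-class standard deviations, balanced classes.
    """

    n_samples: int = 62
    n_features: int = 50
    n_informative: int = 5
    effect: float = 2.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_informative <= self.n_features:
            raise ValueError(
                f"n_informative={self.n_informative} outside "
                f"[1, {self.n_features}]"
            )
        if self.n_samples < 4:
            raise ValueError(f"n_samples must be >= 4, got {self.n_samples}")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie strictly inside (0, 1)")


def _detect_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def load_dataset(path, label_column=None, positive_label=None) -> Dataset:
    """Load a delimited two-class dataset.

    Parameters
    ----------
    path : str or Path
        CSV (default) or TSV (auto-detected from the header line) with
        one header row; every non-label cell must be numeric.
    label_column : str, optional
        Name of the label column; defaults to the last column.
    positive_label : str, optional
        Which label maps to class 1; defaults to the lexicographically
        larger of the two labels.

    Raises
    ------
    ValueError
        On more or fewer than two distinct labels, non-numeric or
        missing cells (named by row and column), or duplicate feature
        names.
    """
    path = Path(path)
    sep = _detect_sep(path)
    with open(path) as fh:
        header = [h.strip() for h in fh.readline().rstrip("\n").split(sep)]
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise ValueError(f"duplicate column names in header: {sorted(dupes)}")

    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if label_column is None:
        label_column = df.columns[-1]
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found")

    labels = df[label_column].astype(str)
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(
            f"expected exactly 2 classes, found {len(classes)}: {classes}"
        )
    if positive_label is None:
        positive_label = classes[1]
    else:
        positive_label = str(positive_label)
        if positive_label not in classes:
            raise ValueError(
                f"positive_label {positive_label!r} not among labels {classes}"
            )

    features = df.drop(columns=[label_column])
    for col in features.columns:
        numeric = pd.to_numeric(features[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-numeric or missing value in column {col!r}, row {row}"
            )
        features[col] = numeric

    y = (labels == positive_label).to_numpy(dtype=np.int8)
    return Dataset(
        X=features.to_numpy(dtype=float),
        y=y,
        feature_names=list(features.columns),
        normalized=False,
        positive_label=positive_label,
    )


def write_dataset(ds: Dataset, path) -> None:
    """Write a dataset as CSV with a trailing 0/1 ``label`` column."""
    df = pd.DataFrame(ds.X, columns=ds.feature_names)
    df["label"] = ds.y.astype(int)
    # repr gives the shortest digit string that round-trips float64 exactly
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def minmax_normalize(ds: Dataset) -> Dataset:
    """Scale every feature column to [0, 1] via (x - min) / (max - min).

    Idempotent: an already-normalized dataset is returned unchanged.
    Constant columns carry no information and are mapped to all-zeros
    with a warning.
    """
    if ds.normalized:
        return ds
    lo = ds.X.min(axis=0)
    hi = ds.X.max(axis=0)
    span = hi - lo
    constant = span == 0
    if constant.any():
        names = [ds.feature_names[i] for i in np.flatnonzero(constant)[:5]]
        warnings.warn(
            f"{int(constant.sum())} constant column(s) mapped to zeros "
            f"(e.g. {names})",
            stacklevel=2,
        )
    safe_span = np.where(constant, 1.0, span)
    x = (ds.X - lo) / safe_span
    x[:, constant] = 0.0
    return replace(ds, X=x, normalized=True)


def generate_synthetic(spec: SyntheticSpec, normalize: bool = True):
    """Generate a planted-feature two-class dataset.

    Noise features are standard normal for all samples; the
    ``n_informative`` planted features have class-conditional means 0
    (class 0) and ``effect`` (class 1) at unit variance.  Labels follow
    ``class_balance``; planted column positions are drawn at random.
    Columns are min-max normalized unless ``normalize=False`` (useful
    for checks on the raw effect-size scale).

    Returns
    -------
    (Dataset, ndarray)
        The dataset and the sorted planted feature indices.
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    n_pos = int(round(n * spec.class_balance))
    n_pos = min(max(n_pos, 2), n - 2)  # both classes large enough to stratify
    y = np.zeros(n, dtype=np.int8)
    y[rng.permutation(n)[:n_pos]] = 1
    x = rng.standard_normal((n, d))
    planted = np.sort(rng.choice(d, size=spec.n_informative, replace=False))
    x[np.ix_(y == 1, planted)] += spec.effect
    names = [f"f{i:05d}" for i in range(d)]
    ds = Dataset(X=x, y=y, feature_names=names, normalized=False,
                 positive_label="1")
    if normalize:
        ds = minmax_normalize(ds)
    return ds, planted


def write_synthetic(ds: Dataset, planted, spec: SyntheticSpec, csv_path) -> None:
    """Write a synthetic dataset as CSV plus a JSON ground-truth sidecar."""
    csv_path = Path(csv_path)
    write_dataset(ds, csv_path)
    sidecar = csv_path.with_suffix(".json")
    payload = {
        "spec": asdict(spec),
        "planted_indices": [int(i) for i in planted],
        "planted_features": [ds.feature_names[i] for i in planted],
    }
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
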