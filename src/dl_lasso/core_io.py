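"""Feature-table data model, CSV I/O, Z-score normalization and stratified splitting.

A radiomics study arrives here as a flat table: one row per lesion, one
numeric column per extracted feature (first-order statistics, texture
matrices, shape descriptors, ...), plus an id column and a binary grade
label (0 = low-grade, 1 = high-grade). Everything downstream operates on
the :class:`FeatureTable` container defined in this module.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "NormParams",
    "read_feature_table",
    "write_feature_table",
    "zscore_fit",
    "zscore_apply",
    "stratified_split",
    "write_run_record",
]

#: standard deviations below this are treated as zero (constant feature)
EPS_SD = 1e-12


@dataclass(frozen=True)
class FeatureTable:
    """An n-samples x k-features numeric table with binary grade labels.

    Parameters
    ----------
    values
        ``(n, k)`` float array; rows are lesions/samples, columns are
        radiomic features. Must be finite.
    feature_names
        ``k`` unique column names.
    sample_ids
        ``n`` unique row identifiers.
    labels
        ``(n,)`` integer array of 0/1 grade labels; both classes must be
        present.
    """

    values: np.ndarray
    feature_names: tuple[str, ...]
    sample_ids: tuple[str, ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, k = values.shape
        # splits may produce small tables; full-cohort minimums are enforced at load
        if n < 2 or k < 2:
            raise ValueError(f"need n >= 2 samples and k >= 2 features, got n={n}, k={k}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[bad[0]]!r}, "
                f"feature {self.feature_names[bad[1]]!r}"
            )
        if len(self.feature_names) != k:
            raise ValueError("feature_names length does not match number of columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")
        _check_unique(self.feature_names, "feature name")
        _check_unique(self.sample_ids, "sample id")
        if labels.shape != (n,):
            raise ValueError("labels must be a length-n vector")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(labels)) < 2:
            raise ValueError("both grade classes must be present")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        """Row subset preserving column order."""
        idx = np.asarray(idx, dtype=int)
        return FeatureTable(
            values=self.values[idx],
            feature_names=self.feature_names,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            labels=self.labels[idx],
        )

    def to_frame(self, label_column: str = "label", id_column: str = "sample_id") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, id_column, list(self.sample_ids))
        df[label_column] = self.labels
        return df


@dataclass(frozen=True)
class NormParams:
    """Per-feature Z-score statistics (mean and sample sd, ddof=1).

    Standard deviations below :data:`EPS_SD` are replaced by 1 so that a
    constant feature maps to all-zeros instead of dividing by zero.
    """

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D vectors of equal length")
        if np.any(self.sd <= 0):
            raise ValueError("sd entries must be strictly positive (guard applied at fit)")

    @property
    def k(self) -> int:
        return self.mean.shape[0]


def _check_unique(names, what: str) -> None:
    seen: set = set()
    for name in names:
        if name in seen:
            raise ValueError(f"duplicate {what}: {name!r}")
        seen.add(name)


def read_feature_table(
    path: str | Path,
    label_column: str,
    id_column: str | None = None,
    label_map: dict | None = None,
) -> FeatureTable:
    """Load a CSV feature table.

    The file must have a header row, one label column, optionally one id
    column (otherwise row numbers are used), and numeric feature columns.
    Non-numeric or missing feature cells raise with the offending
    row/column named; string labels require an explicit ``label_map``
    onto {0, 1}.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    _check_unique(header, "column name")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    if id_column is not None:
        if id_column not in df.columns:
            raise ValueError(f"id column {id_column!r} not found in {path}")
        sample_ids = tuple(df[id_column].astype(str))
        df = df.drop(columns=[id_column])
    else:
        # first non-label column named like an id, else positional ids
        guess = next((c for c in df.columns if c.lower() in ("id", "sample_id", "lesion_id")), None)
        if guess is not None:
            sample_ids = tuple(df[guess].astype(str))
            df = df.drop(columns=[guess])
        else:
            sample_ids = tuple(str(i) for i in range(len(df)))

    raw_labels = df[label_column]
    feat = df.drop(columns=[label_column])
    feature_names = tuple(feat.columns)

    values = np.empty((len(feat), len(feature_names)), dtype=float)
    for j, name in enumerate(feature_names):
        raw = feat[name].to_numpy()
        try:
            # numpy's string->double conversion is correctly rounded, unlike
            # pandas' fast to_numeric path, so round-trips are bit-exact
            values[:, j] = raw.astype(np.float64)
        except ValueError:
            for i, cell in enumerate(raw):
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric or missing value in feature {name!r} at row "
                        f"{i} (sample {sample_ids[i]!r}): {cell!r}"
                    ) from None
            raise

    labels = np.empty(len(raw_labels), dtype=int)
    for i, lab in enumerate(raw_labels):
        if lab == "":
            raise ValueError(f"missing label at row {i} (sample {sample_ids[i]!r})")
        if label_map is not None and lab in label_map:
            labels[i] = int(label_map[lab])
        else:
            try:
                labels[i] = int(float(lab))
            except ValueError as exc:
                raise ValueError(
                    f"label {lab!r} at row {i} is not numeric and not in label_map"
                ) from exc

    if len(values) < 4:
        raise ValueError(f"cohort too small: need at least 4 samples, got {len(values)}")
    return FeatureTable(values=values, feature_names=feature_names, sample_ids=sample_ids, labels=labels)


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    label_column: str = "label",
    id_column: str = "sample_id",
) -> None:
    """Write a feature table as CSV at full float precision (round-trip safe)."""
    df = table.to_frame(label_column=label_column, id_column=id_column)
    df.to_csv(path, index=False, float_format="%.17g")


def zscore_fit(table: FeatureTable) -> NormParams:
    """Fit per-feature mean and sample sd (denominator n-1).

    Constant features (sd below the guard) get sd 1 so they pass through
    as zeros rather than being dropped, keeping feature indices aligned
    with names.
    """
    if table.n < 2:
        raise ValueError("need at least 2 samples to fit normalization")
    mean = table.values.mean(axis=0)
    sd = table.values.std(axis=0, ddof=1)
    sd = np.where(sd < EPS_SD, 1.0, sd)
    return NormParams(mean=mean, sd=sd)


def zscore_apply(table: FeatureTable, params: NormParams) -> FeatureTable:
    """Apply (x - mean) / sd with statistics from ``params`` (typically train-fitted)."""
    if params.k != table.k:
        raise ValueError(f"normalization fitted on k={params.k} features, table has k={table.k}")
    return FeatureTable(
        values=(table.values - params.mean) / params.sd,
        feature_names=table.feature_names,
        sample_ids=table.sample_ids,
        labels=table.labels,
    )


def stratified_split(
    table: FeatureTable, train_fraction: float, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Random class-stratified split into train/test.

    The total training size is ``round(train_fraction * n)``, apportioned
    across classes by largest remainder so per-class proportions are as
    close as possible to the target fraction; each class keeps at least
    one sample on both sides. Deterministic given ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    classes, counts = np.unique(table.labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples to split")

    target_total = int(round(train_fraction * table.n))
    quotas = train_fraction * counts
    n_train = np.floor(quotas).astype(int)
    remainders = quotas - n_train
    short = target_total - int(n_train.sum())
    # hand leftover seats to the largest remainders, lower class index on ties
    for c in np.lexsort((np.arange(len(classes)), -remainders))[:max(short, 0)]:
        n_train[c] += 1
    n_train = np.clip(n_train, 1, counts - 1)

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c, cls in enumerate(classes):
        members = np.flatnonzero(table.labels == cls)
        perm = rng.permutation(len(members))
        train_idx.extend(members[perm[: n_train[c]]])
        test_idx.extend(members[perm[n_train[c]:]])
    return table.subset(np.sort(train_idx)), table.subset(np.sort(test_idx))


def write_run_record(path: str | Path, **params) -> None:
    """Echo all run parameters (seeds, hyperparameters, file paths) to JSON."""

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, Path):
            return str(obj)
        return str(obj)

    Path(path).write_text(json.dumps(params, indent=2, default=_default) + "\n")
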