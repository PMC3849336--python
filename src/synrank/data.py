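"""Case-control dataset container and delimited-text I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["CaseControlDataset", "read_dataset", "write_dataset"]


@dataclass
class CaseControlDataset:
    """A real-valued feature matrix with a binary outcome.

    Parameters
    ----------
    features : ndarray of shape (n_samples, n_features)
        Real-valued, no missing values.
    outcome : ndarray of shape (n_samples,)
        Binary vector; 0 = control, 1 = case. Both classes must be present.
    feature_names : list of str
        Distinct, non-empty names, one per feature column.
    """

    features: np.ndarray
    outcome: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.outcome = np.asarray(self.outcome)
        if self.features.ndim != 2:
            raise InputError("features must be a 2-D matrix")
        n, d = self.features.shape
        if self.outcome.shape != (n,):
            raise InputError(
                f"outcome length {self.outcome.shape} does not match {n} samples"
            )
        if not np.isfinite(self.features).all():
            bad = np.argwhere(~np.isfinite(self.features))[0]
            raise InputError(
                f"missing/non-finite value in feature column "
                f"{bad[1]} at row {bad[0]}"
            )
        vals = np.unique(self.outcome)
        if not np.isin(vals, [0, 1]).all():
            offending = vals[~np.isin(vals, [0, 1])][0]
            raise InputError(f"outcome must contain only 0/1, found {offending!r}")
        if vals.size < 2:
            raise InputError("outcome contains a single class; both 0 and 1 required")
        self.outcome = self.outcome.astype(np.int64)
        if d < 2:
            raise InputError("at least 2 features are required")
        if not self.feature_names:
            self.feature_names = [f"v{i + 1}" for i in range(d)]
        self.feature_names = [str(s) for s in self.feature_names]
        if len(self.feature_names) != d:
            raise InputError("feature_names length does not match n_features")
        if len(set(self.feature_names)) != d or any(
            not s for s in self.feature_names
        ):
            raise InputError("feature names must be distinct and non-empty")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset_rows(self, idx: np.ndarray) -> "CaseControlDataset":
        """Row-restricted copy (used by cross-validation folds)."""
        return CaseControlDataset(
            self.features[idx], self.outcome[idx], list(self.feature_names)
        )


def _infer_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_dataset(
    path: str | Path,
    outcome_column: str = "outcome",
    drop_columns: Sequence[str] = (),
) -> CaseControlDataset:
    """Read a delimited-text (CSV/TSV with header) case-control dataset.

    Every column other than ``outcome_column`` and ``drop_columns`` is
    treated as a feature; column order is preserved as feature order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path), float_precision="round_trip")
    if outcome_column not in df.columns:
        raise InputError(
            f"outcome column {outcome_column!r} not found in {path.name} "
            f"(columns: {list(df.columns)})"
        )
    for col in drop_columns:
        if col not in df.columns:
            raise InputError(f"drop column {col!r} not found in {path.name}")
    feat_df = df.drop(columns=[outcome_column, *drop_columns])
    if feat_df.shape[1] < 2:
        raise InputError("dataset must have at least 2 feature columns")
    for col in feat_df.columns:
        try:
            feat_df[col] = pd.to_numeric(feat_df[col])
        except (ValueError, TypeError) as exc:
            raise InputError(f"non-numeric value in feature column {col!r}: {exc}")
        if feat_df[col].isna().any():
            row = int(feat_df[col].isna().idxmax())
            raise InputError(f"missing value in feature column {col!r} at row {row}")
    out = df[outcome_column]
    if out.isna().any():
        row = int(out.isna().idxmax())
        raise InputError(f"missing value in outcome column at row {row}")
    bad = ~out.isin([0, 1])
    if bad.any():
        raise InputError(
            f"outcome column contains non-binary value "
            f"{out[bad].iloc[0]!r} (row {int(np.flatnonzero(bad)[0])})"
        )
    return CaseControlDataset(
        feat_df.to_numpy(dtype=float),
        out.to_numpy(dtype=np.int64),
        list(feat_df.columns),
    )


def write_dataset(dataset: CaseControlDataset, path: str | Path) -> None:
    """Write a dataset as delimited text with full-precision floats.

    Uses Python float repr so that a write/read round trip is bit-exact.
    """
    path = Path(path)
    df = pd.DataFrame(dataset.features, columns=dataset.feature_names)
    df["outcome"] = dataset.outcome
    df.to_csv(path, sep=_infer_sep(path), index=False, float_format="%.17g")
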