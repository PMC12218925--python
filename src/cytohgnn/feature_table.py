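"""The N x D feature container shared by every pipeline stage.

A :class:`FeatureTable` couples a real feature matrix with integer class
labels, per-sample identifiers and class names.  Two on-disk forms are
supported: a delimited text table (CSV with header ``sample_id, label,
f0001, ...``) and a lossless binary pair (``.npy`` matrix + JSON sidecar
with ids, labels and the label map).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .exceptions import FormatError, ShapeError

__all__ = ["FeatureTable", "save_feature_table", "load_feature_table"]


@dataclass
class FeatureTable:
    features: np.ndarray
    labels: np.ndarray
    sample_ids: List[str]
    class_names: List[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2 or self.features.shape[0] == 0 or self.features.shape[1] == 0:
            raise ShapeError(f"features must be a non-empty 2-D matrix, got {self.features.shape}")
        if not np.all(np.isfinite(self.features)):
            raise ShapeError("features contain NaN or Inf entries")
        n = self.features.shape[0]
        if self.labels.shape != (n,):
            raise ShapeError(f"labels must have shape ({n},), got {self.labels.shape}")
        if len(self.sample_ids) != n:
            raise ShapeError("sample_ids length must match the number of rows")
        c = len(self.class_names)
        if self.labels.min() < 0 or self.labels.max() >= c:
            raise ShapeError(
                f"labels must lie in [0, {c}); got range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def feature_columns(self) -> List[str]:
        width = max(4, len(str(self.n_features)))
        return [f"f{j + 1:0{width}d}" for j in range(self.n_features)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_columns())
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def save_feature_table(table: FeatureTable, path, fmt: str = "csv") -> None:
    """Write a feature table; ``fmt`` is ``csv`` (text) or ``npy`` (binary).

    The binary form is lossless; the text form preserves values to about
    1e-12 relative precision (17 significant digits).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "sample_ids": list(table.sample_ids),
        "labels": table.labels.tolist(),
        "class_names": list(table.class_names),
        "n_features": table.n_features,
    }
    if fmt == "csv":
        table.to_dataframe().to_csv(path, index=False, float_format="%.17g")
        path.with_suffix(".labels.json").write_text(json.dumps(
            {"class_names": meta["class_names"]}, indent=2))
    elif fmt == "npy":
        np.save(path.with_suffix(".npy"), table.features)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    else:
        raise FormatError(f"unknown feature-table format {fmt!r}")


def load_feature_table(path, fmt: str = "csv") -> FeatureTable:
    """Read a feature table written by :func:`save_feature_table`."""
    path = Path(path)
    if fmt == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas error detail
            raise FormatError(f"cannot parse feature table {path}: {exc}") from exc
        if df.columns[:2].tolist() != ["sample_id", "label"]:
            raise FormatError(
                f"feature table {path} must start with columns sample_id, label"
            )
        feature_cols = [c for c in df.columns[2:]]
        if not feature_cols or not all(c.startswith("f") for c in feature_cols):
            raise FormatError(f"feature table {path} has malformed feature columns")
        features = df[feature_cols].to_numpy(dtype=np.float64)
        if np.isnan(features).any():
            raise FormatError(f"feature table {path} is truncated or contains gaps")
        labels = df["label"].to_numpy(dtype=np.int64)
        sidecar = path.with_suffix(".labels.json")
        if sidecar.exists():
            class_names = json.loads(sidecar.read_text())["class_names"]
        else:
            class_names = [f"class_{c}" for c in range(int(labels.max()) + 1)]
        return FeatureTable(features, labels, df["sample_id"].astype(str).tolist(), class_names)
    if fmt == "npy":
        features = np.load(path.with_suffix(".npy"))
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FormatError(f"missing metadata sidecar for {path}")
        meta = json.loads(sidecar.read_text())
        if features.shape != (len(meta["sample_ids"]), meta["n_features"]):
            raise FormatError(f"metadata of {path} does not match the stored matrix")
        return FeatureTable(
            features,
            np.asarray(meta["labels"], dtype=np.int64),
            [str(s) for s in meta["sample_ids"]],
            [str(c) for c in meta["class_names"]],
        )
    raise FormatError(f"unknown feature-table format {fmt!r}")
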