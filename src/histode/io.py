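"""Feature-matrix container and readers/writers.

Labelled feature matrices travel as delimited text with a header row
``f0,...,f{d-1},label`` (the label column is always last), or as a columnar
binary twin (Parquet) that round-trips bit-exactly.  Labels live inside the
file rather than a sidecar so row alignment survives shuffling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidDatasetError, ParseError

__all__ = ["FeatureMatrix", "read_feature_matrix", "write_feature_matrix"]


@dataclass
class FeatureMatrix:
    """N×d real matrix plus per-sample class labels.

    Parameters
    ----------
    values : (N, d) float array, no missing values.
    labels : length-N class identifiers (strings).
    feature_names : length-d identifiers; defaults to ``f0..f{d-1}``.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidDatasetError("values must be a 2-D array")
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape[0] != self.values.shape[0]:
            raise InvalidDatasetError(
                f"{self.labels.shape[0]} labels for {self.values.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidDatasetError("feature matrix contains non-finite values")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise InvalidDatasetError("feature_names length does not match d")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        """Declared class set: sorted unique labels."""
        return sorted(set(self.labels.tolist()))

    def select(self, bits: np.ndarray) -> "FeatureMatrix":
        """Restrict to the columns where ``bits`` is 1, preserving names."""
        bits = np.asarray(bits)
        if bits.shape[0] != self.d:
            raise InvalidDatasetError(f"mask length {bits.shape[0]} != d={self.d}")
        cols = np.flatnonzero(bits)
        return FeatureMatrix(
            self.values[:, cols],
            self.labels.copy(),
            [self.feature_names[j] for j in cols],
        )

    def subset(self, idx: np.ndarray) -> "FeatureMatrix":
        """Row subset (copy)."""
        idx = np.asarray(idx)
        return FeatureMatrix(
            self.values[idx], self.labels[idx], list(self.feature_names)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        return df


def write_feature_matrix(data: FeatureMatrix, path: str | Path) -> Path:
    """Write a feature matrix as delimited text (``.csv``/``.tsv``) or
    Parquet (``.parquet``).

    Text floats carry 17 significant digits, so a text round-trip is exact to
    well beyond 10 significant digits; the Parquet twin is bit-exact.
    """
    path = Path(path)
    df = data.to_frame()
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        sep = "\t" if path.suffix == ".tsv" else ","
        df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    return path


def read_feature_matrix(path: str | Path, expect_dim: int | None = None) -> FeatureMatrix:
    """Read a feature matrix written by :func:`write_feature_matrix`.

    Raises :class:`ParseError` (with a line number where possible) on a
    missing label column, ragged rows, or non-numeric feature cells, and
    :class:`InvalidDatasetError` when ``expect_dim`` does not match.
    """
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        sep = "\t" if path.suffix == ".tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep)
        except pd.errors.ParserError as exc:  # pandas reports the line number
            raise ParseError(f"{path}: ragged or malformed row ({exc})") from exc
    if df.shape[1] < 2 or df.columns[-1] != "label":
        raise ParseError(f"{path}: header must end with a 'label' column")
    feature_cols = df.columns[:-1].tolist()
    numeric = df[feature_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df[feature_cols].notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0, 0])
        raise ParseError(
            f"{path}: non-numeric feature cell at data line {row + 2}"
        )
    if numeric.isna().to_numpy().any():
        row = int(np.argwhere(numeric.isna().to_numpy())[0, 0])
        raise ParseError(f"{path}: missing feature value at data line {row + 2}")
    values = numeric.to_numpy(dtype=np.float64)
    if expect_dim is not None and values.shape[1] != expect_dim:
        raise InvalidDatasetError(
            f"{path}: {values.shape[1]} feature columns, expected {expect_dim}"
        )
    return FeatureMatrix(values, df["label"].astype(str).to_numpy(), feature_cols)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
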