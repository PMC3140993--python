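"""Feature normalisation.

Every feature is linearly rescaled to [0, 1] using the minimum and
maximum observed on the *training* set; the identical affine map is then
applied to test data, whose values may therefore fall outside [0, 1]
(no clipping). Constant training features map to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ScalingParams", "fit_minmax", "apply_minmax"]


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature training minima/maxima defining the [0, 1] rescaling."""

    feature_names: tuple
    mins: np.ndarray
    maxs: np.ndarray

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of constant (min == max) training features."""
        return self.maxs == self.mins

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mins": [float(v) for v in self.mins],
            "maxs": [float(v) for v in self.maxs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(
            tuple(d["feature_names"]),
            np.asarray(d["mins"], dtype=float),
            np.asarray(d["maxs"], dtype=float),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScalingParams":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _as_matrix(X):
    """Return (values, feature_names or None) for a DataFrame/ndarray."""
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D subjects x features matrix")
    return arr, None


def fit_minmax(train) -> ScalingParams:
    """Learn per-feature min/max from the training matrix only."""
    arr, names = _as_matrix(train)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 training subjects")
    if np.isnan(arr).any():
        raise ValueError("missing values are not supported; complete data required")
    if names is None:
        names = tuple(f"f{i}" for i in range(arr.shape[1]))
    return ScalingParams(names, arr.min(axis=0), arr.max(axis=0))


def apply_minmax(params: ScalingParams, X):
    """Apply ``(x - min) / (max - min)`` using stored training bounds.

    Constant training features map to 0. Test values outside the training
    range are deliberately not clipped. Returns the same container type
    as the input (DataFrame columns are aligned to the params' order).
    """
    if isinstance(X, pd.DataFrame):
        missing = [n for n in params.feature_names if n not in X.columns]
        if missing:
            raise KeyError(f"unknown features (absent from input): {missing}")
        arr = X.loc[:, list(params.feature_names)].to_numpy(dtype=float)
        out = scale_with_bounds(arr, params.mins, params.maxs)
        return pd.DataFrame(out, index=X.index, columns=list(params.feature_names))
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(params.feature_names):
        raise ValueError("matrix width does not match scaling parameters")
    return scale_with_bounds(arr, params.mins, params.maxs)


def scale_with_bounds(arr: np.ndarray, mins: np.ndarray, maxs: np.ndarray) -> np.ndarray:
    """ndarray fast path shared with the cross-validation loops."""
    rng = maxs - mins
    safe = np.where(rng > 0, rng, 1.0)
    out = (arr - mins) / safe
    out[:, rng == 0] = 0.0
    return out
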