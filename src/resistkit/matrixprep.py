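"""Analyte x sample intensity-matrix preprocessing (RPPA-style).

Two display-oriented transforms: per-analyte (row) median centering, and
saturation of values into a fixed range (default [-3, 3]) for heatmap
shading.  The range step clips rather than rescales: in-range values pass
through unchanged and the transform is idempotent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["MedianCenterer", "RangeClipper", "median_center", "scale_to_range", "EmptyRowError"]


class EmptyRowError(ValueError):
    """A row (analyte) has no values to center."""


def _as_frame(matrix):
    if isinstance(matrix, pd.DataFrame):
        return matrix, True
    return pd.DataFrame(np.asarray(matrix, dtype=float)), False


class MedianCenterer(TransformerMixin, BaseEstimator):
    """Subtract each row's (or column's) median so output medians are zero.

    ``axis="rows"`` centers per analyte (the default for antibody panels,
    where absolute intensities differ by orders of magnitude between
    analytes); ``axis="columns"`` centers per sample.
    """

    def __init__(self, axis: str = "rows"):
        self.axis = axis

    def fit(self, X, y=None):
        if self.axis not in ("rows", "columns"):
            raise ValueError(f"axis must be 'rows' or 'columns', got {self.axis!r}")
        return self

    def transform(self, X):
        self.fit(X)
        df, was_frame = _as_frame(X)
        if not np.all(np.isfinite(df.to_numpy(dtype=float))):
            raise ValueError("intensity matrix must be finite")
        if self.axis == "rows":
            for label, row in df.iterrows():
                if row.size == 0:
                    raise EmptyRowError(f"analyte {label!r} has no values")
            if df.shape[1] == 0:
                raise EmptyRowError("matrix has no samples (empty rows)")
            out = df.sub(df.median(axis=1), axis=0)
        else:
            if df.shape[0] == 0:
                raise EmptyRowError("matrix has no analytes (empty columns)")
            out = df.sub(df.median(axis=0), axis=1)
        return out if was_frame else out.to_numpy()


class RangeClipper(TransformerMixin, BaseEstimator):
    """Clip values into [lo, hi] (default [-3, 3]); idempotent."""

    def __init__(self, lo: float = -3.0, hi: float = 3.0):
        self.lo = lo
        self.hi = hi

    def fit(self, X, y=None):
        if not self.hi > self.lo:
            raise ValueError(f"hi ({self.hi}) must exceed lo ({self.lo})")
        return self

    def transform(self, X):
        self.fit(X)
        df, was_frame = _as_frame(X)
        out = df.clip(lower=self.lo, upper=self.hi)
        return out if was_frame else out.to_numpy()


def median_center(matrix, axis: str = "rows"):
    """Median-center a matrix; thin wrapper over :class:`MedianCenterer`."""
    return MedianCenterer(axis=axis).fit_transform(matrix)


def scale_to_range(matrix, lo: float = -3.0, hi: float = 3.0):
    """Clip a matrix into [lo, hi]; thin wrapper over :class:`RangeClipper`."""
    return RangeClipper(lo=lo, hi=hi).fit_transform(matrix)
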