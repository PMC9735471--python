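"""Point-sample containers and CSV I/O.

A :class:`SampleSet` holds planar point observations of a soil contaminant:
sample labels, (x, y) coordinates in meters, and concentrations in mg/kg.
Raw concentrations must be strictly positive (a precondition of the Box-Cox
transform); sets carrying transformed values relax that check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SampleSet", "read_samples", "write_samples"]


class ValidationError(ValueError):
    """Raised when sample data violate a container invariant."""


@dataclass(frozen=True)
class SampleSet:
    """Immutable set of point observations.

    Parameters
    ----------
    ids : sequence of str
        Sample labels, one per point.
    coords : (n, 2) array
        Planar x/y coordinates in meters.
    values : (n,) array
        Observed values. Concentrations (``positive=True``, the default)
        must be strictly positive; transformed values may be any finite real.
    positive : bool
        Whether to enforce strict positivity of ``values``.
    """

    ids: tuple[str, ...]
    coords: np.ndarray
    values: np.ndarray
    positive: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        values = np.asarray(self.values, dtype=float).ravel()
        ids = tuple(str(i) for i in self.ids)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValidationError(f"coords must be (n, 2), got {coords.shape}")
        n = coords.shape[0]
        if not (len(ids) == n == values.size):
            raise ValidationError(
                f"length mismatch: {len(ids)} ids, {n} coords, {values.size} values"
            )
        if n < 2:
            raise ValidationError(f"need at least 2 samples, got {n}")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("non-finite coordinates")
        if not np.all(np.isfinite(values)):
            bad = np.flatnonzero(~np.isfinite(values))
            raise ValidationError(f"non-finite values at rows {bad.tolist()}")
        if self.positive and np.any(values <= 0):
            bad = np.flatnonzero(values <= 0)
            raise ValidationError(
                f"concentrations must be strictly positive; offending rows {bad.tolist()}"
            )
        # duplicate coordinates make kriging systems singular
        _, counts = np.unique(coords.round(9), axis=0, return_counts=True)
        if np.any(counts > 1):
            raise ValidationError("duplicate sample coordinates")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "values", values)
        self.coords.setflags(write=False)
        self.values.setflags(write=False)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def with_values(self, values: np.ndarray, *, positive: bool = False) -> "SampleSet":
        """Copy with the same geometry but new (e.g. transformed) values."""
        return SampleSet(self.ids, self.coords, np.asarray(values, float), positive=positive)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids, "x": self.coords[:, 0], "y": self.coords[:, 1], "value": self.values}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, positive: bool = True) -> "SampleSet":
        missing = {"id", "x", "y", "value"} - set(df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        return cls(
            tuple(df["id"].astype(str)),
            np.column_stack([df["x"].to_numpy(float), df["y"].to_numpy(float)]),
            df["value"].to_numpy(float),
            positive=positive,
        )


def read_samples(path: str | Path, *, positive: bool = True) -> SampleSet:
    """Read a sample CSV with header ``id,x,y,value``.

    Malformed numeric fields are reported with their 1-based file line number.
    """
    df = pd.read_csv(path)
    missing = {"id", "x", "y", "value"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x", "y", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad]  # +1 header, +1 one-based
            raise ValidationError(f"{path}: non-numeric '{col}' at line(s) {lines}")
        df[col] = coerced
    if df[["x", "y", "value"]].isna().any(axis=None):
        lines = [int(i) + 2 for i in df.index[df[["x", "y", "value"]].isna().any(axis=1)]]
        raise ValidationError(f"{path}: missing fields at line(s) {lines}")
    if positive and (df["value"] <= 0).any():
        lines = [int(i) + 2 for i in df.index[df["value"] <= 0]]
        raise ValidationError(f"{path}: non-positive value at line(s) {lines}")
    return SampleSet.from_frame(df, positive=positive)


def write_samples(samples: SampleSet, path: str | Path) -> None:
    """Write the standard ``id,x,y,value`` CSV."""
    samples.to_frame().to_csv(path, index=False, float_format="%.10g")
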