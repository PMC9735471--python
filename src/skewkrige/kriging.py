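"""Ordinary kriging in semivariance form.

Predictions are weighted averages of neighboring observations with weights
solving the ordinary-kriging system: semivariances between neighbors on the
left, semivariances to the target on the right, plus a Lagrange row forcing
the weights to sum to one (unbiasedness).  The kriging variance is
``sum(w_i * gamma(x_i, x0)) + mu``.  The semivariance form (rather than the
covariance form) keeps unbounded variogram models usable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, RegressorMixin

from .samples import SampleSet
from .variogram import (
    FAMILIES,
    VariogramModel,
    empirical_semivariogram,
    fit_best_variogram,
)

__all__ = [
    "OrdinaryKriging",
    "PredictionGrid",
    "GridDefinition",
    "solve_ok_weights",
    "krige_points",
    "krige_grid",
]

_COINCIDENT = 1e-9  # m; targets closer than this to a sample return it directly
_VAR_CLAMP = -1e-10  # round-off guard for tiny negative kriging variances


class KrigingError(RuntimeError):
    pass


def _pairwise_gamma(model: VariogramModel, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    return model(d)


class OrdinaryKriging(RegressorMixin, BaseEstimator):
    """Ordinary-kriging spatial predictor.

    Parameters
    ----------
    variogram : VariogramModel or None
        Fitted semivariogram.  If None, one is fitted on the training data
        at :meth:`fit` (best of ``families`` by residual SS).
    neighborhood : int
        Number of nearest samples used per prediction.  With the study-scale
        sample counts (n <= 64) the default 16 still amounts to a local
        moving window; set ``neighborhood >= n`` for global kriging.
    n_lags, max_lag, families : variogram-fitting settings used when
        ``variogram`` is None.

    Attributes
    ----------
    X_ : (n, 2) array of sample coordinates (meters).
    y_ : (n,) array of sample values.
    variogram_ : VariogramModel actually used for prediction.
    """

    def __init__(
        self,
        variogram: VariogramModel | None = None,
        neighborhood: int = 16,
        n_lags: int = 12,
        max_lag: float | None = None,
        families: tuple[str, ...] = FAMILIES,
    ):
        self.variogram = variogram
        self.neighborhood = neighborhood
        self.n_lags = n_lags
        self.max_lag = max_lag
        self.families = families

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"X must be (n, 2) coordinates, got {X.shape}")
        if X.shape[0] != y.size:
            raise ValueError("X and y length mismatch")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite inputs")
        if self.neighborhood < 1:
            raise ValueError("neighborhood must be >= 1")
        self.X_ = X
        self.y_ = y
        if self.variogram is not None:
            self.variogram_ = self.variogram
        else:
            emp = empirical_semivariogram(X, y, n_lags=self.n_lags, max_lag=self.max_lag)
            self.variogram_ = fit_best_variogram(emp, tuple(self.families))
        self._tree = cKDTree(X)
        self.n_features_in_ = 2
        return self

    # ------------------------------------------------------------------
    def _solve_one(self, x0: np.ndarray):
        """Weights, Lagrange multiplier and kriging variance at one target."""
        m = min(self.neighborhood, self.X_.shape[0])
        dist, idx = self._tree.query(x0, k=m)
        dist = np.atleast_1d(dist)
        idx = np.atleast_1d(idx)
        model = self.variogram_
        if m == 1:
            w = np.ones(1)
            var = 2.0 * float(model(dist)[0]) if dist[0] > 0 else 0.0
            return idx, w, 0.0, var
        pts = self.X_[idx]
        A = np.empty((m + 1, m + 1))
        A[:m, :m] = _pairwise_gamma(model, pts, pts)
        A[:m, m] = 1.0
        A[m, :m] = 1.0
        A[m, m] = 0.0
        b = np.empty(m + 1)
        b[:m] = model(dist)
        b[m] = 1.0
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise KrigingError(
                f"singular kriging system at target {x0.tolist()} "
                f"(neighbors {idx.tolist()}): {exc}"
            ) from exc
        w, mu = sol[:m], sol[m]
        var = float(w @ b[:m] + mu)
        if var < 0.0:
            if var < _VAR_CLAMP:
                raise KrigingError(f"negative kriging variance {var} at {x0.tolist()}")
            var = 0.0
        return idx, w, float(mu), var

    def predict(self, X, return_std: bool = False, return_weights: bool = False):
        """Predict at target coordinates.

        With ``return_std=True`` also returns the kriging standard error.
        Targets coinciding with a sample (within 1 nm) return the sample
        value with zero variance, bypassing the solve.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        preds = np.empty(X.shape[0])
        stds = np.empty(X.shape[0])
        weights: list[tuple[np.ndarray, np.ndarray]] = []
        for i, x0 in enumerate(X):
            d, j = self._tree.query(x0, k=1)
            if d < _COINCIDENT:
                preds[i] = self.y_[j]
                stds[i] = 0.0
                weights.append((np.array([j]), np.ones(1)))
                continue
            idx, w, _, var = self._solve_one(x0)
            preds[i] = w @ self.y_[idx]
            stds[i] = np.sqrt(var)
            weights.append((idx, w))
        out = [preds]
        if return_std:
            out.append(stds)
        if return_weights:
            out.append(weights)
        return preds if len(out) == 1 else tuple(out)


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridDefinition:
    """Regular raster: lower-left corner, square cell size, shape."""

    xll: float
    yll: float
    cellsize: float
    ncols: int
    nrows: int

    def __post_init__(self):
        if self.ncols < 1 or self.nrows < 1 or self.cellsize <= 0:
            raise ValueError("grid must have positive shape and cell size")

    def cell_centers(self) -> np.ndarray:
        """(nrows*ncols, 2) centers, row-major from the north-west corner."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (np.arange(self.nrows)[::-1] + 0.5) * self.cellsize
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass(frozen=True)
class PredictionGrid:
    """Raster of kriged predictions and variances (row-major from NW)."""

    definition: GridDefinition
    predictions: np.ndarray  # (nrows, ncols)
    variances: np.ndarray    # (nrows, ncols)

    def __post_init__(self):
        shape = (self.definition.nrows, self.definition.ncols)
        for name in ("predictions", "variances"):
            arr = np.asarray(getattr(self, name), float).reshape(shape)
            object.__setattr__(self, name, arr)

    def to_ascii(self, path: str | Path, field: str = "predictions") -> None:
        """Write an ESRI ASCII grid (.asc)."""
        d = self.definition
        arr = getattr(self, field)
        with open(path, "w") as fh:
            fh.write(f"ncols {d.ncols}\n")
            fh.write(f"nrows {d.nrows}\n")
            fh.write(f"xllcorner {d.xll:.6f}\n")
            fh.write(f"yllcorner {d.yll:.6f}\n")
            fh.write(f"cellsize {d.cellsize:.6f}\n")
            fh.write("NODATA_value -9999\n")
            for row in arr:
                fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")

    def to_frame(self) -> pd.DataFrame:
        centers = self.definition.cell_centers()
        return pd.DataFrame({
            "x": centers[:, 0],
            "y": centers[:, 1],
            "prediction": self.predictions.ravel(),
            "variance": self.variances.ravel(),
        })


def read_ascii_grid(path: str | Path) -> tuple[GridDefinition, np.ndarray]:
    """Read an ESRI ASCII grid back into a definition and array."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    d = GridDefinition(
        header["xllcorner"], header["yllcorner"], header["cellsize"],
        int(header["ncols"]), int(header["nrows"]),
    )
    return d, np.atleast_2d(arr)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def solve_ok_weights(
    samples: SampleSet | np.ndarray,
    model: VariogramModel,
    x0,
    neighborhood: int = 16,
    values: np.ndarray | None = None,
):
    """Solve the OK system at one target: ``(weights, lagrange, variance)``.

    Weights refer to the ``neighborhood`` nearest samples (indices returned
    by the estimator path are resolved internally; weights are returned in
    neighbor order together with their sample indices).
    """
    if isinstance(samples, SampleSet):
        coords, vals = samples.coords, samples.values
    else:
        coords = np.asarray(samples, float)
        vals = np.zeros(coords.shape[0]) if values is None else np.asarray(values, float)
    ok = OrdinaryKriging(variogram=model, neighborhood=neighborhood).fit(coords, vals)
    idx, w, mu, var = ok._solve_one(np.asarray(x0, float))
    return idx, w, mu, var


def krige_points(
    samples: SampleSet,
    model: VariogramModel,
    targets,
    neighborhood: int = 16,
) -> pd.DataFrame:
    """Krige at arbitrary points; returns x, y, prediction, variance."""
    ok = OrdinaryKriging(variogram=model, neighborhood=neighborhood)
    ok.fit(samples.coords, samples.values)
    targets = np.atleast_2d(np.asarray(targets, float))
    pred, std = ok.predict(targets, return_std=True)
    return pd.DataFrame({
        "x": targets[:, 0], "y": targets[:, 1],
        "prediction": pred, "variance": std**2,
    })


def krige_grid(
    samples: SampleSet,
    model: VariogramModel,
    grid: GridDefinition,
    neighborhood: int = 16,
) -> PredictionGrid:
    """Krige every cell center of a regular grid."""
    ok = OrdinaryKriging(variogram=model, neighborhood=neighborhood)
    ok.fit(samples.coords, samples.values)
    pred, std = ok.predict(grid.cell_centers(), return_std=True)
    shape = (grid.nrows, grid.ncols)
    return PredictionGrid(grid, pred.reshape(shape), (std**2).reshape(shape))
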