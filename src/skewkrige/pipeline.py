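"""End-to-end study workflow: simulate/load -> diagnose -> transform ->
variogram -> krige -> cross-validate -> tables, grids and manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossval import compare_methods
from .kriging import GridDefinition, krige_grid
from .samples import SampleSet, read_samples, write_samples
from .synthetic import SyntheticSiteConfig, simulate_site
from .transforms import METHODS, summary_stats
from .variogram import FAMILIES

__all__ = ["RunConfig", "run_comparison", "diagnostics_table", "variogram_table"]

log = logging.getLogger("skewkrige")

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one comparison run."""

    input_path: str | None = None            # sample CSV; None -> synthetic
    synthetic: dict = field(default_factory=dict)  # SyntheticSiteConfig overrides
    methods: tuple[str, ...] = METHODS
    families: tuple[str, ...] = FAMILIES
    n_lags: int = 12
    max_lag: float | None = None
    neighborhood: int = 16
    grid_cellsize: float = 50.0
    cv_scale: str = "transformed"
    seed: int = 0
    out_dir: str = "out"

    def __post_init__(self):
        if not self.methods:
            raise ValueError("need at least one method")
        if self.cv_scale not in ("transformed", "raw"):
            raise ValueError(f"unknown cv_scale {self.cv_scale!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        d["families"] = list(self.families)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("methods", "families"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def diagnostics_table(values_by_label: dict[str, np.ndarray]) -> pd.DataFrame:
    """Summary-statistics table, one row per labelled value vector."""
    rows = []
    for label, values in values_by_label.items():
        row = {"label": label}
        row.update(summary_stats(values).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def variogram_table(models_by_label: dict[str, object]) -> pd.DataFrame:
    """Fitted-variogram table (family, nugget, sill, proportion, range, r2, RSS)."""
    rows = []
    for label, m in models_by_label.items():
        rows.append({
            "label": label, "family": m.family, "nugget": m.nugget, "sill": m.sill,
            "proportion": m.proportion, "range": m.range_, "r2": m.r2, "rss": m.rss,
            "dependence": m.dependence,
        })
    return pd.DataFrame(rows)


def _load_samples(config: RunConfig) -> tuple[SampleSet, dict]:
    if config.input_path:
        samples = read_samples(config.input_path)
        meta = {"source": "file", "path": str(config.input_path)}
    else:
        site = SyntheticSiteConfig.from_dict({"seed": config.seed, **config.synthetic})
        samples = simulate_site(site)
        meta = {"source": "synthetic", "site_config": site.to_dict()}
    return samples, meta


def _default_grid(samples: SampleSet, cellsize: float) -> GridDefinition:
    xmin, ymin = samples.coords.min(axis=0)
    xmax, ymax = samples.coords.max(axis=0)
    ncols = max(1, int(np.ceil((xmax - xmin) / cellsize)))
    nrows = max(1, int(np.ceil((ymax - ymin) / cellsize)))
    return GridDefinition(float(xmin), float(ymin), float(cellsize), ncols, nrows)


def run_comparison(config: RunConfig) -> dict:
    """Execute the full workflow and write all outputs under ``out_dir``.

    Emits raw + transformed diagnostics tables, the fitted variogram table,
    the ranked cross-validation table, per-method prediction and variance
    grids (back-transformed concentration scale, plus transformed-scale
    diagnostics grids), and a JSON manifest.  On failure, partial outputs
    are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t0 = time.time()
    try:
        samples, source_meta = _load_samples(config)
        log.info("stage=load n=%d source=%s", samples.n, source_meta["source"])

        write_samples(samples, out / "samples.csv")
        written.append(out / "samples.csv")

        raw_diag = diagnostics_table({"raw": samples.values})
        raw_diag.to_csv(out / "diagnostics_raw.csv", index=False, float_format=_FLOAT_FMT)
        written.append(out / "diagnostics_raw.csv")

        table, details = compare_methods(
            samples, tuple(config.methods), tuple(config.families),
            n_lags=config.n_lags, max_lag=config.max_lag,
            neighborhood=config.neighborhood, scale=config.cv_scale,
        )
        log.info("stage=crossval methods=%d best=%s", len(table), table.iloc[0]["method"])

        trans_diag = diagnostics_table(
            {m: d["normalizer"].transform(samples.values) for m, d in details.items()}
        )
        trans_diag.to_csv(out / "diagnostics_transformed.csv", index=False, float_format=_FLOAT_FMT)
        written.append(out / "diagnostics_transformed.csv")

        vtable = variogram_table({m: d["variogram"] for m, d in details.items()})
        vtable.to_csv(out / "variograms.csv", index=False, float_format=_FLOAT_FMT)
        written.append(out / "variograms.csv")

        table.to_csv(out / "crossval.csv", index=False, float_format=_FLOAT_FMT)
        written.append(out / "crossval.csv")

        grid = _default_grid(samples, config.grid_cellsize)
        for method, d in details.items():
            normalizer = d["normalizer"]
            t = normalizer.transform(samples.values)
            tset = samples.with_values(t)
            pg = krige_grid(tset, d["variogram"], grid, neighborhood=config.neighborhood)
            back = normalizer.inverse_transform(pg.predictions.ravel()).reshape(pg.predictions.shape)
            from .kriging import PredictionGrid
            back_grid = PredictionGrid(grid, back, pg.variances)
            for name, g, fld in (
                (f"{method}_prediction.asc", back_grid, "predictions"),
                (f"{method}_variance.asc", pg, "variances"),
                (f"{method}_prediction_transformed.asc", pg, "predictions"),
            ):
                g.to_ascii(out / name, field=fld)
                written.append(out / name)
            log.info("stage=krige method=%s cells=%d", method, grid.ncols * grid.nrows)

        manifest = {
            "tool": "skewkrige",
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "source": source_meta,
            "n_samples": samples.n,
            "outputs": sorted(p.name for p in written),
            "elapsed_s": round(time.time() - t0, 3),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return {
            "samples": samples,
            "diagnostics_raw": raw_diag,
            "diagnostics_transformed": trans_diag,
            "variograms": vtable,
            "crossval": table,
            "details": details,
            "manifest": manifest,
        }
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        (out / "manifest.json").unlink(missing_ok=True)
        if out.exists() and not any(out.iterdir()):
            shutil.rmtree(out, ignore_errors=True)
        raise
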