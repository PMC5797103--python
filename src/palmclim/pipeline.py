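"""End-to-end orchestration of the analysis as a configured, logged run.

A :class:`RunConfig` declares every knob of a run — synthetic-data
switch, permutation/surrogate/bootstrap counts, seeds, predictor sets,
output directory — and :func:`run_all` executes the stages in order
(generate → derive → variability → composites → correlations → models),
writing each stage's outputs plus a manifest with the config, seeds and
per-file checksums so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composites, correlations, io, models, synthetic, variability

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "run_all"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "palmclim_run"
    synthetic: bool = True
    yields_csv: str | None = None  # real-data mode inputs
    indices_dir: str | None = None
    region: str = "synthetic"
    seed: int = 0
    n_perm_series: int = 10000
    n_perm_maps: int = 5000
    n_surrogates: int = 10000
    n_boot: int = 10000
    max_lag: int = 30
    loess_span: float = 0.32
    sd_multiplier: float = 0.7
    model1: list[dict] = field(
        default_factory=lambda: [{"variable": "PRCP", "month": 7, "year_offset": -1}]
    )
    model2_extra: list[dict] = field(
        default_factory=lambda: [
            {"variable": "NINO3", "month": 3, "year_offset": 0},
            {"variable": "NNI", "month": 7, "year_offset": 0},
        ]
    )
    synthetic_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        for k in ("n_perm_series", "n_perm_maps", "n_surrogates", "n_boot"):
            if getattr(self, k) < 100:
                raise ValueError(f"{k} must be >= 100, got {getattr(self, k)}")
        if not self.synthetic and self.yields_csv is None:
            raise ValueError("real-data mode requires yields_csv")

    def smoke(self) -> "RunConfig":
        """A reduced-counts copy for quick end-to-end runs."""
        import dataclasses

        return dataclasses.replace(
            self, n_perm_series=200, n_perm_maps=200, n_surrogates=200, n_boot=200
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _specs(entries: list[dict]) -> list[models.PredictorSpec]:
    return [models.PredictorSpec(**e) for e in entries]


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name and cause."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage {name!r} failed: {err}") from err


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": vars(config).copy(), "seed": config.seed, "files": {}}

    # --- stage 1: inputs -------------------------------------------------
    with _stage("inputs"):
        if config.synthetic:
            syn_cfg = synthetic.SyntheticConfig(
                seed=config.seed, **config.synthetic_overrides
            )
            logger.info("generating synthetic dataset (seed=%d)", config.seed)
            data = synthetic.generate_dataset(syn_cfg)
            yields = data.yields
            indices = data.indices
            io.write_yields(yields, out / "yields.csv", region=config.region)
            for name, series in indices.items():
                io.write_series(series, out / "indices" / f"{name}.csv")
            io.write_field(data.sst, out / "sst.nc")
        else:
            yields = io.read_yields(config.yields_csv, region=config.region)
            indices = {
                p.stem: io.read_series(p)
                for p in sorted(Path(config.indices_dir).glob("*.csv"))
            }
            data = None

    # --- stage 2: yield variability --------------------------------------
    with _stage("variability"):
        record = variability.build_record(
            config.region, yields, span=config.loess_span, k=config.sd_multiplier
        )
        record.to_frame().to_csv(out / "variability.csv", index=False)
        io.write_manifest(
            {"threshold_percent": record.threshold,
             "low_years": record.low_years.tolist(),
             "high_years": record.high_years.tolist()},
            out / "variability.yaml",
        )
        logger.info(
            "classified %d low / %d high years (threshold ±%.2f%%)",
            len(record.low_years), len(record.high_years), record.threshold,
        )

    # --- stage 3: composites ----------------------------------------------
    with _stage("composites"):
        comp_frames = []
        for name in ("PRCP", "TX2M", "TN2M", "SSR"):
            if name not in indices:
                continue
            res = composites.composite_timeseries(
                indices[name], record, n_perm=config.n_perm_series, seed=config.seed
            )
            frame = res.to_frame()
            frame.insert(0, "variable", name)
            comp_frames.append(frame)
        if comp_frames:
            pd.concat(comp_frames).to_csv(out / "composites_timeseries.csv", index=False)
        if data is not None:
            from .derived import preprocess

            sst_anom = preprocess(data.sst, smooth=False)
            maps = composites.composite_maps(
                sst_anom, record, n_perm=config.n_perm_maps, seed=config.seed
            )
            rows = []
            for season, res in maps.items():
                rows.append(
                    {
                        "season": season,
                        "n_low": res.n_low,
                        "n_high": res.n_high,
                        "frac_significant": float(np.mean(res.pvalue < 0.05)),
                        "max_abs_diff": float(np.max(np.abs(res.mean_low - res.mean_high))),
                    }
                )
            pd.DataFrame(rows).to_csv(out / "composites_maps_summary.csv", index=False)

    # --- stage 4: correlations --------------------------------------------
    with _stage("correlations"):
        rate = pd.Series(record.rate, index=pd.Index(record.years, name="year"))
        corr_frames = []
        for name in ("PRCP", "TX2M", "NINO3"):
            if name not in indices:
                continue
            from .derived import preprocess

            series = preprocess(indices[name], smooth=True)
            series.name = name
            res = correlations.lagged_correlation(
                rate, series, max_lag=config.max_lag,
                n_surrogates=config.n_surrogates, seed=config.seed,
            )
            corr_frames.append(res.to_frame())
        if "NINO3" in indices:
            from .derived import preprocess

            enso = preprocess(indices["NINO3"], smooth=True)
            enso.name = "NINO3"
            for name in ("MODOKI", "DMI", "NNI", "ICMI"):
                if name not in indices:
                    continue
                series = preprocess(indices[name], smooth=True)
                series.name = name
                res = correlations.partial_lagged_correlation(
                    rate, series, {"NINO3": enso}, max_lag=config.max_lag,
                    n_surrogates=config.n_surrogates, seed=config.seed,
                )
                corr_frames.append(res.to_frame())
        if corr_frames:
            pd.concat(corr_frames).to_csv(out / "correlations.csv", index=False)

    # --- stage 5: yield models --------------------------------------------
    with _stage("models"):
        spec1 = _specs(config.model1)
        spec2 = spec1 + _specs(config.model2_extra)
        model1 = models.fit(config.region, spec1, yields, indices)
        model2 = models.fit(config.region, spec2, yields, indices)
        acc1 = models.accuracy(model1, n_boot=config.n_boot, seed=config.seed)
        acc2 = models.accuracy(model2, n_boot=config.n_boot, seed=config.seed)
        comparison = models.compare_nested(model1, model2)
        stab = models.stability(config.region, spec2, yields, indices)
        stab.to_csv(out / "stability.csv", index=False)
        years = np.asarray(yields.index, dtype=int)
        new_X = models.resolve_design(spec2, indices, years[-2:])
        fc = models.forecast(model2, new_X)
        fc.to_csv(out / "forecast.csv")
        io.write_json(
            {
                "model1": model1.summary_dict(),
                "model2": model2.summary_dict(),
                "accuracy_model1": vars(acc1),
                "accuracy_model2": vars(acc2),
                "anova": vars(comparison),
            },
            out / "models.json",
        )
        logger.info(
            "model1 R2=%.3f model2 R2=%.3f F=%.2f p=%.2g",
            model1.r_squared, model2.r_squared, comparison.F, comparison.pvalue,
        )

    # --- manifest ----------------------------------------------------------
    with _stage("manifest"):
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name != "manifest.yaml":
                manifest["files"][str(p.relative_to(out))] = io.file_checksum(p)
        io.write_manifest(manifest, out / "manifest.yaml")
    return manifest
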