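"""End-to-end orchestration of the analysis stages with config, logging and
seeds.

Stage graph: ``simulate`` (or an input dataset) feeds ``cluster``,
``importance``, ``fit-pooled``, ``fit-hier`` and ``anova``; ``chart`` depends
on ``fit-pooled`` draws.  Every run writes a manifest listing each output file
with its SHA-256 content hash; identical config + seed reproduce identical
hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import anova as anova_mod
from . import bayes, chart as chart_mod, clustering, pls, synthetic
from .core_data import PanelDataset, SchemaConfig, read_dataset, write_dataset
from .errors import ConfigError, DependencyError

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "cluster", "importance", "fit-pooled", "fit-hier",
              "chart", "anova")


def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - {"seed", "outdir", "dataset", "stages", "generator",
                          "bayes", "importance", "kmeans", "chart", "anova",
                          "log_level"}
    if unknown:
        raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


class PipelineRun:
    """Mutable run state: dataset, draws, outputs written so far."""

    def __init__(self, outdir: str | Path, seed: int = 0):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(seed)
        self.dataset: PanelDataset | None = None
        self.truth: synthetic.GroundTruth | None = None
        self.pooled_draws: bayes.PosteriorDraws | None = None
        self.outputs: list[Path] = []

    def _write_csv(self, df, name: str) -> Path:
        path = self.outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        self.outputs.append(path)
        return path

    def _write_json(self, obj, name: str) -> Path:
        path = self.outdir / name
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=1, default=str)
        self.outputs.append(path)
        return path

    # -- stages ------------------------------------------------------------

    def simulate(self, generator_cfg: dict | None = None) -> None:
        overrides = dict(generator_cfg or {})
        overrides.setdefault("seed", self.seed)
        if "month_slopes" in overrides and overrides["month_slopes"]:
            overrides["month_slopes"] = {
                int(k): float(v) for k, v in overrides["month_slopes"].items()}
        cfg = synthetic.GeneratorConfig(**overrides)
        self.dataset, self.truth = synthetic.generate_dataset(cfg)
        path = self.outdir / "dataset.csv"
        write_dataset(self.dataset, path)
        self.outputs += [path, path.with_name("dataset.panelists.csv"),
                         path.with_name("dataset.replicates.csv")]
        gt = self.outdir / "groundtruth.json"
        self.truth.save(gt)
        self.outputs.append(gt)

    def load(self, path: str | Path, schema: SchemaConfig | None = None) -> None:
        self.dataset = read_dataset(path, schema)

    def _require_dataset(self, stage: str) -> PanelDataset:
        if self.dataset is None:
            raise DependencyError(
                f"stage {stage!r} needs a dataset: run 'simulate' or pass an input path")
        return self.dataset

    def cluster(self, k: int = 3, n_restarts: int = 25) -> None:
        ds = self._require_dataset("cluster")
        pca = clustering.run_pca(ds)
        km = clustering.run_kmeans(ds, k=k, n_restarts=n_restarts, seed=self.seed)
        self._write_csv(pca.scores.reset_index(), "pca_scores.csv")
        self._write_csv(pca.loadings.reset_index(names="variable"), "pca_loadings.csv")
        self._write_csv(km.labels.reset_index(), "clusters.csv")

    def importance(self, attribute: str = "sweetness", n_components: int = 5) -> None:
        ds = self._require_dataset("importance")
        table = pls.screen_attribute(ds, attribute, n_components=n_components)
        self._write_csv(table.to_long_frame(), f"importance_{attribute}.csv")

    def _regression_data(self, with_month: bool) -> bayes.RegressionData:
        ds = self._require_dataset("fit")
        rf = ds.regression_frame("sweetness", "ssc")
        month = rf["month"].to_numpy() if with_month else None
        return bayes.RegressionData(y=rf["y"].to_numpy(), x=rf["x"].to_numpy(),
                                    month=month)

    def fit_pooled(self, **spec_kw) -> None:
        data = self._regression_data(with_month=False)
        spec = bayes.ModelSpec(kind="pooled", seed=self.seed, **spec_kw)
        t0 = time.time()
        self.pooled_draws = bayes.fit_pooled(data, spec)
        summary = bayes.summarize(self.pooled_draws, data, seed=self.seed)
        logger.info("fit-pooled: %.1fs, avg R-hat %.4f",
                    time.time() - t0, summary.avg_rhat or float("nan"))
        self._write_csv(self.pooled_draws.to_long_frame(), "draws_pooled.csv")
        self._write_csv(summary.params, "summary_pooled.csv")
        self._write_csv(summary.predictive, "predictive_pooled.csv")

    def fit_hier(self, **spec_kw) -> None:
        data = self._regression_data(with_month=True)
        spec = bayes.ModelSpec(kind="hierarchical", seed=self.seed, **spec_kw)
        draws = bayes.fit_hierarchical(data, spec)
        summary = bayes.summarize(draws, data, seed=self.seed)
        self._write_csv(draws.to_long_frame(), "draws_hier.csv")
        self._write_csv(summary.params, "summary_hier.csv")
        self._write_csv(summary.predictive, "predictive_hier.csv")

    def chart(self, grid_min: float = 6.0, grid_max: float = 12.0,
              grid_step: float = 0.5, confidence: float = 0.8) -> None:
        ds = self._require_dataset("chart")
        if self.pooled_draws is None:
            draws_file = self.outdir / "draws_pooled.csv"
            if draws_file.exists():
                import pandas as pd
                self.pooled_draws = bayes.PosteriorDraws.from_long_frame(
                    pd.read_csv(draws_file))
            else:
                raise DependencyError(
                    "stage 'chart' needs pooled draws: run 'fit-pooled' first "
                    f"or provide {draws_file}")
        rf = ds.regression_frame("sweetness", "ssc")
        grid = np.arange(grid_min, grid_max + 1e-9, grid_step)
        ch = chart_mod.make_chart(self.pooled_draws, rf["y"].to_numpy(),
                                  rf["x"].to_numpy(), grid=grid)
        self._write_csv(ch.to_frame(), "chart.csv")
        meta = {
            "thresholds": ch.thresholds,
            "threshold_provenance": ch.threshold_provenance,
            "ols_crossings": ch.ols_crossings,
            "ssc_for_confidence": {
                name: chart_mod.threshold_ssc(ch, name, confidence)
                for name in chart_mod.THRESHOLD_ORDER
            },
            "confidence": confidence,
        }
        self._write_json(meta, "chart_meta.json")

    def anova(self, alpha: float = 0.01, ss_type: int = 1) -> None:
        ds = self._require_dataset("anova")
        res = anova_mod.effects_table(ds, alpha=alpha, ss_type=ss_type)
        self._write_csv(res.table, "effects.csv")

    # -- manifest ----------------------------------------------------------

    def write_manifest(self, status: str = "ok") -> Path:
        entries = [
            {"path": str(p.relative_to(self.outdir)), "sha256": _sha256(p)}
            for p in self.outputs if p.exists()
        ]
        path = self.outdir / "manifest.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"status": status, "seed": self.seed, "files": entries},
                      fh, indent=1)
        return path


def run_pipeline(cfg: dict) -> dict:
    """Execute the stages requested in ``cfg`` in dependency order and return
    the manifest.  A stage failure aborts its dependents and still writes a
    partial manifest."""
    seed = int(cfg.get("seed", 0))
    outdir = cfg.get("outdir", "strawsense_out")
    stages = cfg.get("stages") or list(ALL_STAGES)
    bad = set(stages) - set(ALL_STAGES)
    if bad:
        raise ConfigError(f"unknown stages: {sorted(bad)}; valid: {ALL_STAGES}")
    run = PipelineRun(outdir, seed=seed)
    logging.basicConfig(level=cfg.get("log_level", "INFO"))

    try:
        if "simulate" in stages:
            run.simulate(cfg.get("generator"))
        elif cfg.get("dataset"):
            run.load(cfg["dataset"])
        for stage in stages:
            t0 = time.time()
            if stage == "simulate":
                continue
            elif stage == "cluster":
                run.cluster(**(cfg.get("kmeans") or {}))
            elif stage == "importance":
                run.importance(**(cfg.get("importance") or {}))
            elif stage == "fit-pooled":
                run.fit_pooled(**(cfg.get("bayes") or {}))
            elif stage == "fit-hier":
                run.fit_hier(**(cfg.get("bayes") or {}))
            elif stage == "chart":
                run.chart(**(cfg.get("chart") or {}))
            elif stage == "anova":
                run.anova(**(cfg.get("anova") or {}))
            logger.info("stage %s done in %.1fs (seed %d)", stage,
                        time.time() - t0, seed)
    except Exception:
        run.write_manifest(status="failed")
        raise
    manifest_path = run.write_manifest()
    with open(manifest_path, "r", encoding="utf-8") as fh:
        return json.load(fh)
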