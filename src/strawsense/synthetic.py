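"""Synthetic panel-dataset generator with the study's statistical structure.

Emulates a multi-season strawberry sensory/chemistry trial: ~56 genotypes
sampled over 7 seasons, 2-3 harvests per genotype-year during the winter
fruiting months, trained-panel sensory means on a 0-10 scale from 10-12
panelists, pooled chemistry from up to 5 field replicates, and ~71
internal-standard-normalized volatile peak areas on a log-normal scale with
month-dependent presence/absence for a subset of compounds.

The sweetness signal is

    sweetness_i = beta0 + slope(month_i) * SSC_i + sum_k gamma_k * z_ik + eps_i

with z_ik the standardized log(1+abundance) of the k-th sweetness-active
volatile and eps_i heavy-tailed Student-t(nu) noise scaled by sigma, so the
robust scale-mixture regression downstream is the correctly specified
estimator.  A configurable fraction of samples is contaminated with residuals
exceeding 3*sigma by construction.  SSC declines from January to March
(``ssc_month_trend`` < 0), dragging mean sweetness down with it over the
season.  Ratings are clipped to [0, 10] after noise; the clipped fraction is
recorded in the ground truth.

Identical seed => bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import PanelDataset, SampleRecord
from .errors import ConfigError

DEFAULT_YEARS = [2009, 2010, 2015, 2016, 2017, 2018, 2019]
DEFAULT_ATTRIBUTES = [
    "sweetness", "sourness", "strawberry", "green",
    "overripe", "woody", "astringent", "firmness",
]
# panel-mean baselines for the non-sweetness attributes (0-10 scale)
ATTRIBUTE_BASELINES = {
    "sourness": 3.5, "strawberry": 4.3, "green": 2.5, "overripe": 1.5,
    "woody": 1.0, "astringent": 2.0, "firmness": 4.5,
}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults mirror the real trial layout."""

    n_genotypes: int = 56
    years: list[int] = field(default_factory=lambda: list(DEFAULT_YEARS))
    months_per_year: list[int] = field(default_factory=lambda: [1, 2, 3])
    genotypes_per_year: int = 12
    min_harvests: int = 2
    max_harvests: int = 3
    n_panelists: int = 11
    n_replicates: int = 5
    n_volatiles: int = 71
    n_active_volatiles: int = 20
    n_negative_active: int = 2
    n_absent_volatiles: int = 8

    # sweetness model
    beta0: float = 0.8
    beta_ssc: float = 0.45
    month_slope_sd: float = 0.0
    month_slopes: dict[int, float] | None = None  # explicit per-month slopes override
    gamma_scale: float = 0.08
    sigma: float = 0.3
    nu: float = 5.0
    outlier_fraction: float = 0.05

    # SSC model
    ssc_base: float = 8.2
    ssc_month_trend: float = -0.6
    ssc_genotype_sd: float = 0.9
    ssc_noise_sd: float = 0.5

    # generic attribute effect structure (G + M + GxM + noise)
    attr_genotype_sd: float = 0.5
    attr_month_sd: float = 0.3
    attr_interaction_sd: float = 0.15
    attr_noise_sd: float = 0.25

    # observation-level noise
    panelist_bias_sd: float = 0.5
    panelist_noise_sd: float = 0.8
    replicate_ssc_sd: float = 0.15
    replicate_ta_sd: float = 0.05
    replicate_ph_sd: float = 0.05

    # volatile abundance model (log scale)
    vol_base_mean: float = 1.5
    vol_base_sd: float = 1.0
    vol_genotype_sd: float = 0.6
    vol_month_sd: float = 0.4
    vol_noise_sd: float = 0.5

    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_genotypes=self.n_genotypes, genotypes_per_year=self.genotypes_per_year,
            min_harvests=self.min_harvests, max_harvests=self.max_harvests,
            n_panelists=self.n_panelists, n_replicates=self.n_replicates,
            n_volatiles=self.n_volatiles,
        )
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        if not 0 <= self.outlier_fraction < 1:
            raise ConfigError("outlier_fraction must be in [0, 1)")
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if self.nu <= 0:
            raise ConfigError("nu must be > 0")
        if self.n_active_volatiles > self.n_volatiles:
            raise ConfigError(
                f"n_active_volatiles ({self.n_active_volatiles}) exceeds "
                f"n_volatiles ({self.n_volatiles})"
            )
        if self.n_negative_active > self.n_active_volatiles:
            raise ConfigError("n_negative_active exceeds n_active_volatiles")
        if self.genotypes_per_year > self.n_genotypes:
            raise ConfigError("genotypes_per_year exceeds n_genotypes")
        if self.min_harvests > self.max_harvests:
            raise ConfigError("min_harvests exceeds max_harvests")
        if self.max_harvests > len(self.months_per_year):
            raise ConfigError("max_harvests exceeds available months")


@dataclass
class GroundTruth:
    """The realized effects behind one generated dataset (for recovery tests)."""

    month_slopes: dict[int, float]
    active_volatile_coefs: dict[str, float]
    outlier_flags: dict[str, bool]  # sample_id -> contaminated?
    ssc_genotype_effects: dict[str, float]
    attribute_effects: dict[str, dict[str, dict[str, float]]]  # attr -> {genotype|month|interaction -> effects}
    clipped_fraction: float
    config: GeneratorConfig

    def save(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["config"] = asdict(self.config)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=str)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with open(path, "r", encoding="utf-8") as fh:
            payload = json.load(fh)
        cfg_raw = payload.pop("config")
        if cfg_raw.get("month_slopes"):
            cfg_raw["month_slopes"] = {int(k): float(v) for k, v in cfg_raw["month_slopes"].items()}
        cfg = GeneratorConfig(**cfg_raw)
        payload["month_slopes"] = {int(k): float(v) for k, v in payload["month_slopes"].items()}
        return cls(config=cfg, **payload)


def generate_dataset(cfg: GeneratorConfig) -> tuple[PanelDataset, GroundTruth]:
    """Draw one dataset (and its ground truth) from the generative model."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genotypes = [f"G{g:03d}" for g in range(1, cfg.n_genotypes + 1)]
    compounds = [f"compound{k:02d}" for k in range(1, cfg.n_volatiles + 1)]
    months = sorted(cfg.months_per_year)

    # --- realized effects --------------------------------------------------
    if cfg.month_slopes is not None:
        month_slopes = {int(m): float(cfg.month_slopes[m]) for m in months}
    else:
        month_slopes = {
            m: float(cfg.beta_ssc + cfg.month_slope_sd * rng.standard_normal())
            for m in months
        }
    ssc_geno = {g: float(cfg.ssc_genotype_sd * rng.standard_normal()) for g in genotypes}

    active_idx = rng.choice(cfg.n_volatiles, size=cfg.n_active_volatiles, replace=False)
    signs = np.ones(cfg.n_active_volatiles)
    if cfg.n_negative_active:
        signs[:cfg.n_negative_active] = -1.0
    mags = cfg.gamma_scale * (0.5 + rng.random(cfg.n_active_volatiles))
    gamma = {compounds[i]: float(s * m) for i, s, m in zip(active_idx, signs, mags)}

    attr_effects: dict[str, dict[str, dict[str, float]]] = {}
    for a in DEFAULT_ATTRIBUTES:
        if a == "sweetness":
            continue
        attr_effects[a] = {
            "genotype": {g: float(cfg.attr_genotype_sd * rng.standard_normal())
                         for g in genotypes},
            "month": {str(m): float(cfg.attr_month_sd * rng.standard_normal())
                      for m in months},
        }

    vol_base = cfg.vol_base_mean + cfg.vol_base_sd * rng.standard_normal(cfg.n_volatiles)
    vol_geno = {g: cfg.vol_genotype_sd * rng.standard_normal(cfg.n_volatiles)
                for g in genotypes}
    vol_month = {m: cfg.vol_month_sd * rng.standard_normal(cfg.n_volatiles)
                 for m in months}
    absent_idx = set(
        rng.choice(cfg.n_volatiles,
                   size=min(cfg.n_absent_volatiles, cfg.n_volatiles),
                   replace=False).tolist()
    )

    # --- sampling plan: which genotype appears in which year/months --------
    plan: list[tuple[str, int, int]] = []  # (genotype, year, month)
    for year in cfg.years:
        chosen = rng.choice(cfg.n_genotypes, size=cfg.genotypes_per_year, replace=False)
        for gi in chosen:
            n_harv = int(rng.integers(cfg.min_harvests, cfg.max_harvests + 1))
            harv = sorted(rng.choice(months, size=n_harv, replace=False).tolist())
            for m in harv:
                plan.append((genotypes[gi], year, int(m)))
    n = len(plan)

    # --- per-sample chemistry and volatiles --------------------------------
    month_arr = np.array([m for _, _, m in plan])
    ssc = np.array([
        cfg.ssc_base + ssc_geno[g] + cfg.ssc_month_trend * (m - months[0])
        for g, _, m in plan
    ]) + cfg.ssc_noise_sd * rng.standard_normal(n)
    ssc = np.clip(ssc, 0.5, None)

    ta_geno = {g: 0.15 * rng.standard_normal() for g in genotypes}
    ta = np.array([0.85 + ta_geno[g] + 0.03 * (m - months[0]) for g, _, m in plan])
    ta += 0.05 * rng.standard_normal(n)
    ta = np.clip(ta, 0.05, None)
    ph = 3.9 - 0.5 * (ta - ta.mean()) + 0.05 * rng.standard_normal(n)

    log_ab = np.empty((n, cfg.n_volatiles))
    for i, (g, _, m) in enumerate(plan):
        log_ab[i] = vol_base + vol_geno[g] + vol_month[m]
    log_ab += cfg.vol_noise_sd * rng.standard_normal((n, cfg.n_volatiles))
    abundance = np.exp(log_ab)
    detected = np.ones((n, cfg.n_volatiles), dtype=bool)
    for k in absent_idx:
        # detection probability declines over the season for these compounds
        rank = {m: r for r, m in enumerate(months)}
        p = np.clip(0.95 - 0.35 * np.array([rank[m] for m in month_arr]), 0.05, 1.0)
        detected[:, k] = rng.random(n) < p

    # standardized log(1+abundance) for the sweetness-active subset;
    # undetected peaks enter as 0 abundance (below detection)
    obs_ab = np.where(detected, abundance, 0.0)
    z = np.log1p(obs_ab)
    sd = z.std(axis=0)
    sd[sd == 0] = 1.0
    z = (z - z.mean(axis=0)) / sd

    # --- sweetness ----------------------------------------------------------
    slope = np.array([month_slopes[m] for m in month_arr])
    vol_signal = np.zeros(n)
    for comp, g_k in gamma.items():
        vol_signal += g_k * z[:, compounds.index(comp)]
    mean_sw = cfg.beta0 + slope * ssc + vol_signal

    eps = cfg.sigma * rng.standard_t(cfg.nu, size=n) if cfg.sigma > 0 else np.zeros(n)
    outlier = rng.random(n) < cfg.outlier_fraction
    if outlier.any():
        k = int(outlier.sum())
        sgn = rng.choice([-1.0, 1.0], size=k)
        eps[outlier] = sgn * cfg.sigma * (3.0 + rng.exponential(1.0, size=k) + 0.5)
    sweetness_raw = mean_sw + eps
    sweetness = np.clip(sweetness_raw, 0.0, 10.0)
    clipped_fraction = float(np.mean(sweetness != sweetness_raw))

    # --- other attributes ---------------------------------------------------
    attr_values: dict[str, np.ndarray] = {"sweetness": sweetness}
    for a in DEFAULT_ATTRIBUTES:
        if a == "sweetness":
            continue
        eff = attr_effects[a]
        inter = {}
        base = ATTRIBUTE_BASELINES[a]
        vals = np.empty(n)
        for i, (g, _, m) in enumerate(plan):
            key = f"{g}|{m}"
            if key not in inter:
                inter[key] = float(cfg.attr_interaction_sd * rng.standard_normal())
            vals[i] = base + eff["genotype"][g] + eff["month"][str(m)] + inter[key]
        vals += cfg.attr_noise_sd * rng.standard_normal(n)
        attr_values[a] = np.clip(vals, 0.0, 10.0)
        eff["interaction"] = inter

    # sourness tracks TA on top of its G/M structure
    attr_values["sourness"] = np.clip(
        attr_values["sourness"] + 2.0 * (ta - ta.mean()), 0.0, 10.0
    )

    # --- assemble records ---------------------------------------------------
    records: list[SampleRecord] = []
    outlier_flags: dict[str, bool] = {}
    for i, (g, year, m) in enumerate(plan):
        sid = f"{g}-{year}-M{m}"
        records.append(SampleRecord(
            sample_id=sid, genotype=g, year=year, month=m,
            sensory={a: float(attr_values[a][i]) for a in DEFAULT_ATTRIBUTES},
            ssc=float(ssc[i]), ta=float(ta[i]), ph=float(ph[i]),
            volatiles={compounds[k]: float(obs_ab[i, k])
                       for k in range(cfg.n_volatiles) if detected[i, k]},
        ))
        outlier_flags[sid] = bool(outlier[i])

    # --- panelist-level ratings --------------------------------------------
    pan_rows = []
    bias = cfg.panelist_bias_sd * rng.standard_normal(cfg.n_panelists)
    for i, rec in enumerate(records):
        for p in range(cfg.n_panelists):
            for a in DEFAULT_ATTRIBUTES:
                r = rec.sensory[a] + bias[p] + cfg.panelist_noise_sd * rng.standard_normal()
                pan_rows.append((rec.sample_id, f"P{p + 1:02d}", a,
                                 float(np.clip(r, 0.0, 10.0))))
    panelists = pd.DataFrame(pan_rows,
                             columns=["sample_id", "panelist_id", "attribute", "rating"])

    rep_rows = []
    for rec in records:
        for r in range(cfg.n_replicates):
            rid = f"R{r + 1}"
            rep_rows.append((rec.sample_id, rid, "ssc",
                             float(max(rec.ssc + cfg.replicate_ssc_sd * rng.standard_normal(), 0.1))))
            rep_rows.append((rec.sample_id, rid, "ta",
                             float(max(rec.ta + cfg.replicate_ta_sd * rng.standard_normal(), 0.01))))
            rep_rows.append((rec.sample_id, rid, "ph",
                             float(rec.ph + cfg.replicate_ph_sd * rng.standard_normal())))
    replicates = pd.DataFrame(rep_rows,
                              columns=["sample_id", "replicate_id", "measure", "value"])

    ds = PanelDataset(
        records=records,
        attribute_names=list(DEFAULT_ATTRIBUTES),
        compound_names=compounds,
        panelist_ratings=panelists,
        replicate_chem=replicates,
    )
    truth = GroundTruth(
        month_slopes=month_slopes,
        active_volatile_coefs=gamma,
        outlier_flags=outlier_flags,
        ssc_genotype_effects=ssc_geno,
        attribute_effects=attr_effects,
        clipped_fraction=clipped_fraction,
        config=cfg,
    )
    return ds, truth


def _truncate(ds: PanelDataset, truth: GroundTruth, n: int) -> tuple[PanelDataset, GroundTruth]:
    """Keep the first ``n`` records (fixture sizing), pruning sidecars/flags."""
    records = ds.records[:n]
    keep = {r.sample_id for r in records}
    pan = ds.panelist_ratings[ds.panelist_ratings["sample_id"].isin(keep)].reset_index(drop=True)
    rep = ds.replicate_chem[ds.replicate_chem["sample_id"].isin(keep)].reset_index(drop=True)
    out = PanelDataset(records=records, attribute_names=ds.attribute_names,
                       compound_names=ds.compound_names,
                       panelist_ratings=pan, replicate_chem=rep)
    truth.outlier_flags = {k: v for k, v in truth.outlier_flags.items() if k in keep}
    return out, truth


FIXTURES = ("tiny", "pooled_demo", "hier_demo")


def make_fixture(name: str) -> tuple[PanelDataset, GroundTruth]:
    """Deterministic small datasets for oracle tests and demos.

    * ``tiny`` — 6 samples, one month, no volatile signal: small enough for a
      dense grid-posterior oracle.
    * ``pooled_demo`` — 207 samples across 7 seasons with a single common SSC
      slope of 0.45 and t(5) noise, the pooled-model scale.
    * ``hier_demo`` — 3 months x 70 samples with per-month slopes
      (0.49, 0.49, 0.54): the hierarchical model's target, highest in month 3.
    """
    if name == "tiny":
        cfg = GeneratorConfig(
            n_genotypes=6, years=[2019], months_per_year=[2],
            genotypes_per_year=6, min_harvests=1, max_harvests=1,
            n_panelists=3, n_replicates=2, n_volatiles=3,
            n_active_volatiles=0, n_negative_active=0, n_absent_volatiles=0,
            sigma=0.3, outlier_fraction=0.0, ssc_genotype_sd=1.6, seed=20210317,
        )
        return generate_dataset(cfg)
    if name == "pooled_demo":
        cfg = GeneratorConfig(
            genotypes_per_year=10, min_harvests=3, max_harvests=3,
            n_active_volatiles=0, n_negative_active=0,
            month_slope_sd=0.0, sigma=0.3, nu=5.0, outlier_fraction=0.05,
            seed=20210317,
        )
        ds, truth = generate_dataset(cfg)
        return _truncate(ds, truth, 207)
    if name == "hier_demo":
        cfg = GeneratorConfig(
            n_genotypes=70, years=[2019], months_per_year=[1, 2, 3],
            genotypes_per_year=70, min_harvests=3, max_harvests=3,
            n_panelists=5, n_replicates=2,
            n_volatiles=5, n_active_volatiles=0, n_negative_active=0,
            n_absent_volatiles=0,
            month_slopes={1: 0.49, 2: 0.49, 3: 0.54},
            sigma=0.25, nu=8.0, outlier_fraction=0.0, seed=20210317,
        )
        return generate_dataset(cfg)
    raise ConfigError(f"unknown fixture {name!r}; valid fixtures: {FIXTURES}")
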