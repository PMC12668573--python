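"""Database schema, validation, run manifest, and the end-to-end pipeline.

The database is a flat CSV with one row per (observation, attribute):
identifiers, the paired treatment means, one 0/1 column per practice axis,
and the 14 site-level covariate columns.  Loading validates the schema,
coerces numerics, and excludes invalid rows with machine-readable reason
codes collected in a ValidationReport.

``run_pipeline`` chains simulate -> effects -> envpart -> map -> report
deterministically: a single master seed is split into per-stage seeds via
``numpy.random.SeedSequence`` so each stage is independently reproducible.
All outputs are plain CSV plus a JSON manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import effects as eff
from . import env_analysis as env
from . import mapping as mp
from .effects import DEFAULT_AXES, SERVICES
from .env_analysis import BLOCKS, COVARIATE_COLUMNS
from .synthetic_data import SimConfig, simulate_covariate_grid, simulate_database

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

ID_COLUMNS = ("study_id", "obs_id", "site_id", "lat", "lon", "crop",
              "attribute_id", "service_id", "x_s", "x_i")


class ValidationError(ValueError):
    """Schema or configuration validation failure (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""


def required_columns(axes: Sequence[str] = DEFAULT_AXES) -> list[str]:
    return list(ID_COLUMNS) + list(axes) + list(COVARIATE_COLUMNS)


@dataclass
class ValidationReport:
    rows_in: int = 0
    rows_used: int = 0
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def rows_excluded(self) -> int:
        return sum(self.exclusions.values())

    def add(self, reason: str, count: int) -> None:
        if count:
            self.exclusions[reason] = self.exclusions.get(reason, 0) + int(count)


_NUMERIC = ("lat", "lon", "x_s", "x_i") + COVARIATE_COLUMNS


def validate_database(
    df: pd.DataFrame, axes: Sequence[str] = DEFAULT_AXES
) -> tuple[pd.DataFrame, ValidationReport]:
    """Validate schema and row contents; exclude bad rows with reason codes."""
    missing = [c for c in required_columns(axes) if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    report = ValidationReport(rows_in=len(df))
    if df.empty:
        raise ValidationError("empty database")
    df = df.copy()
    drop = pd.Series(False, index=df.index)
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            report.add(f"malformed_numeric:{col}", int(bad.sum()))
            drop |= bad
        df[col] = coerced
    nonpos = (df["x_s"] <= 0) | (df["x_i"] <= 0) | df["x_s"].isna() | df["x_i"].isna()
    nonpos &= ~drop
    report.add("nonpositive mean", int(nonpos.sum()))
    drop |= nonpos
    for a in axes:
        coerced = pd.to_numeric(df[a], errors="coerce")
        bad = (~coerced.isin((0, 1))) & ~drop
        if bad.any():
            report.add(f"non_binary_practice:{a}", int(bad.sum()))
            drop |= bad
        df[a] = coerced
    bad_svc = ~df["service_id"].isin(SERVICES) & ~drop
    report.add("unknown service", int(bad_svc.sum()))
    drop |= bad_svc
    out = df.loc[~drop].reset_index(drop=True)
    out[list(axes)] = out[list(axes)].astype(int)
    report.rows_used = len(out)
    if report.rows_excluded:
        logger.warning("validation excluded %d rows: %s", report.rows_excluded, report.exclusions)
    return out, report


def load_database(
    path, axes: Sequence[str] = DEFAULT_AXES
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a database CSV."""
    p = Path(path)
    if not p.exists():
        raise ValidationError(f"database file not found: {p}")
    try:
        df = pd.read_csv(p)
    except pd.errors.EmptyDataError as e:
        raise ValidationError(f"empty database file: {p}") from e
    return validate_database(df, axes)


def write_database(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline configuration and manifest


@dataclass
class PipelineConfig:
    """End-to-end run parameters; analysis knobs plus the generator config."""

    sim: SimConfig = field(default_factory=SimConfig)
    database: str | None = None  # path to an existing CSV; None = simulate
    bootstrap: int = 4999
    alpha: float = 0.05
    n_permutations: int = 999
    trees: int = 100
    replicates: int = 5
    importance_permutations: int = 19
    grid_shape: tuple[int, int] = (20, 20)
    mask_alpha: float = 0.95
    mask_df: int | None = None
    map_service: str = "carbon_sequestration"
    equivalence_band: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.map_service not in SERVICES:
            raise ValidationError(f"unknown map service {self.map_service!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sim"]["practice_axes"] = list(self.sim.practice_axes)
        d["sim"]["count_weights"] = list(self.sim.count_weights)
        d["grid_shape"] = list(self.grid_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "sim" in d and isinstance(d["sim"], dict):
            sim = d["sim"]
            if "practice_axes" in sim:
                sim["practice_axes"] = tuple(sim["practice_axes"])
            if "count_weights" in sim:
                sim["count_weights"] = tuple(sim["count_weights"])
            d["sim"] = SimConfig(**sim)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class StageRecord:
    name: str
    status: str = "ok"
    rows_in: int = 0
    rows_used: int = 0
    rows_excluded: int = 0
    error: str | None = None
    outputs: list[str] = field(default_factory=list)


@dataclass
class RunManifest:
    seed: int
    version: str = __version__
    config: dict = field(default_factory=dict)
    stages: list[StageRecord] = field(default_factory=list)
    exclusion_log: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = {
            "seed": self.seed,
            "version": self.version,
            "config": self.config,
            "stages": [asdict(s) for s in self.stages],
            "exclusion_log": self.exclusion_log,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# end-to-end run


def _effects_stage(obs, out_dir: Path, cfg: PipelineConfig, seeds) -> list[str]:
    outputs = []
    by_bin = eff.summarize_by(obs, "bin", B=cfg.bootstrap, alpha=cfg.alpha, seed=seeds[0])
    by_class = eff.summarize_by(obs, "class", B=cfg.bootstrap, alpha=cfg.alpha, seed=seeds[1])
    counts = eff.tabulate_counts(obs)
    per_practice = eff.per_practice_summary(
        obs, cfg.sim.practice_axes, B=cfg.bootstrap, alpha=cfg.alpha, seed=seeds[2]
    )
    arid, non_arid = eff.stratify_by_aridity(obs)
    strata = []
    for label, subset, sd in (("arid", arid, seeds[3]), ("non_arid", non_arid, seeds[4])):
        if len(subset):
            t = eff.summarize_by(subset, "bin", B=cfg.bootstrap, alpha=cfg.alpha, seed=sd)
            t.insert(0, "stratum", label)
            strata.append(t)
    for name, frame in (
        ("effects_by_bin.csv", by_bin),
        ("effects_by_class.csv", by_class),
        ("practice_counts.csv", counts),
        ("effects_per_practice.csv", per_practice),
    ):
        frame.to_csv(out_dir / name, index=False)
        outputs.append(name)
    if strata:
        pd.concat(strata, ignore_index=True).to_csv(out_dir / "effects_by_aridity.csv", index=False)
        outputs.append("effects_by_aridity.csv")
    return outputs


def _envpart_stage(obs, out_dir: Path, cfg: PipelineConfig, seed) -> list[str]:
    cov_cols = ["lat"] + list(COVARIATE_COLUMNS)
    X_all = obs[cov_cols]
    vifs = env.vif(X_all)
    vifs.to_frame().assign(flagged=vifs > env.VIF_THRESHOLD).to_csv(out_dir / "vif.csv")
    spearman_rows, varpart_rows = [], []
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(SERVICES) * 2 * 5))
    for svc in SERVICES:
        for cls in ("low", "high"):
            sel = obs[(obs["service_id"] == svc) & (obs["class"] == cls)]
            y = sel["lnrr"].to_numpy()
            n_min = max(len(b) for b in BLOCKS.values()) + 2
            if len(sel) < max(n_min, sum(len(b) for b in BLOCKS.values()) + 2):
                logger.warning("skipping envpart for %s/%s (n=%d too small)", svc, cls, len(sel))
                continue
            sp = env.spearman_assoc(sel[cov_cols], y)
            sp = sp.assign(service_id=svc, **{"class": cls})
            spearman_rows.append(sp.reset_index())
            blocks = {name: sel[list(cols)] for name, cols in BLOCKS.items()}
            vp = env.varpart4(y, blocks)
            for name, cols in BLOCKS.items():
                bf = env.block_fit(
                    y, sel[list(cols)], n_perm=cfg.n_permutations,
                    seed=next(children),
                )
                varpart_rows.append(
                    {"service_id": svc, "class": cls, "component": f"{name} (solo)",
                     "value": bf.adj_r2, "p": bf.p, "n": bf.n}
                )
            for comp, val in vp.fractions.items():
                varpart_rows.append(
                    {"service_id": svc, "class": cls, "component": comp,
                     "value": val, "p": np.nan, "n": len(sel)}
                )
            varpart_rows.append(
                {"service_id": svc, "class": cls, "component": "total",
                 "value": vp.total, "p": np.nan, "n": len(sel)}
            )
            varpart_rows.append(
                {"service_id": svc, "class": cls, "component": "residual",
                 "value": vp.residual, "p": np.nan, "n": len(sel)}
            )
    outputs = ["vif.csv"]
    if spearman_rows:
        pd.concat(spearman_rows, ignore_index=True).to_csv(out_dir / "spearman.csv", index=False)
        outputs.append("spearman.csv")
    if varpart_rows:
        pd.DataFrame(varpart_rows).to_csv(out_dir / "varpart.csv", index=False)
        outputs.append("varpart.csv")
    return outputs


def _map_stage(obs, out_dir: Path, cfg: PipelineConfig, seed) -> list[str]:
    predictors = list(COVARIATE_COLUMNS)  # 14 covariates; latitude excluded
    layers = simulate_covariate_grid(cfg.sim, cfg.grid_shape, seed=cfg.seed + 7919)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = ss.spawn(4)
    outputs = []
    std_maps: dict[str, mp.Grid] = {}
    validation_rows, importance_rows = [], []
    for cls, fit_seed, imp_seed in (("low", seeds[0], seeds[1]), ("high", seeds[2], seeds[3])):
        sel = obs[(obs["service_id"] == cfg.map_service) & (obs["class"] == cls)]
        if len(sel) < 20:
            raise StageError(f"too few observations ({len(sel)}) for {cfg.map_service}/{cls} map")
        X = sel[predictors]
        y = sel["lnrr"].to_numpy()
        model = mp.fit_rf_ensemble(
            X, y, trees=cfg.trees, replicates=cfg.replicates,
            seed=int(fit_seed.generate_state(1)[0] % (2**31 - 1)),
        )
        if cfg.importance_permutations > 0:
            imp = mp.permutation_importance(
                model, X, y, n_perm=cfg.importance_permutations,
                seed=int(imp_seed.generate_state(1)[0] % (2**31 - 1)),
            )
            importance_rows.append(imp.assign(**{"class": cls}).reset_index())
        pred = mp.predict_grid(model, layers)
        mask = mp.mahalanobis_mask(
            layers, X, alpha=cfg.mask_alpha, df=cfg.mask_df, predictors=predictors
        )
        std = mp.standardize01(pred, mask)
        std_maps[cls] = std
        vs = mp.validate_pred_obs(model.predict(X), y)
        validation_rows.append(
            {"class": cls, "slope": vs.slope, "intercept": vs.intercept,
             "r2": vs.r2, "n": vs.n,
             "oob_r2_mean": float(np.mean(model.oob_r2)),
             "masked_fraction": float(np.mean(mask.values == 1.0))}
        )
        for name, grid in (("prediction", pred), ("mask", mask), ("standardized", std)):
            fname = f"map_{cfg.map_service}_{cls}_{name}.csv"
            mp.write_grid(grid, out_dir / fname)
            outputs.append(fname)
    comparison = mp.compare_scenarios(std_maps["low"], std_maps["high"], band=cfg.equivalence_band)
    mp.write_grid(comparison, out_dir / "map_scenario_comparison.csv")
    outputs.append("map_scenario_comparison.csv")
    pd.DataFrame(validation_rows).to_csv(out_dir / "map_validation.csv", index=False)
    outputs.append("map_validation.csv")
    if importance_rows:
        pd.concat(importance_rows, ignore_index=True).to_csv(
            out_dir / "map_importance.csv", index=False
        )
        outputs.append("map_importance.csv")
    return outputs


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Run simulate -> effects -> envpart -> map -> report into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, config=json.loads(json.dumps(asdict(config), default=str)))
    master = np.random.SeedSequence(config.seed)
    stage_seeds = master.spawn(5)
    failed = False

    def run_stage(name, fn):
        nonlocal failed
        rec = StageRecord(name=name)
        if failed:
            rec.status = "skipped"
            manifest.stages.append(rec)
            return None
        try:
            result = fn(rec)
            manifest.stages.append(rec)
            return result
        except Exception as e:  # noqa: BLE001 - manifest records any stage failure
            rec.status = "failed"
            rec.error = f"{type(e).__name__}: {e}"
            manifest.stages.append(rec)
            failed = True
            logger.error("stage %s failed: %s", name, rec.error)
            return None

    def _simulate(rec: StageRecord):
        if config.database is not None:
            db, report = load_database(config.database, config.sim.practice_axes)
            truth = None
        else:
            db, truth = simulate_database(config.sim)
            write_database(db, out / "database.csv")
            truth.to_csv(out / "truth.csv")
            rec.outputs += ["database.csv", "truth.csv"]
            db, report = validate_database(db, config.sim.practice_axes)
        rec.rows_in = report.rows_in
        rec.rows_used = report.rows_used
        rec.rows_excluded = report.rows_excluded
        manifest.exclusion_log.update(report.exclusions)
        config.to_yaml(out / "config.yaml")
        rec.outputs.append("config.yaml")
        return db, truth

    sim_result = run_stage("simulate", _simulate)

    def _effects(rec: StageRecord):
        db, _ = sim_result
        obs = eff.observation_effects(db, config.sim.practice_axes)
        rec.rows_in = len(db)
        rec.rows_used = len(obs)
        rec.rows_excluded = int(db["obs_id"].nunique() - len(obs))
        eff_seeds = stage_seeds[1].spawn(5)
        rec.outputs += _effects_stage(obs, out, config, eff_seeds)
        obs.to_csv(out / "observation_effects.csv", index=False)
        rec.outputs.append("observation_effects.csv")
        return obs

    obs = run_stage("effects", _effects)

    run_stage("envpart", lambda rec: rec.outputs.extend(
        _envpart_stage(obs, out, config, stage_seeds[2])
    ))
    run_stage("map", lambda rec: rec.outputs.extend(
        _map_stage(obs, out, config, stage_seeds[3])
    ))

    def _report(rec: StageRecord):
        summary = {
            "n_observations": int(obs["obs_id"].nunique()) if obs is not None else 0,
            "n_sites": int(obs["site_id"].nunique()) if obs is not None else 0,
            "n_studies": int(obs["study_id"].nunique()) if obs is not None else 0,
            "stages": [s.name for s in manifest.stages if s.status == "ok"],
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        rec.outputs.append("summary.json")

    run_stage("report", _report)
    manifest.to_json(out / "manifest.json")
    if failed:
        first = next(s for s in manifest.stages if s.status == "failed")
        raise StageError(f"stage {first.name} failed: {first.error}")
    return manifest
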