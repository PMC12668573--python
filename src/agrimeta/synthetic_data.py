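"""Synthetic paired-observation databases with known ground truth.

Generates databases shaped like the compiled field-study data the analysis
assumes: paired treatment means (sustainable x_s vs intensive x_i) for
ecosystem attributes grouped into six services, a binary practice vector per
observation with counts spanning 1-8, and 14 site-level environmental
covariates in four blocks.

The generative model is linear in the (optionally saturating) practice
count on the log-response-ratio scale:

    LnRR_obs = alpha_s + beta_s * g(n) + gamma . z_env + u_site + eps

with g(n) = n (default) or log(1 + n), standardized covariates z_env,
Gaussian site effects u_site ~ N(0, site_sd^2) and residuals
eps ~ N(0, residual_sd^2).  Intensive means are lognormal (positivity);
x_s = x_i * exp(LnRR).  The per-(service, bin) deterministic group means are
returned as a TruthTable so downstream estimators can be checked against a
known target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .effects import DEFAULT_AXES, SERVICES, bin_count
from .env_analysis import BLOCKS, COVARIATE_COLUMNS

#: Stand-in attribute lists per service (the real per-study attribute
#: grouping is user-supplied; override via SimConfig.attribute_map).
DEFAULT_ATTRIBUTE_MAP: dict[str, str] = {
    "grain_yield": "crop_yield",
    "aboveground_biomass": "crop_yield",
    "total_n": "soil_fertility",
    "available_p": "soil_fertility",
    "soc_stock": "carbon_sequestration",
    "microbial_biomass_c": "carbon_sequestration",
    "litter_mass_loss": "som_decomposition",
    "enzyme_activity": "som_decomposition",
    "aggregate_stability": "habitat",
    "soil_porosity": "habitat",
    "microbial_richness": "biodiversity",
    "faunal_abundance": "biodiversity",
}

_DEFAULT_ALPHA = {
    "crop_yield": 0.02,
    "soil_fertility": 0.03,
    "carbon_sequestration": 0.01,
    "som_decomposition": -0.02,
    "habitat": 0.02,
    "biodiversity": 0.03,
}
_DEFAULT_BETA = {
    "crop_yield": 0.015,
    "soil_fertility": 0.03,
    "carbon_sequestration": 0.04,
    "som_decomposition": -0.015,
    "habitat": 0.03,
    "biodiversity": 0.035,
}

#: Sampling weights for practice counts 1..8, skewed towards few practices
#: like the compiled literature (counts 7-8 are rare).
_COUNT_WEIGHTS = (0.22, 0.20, 0.18, 0.14, 0.11, 0.08, 0.05, 0.02)

CROPS = ("wheat", "barley", "maize", "rice", "other")


@dataclass
class SimConfig:
    """Parameters of the synthetic database generator."""

    n_sites: int = 349
    n_obs: int = 1570
    practice_axes: tuple[str, ...] = DEFAULT_AXES
    attribute_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ATTRIBUTE_MAP)
    )
    effect_intercept: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ALPHA)
    )
    effect_slope: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_BETA))
    env_modulation: Mapping[str, float] = field(default_factory=dict)
    effect_shape: str = "linear"  # or "saturating": g(n) = log(1 + n)
    site_sd: float = 0.05
    residual_sd: float = 0.10
    baseline_mu: float = 1.0
    baseline_sigma: float = 0.5
    block_correlation: float = 0.3
    count_weights: tuple[float, ...] = _COUNT_WEIGHTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_obs < self.n_sites:
            raise ValueError("need n_obs >= n_sites >= 1")
        for name in ("site_sd", "residual_sd", "baseline_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must be in [0, 1)")
        if self.effect_shape not in ("linear", "saturating"):
            raise ValueError("effect_shape must be 'linear' or 'saturating'")
        if set(self.attribute_map.values()) != set(SERVICES):
            raise ValueError("attribute_map must cover exactly the six services")
        for mapping, label in ((self.effect_intercept, "effect_intercept"),
                               (self.effect_slope, "effect_slope")):
            missing = set(SERVICES) - set(mapping)
            if missing:
                raise ValueError(f"{label} missing services: {sorted(missing)}")
        unknown = set(self.env_modulation) - set(COVARIATE_COLUMNS) - {"lat"}
        if unknown:
            raise ValueError(f"env_modulation names unknown covariates: {sorted(unknown)}")
        if len(self.count_weights) != 8 or any(w < 0 for w in self.count_weights):
            raise ValueError("count_weights must be 8 nonnegative values")

    def g(self, n) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return np.log1p(n) if self.effect_shape == "saturating" else n

    # -- config I/O (plain YAML) --------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["practice_axes"] = list(self.practice_axes)
        d["count_weights"] = list(self.count_weights)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "practice_axes" in d:
            d["practice_axes"] = tuple(d["practice_axes"])
        if "count_weights" in d:
            d["count_weights"] = tuple(d["count_weights"])
        return cls(**d)


@dataclass
class TruthTable:
    """Generative parameters plus realized deterministic group means.

    ``expected`` holds, per (service, practice-count bin), the mean of the
    noise-free part alpha_s + beta_s*g(n) + gamma.z_env over the observations
    that fell in that group; site effects and residuals are mean-zero and
    excluded.
    """

    alpha: Mapping[str, float]
    beta: Mapping[str, float]
    gamma: Mapping[str, float]
    effect_shape: str
    expected: pd.DataFrame  # columns: service_id, bin, expected_mean, n_obs

    def expected_mean(self, service: str, bin_label: str) -> float:
        sel = self.expected[
            (self.expected["service_id"] == service) & (self.expected["bin"] == bin_label)
        ]
        if sel.empty:
            raise KeyError(f"no expectation for ({service}, {bin_label})")
        return float(sel["expected_mean"].iloc[0])

    def to_csv(self, path) -> None:
        rows = [
            {"kind": "param", "service_id": s, "bin": "", "name": "alpha", "value": a}
            for s, a in self.alpha.items()
        ]
        rows += [
            {"kind": "param", "service_id": s, "bin": "", "name": "beta", "value": b}
            for s, b in self.beta.items()
        ]
        rows += [
            {"kind": "param", "service_id": "", "bin": "", "name": f"gamma:{c}", "value": g}
            for c, g in self.gamma.items()
        ]
        rows.append(
            {"kind": "param", "service_id": "", "bin": "", "name": "effect_shape",
             "value": 0.0 if self.effect_shape == "linear" else 1.0}
        )
        df = pd.DataFrame(rows)
        exp = self.expected.assign(kind="group_mean", name="expected_mean").rename(
            columns={"expected_mean": "value"}
        )[["kind", "service_id", "bin", "name", "value"]]
        pd.concat([df, exp], ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# site covariates


def _block_correlated_normals(
    rng: np.random.Generator, n: int, rho: float
) -> dict[str, np.ndarray]:
    """Standard normals per covariate with equicorrelation rho inside each
    block and independence across blocks."""
    out: dict[str, np.ndarray] = {}
    for cols in BLOCKS.values():
        k = len(cols)
        C = np.full((k, k), rho) + (1.0 - rho) * np.eye(k)
        L = np.linalg.cholesky(C)
        Z = rng.standard_normal((n, k)) @ L.T
        for j, c in enumerate(cols):
            out[c] = Z[:, j]
    return out


# Monotone marginal transforms keep the copula correlation structure while
# giving each covariate a plausible range.
def _marginals(z: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    u = {c: norm.cdf(v) for c, v in z.items()}
    return {
        "lat": -60.0 + 130.0 * u["lat"],
        "elevation": np.exp(5.5 + 1.0 * z["elevation"]),
        "slope": 25.0 * u["slope"],
        "aridity_index": np.exp(-0.2 + 0.6 * z["aridity_index"]),
        "mat": 12.0 + 8.0 * z["mat"],
        "mdr": 11.0 + 2.5 * z["mdr"],
        "tsea": 700.0 + 250.0 * z["tsea"],
        "psea": 55.0 + 20.0 * z["psea"],
        "ph": 3.5 + 5.5 * u["ph"],
        "sand": 100.0 * u["sand"],
        "soc": np.exp(2.7 + 0.5 * z["soc"]),
        "total_p": np.exp(6.0 + 0.4 * z["total_p"]),
        "plant_cover": 100.0 * u["plant_cover"],
        "ndvi": 0.9 * u["ndvi"],
        "lai": 6.0 * u["lai"],
    }


def simulate_sites(
    config: SimConfig, n_sites: int | None = None, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """One row per site: id, lon, and the 15 block covariates (incl. lat)."""
    n = n_sites if n_sites is not None else config.n_sites
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    z = _block_correlated_normals(rng, n, config.block_correlation)
    cols = _marginals(z)
    df = pd.DataFrame({"site_id": [f"site{idx:04d}" for idx in range(n)]})
    df["lon"] = rng.uniform(-180.0, 180.0, size=n)
    for c, v in cols.items():
        df[c] = v
    return df


def simulate_covariate_grid(
    config: SimConfig, shape: tuple[int, int] = (20, 20), seed: int | None = None,
    cell_size: float = 1.0,
):
    """Covariate layers on a lattice, same marginals as the site generator."""
    from .mapping import Grid

    nr, nc = shape
    rng = np.random.default_rng(seed if seed is not None else config.seed + 1)
    z = _block_correlated_normals(rng, nr * nc, config.block_correlation)
    cols = _marginals(z)
    return {c: Grid(v.reshape(nr, nc), cell_size=cell_size) for c, v in cols.items()}


# ---------------------------------------------------------------------------
# database generation


def _practice_counts(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    w = np.asarray(config.count_weights, dtype=float)
    counts = rng.choice(np.arange(1, 9), size=config.n_obs, p=w / w.sum())
    # guarantee full 1..8 coverage for realistically sized databases
    if config.n_obs >= 8:
        counts[:8] = np.arange(1, 9)
        rng.shuffle(counts)
    return counts


def simulate_database(config: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Generate a paired-observation database and its TruthTable.

    The returned frame has one row per (observation, attribute) and follows
    the pipeline_io schema.  Deterministic for a fixed config seed.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_sites, rng_db = (np.random.default_rng(s) for s in ss.spawn(2))

    sites = simulate_sites(config, rng=rng_sites)
    cov_cols = ["lat"] + list(COVARIATE_COLUMNS)
    zstd = (sites[cov_cols] - sites[cov_cols].mean()) / sites[cov_cols].std(ddof=0)
    gamma = {c: float(config.env_modulation.get(c, 0.0)) for c in cov_cols}
    env_term_site = sum(g * zstd[c].to_numpy() for c, g in gamma.items() if g != 0.0)
    if np.isscalar(env_term_site):  # all gammas zero
        env_term_site = np.zeros(config.n_sites)
    site_effect = rng_db.normal(0.0, config.site_sd, size=config.n_sites)

    # observation-level design
    n = config.n_obs
    site_idx = np.concatenate(
        [np.arange(config.n_sites), rng_db.integers(0, config.n_sites, n - config.n_sites)]
    )
    rng_db.shuffle(site_idx)
    counts = _practice_counts(rng_db, config)
    axes = list(config.practice_axes)
    pv = np.zeros((n, len(axes)), dtype=int)
    for i, c in enumerate(counts):
        pv[i, rng_db.choice(len(axes), size=c, replace=False)] = 1

    services = np.array(SERVICES)[np.arange(n) % len(SERVICES)]
    rng_db.shuffle(services)
    crops = rng_db.choice(CROPS, size=n)

    alpha = np.array([config.effect_intercept[s] for s in services])
    beta = np.array([config.effect_slope[s] for s in services])
    det = alpha + beta * config.g(counts) + np.asarray(env_term_site)[site_idx]
    eps = rng_db.normal(0.0, config.residual_sd, size=n)
    lnrr_true = det + site_effect[site_idx] + eps

    attrs_by_service: dict[str, list[str]] = {s: [] for s in SERVICES}
    for attr, svc in config.attribute_map.items():
        attrs_by_service[svc].append(attr)

    rows = []
    for i in range(n):
        svc = services[i]
        site_row = sites.iloc[site_idx[i]]
        base = {
            "study_id": f"study{site_idx[i]:04d}",
            "obs_id": f"obs{i:05d}",
            "site_id": site_row["site_id"],
            "lat": site_row["lat"],
            "lon": site_row["lon"],
            "crop": crops[i],
            "service_id": svc,
        }
        for j, a in enumerate(axes):
            base[a] = int(pv[i, j])
        for c in COVARIATE_COLUMNS:
            base[c] = site_row[c]
        for attr in attrs_by_service[svc]:
            x_i = float(
                np.exp(rng_db.normal(config.baseline_mu, config.baseline_sigma))
            )
            row = dict(base)
            row["attribute_id"] = attr
            row["x_i"] = x_i
            row["x_s"] = x_i * float(np.exp(lnrr_true[i]))
            rows.append(row)
    db = pd.DataFrame(rows)

    # realized deterministic expectations per (service, bin)
    bins = np.array([bin_count(c) for c in counts])
    exp_rows = []
    for svc in SERVICES:
        for b in ("1", "2", "3", "4", "5", "6", "7+"):
            sel = (services == svc) & (bins == b)
            if sel.any():
                exp_rows.append(
                    {
                        "service_id": svc,
                        "bin": b,
                        "expected_mean": float(det[sel].mean()),
                        "n_obs": int(sel.sum()),
                    }
                )
    truth = TruthTable(
        alpha=dict(config.effect_intercept),
        beta=dict(config.effect_slope),
        gamma={c: g for c, g in gamma.items() if g != 0.0},
        effect_shape=config.effect_shape,
        expected=pd.DataFrame(exp_rows),
    )
    return db, truth
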