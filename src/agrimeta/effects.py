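"""Effect sizes of sustainable vs intensive management.

The unit of analysis is a paired comparison: the mean of an ecosystem
attribute under sustainable management (x_s) against its mean under the
matched intensive treatment (x_i).  The effect size is the log response
ratio LnRR = ln(x_s / x_i); positive values favour the sustainable
treatment.

Attribute-level effects are averaged (unweighted) to the service level per
observation, then observations are grouped by the number of sustainable
practices — individually (bins 1..6, with 7 and 8 merged as "7+") or as
low (1-3) vs high (4-8) intensity classes — and summarised with a
percentile-bootstrap mean and 95% CI.  A group is called significant when
its CI excludes zero; no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _seed_seq(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)


SERVICES: tuple[str, ...] = (
    "crop_yield",
    "soil_fertility",
    "carbon_sequestration",
    "som_decomposition",
    "habitat",
    "biodiversity",
)

DEFAULT_AXES: tuple[str, ...] = (
    "tillage",
    "crop_rotation",
    "residue_management",
    "fertilization_source",
    "cover_cropping",
    "pesticide_use",
    "irrigation_regime",
    "crop_diversification",
)

COUNT_BINS: tuple[str, ...] = ("1", "2", "3", "4", "5", "6", "7+")
CLASSES: tuple[str, ...] = ("low", "high")

#: Stand-in label coding for each practice axis: 1 = sustainable, 0 =
#: intensive.  User-overridable; the authoritative per-study criteria live
#: with the database, not here.
_DEFAULT_CODES: dict[str, dict[str, int]] = {
    "tillage": {"no_till": 1, "reduced_till": 1, "conventional_till": 0},
    "crop_rotation": {"rotation": 1, "monoculture": 0},
    "residue_management": {"residue_retained": 1, "residue_removed": 0},
    "fertilization_source": {"organic": 1, "mineral": 0},
    "cover_cropping": {"cover_crop": 1, "bare_fallow": 0},
    "pesticide_use": {"no_pesticide": 1, "reduced_pesticide": 1, "conventional_pesticide": 0},
    "irrigation_regime": {"deficit_irrigation": 1, "rainfed": 1, "full_irrigation": 0},
    "crop_diversification": {"intercropping": 1, "sole_crop": 0},
}


@dataclass(frozen=True)
class PracticeTaxonomy:
    """Binary coding of raw management labels onto ordered practice axes."""

    axes: tuple[str, ...] = DEFAULT_AXES
    codes: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: dict(_DEFAULT_CODES)
    )

    def __post_init__(self) -> None:
        for axis in self.axes:
            if axis not in self.codes:
                raise ValueError(f"no label codes for axis {axis!r}")
            for label, code in self.codes[axis].items():
                if code not in (0, 1):
                    raise ValueError(f"code for {axis}:{label} must be 0 or 1")

    def code(self, axis: str, label: str) -> int:
        """Code one raw label on one axis; unknown labels are rejected."""
        if axis not in self.codes:
            raise ValueError(f"unknown practice axis {axis!r}")
        table = self.codes[axis]
        if label not in table:
            raise ValueError(f"unknown label {label!r} for axis {axis!r}")
        return table[label]

    def code_treatment(self, labels: Mapping[str, str]) -> np.ndarray:
        """Code a full treatment description into a binary practice vector."""
        return np.array([self.code(a, labels[a]) for a in self.axes], dtype=int)


# ---------------------------------------------------------------------------
# core effect-size operations


def lnrr(x_s, x_i):
    """Log response ratio ln(x_s / x_i).  Both means must be positive."""
    x_s = np.asarray(x_s, dtype=float)
    x_i = np.asarray(x_i, dtype=float)
    if np.any(x_s <= 0) or np.any(x_i <= 0):
        raise ValueError("LnRR requires strictly positive means")
    out = np.log(x_s) - np.log(x_i)
    return float(out) if out.ndim == 0 else out


def count_practices(practice_vector: Sequence[int]) -> int:
    """Number of axes coded sustainable (sum of a binary practice vector)."""
    v = np.asarray(practice_vector)
    if v.size == 0:
        raise ValueError("empty practice vector")
    if not np.isin(v, (0, 1)).all():
        raise ValueError("practice vector entries must be 0 or 1")
    return int(v.sum())


def bin_count(n_practices: int) -> str:
    """Practice-count bin: 1..6 map to themselves, 7 and 8 merge to '7+'."""
    n = int(n_practices)
    if n < 1:
        raise ValueError("practice count must be >= 1 for binning")
    return "7+" if n >= 7 else str(n)


def intensity_class(n_practices: int) -> str:
    """Low (1-3 practices) vs high (4-8 practices) intensity class."""
    n = int(n_practices)
    if not 1 <= n <= 8:
        raise ValueError("practice count must be in 1..8")
    return "low" if n <= 3 else "high"


def service_effect(attribute_lnrrs: Iterable[float]) -> float:
    """Unweighted mean of attribute-level LnRRs for one observation/service."""
    vals = np.asarray(list(attribute_lnrrs), dtype=float)
    if vals.size == 0:
        raise ValueError("no attribute effect sizes to aggregate")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# group summaries


@dataclass(frozen=True)
class EffectSummary:
    """Group-level mean LnRR with a 95% CI and the CI-excludes-zero flag."""

    n: int
    mean_lnrr: float
    ci_low: float
    ci_high: float
    significant: bool
    ci_defined: bool = True
    service_id: str | None = None
    group: str | None = None


def summarize_group(
    effects: Sequence[float],
    B: int = 4999,
    alpha: float = 0.05,
    seed=None,
    method: str = "bootstrap",
    service_id: str | None = None,
    group: str | None = None,
) -> EffectSummary:
    """Mean effect with percentile-bootstrap CI and significance flag.

    ``method='bootstrap'`` (default) resamples with replacement B times and
    takes the alpha/2 and 1-alpha/2 percentiles of the resampled means;
    ``method='t'`` gives the parametric Student-t interval for cross-checks.
    Groups with n < 2 get an undefined CI and significant=False.
    """
    vals = np.asarray(list(effects), dtype=float)
    n = vals.size
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    mean = float(vals.mean()) if n else float("nan")
    if n < 2:
        return EffectSummary(
            n=n, mean_lnrr=mean, ci_low=float("nan"), ci_high=float("nan"),
            significant=False, ci_defined=False, service_id=service_id, group=group,
        )
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(B, n))
        boot_means = vals[idx].mean(axis=1)
        lo, hi = np.percentile(boot_means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    elif method == "t":
        from scipy import stats

        sem = vals.std(ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
    else:
        raise ValueError(f"unknown CI method {method!r}")
    significant = bool(lo > 0 or hi < 0)
    return EffectSummary(
        n=n, mean_lnrr=mean, ci_low=float(lo), ci_high=float(hi),
        significant=significant, service_id=service_id, group=group,
    )


# ---------------------------------------------------------------------------
# table-level pipeline


def attribute_effects(db: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Add an ``lnrr`` column; exclude rows with nonpositive means.

    Returns the augmented frame and the number of excluded rows (each
    exclusion is logged — log-ratios are undefined for nonpositive means).
    """
    bad = (db["x_s"] <= 0) | (db["x_i"] <= 0) | db["x_s"].isna() | db["x_i"].isna()
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("excluded %d rows with nonpositive/missing means", n_bad)
    kept = db.loc[~bad].copy()
    kept["lnrr"] = np.log(kept["x_s"].to_numpy()) - np.log(kept["x_i"].to_numpy())
    return kept, n_bad


def observation_effects(
    db: pd.DataFrame, axes: Sequence[str] = DEFAULT_AXES
) -> pd.DataFrame:
    """Collapse attribute rows to one service-level effect per observation.

    Attribute LnRRs are averaged (unweighted) within each observation; the
    practice count, bin and intensity class are attached.  Observations with
    zero sustainable practices are excluded (no sustainable treatment).
    """
    rows, _ = attribute_effects(db)
    axes = [a for a in axes if a in rows.columns]
    meta_cols = ["study_id", "site_id", "service_id", "lat", "lon", "crop"]
    extra = [
        c for c in rows.columns
        if c not in meta_cols + axes + ["obs_id", "attribute_id", "x_s", "x_i", "lnrr"]
    ]
    grouped = rows.groupby("obs_id", sort=True)
    obs = grouped[meta_cols + axes + extra].first()
    obs["lnrr"] = grouped["lnrr"].mean()
    obs["n_attributes"] = grouped["lnrr"].size()
    counts = obs[axes].to_numpy(dtype=int).sum(axis=1)
    obs["n_practices"] = counts
    zero = obs["n_practices"] < 1
    if zero.any():
        logger.warning("excluded %d observations with zero sustainable practices", int(zero.sum()))
        obs = obs.loc[~zero]
    obs["bin"] = [bin_count(n) for n in obs["n_practices"]]
    obs["class"] = [intensity_class(n) for n in obs["n_practices"]]
    return obs.reset_index()


def summarize_by(
    obs: pd.DataFrame,
    group_by: str = "bin",
    B: int = 4999,
    alpha: float = 0.05,
    seed=None,
) -> pd.DataFrame:
    """EffectSummary table per (service, group).

    ``group_by`` is 'bin' (practice-count bins) or 'class' (low/high).
    Group seeds are derived from ``seed`` so results do not depend on
    iteration order.
    """
    if group_by not in ("bin", "class"):
        raise ValueError("group_by must be 'bin' or 'class'")
    order = COUNT_BINS if group_by == "bin" else CLASSES
    ss = _seed_seq(seed)
    records = []
    keys = sorted(
        {(s, g) for s, g in zip(obs["service_id"], obs[group_by])},
        key=lambda k: (k[0], order.index(k[1])),
    )
    children = ss.spawn(len(keys))
    for (svc, grp), child in zip(keys, children):
        sel = obs[(obs["service_id"] == svc) & (obs[group_by] == grp)]
        summ = summarize_group(
            sel["lnrr"], B=B, alpha=alpha, seed=child, service_id=svc, group=grp
        )
        records.append(
            {
                "service_id": svc,
                "group": grp,
                "n": summ.n,
                "n_studies": int(sel["study_id"].nunique()),
                "mean_lnrr": summ.mean_lnrr,
                "ci_low": summ.ci_low,
                "ci_high": summ.ci_high,
                "significant": summ.significant,
                "ci_defined": summ.ci_defined,
            }
        )
    return pd.DataFrame.from_records(records)


def stratify_by_aridity(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split rows into arid (aridity index < 1) and non-arid (>= 1) subsets.

    The boundary AI == 1 goes to non-arid (arid is defined strictly below 1).
    Rows with missing aridity index are dropped with a logged warning.
    """
    if "aridity_index" not in df.columns:
        raise ValueError("aridity_index column required for stratification")
    missing = df["aridity_index"].isna()
    if missing.any():
        logger.warning("dropped %d rows with missing aridity index", int(missing.sum()))
        df = df.loc[~missing]
    arid = df[df["aridity_index"] < 1.0]
    non_arid = df[df["aridity_index"] >= 1.0]
    return arid, non_arid


def tabulate_counts(obs: pd.DataFrame) -> pd.DataFrame:
    """Observations (and studies) per practice-count bin with percent shares.

    Percent = 100 * bin observation count / total observations, rounded to
    two decimals.
    """
    if obs.empty:
        raise ValueError("empty observation table")
    total = len(obs)
    rows = []
    for b in COUNT_BINS:
        sel = obs[obs["bin"] == b]
        rows.append(
            {
                "bin": b,
                "n_obs": len(sel),
                "n_studies": int(sel["study_id"].nunique()) if len(sel) else 0,
                "percent": round(100.0 * len(sel) / total, 2),
            }
        )
    return pd.DataFrame(rows)


def per_practice_summary(
    obs: pd.DataFrame,
    axes: Sequence[str] = DEFAULT_AXES,
    B: int = 4999,
    alpha: float = 0.05,
    seed=None,
) -> pd.DataFrame:
    """Effect summary per practice axis over observations using that practice."""
    ss = _seed_seq(seed)
    children = ss.spawn(len(axes))
    records = []
    for axis, child in zip(axes, children):
        if axis not in obs.columns:
            continue
        sel = obs[obs[axis] == 1]
        summ = summarize_group(sel["lnrr"], B=B, alpha=alpha, seed=child, group=axis)
        records.append(
            {
                "practice": axis,
                "n": summ.n,
                "mean_lnrr": summ.mean_lnrr,
                "ci_low": summ.ci_low,
                "ci_high": summ.ci_high,
                "significant": summ.significant,
            }
        )
    return pd.DataFrame.from_records(records)
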