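"""Environmental-driver analysis for service-level effect sizes.

Covariates are organised in four fixed predictor blocks (spatial, climate,
soil, vegetation).  The module provides collinearity screening by variance
inflation factors, Spearman rank correlations between covariates and effect
sizes, per-block least-squares fits with permutation significance, and a
four-block variance partitioning of adjusted R-squared by inclusion-exclusion
over the 15 non-empty block unions.

With a univariate response (one service's LnRR vector) a redundancy analysis
degenerates to ordinary multiple linear regression, and the partitioning is
computed directly from subset-model adjusted R-squared values rather than
delegated to an external routine.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Predictor block membership.  ``lat`` doubles as the latitude coordinate of
#: the observation; the remaining 14 names are the covariate columns of the
#: database schema.
BLOCKS: dict[str, tuple[str, ...]] = {
    "spatial": ("lat", "elevation", "slope"),
    "climate": ("aridity_index", "mat", "mdr", "tsea", "psea"),
    "soil": ("ph", "sand", "soc", "total_p"),
    "vegetation": ("plant_cover", "ndvi", "lai"),
}

BLOCK_NAMES: tuple[str, ...] = tuple(BLOCKS)

#: The 14 per-site covariate columns (latitude is stored as ``lat`` in the
#: core schema and re-used by the spatial block).
COVARIATE_COLUMNS: tuple[str, ...] = tuple(
    c for cols in BLOCKS.values() for c in cols if c != "lat"
)

VIF_THRESHOLD = 5.0


# ---------------------------------------------------------------------------
# least-squares helpers


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R-squared of an intercept-included least-squares fit."""
    y = np.asarray(y, dtype=float)
    D = _design(X)
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("response has zero variance; R^2 undefined")
    return 1.0 - float(resid @ resid) / ss_tot


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R-squared: ``1 - (1 - r2) * (n - 1) / (n - p - 1)``.

    Raises
    ------
    ValueError
        If ``n <= p + 1`` (no residual degrees of freedom).
    """
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


# ---------------------------------------------------------------------------
# collinearity screening


def vif(X: pd.DataFrame | np.ndarray) -> pd.Series:
    """Variance inflation factor per predictor.

    ``VIF_j = 1 / (1 - R^2_j)`` where predictor j is regressed on all the
    others (with intercept).  Exact linear dependence yields ``inf``.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(M.shape[1])]
    n, p = M.shape
    if p < 2:
        raise ValueError("VIF needs at least two predictors")
    if n <= p + 1:
        raise ValueError("VIF needs more rows than predictors")
    if np.any(M.std(axis=0) == 0):
        raise ValueError("constant column in predictor matrix")
    out = np.empty(p)
    for j in range(p):
        others = np.delete(M, j, axis=1)
        r2 = _ols_r2(M[:, j], others)
        out[j] = np.inf if r2 >= 1.0 - 1e-10 else 1.0 / (1.0 - r2)
    return pd.Series(out, index=names, name="vif")


def flag_collinear(vifs: pd.Series, threshold: float = VIF_THRESHOLD) -> list[str]:
    """Names of predictors whose VIF exceeds ``threshold`` (or is infinite)."""
    return [str(k) for k, v in vifs.items() if v > threshold]


def screen_collinear(
    X: pd.DataFrame, threshold: float = VIF_THRESHOLD
) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop the worst-VIF predictor until all VIFs <= threshold.

    Returns the screened frame and the list of dropped column names.
    """
    kept = X.copy()
    dropped: list[str] = []
    while kept.shape[1] >= 2:
        v = vif(kept)
        worst = v.idxmax()
        if v[worst] <= threshold:
            break
        kept = kept.drop(columns=[worst])
        dropped.append(str(worst))
        logger.info("collinearity screen dropped %s (VIF=%.3g)", worst, v[worst])
    return kept, dropped


# ---------------------------------------------------------------------------
# Spearman correlations


def spearman_assoc(X: pd.DataFrame, y: Sequence[float]) -> pd.DataFrame:
    """Spearman rho and two-sided p for each predictor column against ``y``.

    Ranks use average ranks for ties; p-values use the large-sample t
    approximation.  Constant columns yield NaN (undefined correlation).
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 4:
        raise ValueError("need n >= 4 paired values")
    if len(y) != len(X):
        raise ValueError("X and y must have the same length")
    rows = []
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append((col, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append((col, float(rho), float(p)))
    return pd.DataFrame(rows, columns=["predictor", "rho", "p"]).set_index("predictor")


# ---------------------------------------------------------------------------
# per-block fits with permutation significance


@dataclass(frozen=True)
class BlockFit:
    r2: float
    adj_r2: float
    p: float
    n_perm: int
    n: int
    n_predictors: int


def block_fit(
    y: Sequence[float],
    X: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> BlockFit:
    """Least-squares fit of ``y`` on one predictor block with permutation p.

    p = (1 + #{R^2_perm >= R^2_obs}) / (1 + n_perm), never zero.  Rank
    deficiency is tolerated (lstsq minimum-norm solution) with a warning.
    """
    y = np.asarray(y, dtype=float)
    M = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if M.ndim == 1:
        M = M[:, None]
    n, p_cols = M.shape
    if n <= p_cols + 1:
        raise ValueError("need n > block size + 1")
    D = _design(M)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        warnings.warn("rank-deficient predictor block; dependent columns ignored")
    # Orthonormal basis of the column span gives R^2 for every permuted copy
    # as one matrix product.
    Q, _ = np.linalg.qr(D)
    ybar = y.mean()
    sst = float(np.sum((y - ybar) ** 2))
    if sst == 0.0:
        raise ValueError("response has zero variance")

    def _r2_many(Y: np.ndarray) -> np.ndarray:
        proj = Q.T @ Y
        ss_model = (proj**2).sum(axis=0) - len(y) * ybar**2
        return ss_model / sst

    r2_obs = float(_r2_many(y[:, None])[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for k in range(n_perm):
        perms[:, k] = rng.permutation(y)
    r2_perm = _r2_many(perms)
    p_val = (1.0 + int(np.sum(r2_perm >= r2_obs))) / (1.0 + n_perm)
    rank_p = int(np.linalg.matrix_rank(D)) - 1
    return BlockFit(
        r2=r2_obs,
        adj_r2=adjusted_r2(r2_obs, n, rank_p),
        p=p_val,
        n_perm=n_perm,
        n=n,
        n_predictors=p_cols,
    )


# ---------------------------------------------------------------------------
# four-block variance partitioning


def _subsets(items: Sequence[int]):
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


@dataclass
class VariancePartition:
    """Adjusted-R^2 decomposition over four predictor blocks.

    ``fractions`` holds the 15 exactly-shared components keyed by
    '+'-joined block names (4 unique, 6 pairwise, 4 triple, 1 quadruple).
    Fractions may be negative, as usual for adjusted-R^2 partitions.
    """

    fractions: dict[str, float]
    total: float
    residual: float
    block_names: tuple[str, ...]
    subset_adj_r2: dict[str, float] = field(default_factory=dict)

    def unique(self, block: str) -> float:
        return self.fractions[block]

    @property
    def pooled_shared(self) -> float:
        uniques = sum(self.fractions[b] for b in self.block_names)
        return self.total - uniques

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, v) for k, v in self.fractions.items()]
        rows.append(("residual", self.residual))
        rows.append(("total", self.total))
        return pd.DataFrame(rows, columns=["component", "adj_r2_fraction"])


def varpart4(
    y: Sequence[float],
    blocks: Mapping[str, pd.DataFrame | np.ndarray],
) -> VariancePartition:
    """Partition the adjusted R-squared of ``y ~ all blocks`` into the 15
    unique/shared components of four predictor blocks.

    All 15 non-empty block unions are fitted; the exactly-shared fractions
    follow by Moebius inversion of G(V) = adjR2(all) - adjR2(complement of V).
    The fractions sum to the full-model adjusted R-squared by construction;
    residual = 1 - total.
    """
    if len(blocks) != 4:
        raise ValueError("varpart4 requires exactly four predictor blocks")
    names = tuple(blocks)
    mats = []
    for nm in names:
        B = blocks[nm]
        M = B.to_numpy(dtype=float) if isinstance(B, pd.DataFrame) else np.asarray(B, float)
        if M.ndim == 1:
            M = M[:, None]
        mats.append(M)
    y = np.asarray(y, dtype=float)
    n = len(y)
    p_total = sum(m.shape[1] for m in mats)
    if n <= p_total + 1:
        raise ValueError(
            f"insufficient n={n} for full model with {p_total} predictors "
            f"(blocks {'+'.join(names)})"
        )

    idx = tuple(range(4))
    adj: dict[frozenset, float] = {frozenset(): 0.0}
    for s in _subsets(idx):
        if not s:
            continue
        M = np.hstack([mats[i] for i in s])
        r2 = _ols_r2(y, M)
        adj[frozenset(s)] = adjusted_r2(r2, n, M.shape[1])

    full = frozenset(idx)
    g = {frozenset(): 0.0}
    for s in _subsets(idx):
        if s:
            g[frozenset(s)] = adj[full] - adj[full - frozenset(s)]

    fractions: dict[str, float] = {}
    for s in _subsets(idx):
        if not s:
            continue
        fs = frozenset(s)
        val = 0.0
        for t in _subsets(sorted(fs)):
            val += (-1) ** (len(fs) - len(t)) * g[frozenset(t)]
        key = "+".join(names[i] for i in sorted(fs))
        fractions[key] = val

    total = adj[full]
    subset_tbl = {
        "+".join(names[i] for i in sorted(s)): adj[frozenset(s)]
        for s in _subsets(idx)
        if s
    }
    return VariancePartition(
        fractions=fractions,
        total=total,
        residual=1.0 - total,
        block_names=names,
        subset_adj_r2=subset_tbl,
    )
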