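"""Spatial prediction of service-level effects on covariate grids.

Grids are abstract lattices (no projection handling): a 2D value array with
a cell size, an origin, and NaN as the missing marker.  The workflow is:
align covariate layers on a common lattice (block aggregation / resampling),
fit a replicated random-forest ensemble on observation-level effects, predict
per cell, mask non-analog environments by squared Mahalanobis distance
against a chi-square quantile, and standardise unmasked predictions to [0,1]
per scenario so low- and high-practice maps are comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# grid container and I/O


@dataclass
class Grid:
    """A single-layer lattice; NaN marks missing cells."""

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2D")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def with_values(self, values: np.ndarray) -> "Grid":
        return Grid(np.asarray(values, dtype=float), self.cell_size, self.origin)


def write_grid(grid: Grid, path) -> None:
    """Write a grid as CSV with a small '#'-prefixed header."""
    with open(path, "w") as fh:
        fh.write(f"# cell_size={grid.cell_size!r}\n")
        fh.write(f"# origin={grid.origin[0]!r},{grid.origin[1]!r}\n")
        fh.write("# missing=nan\n")
        np.savetxt(fh, grid.values, delimiter=",")


def read_grid(path) -> Grid:
    header: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                header[key.strip()] = val.strip()
            else:
                rows.append([float(v) for v in line.split(",")])
    ox, oy = (float(v) for v in header.get("origin", "0,0").split(","))
    return Grid(np.array(rows), float(header.get("cell_size", 1.0)), (ox, oy))


def _stack_layers(layers: Mapping[str, Grid], names: Sequence[str]) -> np.ndarray:
    """Stack aligned layers into an (n_cells, n_layers) matrix."""
    ref = layers[names[0]]
    for nm in names:
        if not layers[nm].aligned_with(ref):
            raise ValueError(f"layer {nm!r} not aligned with {names[0]!r}")
    return np.column_stack([layers[nm].values.ravel() for nm in names])


# ---------------------------------------------------------------------------
# aggregation / resampling


def aggregate_grid(fine: Grid, factor: int) -> Grid:
    """Block-mean aggregation by an integer factor, ignoring missing cells.

    Edge blocks average whatever cells are available; an all-missing block
    stays missing.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    if factor == 1:
        return Grid(fine.values.copy(), fine.cell_size, fine.origin)
    nr, nc = fine.shape
    out_r = -(-nr // factor)
    out_c = -(-nc // factor)
    out = np.full((out_r, out_c), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        for i in range(out_r):
            for j in range(out_c):
                block = fine.values[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
                out[i, j] = np.nanmean(block)
    return Grid(out, fine.cell_size * factor, fine.origin)


def resample_grid(grid: Grid, target_cell_size: float, method: str = "block_mean") -> Grid:
    """Resample onto a coarser lattice (target >= source cell size).

    ``block_mean`` averages the fine cells whose centres fall in each coarse
    cell; ``nearest`` samples the fine cell nearest each coarse-cell centre.
    """
    if target_cell_size <= 0:
        raise ValueError("target cell size must be positive")
    if target_cell_size < grid.cell_size:
        raise ValueError("upsampling (target < source cell size) not supported")
    if np.isclose(target_cell_size, grid.cell_size):
        return Grid(grid.values.copy(), grid.cell_size, grid.origin)
    ratio = target_cell_size / grid.cell_size
    if method == "block_mean" and np.isclose(ratio, round(ratio)):
        return aggregate_grid(grid, int(round(ratio)))
    nr, nc = grid.shape
    out_r = max(1, int(np.ceil(nr / ratio)))
    out_c = max(1, int(np.ceil(nc / ratio)))
    out = np.full((out_r, out_c), np.nan)
    fine_centers_r = (np.arange(nr) + 0.5) * grid.cell_size
    fine_centers_c = (np.arange(nc) + 0.5) * grid.cell_size
    if method == "block_mean":
        bin_r = np.minimum((fine_centers_r // target_cell_size).astype(int), out_r - 1)
        bin_c = np.minimum((fine_centers_c // target_cell_size).astype(int), out_c - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for i in range(out_r):
                for j in range(out_c):
                    block = grid.values[np.ix_(bin_r == i, bin_c == j)]
                    if block.size:
                        out[i, j] = np.nanmean(block)
    elif method == "nearest":
        coarse_r = (np.arange(out_r) + 0.5) * target_cell_size
        coarse_c = (np.arange(out_c) + 0.5) * target_cell_size
        ir = np.clip(np.searchsorted(fine_centers_r, coarse_r), 0, nr - 1)
        ic = np.clip(np.searchsorted(fine_centers_c, coarse_c), 0, nc - 1)
        out = grid.values[np.ix_(ir, ic)]
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return Grid(out, target_cell_size, grid.origin)


# ---------------------------------------------------------------------------
# random-forest ensemble


@dataclass
class RFEnsemble:
    """Replicated random forests; ensemble prediction = mean over replicates."""

    forests: list
    predictors: list[str]
    oob_r2: list[float]
    trees: int
    replicates: int
    seed: int | None = None
    rf_kwargs: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        M = X[self.predictors].to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        preds = np.stack([f.predict(M) for f in self.forests])
        return preds.mean(axis=0)

    def predict_spread(self, X) -> np.ndarray:
        """Std-dev across replicate forests (an uncertainty layer)."""
        M = X[self.predictors].to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        preds = np.stack([f.predict(M) for f in self.forests])
        return preds.std(axis=0)


def fit_rf_ensemble(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    trees: int = 999,
    replicates: int = 100,
    seed: int | None = None,
    **rf_kwargs,
) -> RFEnsemble:
    """Fit `replicates` independently-seeded forests of `trees` trees each.

    Feature sampling uses the regression heuristic (p/3 features per split);
    other hyperparameters stay at library defaults unless overridden.
    Out-of-bag R^2 is recorded per replicate.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        names = [f"x{j}" for j in range(M.shape[1])]
    y = np.asarray(y, dtype=float)
    if len(M) < 20:
        raise ValueError("need at least 20 training rows")
    if np.isnan(M).any():
        raise ValueError("missing values in predictors; screen before fitting")
    if np.all(y == y[0]):
        warnings.warn("constant response; forests will predict a constant")
    kwargs = {"max_features": 1.0 / 3.0}
    kwargs.update(rf_kwargs)
    ss = np.random.SeedSequence(seed)
    forests, oob = [], []
    for child in ss.spawn(replicates):
        rf = RandomForestRegressor(
            n_estimators=trees,
            oob_score=True,
            random_state=np.random.RandomState(child.generate_state(1)[0] % (2**32 - 1)),
            **kwargs,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # OOB warnings on tiny n
            rf.fit(M, y)
        forests.append(rf)
        oob.append(float(rf.oob_score_) if hasattr(rf, "oob_score_") else float("nan"))
    return RFEnsemble(
        forests=forests, predictors=names, oob_r2=oob,
        trees=trees, replicates=replicates, seed=seed, rf_kwargs=kwargs,
    )


def permutation_importance(
    model: RFEnsemble,
    X: pd.DataFrame | np.ndarray,
    y: Sequence[float],
    n_perm: int = 99,
    seed: int | None = None,
    n_repeats: int = 5,
) -> pd.DataFrame:
    """Permutation importance with a permutation-null p-value per predictor.

    Importance = mean increase in MSE when one predictor column is shuffled
    (averaged over ``n_repeats`` shuffles).  The null distribution comes from
    refitting the same ensemble configuration on response-permuted data
    ``n_perm`` times and recomputing the importances; p = (1 + #{null >=
    observed}) / (1 + n_perm).
    """
    if isinstance(X, pd.DataFrame):
        M = X[model.predictors].to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    def _importances(mod: RFEnsemble, reps: int) -> np.ndarray:
        base = float(np.mean((y - mod.predict(M)) ** 2))
        imp = np.zeros(M.shape[1])
        for j in range(M.shape[1]):
            col = M[:, j]
            if np.all(col == col[0]):
                continue  # permuting a constant column is the identity
            acc = 0.0
            for _ in range(reps):
                Xp = M.copy()
                Xp[:, j] = rng.permutation(col)
                acc += float(np.mean((y - mod.predict(Xp)) ** 2)) - base
            imp[j] = acc / reps
        return imp

    obs = _importances(model, n_repeats)
    null = np.empty((n_perm, M.shape[1]))
    for k, child in enumerate(ss.spawn(n_perm)):
        crng = np.random.default_rng(child)
        y_perm = crng.permutation(y)
        null_model = fit_rf_ensemble(
            M, y_perm, trees=model.trees, replicates=model.replicates,
            seed=child.generate_state(1)[0] % (2**31 - 1), **model.rf_kwargs,
        )
        base = float(np.mean((y_perm - null_model.predict(M)) ** 2))
        row = np.zeros(M.shape[1])
        for j in range(M.shape[1]):
            col = M[:, j]
            if np.all(col == col[0]):
                continue
            Xp = M.copy()
            Xp[:, j] = crng.permutation(col)
            row[j] = float(np.mean((y_perm - null_model.predict(Xp)) ** 2)) - base
        null[k] = row

    p = (1.0 + (null >= obs[None, :]).sum(axis=0)) / (1.0 + n_perm)
    return pd.DataFrame(
        {"importance": obs, "p": p}, index=pd.Index(model.predictors, name="predictor")
    )


# ---------------------------------------------------------------------------
# applicability masking and standardisation


def mahalanobis_sq(points: np.ndarray, training: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of rows of ``points`` to the training
    cloud (mean and covariance estimated from ``training``)."""
    T = np.asarray(training, dtype=float)
    P = np.asarray(points, dtype=float)
    if T.shape[0] <= T.shape[1]:
        raise ValueError("training set must have more rows than dimensions")
    mu = T.mean(axis=0)
    n, d = T.shape
    if n < 5 * d:
        # small-sample covariance is too noisy for reliable distances;
        # shrink towards a scaled identity
        from sklearn.covariance import LedoitWolf

        cov = LedoitWolf().fit(T).covariance_
        logger.info("Ledoit-Wolf shrinkage covariance used (n=%d, d=%d)", n, d)
    else:
        cov = np.cov(T, rowvar=False)
    cond = np.linalg.cond(cov)
    if cond > 1e12:
        logger.warning("near-singular training covariance (cond=%.3g); using pseudo-inverse", cond)
        vi = np.linalg.pinv(cov)
    else:
        vi = np.linalg.inv(cov)
    diff = P - mu
    return np.einsum("ij,jk,ik->i", diff, vi, diff)


def mahalanobis_mask(
    layers: Mapping[str, Grid],
    training: pd.DataFrame | np.ndarray,
    alpha: float = 0.95,
    df: int | None = None,
    predictors: Sequence[str] | None = None,
) -> Grid:
    """Boolean grid flagging non-analog cells (1 = masked).

    A cell is masked when its squared Mahalanobis distance to the training
    covariate cloud exceeds the chi-square quantile at ``alpha`` with ``df``
    degrees of freedom (default: the covariate dimension).  Cells with any
    missing covariate are masked.
    """
    if predictors is None:
        predictors = list(layers)
    if isinstance(training, pd.DataFrame):
        T = training[list(predictors)].to_numpy(dtype=float)
    else:
        T = np.asarray(training, dtype=float)
    stack = _stack_layers(layers, list(predictors))
    ref = layers[list(predictors)[0]]
    missing = np.isnan(stack).any(axis=1)
    d2 = np.full(stack.shape[0], np.inf)
    if (~missing).any():
        d2[~missing] = mahalanobis_sq(stack[~missing], T)
    dim = df if df is not None else T.shape[1]
    thresh = stats.chi2.ppf(alpha, dim)
    mask = (d2 > thresh).astype(float).reshape(ref.shape)
    return ref.with_values(mask)


def standardize01(grid: Grid, mask: Grid | None = None) -> Grid:
    """Min-max rescale to [0, 1] over unmasked finite cells.

    Masked/missing cells become NaN.  A constant grid maps to all zeros with
    a warning.
    """
    vals = grid.values.copy()
    valid = np.isfinite(vals)
    if mask is not None:
        if not mask.aligned_with(grid):
            raise ValueError("mask not aligned with grid")
        valid &= mask.values == 0
    if not valid.any():
        raise ValueError("no unmasked finite cells to standardise")
    vmin = vals[valid].min()
    vmax = vals[valid].max()
    out = np.full_like(vals, np.nan)
    if vmax == vmin:
        warnings.warn("constant grid; standardised values set to 0")
        out[valid] = 0.0
    else:
        out[valid] = (vals[valid] - vmin) / (vmax - vmin)
    return grid.with_values(out)


@dataclass(frozen=True)
class ValidationStats:
    slope: float
    intercept: float
    r2: float
    n: int


def validate_pred_obs(predicted: Sequence[float], observed: Sequence[float]) -> ValidationStats:
    """OLS of observed (y) on predicted (x): slope, intercept, R^2."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    if np.all(x == x[0]):
        raise ValueError("zero-variance predictions; regression undefined")
    res = stats.linregress(x, y)
    return ValidationStats(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2), n=len(x),
    )


SCENARIO_CODES = {"low-dependent": -1.0, "equivalent": 0.0, "high-dependent": 1.0}


def compare_scenarios(map_low: Grid, map_high: Grid, band: float = 0.1) -> Grid:
    """Classify cells by high - low against an equivalence band.

    Codes: -1 low-dependent (high - low < -band), 0 equivalent, +1
    high-dependent.  Missing cells stay NaN.
    """
    if not map_low.aligned_with(map_high):
        raise ValueError("scenario grids are not aligned")
    diff = map_high.values - map_low.values
    out = np.full(diff.shape, np.nan)
    ok = np.isfinite(diff)
    out[ok & (diff > band)] = 1.0
    out[ok & (diff < -band)] = -1.0
    out[ok & (np.abs(diff) <= band)] = 0.0
    return map_low.with_values(out)


def predict_grid(model: RFEnsemble, layers: Mapping[str, Grid]) -> Grid:
    """Per-cell ensemble prediction; cells with missing covariates stay NaN."""
    stack = _stack_layers(layers, model.predictors)
    ref = layers[model.predictors[0]]
    ok = ~np.isnan(stack).any(axis=1)
    out = np.full(stack.shape[0], np.nan)
    if ok.any():
        out[ok] = model.predict(stack[ok])
    return ref.with_values(out.reshape(ref.shape))
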