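"""Bioavailable 87Sr/86Sr isoscape fitting with random-forest regression.

Point samples of bioavailable Sr (plants, soils, low-mobility animals)
are joined to gridded covariates by nearest-cell lookup, redundant
covariates are removed (|Pearson r| > 0.9, order-stable greedy rule),
predictors are selected by noise-thresholded permutation importance, and
a random forest is fitted and evaluated by ten-fold cross-validation.
Spatial uncertainty comes from a quantile regression forest in the sense
of Meinshausen (2006): each query point receives a weight over training
responses from leaf co-occupancy, and the per-cell SD is half the width
of the central 68.27% prediction interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold

from .grids import Grid, Isoscape

log = logging.getLogger(__name__)

SD_FLOOR = 1e-6  # ratio units; keeps the SD grid strictly positive


@dataclass
class CovariateStack:
    """Named covariate grids sharing shape and georeferencing."""

    grids: dict[str, Grid]

    def __post_init__(self) -> None:
        if not self.grids:
            raise ValueError("stack needs at least one layer")
        names = list(self.grids)
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        first = next(iter(self.grids.values()))
        for name, g in self.grids.items():
            if g.shape != first.shape or g.cell_size != first.cell_size or g.origin != first.origin:
                raise ValueError(f"layer {name!r} does not share the stack georeferencing")

    @property
    def names(self) -> list[str]:
        return list(self.grids)

    @property
    def template(self) -> Grid:
        return next(iter(self.grids.values()))

    def as_feature_matrix(self, names: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (n_cells, n_layers) matrix and a valid-cell mask."""
        names = names or self.names
        cols = [self.grids[n].values.ravel() for n in names]
        X = np.column_stack(cols)
        valid = ~np.isnan(X).any(axis=1)
        return X, valid


def extract_covariates(samples: pd.DataFrame, stack: CovariateStack) -> pd.DataFrame:
    """One feature row per sampling site by nearest-cell lookup.

    ``samples`` needs ``x``/``y`` columns (metres).  Sites outside the
    stack extent or in no-data cells are dropped; the count is logged and
    reported in ``df.attrs['n_dropped']``.
    """
    tmpl = stack.template
    x = samples["x"].to_numpy(dtype=float)
    y = samples["y"].to_numpy(dtype=float)
    inside = tmpl.contains(x, y)
    rows = np.zeros(x.size, dtype=int)
    cols = np.zeros(x.size, dtype=int)
    rows[inside], cols[inside] = tmpl.index_of(x[inside], y[inside])
    data = {}
    for name, g in stack.grids.items():
        vals = np.full(x.size, np.nan)
        vals[inside] = g.values[rows[inside], cols[inside]]
        data[name] = vals
    feats = pd.DataFrame(data, index=samples.index)
    ok = inside & ~feats.isna().any(axis=1).to_numpy()
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("extract_covariates: dropped %d site(s) outside extent or in no-data cells",
                 n_dropped)
    out = feats.loc[ok]
    out.attrs["n_dropped"] = n_dropped
    return out


def filter_correlated(features: pd.DataFrame, threshold: float = 0.9
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Greedy removal of highly correlated covariates.

    For each pair with |Pearson r| > threshold the later-listed member is
    dropped; the scan is order-stable so results do not depend on dict
    ordering quirks.  Constant features (undefined r) are dropped with a
    warning.
    """
    if features.shape[1] < 2:
        raise ValueError("need at least two features to filter")
    dropped: list[str] = []
    cols = list(features.columns)
    for c in cols:
        if features[c].nunique() <= 1:
            warnings.warn(f"constant feature {c!r} dropped (correlation undefined)",
                          stacklevel=2)
            dropped.append(c)
    kept: list[str] = []
    for c in cols:
        if c in dropped:
            continue
        redundant = False
        for k in kept:
            r = stats.pearsonr(features[k], features[c]).statistic
            if abs(r) > threshold:
                redundant = True
                break
        if redundant:
            dropped.append(c)
        else:
            kept.append(c)
    return features[kept], dropped


def select_variables(
    features: pd.DataFrame,
    response: np.ndarray,
    seed: int = 0,
    n_trees: int = 500,
    n_repeats: int = 5,
) -> list[str]:
    """Noise-thresholded permutation-importance predictor selection.

    A pure-noise feature is appended, a forest is fitted on a random
    70% of the sites, and permutation importance is scored on the held
    30% (held-out scoring keeps overfit irrelevant features near zero
    importance).  Features are retained, ranked by importance, when they
    beat both the noise feature and a small floor (1% of the top
    importance), which guards against ties with the noise probe.  If
    everything falls below the bar the single best feature is kept with
    a warning.
    """
    if features.shape[1] < 1:
        raise ValueError("need at least one feature")
    rng = np.random.default_rng(seed)
    X = features.copy()
    X["__noise__"] = rng.standard_normal(len(X))
    y = np.asarray(response, dtype=float)
    n = len(X)
    perm = rng.permutation(n)
    n_train = max(int(0.7 * n), 2)
    tr, te = perm[:n_train], perm[n_train:]
    if te.size < 5:
        tr = te = perm
    forest = RandomForestRegressor(
        n_estimators=n_trees, random_state=int(rng.integers(2**31 - 1)), n_jobs=1
    )
    Xa = X.to_numpy()
    forest.fit(Xa[tr], y[tr])
    imp = permutation_importance(
        forest, Xa[te], y[te], n_repeats=n_repeats,
        random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
    ).importances_mean
    names = list(X.columns)
    noise_imp = imp[names.index("__noise__")]
    scored = [(names[i], imp[i]) for i in range(len(names)) if names[i] != "__noise__"]
    floor = max(noise_imp, 0.01 * max(nv[1] for nv in scored))
    kept = sorted([nv for nv in scored if nv[1] > floor], key=lambda nv: -nv[1])
    if not kept:
        best = max(scored, key=lambda nv: nv[1])
        warnings.warn("all features fall below the noise-importance bar; "
                      f"keeping the top feature {best[0]!r}", stacklevel=2)
        kept = [best]
    return [name for name, _ in kept]


def _leaf_weights(forest: RandomForestRegressor, X_train: np.ndarray,
                  X_query: np.ndarray) -> np.ndarray:
    """Meinshausen QRF weights: (n_query, n_train), rows sum to 1."""
    leaves_train = forest.apply(X_train)  # (n_train, T)
    leaves_query = forest.apply(X_query)  # (n_query, T)
    n_train, T = leaves_train.shape
    n_query = leaves_query.shape[0]
    W = np.zeros((n_query, n_train))
    for t in range(T):
        lt = leaves_train[:, t]
        lq = leaves_query[:, t]
        order = np.argsort(lt, kind="stable")
        sorted_leaves = lt[order]
        uniq, starts = np.unique(sorted_leaves, return_index=True)
        ends = np.append(starts[1:], n_train)
        pos = np.searchsorted(uniq, lq)
        pos = np.clip(pos, 0, uniq.size - 1)
        match = uniq[pos] == lq
        for u in np.unique(pos[match]):
            members = order[starts[u]: ends[u]]
            q_idx = np.flatnonzero(match & (pos == u))
            W[q_idx[:, None], members[None, :]] += 1.0 / members.size
    W /= T
    return W


def _weighted_quantiles(y_sorted: np.ndarray, W_sorted: np.ndarray,
                        levels: np.ndarray) -> np.ndarray:
    """Per-row weighted quantiles of ``y_sorted`` (ascending) under row
    weight matrices; returns (n_rows, n_levels)."""
    cum = np.cumsum(W_sorted, axis=1)
    total = cum[:, -1:]
    cum = cum / np.where(total > 0, total, 1.0)
    out = np.empty((W_sorted.shape[0], levels.size))
    for j, lev in enumerate(levels):
        idx = np.argmax(cum >= lev, axis=1)
        out[:, j] = y_sorted[idx]
    return out


@dataclass
class CVReport:
    rmse: float
    pct_var_explained: float
    n_folds: int
    fold_rmse: list[float] = field(default_factory=list)


def cross_validate(features: pd.DataFrame, response: np.ndarray, n_trees: int,
                   seed: int, n_folds: int = 10) -> CVReport:
    """K-fold CV of the forest; folds are site-random."""
    y = np.asarray(response, dtype=float)
    X = features.to_numpy()
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    preds = np.empty_like(y)
    fold_rmse = []
    for k, (tr, te) in enumerate(kf.split(X)):
        f = RandomForestRegressor(n_estimators=n_trees, random_state=seed + k, n_jobs=1)
        f.fit(X[tr], y[tr])
        preds[te] = f.predict(X[te])
        fold_rmse.append(float(np.sqrt(np.mean((preds[te] - y[te]) ** 2))))
    mse = float(np.mean((preds - y) ** 2))
    return CVReport(
        rmse=float(np.sqrt(mse)),
        pct_var_explained=float(100.0 * (1.0 - mse / np.var(y))),
        n_folds=n_folds,
        fold_rmse=fold_rmse,
    )


def fit_isoscape(
    features: pd.DataFrame,
    response: np.ndarray,
    stack: CovariateStack,
    n_trees: int = 3000,
    pi_level: float = 0.6827,
    seed: int = 0,
    min_samples_leaf: int = 5,
    cv_folds: int = 10,
) -> Isoscape:
    """Fit the forest, predict the mean surface, and derive the SD
    surface from the central ``pi_level`` quantile-forest prediction
    interval.  A ten-fold CV report is attached to the metadata.
    """
    y = np.asarray(response, dtype=float)
    if y.size < 20:
        raise ValueError("need at least 20 training points")
    if np.allclose(y, y[0]):
        raise ValueError("degenerate (constant) response: variance explained undefined")
    predictors = list(features.columns)
    cv = cross_validate(features, y, n_trees=n_trees, seed=seed, n_folds=cv_folds)
    forest = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, n_jobs=1,
        min_samples_leaf=min_samples_leaf,
    )
    X_train = features.to_numpy()
    forest.fit(X_train, y)

    X_all, valid = stack.as_feature_matrix(predictors)
    tmpl = stack.template
    mean_flat = np.full(X_all.shape[0], np.nan)
    sd_flat = np.full(X_all.shape[0], np.nan)
    Xq = X_all[valid]
    mean_flat[valid] = forest.predict(Xq)

    lo_lvl = 0.5 - pi_level / 2.0
    hi_lvl = 0.5 + pi_level / 2.0
    order = np.argsort(y, kind="stable")
    y_sorted = y[order]
    W = _leaf_weights(forest, X_train, Xq)[:, order]
    qs = _weighted_quantiles(y_sorted, W, np.array([lo_lvl, hi_lvl]))
    sd_flat[valid] = np.maximum((qs[:, 1] - qs[:, 0]) / 2.0, SD_FLOOR)

    meta = {
        "predictors": predictors,
        "n_trees": n_trees,
        "pi_level": pi_level,
        "min_samples_leaf": min_samples_leaf,
        "seed": seed,
        "cv_rmse": cv.rmse,
        "cv_pct_var_explained": cv.pct_var_explained,
        "cv_folds": cv.n_folds,
    }
    shape = tmpl.shape
    return Isoscape(
        tmpl.copy_with(mean_flat.reshape(shape)),
        tmpl.copy_with(sd_flat.reshape(shape)),
        metadata=meta,
    )


def predict_sd_at(
    forest: RandomForestRegressor,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_query: np.ndarray,
    pi_level: float = 0.6827,
) -> np.ndarray:
    """Quantile-forest SD at arbitrary query rows (used by tests and the
    calibration checks): half-width of the central ``pi_level`` interval."""
    order = np.argsort(y_train, kind="stable")
    W = _leaf_weights(forest, X_train, X_query)[:, order]
    lo, hi = 0.5 - pi_level / 2, 0.5 + pi_level / 2
    qs = _weighted_quantiles(y_train[order], W, np.array([lo, hi]))
    return np.maximum((qs[:, 1] - qs[:, 0]) / 2.0, SD_FLOOR)


def validate_points(isoscape: Isoscape, samples: pd.DataFrame) -> dict:
    """Held-out validation: RMSE and squared Pearson correlation of
    predicted vs observed ratios.  ``samples`` needs x, y, ratio."""
    if len(samples) < 3:
        raise ValueError("need at least three held-out points")
    pred = isoscape.mean.lookup(samples["x"].to_numpy(), samples["y"].to_numpy())
    obs = samples["ratio"].to_numpy(dtype=float)
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    r = stats.pearsonr(pred, obs).statistic
    return {"rmse": rmse, "r2": float(r**2), "n": int(len(samples))}
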