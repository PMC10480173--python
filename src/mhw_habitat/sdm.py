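"""Boosted-tree habitat suitability models.

The suitability model is a gradient-boosted decision-tree classifier with
bernoulli (binomial deviance) loss fitted to the presence/pseudo-absence
table: bag fraction 0.6, interaction depth ("tree complexity") 3, and a
learning rate chosen from a descending candidate list as the largest rate
at which at least ``min_trees`` boosting iterations survive early stopping
(default 2000 trees, candidates 1e-4 and 1e-5).  If no candidate sustains
``min_trees`` iterations, the model is refit at the smallest rate for
exactly ``min_trees`` trees with a warning — the tree-count floor is the
goal, the rate search merely serves it.

Predictions are daily suitability-probability rasters spatially constrained
to the minimum convex hull of the training points (presences *and*
pseudo-absences); cells outside the hull are missing, never 0.  Replicate
ensembles refit the model on label-stratified 75% row subsamples to expose
sensitivity to the input data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.ensemble import GradientBoostingClassifier

from .grid import grid_from_coords
from .occurrence import DAY_OF_YEAR, presence_hull, rasterize_mask

logger = logging.getLogger(__name__)

#: Covariates retained by the "temperature-only" model variant: the
#: temperature fields themselves plus the seasonal clock.
TEMPERATURE_COVARIATES = ("sst", "sst_sd", DAY_OF_YEAR)


@dataclass(frozen=True)
class ModelConfig:
    """Boosted-tree configuration.

    ``covariates`` is ``"full"`` (every covariate column present),
    ``"temperature-only"`` (SST, its spatial SD, and day-of-year), or an
    explicit tuple of column names.
    """

    bag_fraction: float = 0.6
    tree_complexity: int = 3
    learning_rates: tuple[float, ...] = (1e-4, 1e-5)
    min_trees: int = 2000
    covariates: str | tuple[str, ...] = "full"
    validation_fraction: float = 0.2
    n_iter_no_change: int = 10
    # strict improvement tolerance: at the shrunk learning rates used here
    # per-iteration holdout-loss gains are far below sklearn's 1e-4 default
    tol: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.bag_fraction <= 1.0):
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.min_trees < 1:
            raise ValueError("min_trees must be >= 1")
        if not self.learning_rates:
            raise ValueError("at least one learning-rate candidate required")


@dataclass
class SuitabilityModel:
    """A fitted suitability model plus the metadata needed to apply it."""

    estimator: GradientBoostingClassifier
    covariate_names: tuple[str, ...]
    hull: object  # shapely Polygon over (lon, lat)
    importance: pd.Series  # % of total split gain, sums to 100
    config: ModelConfig
    learning_rate: float
    n_trees: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Probability of presence for rows of covariates (no hull masking)."""
        return self.estimator.predict_proba(X)[:, 1]


def resolve_covariates(
    selection: str | tuple[str, ...], available: list[str]
) -> tuple[str, ...]:
    if selection == "full":
        return tuple(available)
    if selection == "temperature-only":
        chosen = tuple(c for c in TEMPERATURE_COVARIATES if c in available)
        if not chosen:
            raise ValueError(
                "temperature-only model requested but no temperature "
                f"covariates among {available}"
            )
        return chosen
    missing = [c for c in selection if c not in available]
    if missing:
        raise ValueError(f"requested covariates not in table: {missing}")
    return tuple(selection)


def _covariate_columns(occ: pd.DataFrame) -> list[str]:
    reserved = {"species", "individual", "date", "lon", "lat", "label", "fold"}
    return [c for c in occ.columns if c not in reserved]


def fit_model(occ: pd.DataFrame, config: ModelConfig = ModelConfig()) -> SuitabilityModel:
    """Fit the boosted-tree suitability model to a matched occurrence table.

    The training hull is the convex hull of all training points (both
    labels); it defines where predictions are valid.
    """
    labels = occ["label"].to_numpy()
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    min_rows = int(np.ceil(4.0 / config.bag_fraction))
    if len(occ) < min_rows:
        raise ValueError(f"need at least {min_rows} rows at bag fraction {config.bag_fraction}")

    cov_names = resolve_covariates(config.covariates, _covariate_columns(occ))
    X = occ[list(cov_names)].to_numpy(dtype=float)
    y = labels.astype(int)

    rates = sorted(config.learning_rates, reverse=True)
    est = None
    chosen_rate = rates[-1]
    for lr in rates:
        candidate = GradientBoostingClassifier(
            loss="log_loss",
            learning_rate=lr,
            n_estimators=config.min_trees,
            subsample=config.bag_fraction,
            max_depth=config.tree_complexity,
            validation_fraction=config.validation_fraction,
            n_iter_no_change=config.n_iter_no_change,
            tol=config.tol,
            random_state=config.seed,
        )
        candidate.fit(X, y)
        if candidate.n_estimators_ >= config.min_trees:
            est, chosen_rate = candidate, lr
            break
    if est is None:
        warnings.warn(
            f"no learning-rate candidate sustained {config.min_trees} trees; "
            f"fitting at rate {rates[-1]:g} for exactly {config.min_trees} trees",
            stacklevel=2,
        )
        est = GradientBoostingClassifier(
            loss="log_loss",
            learning_rate=rates[-1],
            n_estimators=config.min_trees,
            subsample=config.bag_fraction,
            max_depth=config.tree_complexity,
            random_state=config.seed,
        )
        est.fit(X, y)
        chosen_rate = rates[-1]

    imp = est.feature_importances_
    total = imp.sum()
    importance = pd.Series(
        100.0 * imp / total if total > 0 else np.full(len(imp), 100.0 / len(imp)),
        index=list(cov_names),
        name="relative_importance",
    )
    hull = presence_hull(occ["lon"], occ["lat"])
    logger.info(
        "fit_model: %d rows, lr=%g, %d trees", len(occ), chosen_rate, est.n_estimators_
    )
    return SuitabilityModel(
        estimator=est,
        covariate_names=cov_names,
        hull=hull,
        importance=importance,
        config=config,
        learning_rate=chosen_rate,
        n_trees=int(est.n_estimators_),
    )


def predict_daily(
    model: SuitabilityModel,
    env: xr.Dataset,
    dates=None,
) -> xr.DataArray:
    """Predict a daily suitability cube, masked to the training hull.

    ``day_of_year`` is derived from each prediction date, not read from the
    cube.  Raises if the cube lacks any model covariate; warns if the hull
    misses the grid entirely (all-missing output).
    """
    if dates is None:
        dates = pd.DatetimeIndex(env["time"].values)
    else:
        dates = pd.DatetimeIndex(dates)
    env_names = set(env.data_vars)
    needed = [c for c in model.covariate_names if c != DAY_OF_YEAR]
    missing = [c for c in needed if c not in env_names]
    if missing:
        raise ValueError(f"environment cube lacks model covariate(s): {missing}")

    grid = grid_from_coords(lats := env["lat"].values, lons := env["lon"].values,
                            res=env.attrs.get("resolution_deg"))
    res = grid.res
    hull_mask = rasterize_mask(grid, model.hull)
    if not hull_mask.any():
        warnings.warn("training hull contains no grid cells; predictions all-missing",
                      stacklevel=2)
    inside = np.flatnonzero(hull_mask.ravel())
    ncell = hull_mask.size

    env_t = env.sel(time=dates)
    out = np.full((len(dates), ncell), np.nan)
    doy_all = dates.dayofyear.to_numpy()
    for t in range(len(dates)):
        cols = []
        for name in model.covariate_names:
            if name == DAY_OF_YEAR:
                cols.append(np.full(inside.size, float(doy_all[t])))
            else:
                cols.append(env_t[name].values[t].ravel()[inside])
        X = np.column_stack(cols)
        finite = np.isfinite(X).all(axis=1)
        probs = np.full(inside.size, np.nan)
        if finite.any():
            probs[finite] = model.predict(X[finite])
        out[t, inside] = probs
    cube = xr.DataArray(
        out.reshape(len(dates), grid.nlat, grid.nlon),
        dims=("time", "lat", "lon"),
        coords={"time": dates, "lat": lats, "lon": lons},
        name="suitability",
    )
    cube.attrs["resolution_deg"] = res
    return cube


@dataclass
class ReplicateEnsemble:
    """Suitability models refit on independent 75% subsamples."""

    models: list[SuitabilityModel]
    subsample_indices: list[np.ndarray]
    fraction: float
    seeds: list[int]


def fit_ensemble(
    occ: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    n_replicates: int = 20,
    fraction: float = 0.75,
    seed: int = 0,
) -> ReplicateEnsemble:
    """Fit ``n_replicates`` models to label-stratified row subsamples.

    Subsamples are drawn without replacement; per-replicate seeds are
    spawned deterministically from the master seed.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    ss = np.random.SeedSequence([seed, 5])  # stage id 5: ensemble
    child_seeds = [int(s) for s in ss.generate_state(n_replicates) % (2**31)]
    label = occ["label"].to_numpy()
    idx_by_class = [np.flatnonzero(label == c) for c in np.unique(label)]

    models, subsets = [], []
    for r in range(n_replicates):
        rng = np.random.default_rng(child_seeds[r])
        take = []
        for idx in idx_by_class:
            k = int(round(fraction * len(idx)))
            take.append(rng.choice(idx, size=k, replace=False))
        sub = np.sort(np.concatenate(take))
        rep_config = replace(config, seed=child_seeds[r])
        models.append(fit_model(occ.iloc[sub].reset_index(drop=True), rep_config))
        subsets.append(sub)
    return ReplicateEnsemble(
        models=models, subsample_indices=subsets, fraction=fraction, seeds=child_seeds
    )


def validate_auc(scores, labels) -> float:
    """Rank-based AUC (Mann-Whitney): ties between classes get half credit."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("validation set must contain both classes")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def kfold_auc(
    occ: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    n_folds: int = 5,
    scheme: str = "random",
    seed: int = 0,
) -> pd.Series:
    """Cross-validated AUC: random k-fold (default) or leave-one-year-out."""
    if scheme == "random":
        rng = np.random.default_rng(seed)
        folds = rng.integers(0, n_folds, size=len(occ))
        fold_ids = np.arange(n_folds)
    elif scheme == "loyo":
        years = pd.to_datetime(occ["date"]).dt.year.to_numpy()
        fold_ids = np.unique(years)
        folds = years
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")
    aucs = {}
    cov_names = None
    for f in fold_ids:
        train = occ.loc[folds != f].reset_index(drop=True)
        test = occ.loc[folds == f]
        if test.empty or train["label"].nunique() < 2 or test["label"].nunique() < 2:
            continue
        model = fit_model(train, config)
        cov_names = cov_names or model.covariate_names
        scores = model.predict(test[list(model.covariate_names)].to_numpy(dtype=float))
        aucs[f] = validate_auc(scores, test["label"].to_numpy())
    return pd.Series(aucs, name="auc")
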