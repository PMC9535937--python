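"""Conventional random-forest land-use regression (RF_LUR).

Protocol: the mobile training data are split 70/30; a discrete grid over
the three forest hyperparameters (number of trees, number of random split
candidates ``m_try``, maximum terminal nodes) is searched by five-fold
cross-validation on the 70 % part, scoring squared Pearson correlation;
the chosen model is then refit and checked for overfitting by comparing
training and 30 %-test accuracy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, train_test_split

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFConfig:
    """Forest hyperparameters: all counts >= 1; ``m_try`` <= n covariates.

    ``max_terminal_nodes=None`` grows trees unbounded.
    """

    n_trees: int = 500
    m_try: int | None = None          # None -> p/3, the regression default
    max_terminal_nodes: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.m_try is not None and self.m_try < 1:
            raise ValueError("m_try must be >= 1")
        if self.max_terminal_nodes is not None and self.max_terminal_nodes < 2:
            raise ValueError("max_terminal_nodes must be >= 2")


@dataclass
class FitReport:
    train_r2: float
    test_r2: float
    cv_scores: dict
    config: RFConfig


def default_grid(p: int, seed: int = 0) -> list[RFConfig]:
    """Discrete search grid over the three tuned hyperparameters."""
    mtrys = sorted({max(1, p // 3), max(1, int(np.sqrt(p))), max(1, p // 2)})
    grid = []
    for n_trees in (250, 500, 1000):
        for m_try in mtrys:
            for leaves in (None, 128, 512):
                grid.append(RFConfig(n_trees, m_try, leaves, seed))
    return grid


def squared_pearson(pred, obs) -> float:
    """Squared Pearson correlation between predictions and observations."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if np.std(pred) == 0 or np.std(obs) == 0:
        raise ValueError("squared Pearson undefined for zero-variance input")
    return float(stats.pearsonr(pred, obs)[0] ** 2)


def split_70_30(X: pd.DataFrame, y, seed: int):
    """Reproducible 70/30 train/test split (disjoint, exhaustive)."""
    y = np.asarray(y, float)
    if len(y) < 10:
        raise ValueError("need at least 10 samples for a 70/30 split")
    idx = np.arange(len(y))
    tr, te = train_test_split(idx, test_size=0.3, random_state=seed, shuffle=True)
    return (X.iloc[tr], y[tr]), (X.iloc[te], y[te])


def fit_rf(X, y, config: RFConfig, sample_weights=None) -> RandomForestRegressor:
    """Fit a bagged regression forest under ``config``.

    Uniform weights reproduce the unweighted fit exactly at a fixed seed,
    and rescaling all weights leaves the fit invariant.
    """
    if sample_weights is not None:
        sample_weights = np.asarray(sample_weights, float)
        if np.any(sample_weights < 0):
            raise ValueError("sample weights must be nonnegative")
        if not np.any(sample_weights > 0):
            raise ValueError("sample weights must not be all zero")
        if np.ptp(sample_weights) == 0:
            # uniform weights are the unweighted fit by contract; dropping
            # them keeps the bootstrap RNG stream identical to sklearn's
            # unweighted path
            sample_weights = None
    p = np.shape(X)[1]
    m_try = config.m_try if config.m_try is not None else max(1, p // 3)
    forest = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=min(m_try, p),
        max_leaf_nodes=config.max_terminal_nodes,
        random_state=config.seed,
        bootstrap=True,
    )
    forest.fit(X, np.asarray(y, float), sample_weight=sample_weights)
    return forest


def tune_rf(
    X: pd.DataFrame,
    y,
    grid: list[RFConfig] | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[RFConfig, dict]:
    """Pick the grid point with the best mean k-fold CV squared Pearson R².

    Fold assignments are fixed once and shared by every grid point.  Folds
    in which the held-out targets have zero variance are excluded with a
    warning (their R² is undefined).
    """
    y = np.asarray(y, float)
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if grid is None:
        grid = default_grid(X.shape[1], seed)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(X))
    cv_scores: dict[RFConfig, float] = {}
    for cfg in grid:
        scores = []
        for tr, te in folds:
            if np.std(y[te]) == 0:
                logger.warning("tune_rf: zero-variance fold excluded")
                continue
            forest = fit_rf(X.iloc[tr], y[tr], cfg)
            scores.append(squared_pearson(forest.predict(X.iloc[te]), y[te]))
        cv_scores[cfg] = float(np.mean(scores)) if scores else -np.inf
    best = max(grid, key=lambda c: cv_scores[c])  # first max wins ties
    return best, cv_scores


def overfit_check(train_r2: float, test_r2: float, tolerance: float = 0.05) -> bool:
    """Model counts as not overfitting when train R² − test R² <= tolerance."""
    for v in (train_r2, test_r2):
        if not 0 <= v <= 1:
            raise ValueError("R² values must lie in [0, 1]")
    return (train_r2 - test_r2) <= tolerance


def train_rf_lur(
    X: pd.DataFrame, y, seed: int = 0, grid=None, k: int = 5,
    overfit_tolerance: float = 0.05,
) -> tuple[RandomForestRegressor, FitReport]:
    """Full RF_LUR training protocol: split, tune, refit, overfit check."""
    (X_tr, y_tr), (X_te, y_te) = split_70_30(X, y, seed)
    best, cv_scores = tune_rf(X_tr, y_tr, grid, k=k, seed=seed)
    forest = fit_rf(X_tr, y_tr, best)
    report = FitReport(
        train_r2=squared_pearson(forest.predict(X_tr), y_tr),
        test_r2=squared_pearson(forest.predict(X_te), y_te),
        cv_scores={str(cfg): s for cfg, s in cv_scores.items()},
        config=best,
    )
    if not overfit_check(report.train_r2, report.test_r2, overfit_tolerance):
        logger.warning(
            "RF_LUR overfit check failed: train R²=%.3f test R²=%.3f",
            report.train_r2, report.test_r2,
        )
    return forest, report


def save_rf(forest: RandomForestRegressor, config: RFConfig, path) -> None:
    """Persist the forest with a JSON sidecar recording config and seed."""
    import joblib

    joblib.dump(forest, path)
    with open(str(path) + ".json", "w") as fh:
        json.dump(asdict(config), fh, indent=2)


def load_rf(path) -> tuple[RandomForestRegressor, RFConfig]:
    import joblib

    forest = joblib.load(path)
    with open(str(path) + ".json") as fh:
        cfg = RFConfig(**json.load(fh))
    return forest, cfg
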