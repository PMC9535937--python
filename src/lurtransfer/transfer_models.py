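"""Instance-based transfer-learning LUR models.

Two ways of carrying mobile-monitoring knowledge (the *source* domain)
into the long-term near-road domain (the *target*):

``Prior_RF``
    Domain adaptation by risk reweighting: every mobile training instance
    is weighted by the RuLSIF estimate of the target/source density ratio
    evaluated at its concentration, and the weighted instances are fed to
    the conventional random forest.  Forest hyperparameters are kept
    identical to the RF_LUR baseline so the two differ only in weighting.

``TrAdaBoost`` (Two-stage TrAdaBoost.R2)
    Boosting-based instance transfer: mobile (source) and long-term
    (target) instances are merged with equal initial weights.  Over S
    steps the total source weight is lowered on a fixed schedule (stage
    one); within each step AdaBoost.R2 runs with the source weights frozen
    so only target weights adapt (stage two).  The step whose ensemble
    has the lowest cross-validated error on the target instances wins.

The internal AdaBoost.R2 uses loss-scaled adjusted errors, multiplicative
weight updates and a weighted-median ensemble prediction, with a mask of
frozen instances whose weights only change through renormalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .density_ratio import RatioModel, RuLSIFConfig, evaluate_ratio, fit_rulsif
from .rf_baseline import RFConfig, fit_rf

logger = logging.getLogger(__name__)

#: Depth cap of the boosting base learner (a regression tree).
BASE_LEARNER_MAX_DEPTH = 6

LOSSES = ("linear", "square", "exponential")


@dataclass
class InstanceSet:
    """Training instances from one domain with nonnegative weights."""

    X: pd.DataFrame
    y: np.ndarray
    domain: str                      # "source" | "target"
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.y):
                raise ValueError("weights length differs")
            if np.sum(self.weights) <= 0:
                raise ValueError("weights must have positive sum")

    def __len__(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# AdaBoost.R2 with a frozen-instance mask
# ---------------------------------------------------------------------------

@dataclass
class AdaBoostR2:
    learners: list
    log_betas: np.ndarray            # ensemble weights log(1/β_m)
    weight_history: np.ndarray       # (n_iter + 1, n) rows sum to 1

    def predict(self, X) -> np.ndarray:
        preds = np.vstack([lr.predict(X) for lr in self.learners])
        return weighted_median(preds, self.log_betas)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Column-wise weighted median of ``values`` (m learners × n samples).

    The smallest value whose cumulative weight reaches half the total;
    with a single learner this is that learner's prediction.
    """
    weights = np.asarray(weights, float)
    if values.shape[0] == 1:
        return values[0]
    if np.sum(weights) <= 0:  # degenerate: all β=1 -> plain median
        weights = np.ones_like(weights)
    order = np.argsort(values, axis=0)
    w_sorted = weights[order]
    cum = np.cumsum(w_sorted, axis=0)
    take = cum >= 0.5 * np.sum(weights)
    first = np.argmax(take, axis=0)
    cols = np.arange(values.shape[1])
    return values[order[first, cols], cols]


def _adjusted_errors(resid_abs: np.ndarray, D: float, loss: str) -> np.ndarray:
    r = resid_abs / D
    if loss == "linear":
        return r
    if loss == "square":
        return r**2
    if loss == "exponential":
        return 1.0 - np.exp(-r)
    raise ValueError(f"loss must be one of {LOSSES}, got {loss!r}")


def _make_base_learner(random_state: int) -> DecisionTreeRegressor:
    return DecisionTreeRegressor(
        max_depth=BASE_LEARNER_MAX_DEPTH, random_state=random_state
    )


def fit_adaboost_r2(
    X,
    y,
    weights=None,
    n_estimators: int = 30,
    loss: str = "linear",
    frozen_mask=None,
    seed=0,
    base_learner_factory=_make_base_learner,
) -> AdaBoostR2:
    """Classic AdaBoost.R2 with an optional mask of frozen instances.

    Per iteration: fit the weighted base learner; scale absolute residuals
    by their maximum D; map them through the loss to adjusted errors e_i;
    form the weighted error ε = Σ w_i e_i; stop if ε ≥ 0.5; otherwise set
    β = ε/(1−ε), multiply unfrozen weights by β^(1−e_i) and renormalize
    everything.  A learner that fits perfectly (D = 0) terminates the
    ensemble with a dominant weight.  Frozen instances keep their relative
    weights except for the common renormalization.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = np.ones(n) / n if weights is None else np.asarray(weights, float).copy()
    if np.sum(w) <= 0:
        raise ValueError("weights must have positive sum")
    w = w / np.sum(w)
    frozen = (
        np.zeros(n, dtype=bool) if frozen_mask is None
        else np.asarray(frozen_mask, dtype=bool)
    )
    rng = np.random.default_rng(seed)

    learners, log_betas, history = [], [], [w.copy()]
    for _ in range(n_estimators):
        lr = base_learner_factory(int(rng.integers(2**31 - 1)))
        lr.fit(X, y, sample_weight=w)
        resid = np.abs(y - lr.predict(X))
        D = resid.max()
        if D <= 1e-10 * max(1.0, float(np.max(np.abs(y)))):  # perfect fit
            # perfect fit: this learner alone decides the prediction
            learners.append(lr)
            log_betas.append(np.log(1.0 / np.finfo(float).tiny) / 2)
            history.append(w.copy())
            break
        e = _adjusted_errors(resid, D, loss)
        eps = float(np.sum(w * e))
        if eps >= 0.5:
            if not learners:
                # keep one learner so the ensemble is usable; its weight is
                # ~0 relative weight only matters with >1 learner anyway
                learners.append(lr)
                log_betas.append(np.log(1.0 / 0.999))
                history.append(w.copy())
            logger.info("AdaBoost.R2 stopped: weighted error %.3f >= 0.5", eps)
            break
        beta = eps / (1.0 - eps)
        learners.append(lr)
        log_betas.append(np.log(1.0 / beta))
        # multiplicative update on the unfrozen block only; renormalize that
        # block to its previous mass so frozen weights are truly untouched
        # (with nothing frozen this is the standard renormalization to 1)
        upd = ~frozen
        mass = np.sum(w[upd])
        w[upd] = w[upd] * beta ** (1.0 - e[upd])
        new_mass = np.sum(w[upd])
        if new_mass > 0:
            w[upd] *= mass / new_mass
        w = w / np.sum(w)
        history.append(w.copy())
    return AdaBoostR2(learners, np.asarray(log_betas), np.vstack(history))


# ---------------------------------------------------------------------------
# Two-stage TrAdaBoost.R2
# ---------------------------------------------------------------------------

@dataclass
class TransferEnsemble:
    """A fitted transfer model: Prior_RF forest or TrAdaBoost step ensembles."""

    method: str                              # "prior_rf" | "tradaboost"
    forest: RandomForestRegressor | None = None
    ratio_model: RatioModel | None = None
    instance_weights: np.ndarray | None = None
    step_ensembles: list[AdaBoostR2] = field(default_factory=list)
    step_cv_errors: np.ndarray | None = None
    chosen_step: int | None = None
    seed: int = 0

    def predict(self, X) -> np.ndarray:
        if self.method == "prior_rf":
            if self.forest is None:
                raise ValueError("ensemble not fitted")
            pred = self.forest.predict(X)
        elif self.method == "tradaboost":
            if not self.step_ensembles:
                raise ValueError("ensemble not fitted")
            pred = self.step_ensembles[self.chosen_step].predict(X)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        n_floor = int(np.sum(pred < 0))
        if n_floor:
            logger.info("predict: %d negative predictions floored at 0", n_floor)
            pred = np.maximum(pred, 0.0)
        return pred


def predict(ensemble: TransferEnsemble, X) -> np.ndarray:
    """Module-level alias for :meth:`TransferEnsemble.predict`."""
    return ensemble.predict(X)


def fit_prior_rf(
    source: InstanceSet,
    target_y,
    rf_config: RFConfig,
    rulsif_config: RuLSIFConfig | None = None,
) -> TransferEnsemble:
    """Ratio-reweighted random forest.

    The RuLSIF ratio of the long-term (target) to mobile (source)
    concentration distribution, evaluated at each source instance's
    concentration, becomes its sample weight in an otherwise conventional
    forest fit under the baseline's own ``rf_config``.
    """
    target_y = np.asarray(target_y, dtype=float)
    if len(source) == 0 or len(target_y) == 0:
        raise ValueError("source and target must be nonempty")
    ratio = fit_rulsif(target_y, source.y, rulsif_config)
    w = evaluate_ratio(ratio, source.y)
    forest = fit_rf(source.X, source.y, rf_config, sample_weights=w)
    return TransferEnsemble(
        method="prior_rf", forest=forest, ratio_model=ratio,
        instance_weights=w, seed=rf_config.seed,
    )


def target_weight_schedule(n_s: int, n_t: int, t: int, S: int) -> float:
    """Stage-one target-weight fraction at step t of S.

    Rises linearly from the natural fraction n_t/(n_s+n_t) at t=0 to 1 at
    t=S−1, progressively de-emphasizing the source domain.
    """
    base = n_t / (n_s + n_t)
    return base + (t / (S - 1)) * (1.0 - base)


def _deemphasize_source(
    w: np.ndarray, is_source: np.ndarray, e: np.ndarray, fraction: float,
    tol: float = 1e-6, max_iter: int = 100,
) -> np.ndarray:
    """Stage-one source update: w_i ← w_i·β^{e_i} on source instances, with
    β found by bisection in (0, 1] so the target fraction of total weight
    equals ``fraction``.

    Source instances the current hypothesis predicts badly (large adjusted
    error e_i, i.e. the ones most unlike the target data) are scaled down
    hardest.  If the fraction is unreachable — e.g. many source errors are
    exactly zero so their weights cannot shrink — β clamps at the nearest
    achievable value and the shortfall is logged.
    """
    W_t = float(np.sum(w[~is_source]))
    if W_t == 0:
        raise ValueError("target instances must carry positive weight")
    w_s = w[is_source]
    e_s = e[is_source]

    def frac(beta: float) -> float:
        return W_t / (float(np.sum(w_s * beta**e_s)) + W_t)

    if frac(1.0) >= fraction:       # already at or past the schedule
        return w / np.sum(w)
    # frac(β) is monotone non-increasing in β on (0, 1]
    lo, hi = 0.0, 1.0               # frac(lo≈0) is the max achievable
    if frac(1e-300) < fraction:
        logger.warning(
            "schedule fraction %.3f unreachable (max %.3f); clamping",
            fraction, frac(1e-300),
        )
    for _ in range(max_iter):
        beta = 0.5 * (lo + hi)
        if frac(beta) < fraction:
            hi = beta
        else:
            lo = beta
        if abs(frac(beta) - fraction) < tol:
            break
    out = w.copy()
    out[is_source] = w_s * beta**e_s
    return out / np.sum(out)


def fit_two_stage_tradaboost_r2(
    source: InstanceSet,
    target: InstanceSet,
    S: int = 10,
    n_estimators: int = 30,
    cv_folds: int = 5,
    seed: int = 0,
    loss: str = "linear",
) -> TransferEnsemble:
    """Two-stage TrAdaBoost.R2 with CV-based step selection.

    Source and target instances are merged with equal initial weights.
    At step t the source weight is scaled down so the target fraction
    follows :func:`target_weight_schedule`; AdaBoost.R2 then runs with all
    source instances frozen.  Each step is scored by ``cv_folds``-fold
    cross-validated MSE on the target instances alone, and the best step's
    ensemble is returned.  Deterministic given ``seed``.
    """
    if S < 2:
        raise ValueError("need S >= 2 schedule steps")
    n_s, n_t = len(source), len(target)
    if n_t == 0:
        raise ValueError("target set must be nonempty")
    if n_t < cv_folds:
        logger.info("cv_folds reduced from %d to %d (small target set)",
                    cv_folds, n_t)
        cv_folds = max(2, n_t)
    X = pd.concat([source.X, target.X], ignore_index=True) if n_s else \
        target.X.reset_index(drop=True)
    y = np.concatenate([source.y, target.y]) if n_s else target.y
    n = n_s + n_t
    is_source = np.arange(n) < n_s
    w_init = np.ones(n) / n

    folds = list(
        KFold(n_splits=cv_folds, shuffle=True, random_state=seed).split(
            np.arange(n_t)
        )
    )
    X_t = X.iloc[n_s:]
    y_t = y[n_s:]

    rng = np.random.default_rng([seed, 1])
    step_ensembles: list[AdaBoostR2] = []
    cv_errors = np.empty(S)
    w = w_init.copy()
    for t in range(S):
        fold_errs = []
        for f, (tr_t, te_t) in enumerate(folds):
            keep = np.concatenate([np.arange(n_s), n_s + np.asarray(tr_t)])
            ens = fit_adaboost_r2(
                X.iloc[keep], y[keep], weights=w[keep],
                n_estimators=n_estimators, loss=loss,
                frozen_mask=is_source[keep], seed=[seed, t, f],
            )
            resid = ens.predict(X_t.iloc[te_t]) - y_t[te_t]
            fold_errs.append(float(np.mean(resid**2)))
        cv_errors[t] = np.mean(fold_errs)
        step_ensembles.append(
            fit_adaboost_r2(
                X, y, weights=w, n_estimators=n_estimators, loss=loss,
                frozen_mask=is_source, seed=seed,
            )
        )
        if t < S - 1 and n_s:
            # stage one: de-emphasize the source instances this step's own
            # ensemble finds hardest (the ones most unlike the target data),
            # moving the target weight fraction to the next schedule point
            resid = np.abs(y - step_ensembles[-1].predict(X))
            D = resid.max()
            e = _adjusted_errors(resid, D, loss) if D > 0 else np.zeros(n)
            frac_next = target_weight_schedule(n_s, n_t, t + 1, S)
            w = _deemphasize_source(w, is_source, e, frac_next)
    chosen = int(np.argmin(cv_errors))
    return TransferEnsemble(
        method="tradaboost", step_ensembles=step_ensembles,
        step_cv_errors=cv_errors, chosen_step=chosen, seed=seed,
    )
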