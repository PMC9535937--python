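"""Validation protocol against external long-term near-road measurements.

Segment-level predictions are compared with long-term site observations by
averaging predictions over the road segments within the matching radius of
each site.  Three metrics summarise agreement: nMAE and nRMSE (MAE and
RMSE normalized by the mean of the validation observations) and the
squared Pearson correlation R².

The repeat design mirrors the study protocol: TrAdaBoost needs long-term
instances in training, so each iteration draws a fresh 50/50 split of the
sites (⌈n/2⌉ train, ⌊n/2⌋ validate), trains on one half and validates on
the other; SLR is fit once on the mobile data (no resampling); RF_LUR and
Prior_RF are refit per iteration on a bootstrap resample of the mobile
segments and validated on the full site set; the sensitivity variants
RF_LUR_half and Prior_RF_half validate on the same half-set TrAdaBoost
uses.  Summaries are mean, percentile 95 % CI and median per model and
metric; improvement percentages compare medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_prep import LongTermSite
from .density_ratio import RuLSIFConfig
from .rf_baseline import RFConfig, fit_rf
from .slr_baseline import DirectionSpec, fit_slr, predict_slr
from .transfer_models import InstanceSet, fit_prior_rf, fit_two_stage_tradaboost_r2

logger = logging.getLogger(__name__)

METRICS = ("nmae", "nrmse", "r2")
ALL_MODELS = ("slr", "rf_lur", "prior_rf", "tradaboost", "rf_lur_half",
              "prior_rf_half")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def nmae(pred, obs) -> float:
    """Mean absolute error normalized by the mean of the observations."""
    pred, obs = _check_pair(pred, obs)
    m = float(np.mean(obs))
    if m <= 0:
        raise ValueError("nMAE undefined: mean of observations must be > 0")
    return float(np.mean(np.abs(pred - obs)) / m)


def nrmse(pred, obs) -> float:
    """Root mean squared error normalized by the mean of the observations."""
    pred, obs = _check_pair(pred, obs)
    m = float(np.mean(obs))
    if m <= 0:
        raise ValueError("nRMSE undefined: mean of observations must be > 0")
    return float(np.sqrt(np.mean((pred - obs) ** 2)) / m)


def r2_pearson(pred, obs) -> float:
    """Squared Pearson correlation between predictions and observations."""
    pred, obs = _check_pair(pred, obs)
    if np.std(pred) == 0 or np.std(obs) == 0:
        raise ValueError("R² undefined for zero-variance input")
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


def _check_pair(pred, obs):
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape or pred.ndim != 1 or len(pred) < 2:
        raise ValueError("pred and obs must be equal-length 1-D, length >= 2")
    return pred, obs


def improvement_percentage(metric_transfer: float, metric_conventional: float) -> float:
    """Percent change of a transfer model's metric vs the conventional one,
    100·(transfer − conventional)/conventional, rounded to one decimal."""
    if metric_conventional == 0:
        raise ValueError("conventional metric must be nonzero")
    return round(100.0 * (metric_transfer - metric_conventional)
                 / metric_conventional, 1)


def site_predictions(
    segment_predictions: pd.Series, sites: list[LongTermSite]
) -> pd.Series:
    """Per-site prediction: mean over the site's matched road segments.

    Sites with no matched segment are excluded with a warning.
    """
    out = {}
    for site in sites:
        ids = [s for s in site.matched_segment_ids if s in segment_predictions.index]
        if not ids:
            logger.warning("site %s has no matched segment; excluded", site.site_id)
            continue
        out[site.site_id] = float(segment_predictions.loc[list(ids)].mean())
    return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# repeat protocol
# ---------------------------------------------------------------------------

@dataclass
class PreparedData:
    """Everything the protocol needs, keyed by segment_id.

    ``X``: per-segment predictor matrix; ``y_mobile``: per-segment mobile
    aggregate concentrations (training signal); ``sites``: matched
    long-term sites; ``directions``: expected signs for the SLR baseline.
    """

    X: pd.DataFrame
    y_mobile: pd.Series
    sites: list[LongTermSite]
    directions: DirectionSpec

    def site_table(self) -> pd.DataFrame:
        """Site-level design: covariates averaged over matched segments."""
        rows, values, ids = [], [], []
        for s in self.sites:
            seg = [i for i in s.matched_segment_ids if i in self.X.index]
            if not seg:
                continue
            rows.append(self.X.loc[seg].mean(axis=0))
            values.append(s.value)
            ids.append(s.site_id)
        return pd.DataFrame(rows, index=ids).assign(_value=values)


@dataclass
class EvaluationReport:
    per_iteration: pd.DataFrame          # model, iteration, nmae, nrmse, r2
    summary: pd.DataFrame                # model, metric, mean, lo, hi, median
    improvements: pd.DataFrame           # transfer, baseline, metric, percent
    failed_iterations: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.per_iteration.to_csv(path, index=False)


def split_sites(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random 50/50 site split: ⌈n/2⌉ train, ⌊n/2⌋ validate."""
    perm = rng.permutation(n)
    n_train = int(np.ceil(n / 2))
    return perm[:n_train], perm[n_train:]


def _metrics_row(pred: pd.Series, obs: pd.Series) -> dict:
    common = pred.index.intersection(obs.index)
    p, o = pred.loc[common].to_numpy(), obs.loc[common].to_numpy()
    return {"nmae": nmae(p, o), "nrmse": nrmse(p, o), "r2": r2_pearson(p, o)}


def run_protocol(
    data: PreparedData,
    models=("slr", "rf_lur", "prior_rf", "tradaboost"),
    n_iterations: int = 20,
    seed: int = 0,
    rf_config: RFConfig | None = None,
    rulsif_config: RuLSIFConfig | None = None,
    tradaboost_kwargs: dict | None = None,
) -> EvaluationReport:
    """Run the repeat validation design and summarise it.

    Returns an :class:`EvaluationReport` with per-iteration metrics, mean /
    percentile-95 % CI / median summaries, and median-based improvement
    percentages of each transfer model over each conventional baseline.
    """
    if n_iterations < 2:
        raise ValueError("need n_iterations >= 2")
    unknown = set(models) - set(ALL_MODELS)
    if unknown:
        raise ValueError(f"unknown models {sorted(unknown)}; choose from {ALL_MODELS}")
    site_tab = data.site_table()
    if len(site_tab) < 4:
        raise ValueError("need at least 4 matched long-term sites")
    rf_config = rf_config or RFConfig(seed=seed)
    rulsif_config = rulsif_config or RuLSIFConfig(seed=seed)
    tb_kwargs = dict(tradaboost_kwargs or {})
    cov_cols = [c for c in site_tab.columns if c != "_value"]
    obs_all = site_tab["_value"]

    rows: list[dict] = []
    failed: dict[str, int] = {}

    # SLR: a single deterministic fit on the full mobile data (no CI)
    slr_pred = None
    if "slr" in models:
        slr_model = fit_slr(data.X, data.y_mobile, data.directions)
        slr_pred = pd.Series(predict_slr(slr_model, data.X), index=data.X.index)

    rng_master = np.random.default_rng(seed)
    iter_seeds = rng_master.integers(0, 2**31 - 1, size=n_iterations)
    for it, it_seed in enumerate(iter_seeds):
        rng = np.random.default_rng(it_seed)
        tr_idx, va_idx = split_sites(len(site_tab), rng)
        half_obs = obs_all.iloc[va_idx]
        boot = rng.choice(len(data.X), size=len(data.X), replace=True)
        Xb, yb = data.X.iloc[boot], data.y_mobile.iloc[boot]
        it_cfg = RFConfig(rf_config.n_trees, rf_config.m_try,
                          rf_config.max_terminal_nodes, seed=int(it_seed) % 2**31)

        for model in models:
            try:
                row = _run_one(
                    model, data, site_tab, cov_cols, obs_all, half_obs,
                    tr_idx, va_idx, Xb, yb, it_cfg, rulsif_config,
                    tb_kwargs, slr_pred, int(it_seed),
                )
            except Exception as exc:  # noqa: BLE001 - protocol must continue
                logger.warning("iteration %d: model %s failed: %s", it, model, exc)
                failed[model] = failed.get(model, 0) + 1
                continue
            rows.append({"model": model, "iteration": it, **row})

    per_iter = pd.DataFrame(rows)
    summary = _summarize(per_iter)
    improvements = _improvement_table(summary, models)
    if failed:
        logger.warning("failed iterations per model: %s", failed)
    return EvaluationReport(per_iter, summary, improvements, failed)


def _run_one(model, data, site_tab, cov_cols, obs_all, half_obs, tr_idx,
             va_idx, Xb, yb, rf_cfg, rulsif_cfg, tb_kwargs, slr_pred, it_seed):
    if model == "slr":
        return _metrics_row(
            site_predictions(slr_pred, data.sites), obs_all
        )
    if model in ("rf_lur", "rf_lur_half"):
        forest = fit_rf(Xb, yb, rf_cfg)
        seg_pred = pd.Series(forest.predict(data.X), index=data.X.index)
        obs = obs_all if model == "rf_lur" else half_obs
        return _metrics_row(site_predictions(seg_pred, data.sites), obs)
    if model in ("prior_rf", "prior_rf_half"):
        # the half variant estimates the ratio from the same long-term half
        # TrAdaBoost trains on (Table-1 alignment)
        target_y = (
            obs_all.to_numpy() if model == "prior_rf"
            else obs_all.iloc[tr_idx].to_numpy()
        )
        ens = fit_prior_rf(
            InstanceSet(Xb, yb.to_numpy(), "source"), target_y, rf_cfg, rulsif_cfg
        )
        seg_pred = pd.Series(ens.predict(data.X), index=data.X.index)
        obs = obs_all if model == "prior_rf" else half_obs
        return _metrics_row(site_predictions(seg_pred, data.sites), obs)
    if model == "tradaboost":
        src = InstanceSet(data.X, data.y_mobile.to_numpy(), "source")
        tgt = InstanceSet(
            site_tab.iloc[tr_idx][cov_cols],
            site_tab.iloc[tr_idx]["_value"].to_numpy(),
            "target",
        )
        ens = fit_two_stage_tradaboost_r2(src, tgt, seed=it_seed % 2**31,
                                          **tb_kwargs)
        seg_pred = pd.Series(ens.predict(data.X), index=data.X.index)
        return _metrics_row(site_predictions(seg_pred, data.sites), half_obs)
    raise ValueError(f"unknown model {model!r}")


def _summarize(per_iter: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for model, grp in per_iter.groupby("model", sort=False):
        for metric in METRICS:
            v = grp[metric].to_numpy()
            rows.append({
                "model": model, "metric": metric,
                "mean": float(np.mean(v)),
                "ci_lo": float(np.percentile(v, 2.5)),
                "ci_hi": float(np.percentile(v, 97.5)),
                "median": float(np.median(v)),
                "n_iterations": len(v),
            })
    return pd.DataFrame(rows)


def _improvement_table(summary: pd.DataFrame, models) -> pd.DataFrame:
    transfer = [m for m in ("prior_rf", "tradaboost") if m in models]
    baseline = [m for m in ("slr", "rf_lur") if m in models]
    med = summary.set_index(["model", "metric"])["median"]
    rows = []
    for tm in transfer:
        for bm in baseline:
            for metric in METRICS:
                if (tm, metric) in med.index and (bm, metric) in med.index:
                    rows.append({
                        "transfer": tm, "baseline": bm, "metric": metric,
                        "percent": improvement_percentage(
                            med[tm, metric], med[bm, metric]
                        ),
                    })
    return pd.DataFrame(rows)
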