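"""Direction-constrained forward stepwise linear land-use regression.

The classic supervised-stepwise LUR: starting from an intercept-only model,
covariates are added one at a time, each step taking the candidate that
increases adjusted R² the most, and accepting it only if

* the gain exceeds a threshold (default 0.01),
* its coefficient — and every previously selected coefficient — keeps the
  a-priori expected sign (e.g. traffic intensity must enter positively),
* it is not a second member of an already-selected buffer family
  (``traffic_50`` and ``traffic_300`` are the same variable at two buffer
  radii; at most one may enter).

After selection, covariates whose p-value exceeds ``p_remove`` (default
0.10) are dropped and the model refit, repeating until all survivors are
significant.  These acceptance/removal thresholds follow common European
LUR practice (ESCAPE-style criteria).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

_BUFFER_SUFFIX = re.compile(r"^(?P<family>.+)_(?P<buffer>\d+)$")


def default_family(name: str) -> str:
    """Buffer family of a covariate name: ``traffic_300`` -> ``traffic``."""
    m = _BUFFER_SUFFIX.match(name)
    return m.group("family") if m else name


@dataclass(frozen=True)
class DirectionSpec:
    """Expected sign of association per covariate (+1 or -1).

    ``families`` optionally maps covariates to buffer families; by default
    the family is the name with a trailing ``_<meters>`` buffer stripped.
    """

    signs: dict[str, int]
    families: dict[str, str] | None = None

    def __post_init__(self):
        bad = {k: v for k, v in self.signs.items() if v not in (+1, -1)}
        if bad:
            raise ValueError(f"directions must be +1 or -1, got {bad}")

    def sign(self, name: str) -> int:
        return self.signs[name]

    def family(self, name: str) -> str:
        if self.families and name in self.families:
            return self.families[name]
        return default_family(name)


@dataclass
class SLRModel:
    intercept: float
    coefficients: dict[str, float]
    adjusted_r2: float
    selection_trace: list[dict] = field(default_factory=list)

    @property
    def covariates(self) -> list[str]:
        return list(self.coefficients)


def _fit_ols(X: pd.DataFrame, y: np.ndarray, cols: list[str]):
    design = sm.add_constant(X[cols], has_constant="add") if cols else pd.DataFrame(
        {"const": np.ones(len(y))}, index=X.index
    )
    return sm.OLS(y, design).fit()


def fit_slr(
    X: pd.DataFrame,
    y,
    directions: DirectionSpec,
    gain_threshold: float = 0.01,
    p_remove: float = 0.10,
) -> SLRModel:
    """Fit the direction-constrained forward stepwise linear model.

    Parameters
    ----------
    X : DataFrame
        Candidate covariates (no missing values); every column must have a
        declared direction.
    y : array-like
        Segment-level concentrations.
    gain_threshold
        Minimum adjusted-R² increase for a candidate to be accepted.
    p_remove
        After selection, covariates with p-value above this are dropped.

    Returns
    -------
    SLRModel with a per-candidate ``selection_trace``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if X.isna().any().any() or not np.all(np.isfinite(y)):
        raise ValueError("missing or non-finite values in X or y")
    undeclared = [c for c in X.columns if c not in directions.signs]
    if undeclared:
        raise ValueError(f"no declared direction for covariates: {undeclared}")

    selected: list[str] = []
    trace: list[dict] = []
    current = _fit_ols(X, y, selected)
    current_adj = 0.0  # adjusted R² of the intercept-only model

    while True:
        used_families = {directions.family(c) for c in selected}
        candidates = [
            c for c in X.columns
            if c not in selected and directions.family(c) not in used_families
        ]
        best = None  # (adj_r2, column_index, name, fit)
        for j, cand in enumerate(candidates):
            cols = selected + [cand]
            try:
                fit = _fit_ols(X, y, cols)
            except np.linalg.LinAlgError:
                trace.append({"candidate": cand, "accepted": False,
                              "reason": "rank-deficient"})
                continue
            if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
                trace.append({"candidate": cand, "accepted": False,
                              "reason": "rank-deficient"})
                logger.debug("SLR: candidate %s skipped (rank-deficient)", cand)
                continue
            adj = fit.rsquared_adj
            # ties in gain resolve to the smaller column index (scan order)
            if best is None or adj > best[0] + 1e-12:
                best = (adj, j, cand, fit)
        if best is None:
            break
        adj, _, cand, fit = best
        gain = adj - current_adj
        if gain <= gain_threshold:
            trace.append({"candidate": cand, "adj_r2": adj, "accepted": False,
                          "reason": f"gain {gain:.4f} <= threshold"})
            break
        signs_ok = all(
            np.sign(fit.params[c]) == directions.sign(c) for c in selected + [cand]
        )
        if not signs_ok:
            trace.append({"candidate": cand, "adj_r2": adj, "accepted": False,
                          "reason": "sign constraint violated"})
            # the best candidate is invalid; no other candidate can be
            # accepted this step with a larger gain, so try the runner-up
            # by removing this candidate from future consideration via a
            # restricted recursion-free scan:
            X = X.drop(columns=[cand])
            continue
        selected.append(cand)
        current, current_adj = fit, adj
        trace.append({"candidate": cand, "adj_r2": adj, "accepted": True,
                      "reason": "largest adjusted-R² gain"})

    # backward removal of insignificant covariates
    while selected:
        pvals = current.pvalues[selected]
        worst = pvals.idxmax()
        if pvals[worst] <= p_remove:
            break
        selected.remove(worst)
        trace.append({"candidate": worst, "accepted": False,
                      "reason": f"removed: p={pvals[worst]:.3f} > {p_remove}"})
        current = _fit_ols(X, y, selected)

    coeffs = {c: float(current.params[c]) for c in selected}
    intercept = float(current.params["const"])
    adj_final = float(current.rsquared_adj) if selected else 0.0
    return SLRModel(intercept, coeffs, adj_final, trace)


def predict_slr(model: SLRModel, X: pd.DataFrame) -> np.ndarray:
    """Predict concentrations; negatives floored at 0 (with a log record)."""
    missing = [c for c in model.covariates if c not in X.columns]
    if missing:
        raise ValueError(f"missing covariates in X: {missing}")
    pred = np.full(len(X), model.intercept, dtype=float)
    for c, b in model.coefficients.items():
        pred += b * X[c].to_numpy(float)
    n_floor = int(np.sum(pred < 0))
    if n_floor:
        logger.info("predict_slr: %d negative predictions floored at 0", n_floor)
        pred = np.maximum(pred, 0.0)
    return pred


def write_slr_text(model: SLRModel, path) -> None:
    """Serialize the model to a human-readable key-value text file."""
    with open(path, "w") as fh:
        fh.write(f"intercept\t{model.intercept!r}\n")
        fh.write(f"adjusted_r2\t{model.adjusted_r2!r}\n")
        for step, (cov, coef) in enumerate(model.coefficients.items(), 1):
            fh.write(f"coef\t{cov}\t{coef!r}\t{step}\n")


def read_slr_text(path) -> SLRModel:
    intercept = adj = 0.0
    coeffs: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "intercept":
                intercept = float(parts[1])
            elif parts[0] == "adjusted_r2":
                adj = float(parts[1])
            elif parts[0] == "coef":
                coeffs[parts[1]] = float(parts[2])
    return SLRModel(intercept, coeffs, adj, [])
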