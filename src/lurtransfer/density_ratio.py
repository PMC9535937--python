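"""RuLSIF: relative unconstrained least-squares importance fitting.

Mobile on-road measurements (the *source* domain) and stationary long-term
near-road measurements (the *target* domain) follow different concentration
distributions.  RuLSIF estimates the α-relative density ratio

    r_α(z) = p_t(z) / (α p_t(z) + (1 − α) p_s(z))

directly from samples of numerator and denominator, without estimating
either density.  The ratio is modelled as a Gaussian-kernel expansion
r̂(z) = Σ_l θ_l K_σ(z, c_l) with centers c_l drawn from the target sample;
θ has the closed form

    θ = (Ĥ + λ I)⁻¹ ĥ,
    Ĥ = α · mean_target[k kᵀ] + (1 − α) · mean_source[k kᵀ],
    ĥ = mean_target[k],

where k is the vector of kernel evaluations.  Kernel width σ and ridge
penalty λ are chosen by k-fold cross-validation of the RuLSIF squared-loss
criterion J = ½ θᵀĤθ − ĥᵀθ on held-out data.

Here the ratio is estimated on the response (concentration) axis: the
evaluated ratio at each mobile instance's concentration reweights the risk
function of the downstream forest, pulling the source risk toward the
target risk (prior-probability shift correction).  A covariate-shift
variant over the predictor matrix is available by passing multivariate
samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

WEIGHT_FLOOR = 1e-3


@dataclass(frozen=True)
class RuLSIFConfig:
    """Estimator settings.

    alpha in [0, 1) controls the relative smoothing: 0 recovers the plain
    density ratio p_t/p_s (uLSIF); larger values bound the ratio by 1/α and
    stabilise estimation.  Grids default to the median-distance heuristic
    for σ and a log-spaced ridge path for λ.
    """

    alpha: float = 0.1
    sigma_grid: tuple[float, ...] | None = None   # None -> median heuristic ×
    sigma_factors: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)
    lambda_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
    n_centers: int = 100
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")
        if len(self.lambda_grid) == 0:
            raise ValueError("lambda_grid must be nonempty")


@dataclass
class RatioModel:
    """Fitted α-relative density-ratio function over concentration space."""

    centers: np.ndarray          # (n_centers, d)
    theta: np.ndarray            # (n_centers,)
    sigma: float
    lam: float
    alpha: float
    cv_table: dict = field(default_factory=dict)

    def __call__(self, points) -> np.ndarray:
        """Raw (unclipped) ratio estimate at ``points``."""
        K = _gauss_kernel(_as_2d(points), self.centers, self.sigma)
        return K @ self.theta


def _as_2d(z) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    return z


def _gauss_kernel(x: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    """K[i, l] = exp(-||x_i - c_l||² / (2σ²))."""
    sq = (
        np.sum(x**2, axis=1)[:, None]
        + np.sum(centers**2, axis=1)[None, :]
        - 2.0 * x @ centers.T
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-sq / (2.0 * sigma**2))


def _median_heuristic(x: np.ndarray, rng: np.random.Generator) -> float:
    n = len(x)
    if n > 500:
        x = x[rng.choice(n, 500, replace=False)]
    sq = (
        np.sum(x**2, axis=1)[:, None]
        + np.sum(x**2, axis=1)[None, :]
        - 2.0 * x @ x.T
    )
    med = float(np.median(np.sqrt(np.maximum(sq, 0.0))))
    return med if med > 0 else 1.0


def _solve_theta(
    K_t: np.ndarray, K_s: np.ndarray, alpha: float, lam_grid: list[float]
) -> tuple[np.ndarray, float]:
    """θ = (Ĥ + λI)⁻¹ĥ; on a singular system move to the next larger λ."""
    H = alpha * (K_t.T @ K_t) / len(K_t) + (1 - alpha) * (K_s.T @ K_s) / len(K_s)
    h = K_t.mean(axis=0)
    for i, lam in enumerate(lam_grid):
        A = H + lam * np.eye(len(h))
        try:
            theta = np.linalg.solve(A, h)
        except np.linalg.LinAlgError:
            logger.warning("singular system at λ=%g; trying next grid value", lam)
            continue
        if np.all(np.isfinite(theta)):
            if i > 0:
                logger.info("λ increased to %g to regularize a singular system", lam)
            return theta, lam
    raise np.linalg.LinAlgError("λ grid exhausted; system remains singular")


def _j_loss(theta, K_t, K_s, alpha) -> float:
    """RuLSIF squared-loss criterion (up to a θ-free constant)."""
    rt = K_t @ theta
    rs = K_s @ theta
    return float(0.5 * alpha * np.mean(rt**2) + 0.5 * (1 - alpha) * np.mean(rs**2)
                 - np.mean(rt))


def fit_rulsif(
    target_samples, source_samples, config: RuLSIFConfig | None = None
) -> RatioModel:
    """Fit the α-relative ratio of target over source distributions.

    Both sample sets are 1-D concentration vectors (or 2-D arrays for the
    covariate-shift variant).  Deterministic given ``config.seed``.
    """
    config = config or RuLSIFConfig()
    zt = _as_2d(target_samples)
    zs = _as_2d(source_samples)
    if len(zt) == 0 or len(zs) == 0:
        raise ValueError("both sample sets must be nonempty")
    if np.var(zt) == 0 and np.var(zs) == 0:
        raise ValueError("samples have zero variance; ratio is unidentifiable")
    rng = np.random.default_rng(config.seed)

    n_centers = min(config.n_centers, len(zt))
    centers = zt[rng.choice(len(zt), n_centers, replace=False)]

    if config.sigma_grid is not None:
        sigmas = list(config.sigma_grid)
    else:
        med = _median_heuristic(np.vstack([zt, zs]), rng)
        sigmas = [med * f for f in config.sigma_factors]
    lambdas = sorted(config.lambda_grid)

    # fold assignment by value order (round-robin over sorted samples):
    # deterministic, spreads each fold over the support, and makes the fit
    # invariant to permuting the input sample order
    k = min(config.cv_folds, len(zt), len(zs))
    order_t = np.lexsort(zt.T[::-1])
    order_s = np.lexsort(zs.T[::-1])
    folds_t = [order_t[i::k] for i in range(k)]
    folds_s = [order_s[i::k] for i in range(k)]

    cv_table: dict[tuple[float, float], float] = {}
    for sigma in sigmas:
        K_t = _gauss_kernel(zt, centers, sigma)
        K_s = _gauss_kernel(zs, centers, sigma)
        for lam in lambdas:
            losses = []
            for ft, fs in zip(folds_t, folds_s):
                tr_t = np.setdiff1d(np.arange(len(zt)), ft)
                tr_s = np.setdiff1d(np.arange(len(zs)), fs)
                theta, _ = _solve_theta(K_t[tr_t], K_s[tr_s], config.alpha, [lam])
                losses.append(_j_loss(theta, K_t[ft], K_s[fs], config.alpha))
            cv_table[(sigma, lam)] = float(np.mean(losses))
    sigma, lam = min(cv_table, key=cv_table.get)

    K_t = _gauss_kernel(zt, centers, sigma)
    K_s = _gauss_kernel(zs, centers, sigma)
    lam_path = [l for l in lambdas if l >= lam]
    theta, lam_used = _solve_theta(K_t, K_s, config.alpha, lam_path)
    return RatioModel(
        centers=centers, theta=theta, sigma=float(sigma), lam=float(lam_used),
        alpha=config.alpha,
        cv_table={f"{s:g},{l:g}": v for (s, l), v in cv_table.items()},
    )


def evaluate_ratio(
    model: RatioModel, points, floor: float = WEIGHT_FLOOR, normalize: bool = True
) -> np.ndarray:
    """Instance weights: the fitted ratio at ``points``, floored above 0.

    The positive floor keeps every training instance alive in downstream
    weighted fits.  With ``normalize`` the weights are scaled to mean 1
    (scale-free; comparable with uniform weighting).
    """
    w = np.maximum(model(points), floor)
    if normalize:
        w = w / np.mean(w)
    return w


def save_ratio_model(model: RatioModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "centers": model.centers.tolist(),
                "theta": model.theta.tolist(),
                "sigma": model.sigma,
                "lambda": model.lam,
                "alpha": model.alpha,
            },
            fh,
        )


def load_ratio_model(path) -> RatioModel:
    with open(path) as fh:
        d = json.load(fh)
    return RatioModel(
        centers=np.asarray(d["centers"], float),
        theta=np.asarray(d["theta"], float),
        sigma=d["sigma"], lam=d["lambda"], alpha=d["alpha"],
    )
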