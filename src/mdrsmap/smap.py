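"""Locally weighted regularized regression primitives for S-maps.

An S-map fits, around every time point, a weighted linear regression of the
target's next value on the current state of all taxa (plus temperature).
Weights decay exponentially with multiview state-space distance from the
focal point (locality parameter theta; theta = 0 recovers a single global
linear model).  An elastic-net penalty stabilises the fit against noise and
collinearity and produces exact zeros, which downstream occurrence
statistics rely on.
"""
from __future__ import annotations

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

__all__ = ["smap_weights", "fit_local_regression", "select_hyperparameters"]


def smap_weights(distances: np.ndarray, theta: float) -> np.ndarray:
    """Exponential locality kernel ``w_i = exp(-theta * d_i / mean(d))``.

    Normalising by the mean library distance makes the weights invariant to
    an overall rescaling of the distances.  ``theta = 0`` gives all-ones
    weights (global linear map).
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    dbar = d.mean()
    if dbar == 0:
        raise ValueError("degenerate library: all distances are zero")
    return np.exp(-theta * d / dbar)


def fit_local_regression(
    y: np.ndarray,
    X: np.ndarray,
    w: np.ndarray,
    lam: float = 0.0,
    alpha: float = 0.5,
):
    """Weighted elastic-net regression; returns ``(intercept, coefficients)``.

    Minimises ``sum_i w_i (y_i - b0 - x_i . b)^2
    + lam * (alpha * ||b||_1 + (1 - alpha)/2 * ||b||_2^2)``
    with an unpenalised intercept.  Weights are normalised internally to sum
    to the number of rows, so rescaling all weights by a constant leaves the
    solution unchanged.  With ``lam = 0`` this is exact weighted least
    squares; with ``alpha > 0`` coefficients can be exactly zero.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    w = np.asarray(w, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(w) != X.shape[0]:
        raise ValueError("y, X and w must have aligned rows")
    if np.any(w < 0):
        raise ValueError("weights must be >= 0")
    if int((w > 0).sum()) < 2:
        raise ValueError("need at least 2 rows with positive weight")
    n = len(y)
    w = w * (n / w.sum())
    if lam == 0.0:
        sw = np.sqrt(w)
        Xa = np.column_stack([np.ones(n), X]) * sw[:, None]
        beta, *_ = np.linalg.lstsq(Xa, y * sw, rcond=None)
        return float(beta[0]), beta[1:]
    # weighted centering makes the unpenalised intercept exact, then the
    # sqrt(w) row scaling maps the problem onto sklearn's ElasticNet with
    # alpha_sklearn = lam / (2 n), l1_ratio = alpha.
    wsum = w.sum()
    xbar = w @ X / wsum
    ybar = float(w @ y / wsum)
    sw = np.sqrt(w)
    Xc = (X - xbar) * sw[:, None]
    yc = (y - ybar) * sw
    model = ElasticNet(
        alpha=lam / (2.0 * n),
        l1_ratio=alpha,
        fit_intercept=False,
        max_iter=5000,
        tol=1e-7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xc, yc)
    b = model.coef_.copy()
    return ybar - float(xbar @ b), b


def _loo_forecast_skill(
    y: np.ndarray,
    X: np.ndarray,
    D: np.ndarray,
    t0: int,
    fit_times: np.ndarray,
    eval_times: np.ndarray,
    theta: float,
    lam: float,
    alpha: float,
) -> float:
    """Leave-one-out one-step forecast skill (Pearson rho) of the target."""
    preds = np.empty(len(eval_times))
    for k, t in enumerate(eval_times):
        lib = fit_times[fit_times != t]
        w = smap_weights(D[t - t0, lib - t0], theta)
        b0, b = fit_local_regression(y[lib + 1], X[lib], w, lam, alpha)
        preds[k] = b0 + X[t] @ b
    obs = y[eval_times + 1]
    if np.std(preds) == 0 or np.std(obs) == 0:
        return np.nan
    return float(np.corrcoef(preds, obs)[0, 1])


def select_hyperparameters(
    y: np.ndarray,
    X: np.ndarray,
    D: np.ndarray,
    t0: int,
    fit_times: np.ndarray,
    theta_grid,
    lambda_grid,
    alpha: float,
    cv_stride: int = 1,
):
    """Grid search (theta, lambda) by leave-one-out forecast skill.

    Every grid cell is scored by the Pearson correlation between one-step
    forecasts (focal point left out of the library) and observations at the
    evaluation times (every ``cv_stride``-th fit time).  Ties break toward
    smaller theta, then smaller lambda.  Returns ``(theta, lam, rho)``;
    raises if the skill is undefined for every cell.
    """
    eval_times = fit_times[::max(1, int(cv_stride))]
    best = None
    for theta in sorted(theta_grid):
        for lam in sorted(lambda_grid):
            rho = _loo_forecast_skill(y, X, D, t0, fit_times, eval_times, theta, lam, alpha)
            if np.isfinite(rho) and (best is None or rho > best[2]):
                best = (theta, lam, rho)
    if best is None:
        raise RuntimeError("forecast skill undefined for every (theta, lambda) cell")
    return best
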