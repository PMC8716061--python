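r"""Logistic gating model linking CCAP activity to motoneuron oscillation.

The motoneuronal oscillatory state is reduced to a binary series y(t) by
thresholding the instantaneous oscillation amplitude, and modeled as

.. math::

    p(t) = \frac{1}{1 + \exp(-\beta - \sum_i w_i f_i(t))}

where the :math:`f_i` are the preprocessed alpha-CCAP traces.  The
coefficients are estimated by maximum likelihood under the constraint that
every weight is nonnegative (CCAP input is depolarizing; negative weights
would be biologically meaningless).  Two variants are compared by AIC: the
multi-weight model (one weight per neuron, k = n+1 parameters) and the
single-weight model (one shared weight, k = 2), which asks whether the
neurons are interchangeable.

The constrained MLE is solved with box-constrained L-BFGS-B on
:math:`(\beta, w)` with the analytic gradient, restarted from a fixed set
of seeds to guard against flat directions created by collinear CCAP
columns; the best likelihood is kept, so fits are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "BinarizedActivity",
    "binarize",
    "LogisticFit",
    "fit_logistic",
    "predict_p",
    "aic",
    "count_active",
]

_BETA_CLIP = 20.0
_W_TOL = 1e-6
_N_RESTARTS = 5


@dataclass
class BinarizedActivity:
    """Binary oscillation-state series with the threshold that produced it."""

    y: np.ndarray  # int {0,1}
    threshold: float
    source_period: float | None = None  # period of the amplitude series, if known


def binarize(
    amplitude: np.ndarray,
    threshold_frac: float = 0.5,
    method: str = "fraction",
    source_period: float | None = None,
) -> BinarizedActivity:
    """Threshold an oscillation-amplitude series into a {0,1} state.

    ``method='fraction'`` thresholds at ``threshold_frac`` of the maximum
    amplitude (mirroring the half-max convention of onset detection);
    ``method='otsu'`` picks the threshold minimizing intra-class variance.
    """
    amplitude = np.asarray(amplitude, dtype=float)
    if amplitude.size == 0 or np.any(amplitude < 0):
        raise ValueError("amplitude must be a nonnegative series")
    amax = float(np.max(amplitude))
    if amax == 0:
        raise ValueError("all-zero amplitude cannot be binarized")
    if method == "fraction":
        threshold = threshold_frac * amax
    elif method == "otsu":
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(amplitude))
    else:
        raise ValueError(f"unknown method {method!r}")
    y = (amplitude >= threshold).astype(int)
    return BinarizedActivity(y=y, threshold=threshold, source_period=source_period)


@dataclass
class LogisticFit:
    """Constrained-MLE logistic fit."""

    beta: float
    w: np.ndarray  # nonnegative, length n (single mode: shared value repeated)
    loglik: float
    aic: float
    k: int  # parameter count: n+1 (multi) or 2 (single)
    mode: str  # "multi" | "single"
    converged: bool
    degenerate: bool = False  # constant-y input


def _loglik_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Negative log-likelihood and gradient for design X (with intercept)."""
    z = X @ theta
    # stable: log(1+e^z) and sigmoid
    ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
    grad = X.T @ (y - p)
    return -ll, -grad


def fit_logistic(F: np.ndarray, y: np.ndarray, mode: str = "multi") -> LogisticFit:
    """Maximum-likelihood logistic fit with nonnegative weights.

    ``F`` is the (time x n) matrix of preprocessed CCAP series, ``y`` the
    binary oscillation state on the same grid.  ``mode='multi'`` fits one
    weight per column; ``mode='single'`` one weight shared by all columns.
    The offset beta is clipped to [-20, 20] so that complete separation
    (or a constant y) yields a finite, flagged fit; weights below 1e-6 are
    reported as exactly zero.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if F.shape[0] == 1 and F.shape[1] > 1 and len(np.asarray(y)) == F.shape[1]:
        F = F.T
    y = np.asarray(y, dtype=float)
    if F.shape[0] != len(y):
        raise ValueError("F rows and y must align")
    if mode not in ("multi", "single"):
        raise ValueError(f"unknown mode {mode!r}")
    n = F.shape[1]
    if n < 1:
        raise ValueError("need at least one CCAP column")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y must be binary")

    k = n + 1 if mode == "multi" else 2
    if np.all(y == y[0]):
        # degenerate: likelihood maximized by beta at the clip bound
        beta = _BETA_CLIP if y[0] == 1 else -_BETA_CLIP
        w = np.zeros(n)
        z = np.full(len(y), beta)
        ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
        return LogisticFit(
            beta=beta, w=w, loglik=ll, aic=2 * k - 2 * ll, k=k,
            mode=mode, converged=True, degenerate=True,
        )

    design = F if mode == "multi" else F.sum(axis=1, keepdims=True)
    m = design.shape[1]
    X = np.hstack([np.ones((len(y), 1)), design])
    bounds = [(-_BETA_CLIP, _BETA_CLIP)] + [(0.0, None)] * m

    starts = [np.zeros(m + 1)]
    rng = np.random.default_rng(0)
    scale = max(1.0, float(np.max(np.abs(design))))
    for _ in range(_N_RESTARTS - 1):
        theta0 = np.concatenate([rng.uniform(-2, 2, 1), rng.uniform(0, 2 / scale, m)])
        starts.append(theta0)

    best = None
    converged = False
    for theta0 in starts:
        res = optimize.minimize(
            _loglik_grad, theta0, args=(X, y), jac=True, method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        converged = converged or bool(res.success)

    beta = float(best.x[0])
    w_fit = np.asarray(best.x[1:], dtype=float)
    w_fit[w_fit < _W_TOL] = 0.0
    w = w_fit if mode == "multi" else np.full(n, w_fit[0])
    ll = -float(best.fun)
    return LogisticFit(
        beta=beta, w=w, loglik=ll, aic=2 * k - 2 * ll, k=k,
        mode=mode, converged=converged,
    )


def predict_p(fit: LogisticFit, F: np.ndarray) -> np.ndarray:
    """Predicted oscillation probability p(t) for CCAP series F."""
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if F.shape[1] != len(fit.w):
        raise ValueError(
            f"F has {F.shape[1]} columns but the fit expects {len(fit.w)}"
        )
    z = fit.beta + F @ fit.w
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))


def aic(fit: LogisticFit) -> float:
    """Akaike information criterion, 2k - 2 log L."""
    return 2 * fit.k - 2 * fit.loglik


def count_active(fit: LogisticFit, tol: float = 1e-6) -> int:
    """Number of CCAP neurons with weight above ``tol`` in a multi-weight fit."""
    if fit.mode != "multi":
        raise ValueError("active-weight count applies to multi-weight fits only")
    return int(np.sum(fit.w > tol))
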