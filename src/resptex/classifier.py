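"""Ridge-penalized logistic regression fitted by a DFP quasi-Newton ascent.

The class probability is the standard logistic model

    p(X) = 1 / (1 + exp(-(theta_0 + theta^T X)))

and the fitted weights maximize the penalized log-likelihood

    l_lambda(theta) = sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ]
                      - lambda * sum_{j>=1} theta_j^2

with gradient  sum_i X_i (y_i - p_i) - 2 lambda theta  (intercept
unpenalized). The ridge term (default lambda = 1e-8) shrinks the weights
toward zero, which stabilizes estimation when the 16 texture attributes
are collinear and guards against divergence under perfect separation.

The optimizer is Davidon-Fletcher-Powell: an inverse-Hessian
approximation H (started at the identity) gives the ascent direction
H * grad, the step length is chosen by Armijo backtracking (a <- kappa*a
until the sufficient-increase condition holds), and H is updated by the
DFP rank-two formula, with a reset to the identity whenever the curvature
condition fails. Features are z-scored on the training data before
fitting; the stored means/scales are applied again at prediction time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_LAMBDA = 1.0e-8
DEFAULT_TOL = 1.0e-6
DEFAULT_MAX_ITER = 200
ARMIJO_C1 = 1.0e-4
ARMIJO_KAPPA = 0.5
MAX_BACKTRACKS = 60


class ConvergenceWarning(UserWarning):
    """The DFP iteration stopped before meeting the gradient tolerance."""


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically-stable logistic
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    return np.hstack([np.ones((X.shape[0], 1)), X])


def _check_xy(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> None:
    if X.shape[0] != len(y):
        raise ValueError("X row count must equal y length")
    if len(theta) != X.shape[1] + 1:
        raise ValueError(
            f"theta must have {X.shape[1] + 1} entries (intercept + features)")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")


def _penalty_weights(theta: np.ndarray, penalize_intercept: bool) -> np.ndarray:
    w = np.asarray(theta, dtype=np.float64).copy()
    if not penalize_intercept:
        w[0] = 0.0
    return w


def penalized_loglik(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                     lam: float = DEFAULT_LAMBDA,
                     penalize_intercept: bool = False,
                     penalty_form: str = "squared") -> float:
    """l(theta) - lambda * penalty over the non-intercept weights.

    ``penalty_form='squared'`` uses sum(theta_j^2) (consistent with the
    -2*lambda*theta gradient); ``'norm'`` uses sqrt of that sum.
    """
    theta = np.asarray(theta, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_xy(theta, np.asarray(X), y)
    z = _design(X) @ theta
    # sum_i [y z - log(1 + e^z)] is l(theta) in a stable form
    ll = float(np.sum(y * z - np.logaddexp(0.0, z)))
    w = _penalty_weights(theta, penalize_intercept)
    ssq = float(w @ w)
    pen = np.sqrt(ssq) if penalty_form == "norm" else ssq
    return ll - lam * pen


def gradient(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
             lam: float = DEFAULT_LAMBDA,
             penalize_intercept: bool = False) -> np.ndarray:
    """Gradient of the (squared-penalty) objective: X^T (y - p) - 2*lambda*theta."""
    theta = np.asarray(theta, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    _check_xy(theta, np.asarray(X), y)
    Xd = _design(X)
    p = _sigmoid(Xd @ theta)
    return Xd.T @ (y - p) - 2.0 * lam * _penalty_weights(theta, penalize_intercept)


@dataclass
class RidgeLogisticModel:
    """Fitted ridge logistic model: intercept + one weight per attribute.

    ``theta`` applies to z-scored features; ``means``/``scales`` hold the
    training standardization replayed at prediction time.
    """

    theta: np.ndarray
    lam: float
    feature_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    converged: bool = False
    iterations: int = 0

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"model expects {len(self.feature_names)} features, "
                f"got {X.shape[1]}")
        return (X - self.means) / self.scales

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return _design(self._standardize(X)) @ self.theta

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """p(X) per the logistic model, in (0, 1)."""
        return _sigmoid(self.decision_function(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class 1 (sputum) iff p >= 0.5."""
        return (self.predict_proba(X) >= 0.5).astype(int)

    def to_json(self) -> str:
        return json.dumps({
            "theta": self.theta.tolist(),
            "lambda": self.lam,
            "feature_names": self.feature_names,
            "standardization": {"means": self.means.tolist(),
                                "scales": self.scales.tolist()},
            "converged": self.converged,
            "iterations": self.iterations,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RidgeLogisticModel":
        d = json.loads(text)
        return cls(theta=np.array(d["theta"]), lam=d["lambda"],
                   feature_names=list(d["feature_names"]),
                   means=np.array(d["standardization"]["means"]),
                   scales=np.array(d["standardization"]["scales"]),
                   converged=d["converged"], iterations=d["iterations"])


def fit_dfp(X: np.ndarray, y: np.ndarray, lam: float = DEFAULT_LAMBDA,
            feature_names: list[str] | None = None,
            tol: float = DEFAULT_TOL, max_iter: int = DEFAULT_MAX_ITER,
            standardize: bool = True,
            penalize_intercept: bool = False) -> RidgeLogisticModel:
    """Maximize the penalized log-likelihood by DFP with Armijo backtracking.

    H_0 = I; direction H*grad; step a halved (kappa = 0.5) from 1 until the
    Armijo sufficient-increase condition holds; DFP rank-two update of H,
    reset to I on loss of curvature. Stops when the sup-norm of the
    gradient drops below ``tol`` or after ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    classes = np.unique(y)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("both classes must be present to fit")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]

    if standardize:
        means = X.mean(axis=0)
        scales = X.std(axis=0, ddof=0)
        scales = np.where(scales > 0, scales, 1.0)
    else:
        means = np.zeros(X.shape[1])
        scales = np.ones(X.shape[1])
    Z = (X - means) / scales

    d = Z.shape[1] + 1
    theta = np.zeros(d)
    H = np.eye(d)
    g = gradient(theta, Z, y, lam, penalize_intercept)
    f = penalized_loglik(theta, Z, y, lam, penalize_intercept)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(g)) < tol:
            converged = True
            it -= 1
            break
        p = H @ g  # ascent direction
        slope = float(g @ p)
        if slope <= 0:  # H lost positive definiteness
            H = np.eye(d)
            p = g.copy()
            slope = float(g @ g)
            if slope == 0.0:
                converged = True
                break
        a = 1.0
        f_new = None
        for _ in range(MAX_BACKTRACKS):
            cand = theta + a * p
            f_cand = penalized_loglik(cand, Z, y, lam, penalize_intercept)
            if f_cand >= f + ARMIJO_C1 * a * slope:
                f_new = f_cand
                break
            a *= ARMIJO_KAPPA
        if f_new is None:
            warnings.warn("line search failed; stopping early",
                          ConvergenceWarning, stacklevel=2)
            break
        step = a * p
        theta_new = theta + step
        g_new = gradient(theta_new, Z, y, lam, penalize_intercept)
        # DFP update on the minimization form: yv = -(g_new - g) so that
        # H satisfies the secant condition H @ yv = step
        yv = g - g_new
        sy = float(step @ yv)
        if sy > 1e-12:
            Hy = H @ yv
            H = H + np.outer(step, step) / sy \
                - np.outer(Hy, Hy) / float(yv @ Hy)
        else:
            H = np.eye(d)
        theta, g, f = theta_new, g_new, f_new
    else:
        it = max_iter
    if not converged and np.max(np.abs(g)) < tol:
        converged = True
    if not converged:
        warnings.warn(
            f"DFP did not converge in {max_iter} iterations "
            f"(|grad|_inf = {np.max(np.abs(g)):.2e})",
            ConvergenceWarning, stacklevel=2)
    return RidgeLogisticModel(theta=theta, lam=lam,
                              feature_names=list(feature_names),
                              means=means, scales=scales,
                              converged=converged, iterations=it)
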