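"""Bayesian-regularized artificial neural network (BRANN) regressor.

A single-hidden-layer network (tanh hidden units, linear output) is trained
by minimizing the regularized objective

    F(w) = β_noise · E_D + α · E_W,
    E_D = Σ (y − ŷ(w))²   (sum of squared errors),
    E_W = ½ Σ wᵢ²          (weight prior energy),

with damped Gauss–Newton (Levenberg–Marquardt) steps.  The two hyper-
parameters are re-estimated each outer iteration by the evidence framework:

    γ       = N_w − α · tr(H⁻¹)          (effective number of parameters),
    α       = γ / (2 E_W),
    β_noise = (n − γ) / (2 E_D),

with H ≈ 2 β_noise JᵀJ + α I the Gauss–Newton approximation of the Hessian
of F.  Bayesian regularization replaces early stopping: the network is
trained to convergence of F, and γ reports how many of the N_w weights the
data actually determine.

Inputs are z-scored and the target standardized internally; training is
fully deterministic given the seed (weights initialized from the seeded
stream at scale 1/√fan-in).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError, TrainingError

_BETA_CAP = 1e9   # β_noise cap for (near-)noiseless fits
_ALPHA_FLOOR = 1e-12


@dataclass
class BrannModel:
    """Trained BRANN: flat weight vector, evidence hyperparameters, and the
    standardization constants needed for prediction."""

    n_input: int
    n_hidden: int
    weights: np.ndarray
    alpha: float
    beta_noise: float
    gamma_effective: float
    seed: int
    converged: bool
    objective_trace: list[float]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    feature_names: list[str] = field(default_factory=list)
    clamped: bool = False

    @property
    def n_weights(self) -> int:
        return self.n_hidden * (self.n_input + 1) + self.n_hidden + 1

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_hidden": self.n_hidden,
            "weights": [float(w) for w in self.weights],
            "alpha": self.alpha,
            "beta_noise": self.beta_noise,
            "gamma_effective": self.gamma_effective,
            "seed": self.seed,
            "converged": self.converged,
            "x_mean": [float(v) for v in self.x_mean],
            "x_sd": [float(v) for v in self.x_sd],
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "feature_names": self.feature_names,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _unpack(w: np.ndarray, p: int, h: int):
    i = 0
    W1 = w[i:i + h * p].reshape(h, p); i += h * p
    b1 = w[i:i + h]; i += h
    w2 = w[i:i + h]; i += h
    b2 = w[i]
    return W1, b1, w2, b2


def _forward(w: np.ndarray, Xs: np.ndarray, h: int):
    W1, b1, w2, b2 = _unpack(w, Xs.shape[1], h)
    a = np.tanh(Xs @ W1.T + b1)
    return a @ w2 + b2, a


def _jacobian(w: np.ndarray, Xs: np.ndarray, h: int) -> np.ndarray:
    """J[i, k] = ∂ŷᵢ/∂w_k for the flat weight layout (W1, b1, w2, b2)."""
    n, p = Xs.shape
    W1, b1, w2, b2 = _unpack(w, p, h)
    a = np.tanh(Xs @ W1.T + b1)          # n × h
    da = (1.0 - a ** 2) * w2             # n × h
    J = np.empty((n, w.size))
    J[:, :h * p] = (da[:, :, None] * Xs[:, None, :]).reshape(n, h * p)
    J[:, h * p:h * p + h] = da
    J[:, h * p + h:h * p + 2 * h] = a
    J[:, -1] = 1.0
    return J


def fit_brann(
    X,
    y,
    n_hidden: int = 3,
    seed: int = 0,
    max_iter: int = 200,
    conv_tol: float = 1e-8,
) -> BrannModel:
    """Train a BRANN regressor; deterministic given ``seed``.

    ``max_iter`` caps the outer Gauss–Newton iterations; convergence is
    declared when the relative change of F falls below ``conv_tol``.
    """
    if n_hidden < 1:
        raise ParameterError(f"n_hidden must be ≥ 1, got {n_hidden}")
    if isinstance(X, pd.DataFrame):
        feature_names = [str(c) for c in X.columns]
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        feature_names = [f"x{j}" for j in range(Xm.shape[1])]
    yv = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(Xm)) or not np.all(np.isfinite(yv)):
        raise InputError("non-finite values in X or y")
    n, p = Xm.shape

    x_mean = Xm.mean(axis=0)
    x_sd = Xm.std(axis=0, ddof=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    Xs = (Xm - x_mean) / x_sd
    y_mean = float(yv.mean())
    y_sd = float(yv.std(ddof=0))
    ys = (yv - y_mean) / y_sd if y_sd > 0 else yv - y_mean

    h = n_hidden
    n_w = h * (p + 1) + h + 1
    rng = np.random.default_rng(seed)
    w = np.concatenate([
        rng.normal(0.0, 1.0 / np.sqrt(p), h * p),     # W1
        rng.normal(0.0, 0.1, h),                      # b1
        rng.normal(0.0, 1.0 / np.sqrt(h), h),         # w2
        np.zeros(1),                                  # b2
    ])

    if y_sd == 0:
        # degenerate constant target: the zero network predicts the mean
        return BrannModel(
            n_input=p, n_hidden=h, weights=np.zeros(n_w), alpha=1.0,
            beta_noise=_BETA_CAP, gamma_effective=0.0, seed=seed,
            converged=True, objective_trace=[0.0],
            x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=1.0,
            feature_names=feature_names, clamped=True,
        )

    alpha, beta = 0.01, 1.0
    gamma = 0.0
    clamped = False
    mu = 1e-2
    converged = False

    def objective(wv, al, be):
        pred, _ = _forward(wv, Xs, h)
        e = ys - pred
        return be * float(e @ e) + al * 0.5 * float(wv @ wv), e

    F, e = objective(w, alpha, beta)
    trace: list[float] = [F]
    identity = np.eye(n_w)
    for _ in range(max_iter):
        # inner damped Gauss–Newton descent at fixed hyperparameters
        J = _jacobian(w, Xs, h)
        any_accepted = False
        for _ in range(100):
            grad = -2.0 * beta * (J.T @ e) + alpha * w
            H = 2.0 * beta * (J.T @ J) + alpha * identity
            F_before = F
            accepted = False
            for _ in range(30):
                try:
                    step = np.linalg.solve(H + mu * identity, -grad)
                except np.linalg.LinAlgError:
                    mu *= 10.0
                    continue
                F_try, e_try = objective(w + step, alpha, beta)
                if not np.isfinite(F_try):
                    raise TrainingError(f"non-finite loss during training; trace={trace}")
                if F_try < F_before:
                    w, F, e = w + step, F_try, e_try
                    mu = max(mu / 10.0, 1e-14)
                    accepted = True
                    any_accepted = True
                    break
                mu *= 10.0
                if mu > 1e12:
                    break
            if not accepted:
                break
            J = _jacobian(w, Xs, h)
            if (F_before - F) / max(F_before, 1e-300) < 1e-12:
                break
        # evidence-framework hyperparameter re-estimation
        E_D = float(e @ e)
        E_W = 0.5 * float(w @ w)
        H = 2.0 * beta * (J.T @ J) + alpha * identity
        try:
            tr_Hinv = float(np.trace(np.linalg.inv(H)))
        except np.linalg.LinAlgError:
            tr_Hinv = float(np.trace(np.linalg.pinv(H)))
        gamma = float(np.clip(n_w - alpha * tr_Hinv, 0.0, n_w))
        alpha_new = max(gamma / (2.0 * E_W), _ALPHA_FLOOR) if E_W > 0 else _ALPHA_FLOOR
        if n <= gamma or E_D <= 1e-300:
            beta_new = _BETA_CAP
            clamped = True
        else:
            beta_new = min((n - gamma) / (2.0 * E_D), _BETA_CAP)
        hyper_shift = max(abs(alpha_new - alpha) / max(alpha, _ALPHA_FLOOR),
                          abs(beta_new - beta) / max(beta, _ALPHA_FLOOR))
        alpha, beta = alpha_new, beta_new
        F, e = objective(w, alpha, beta)
        trace.append(F)
        if hyper_shift < max(conv_tol, 1e-8) or not any_accepted:
            converged = True
            break

    return BrannModel(
        n_input=p, n_hidden=h, weights=w, alpha=float(alpha),
        beta_noise=float(beta), gamma_effective=float(gamma), seed=seed,
        converged=converged, objective_trace=trace,
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean,
        y_sd=y_sd if y_sd > 0 else 1.0,
        feature_names=feature_names, clamped=clamped,
    )


def predict_brann(model: BrannModel, X_new) -> np.ndarray:
    """Deterministic forward pass with the stored standardization."""
    if isinstance(X_new, pd.DataFrame):
        if model.feature_names and all(f in X_new.columns for f in model.feature_names):
            Xm = X_new[model.feature_names].to_numpy(dtype=float)
        else:
            Xm = X_new.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X_new, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
    if Xm.shape[1] != model.n_input:
        raise InputError(
            f"X_new has {Xm.shape[1]} columns; model expects {model.n_input}"
        )
    Xs = (Xm - model.x_mean) / model.x_sd
    pred, _ = _forward(model.weights, Xs, model.n_hidden)
    return model.y_mean + model.y_sd * pred


def effective_parameters(model: BrannModel) -> float:
    """γ — the effective number of well-determined parameters; strictly below
    the total weight count whenever regularization is active."""
    return model.gamma_effective
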