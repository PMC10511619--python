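"""Sparse multiple linear regression with expectation–maximization feature
pruning (MLR-EM).

The sparsity-inducing EM scheme is the classical one for a Laplacian
(double-exponential) prior on the regression weights: the E-step replaces the
prior by its local quadratic bound, the M-step is then a reweighted ridge
solve,

    (XᵀX/n + β · D(t)) w(t+1) = Xᵀy/n,      D(t) = diag(1 / max(|wᵢ(t)|, ε)),

so that a fixed point with nonzero wᵢ satisfies the L1 stationarity condition
Xᵀ(y − Xw)/n = β·sign(w) — the surviving coefficients coincide with a lasso
solution at penalty β on the standardized, sample-averaged scale.  The 1/n
normalization makes β comparable across cohort sizes and puts the useful
sweep range at order 0.1–1 for unit-coded ordinal responses.  Features whose weight falls
below ``prune_tol`` are removed from the active set, which is what makes the
surviving-panel size shrink as the sparsity coefficient β grows.  With β = 0
the solution is ordinary least squares on the full active set.

Columns of X are z-scored and y is centred internally; coefficients are
reported on the standardized scale (a raw-scale back-transform is provided).
Per-coefficient t-statistics and p-values come from an *unpenalized*
least-squares refit on the selected panel; they are nominal, not adjusted for
selection.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)

_EPS = 1e-9  # guards the 1/|w| reweighting


@dataclass
class SparseLinearModel:
    """Fitted MLR-EM model: surviving features, standardized-scale weights,
    post-selection t-tests, and the standardization constants needed for
    prediction."""

    intercept: float
    coefficients: dict[str, float]
    beta_sparsity: float
    n_iterations: int
    converged: bool
    selected_features: list[str]
    t_stats: dict[str, float]
    p_values: dict[str, float]
    train_r2: float
    train_se: float
    column_means: dict[str, float]
    column_sds: dict[str, float]
    y_mean: float
    degenerate: bool = False
    exact_fit: bool = False
    dropped_constant: list[str] = field(default_factory=list)
    selected_indices: list[int] = field(default_factory=list)
    n_input_columns: int = 0

    @property
    def n_selected(self) -> int:
        return len(self.selected_features)

    def raw_coefficients(self) -> tuple[float, dict[str, float]]:
        """Back-transform to the raw (unstandardized) X scale; returns
        (raw intercept, raw-scale weights)."""
        raw = {f: w / self.column_sds[f] for f, w in self.coefficients.items()}
        intercept = self.y_mean - sum(
            raw[f] * self.column_means[f] for f in self.coefficients
        )
        return intercept, raw

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "beta_sparsity": self.beta_sparsity,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "selected_features": self.selected_features,
            "t_stats": self.t_stats,
            "p_values": self.p_values,
            "train_r2": self.train_r2,
            "train_se": self.train_se,
            "column_means": self.column_means,
            "column_sds": self.column_sds,
            "y_mean": self.y_mean,
            "degenerate": self.degenerate,
            "exact_fit": self.exact_fit,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def coefficient_table(self) -> pd.DataFrame:
        """Feature / coefficient / t / p table for the selected panel."""
        return pd.DataFrame(
            {
                "coefficient": [self.coefficients[f] for f in self.selected_features],
                "t": [self.t_stats[f] for f in self.selected_features],
                "p": [self.p_values[f] for f in self.selected_features],
            },
            index=pd.Index(self.selected_features, name="feature"),
        )


@dataclass
class SparsitySweepResult:
    """One MLR-EM fit per sparsity value, shared standardization."""

    entries: list[tuple[float, int, SparseLinearModel]]

    def n_selected(self) -> list[int]:
        return [n for _, n, _ in self.entries]

    def betas(self) -> list[float]:
        return [b for b, _, _ in self.entries]


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def fit_mlrem(
    X,
    y,
    beta_sparsity: float = 0.0,
    prune_tol: float = 1e-6,
    conv_tol: float = 1e-8,
    max_iter: int = 500,
) -> SparseLinearModel:
    """Fit the sparse MLR-EM model.

    Parameters
    ----------
    X : (n, p) array or DataFrame
        Design matrix; columns are z-scored internally and constant columns
        dropped with a warning.
    y : (n,) array-like
        Ordinal class codes (or any continuous response); centred internally.
    beta_sparsity : float
        Sparsity coefficient β ≥ 0.  Larger β prunes more features; β = 0
        reduces to ordinary least squares on the full active set.
    prune_tol, conv_tol, max_iter :
        Pruning threshold on standardized weights, convergence tolerance on
        the maximum weight change, and the iteration cap.
    """
    if beta_sparsity < 0:
        raise ParameterError(f"beta_sparsity must be non-negative, got {beta_sparsity}")
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, dtype=float).ravel()
    if Xm.shape[0] != yv.shape[0]:
        raise InputError(f"X has {Xm.shape[0]} rows but y has {yv.shape[0]}")
    if Xm.shape[0] < 3:
        raise InputError("need at least 3 samples")
    if not np.all(np.isfinite(Xm)):
        raise InputError("non-finite values in X")
    if not np.all(np.isfinite(yv)):
        raise InputError("non-finite values in y")

    means = Xm.mean(axis=0)
    sds = Xm.std(axis=0, ddof=0)
    keep = sds > 0
    dropped_constant = [n for n, k in zip(names, keep) if not k]
    if dropped_constant:
        logger.warning("fit_mlrem: dropping %d constant column(s): %s",
                       len(dropped_constant), dropped_constant[:10])
    Xm, names = Xm[:, keep], [n for n, k in zip(names, keep) if k]
    means, sds = means[keep], sds[keep]
    Xs = (Xm - means) / sds
    y_mean = float(yv.mean())
    yc = yv - y_mean

    n = Xs.shape[0]
    p = Xs.shape[1]
    active = np.arange(p)
    XtX_full = Xs.T @ Xs / n
    Xty_full = Xs.T @ yc / n

    if beta_sparsity == 0.0 or p == 0:
        w = (np.linalg.lstsq(Xs, yc, rcond=None)[0] if p else np.empty(0))
        n_iter, converged = 1, True
    else:
        # symmetric, deterministic ridge initialization
        w = np.linalg.solve(XtX_full + beta_sparsity * np.eye(p), Xty_full)
        n_iter, converged = 0, False
        for n_iter in range(1, max_iter + 1):
            d = beta_sparsity / np.maximum(np.abs(w), _EPS)
            A = XtX_full[np.ix_(active, active)] + np.diag(d)
            w_new = np.linalg.solve(A, Xty_full[active])
            delta = float(np.max(np.abs(w_new - w))) if w_new.size else 0.0
            survive = np.abs(w_new) >= prune_tol
            pruned = not survive.all()
            active = active[survive]
            w = w_new[survive]
            if w.size == 0:
                converged = True
                break
            if delta < conv_tol and not pruned:
                converged = True
                break

    selected = [names[j] for j in active]
    coefs = {f: float(v) for f, v in zip(selected, w)}
    degenerate = len(selected) == 0
    if degenerate:
        logger.warning("fit_mlrem: all features pruned at beta=%.4g; "
                       "intercept-only model", beta_sparsity)

    # post-selection inference and training metrics on the selected panel
    exact_fit = False
    if degenerate:
        t_stats: dict[str, float] = {}
        p_values: dict[str, float] = {}
        y_hat = np.full_like(yc, 0.0)
    else:
        Xsel = Xs[:, active]
        y_hat = Xsel @ w
        if Xs.shape[0] > len(selected) + 1:
            t_arr, p_arr, exact_fit = _ttests(Xsel, yc)
            t_stats = {f: float(t) for f, t in zip(selected, t_arr)}
            p_values = {f: float(pv) for f, pv in zip(selected, p_arr)}
        else:
            logger.warning("fit_mlrem: too few samples for t-tests "
                           "(n=%d, selected=%d)", Xs.shape[0], len(selected))
            t_stats = {f: float("nan") for f in selected}
            p_values = {f: float("nan") for f in selected}

    from .evaluate import regression_metrics

    metrics = regression_metrics(yv, y_hat + y_mean)
    return SparseLinearModel(
        intercept=y_mean,
        coefficients=coefs,
        beta_sparsity=float(beta_sparsity),
        n_iterations=n_iter,
        converged=converged,
        selected_features=selected,
        t_stats=t_stats,
        p_values=p_values,
        train_r2=metrics.r2,
        train_se=metrics.se,
        column_means={f: float(means[j]) for f, j in zip(selected, active)},
        column_sds={f: float(sds[j]) for f, j in zip(selected, active)},
        y_mean=y_mean,
        degenerate=degenerate,
        exact_fit=exact_fit,
        dropped_constant=dropped_constant,
        selected_indices=[int(j) for j in active],
        n_input_columns=p,
    )


def _ttests(Xc: np.ndarray, yc: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Unpenalized OLS t-tests on centred data (intercept absorbed by the
    centring, but it still costs a degree of freedom)."""
    n, k = Xc.shape
    rank = np.linalg.matrix_rank(Xc)
    if rank < k:
        # drop aliased columns greedily, report them as t=0, p=1
        keep_idx: list[int] = []
        basis = np.empty((n, 0))
        for j in range(k):
            cand = np.column_stack([basis, Xc[:, j]])
            if np.linalg.matrix_rank(cand) > basis.shape[1]:
                keep_idx.append(j)
                basis = cand
        aliased = sorted(set(range(k)) - set(keep_idx))
        logger.warning("coefficient_ttests: dropping %d aliased column(s) "
                       "(rank %d < %d)", len(aliased), rank, k)
        t_full = np.zeros(k)
        p_full = np.ones(k)
        t_sub, p_sub, exact = _ttests(Xc[:, keep_idx], yc)
        t_full[keep_idx] = t_sub
        p_full[keep_idx] = p_sub
        return t_full, p_full, exact
    XtX = Xc.T @ Xc
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (Xc.T @ yc)
    resid = yc - Xc @ beta
    dof = n - k - 1
    sse = float(resid @ resid)
    exact = sse <= 1e-12 * max(1.0, float(yc @ yc))
    if exact:
        logger.info("coefficient_ttests: exact fit (zero residuals)")
        t = np.where(beta == 0, 0.0, np.sign(beta) * np.inf)
        p = np.where(beta == 0, 1.0, np.finfo(float).tiny)
        return t, p, True
    sigma2 = sse / dof
    se = np.sqrt(np.clip(sigma2 * np.diag(XtX_inv), 0.0, None))
    with np.errstate(divide="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                     np.sign(beta) * np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return t, p, False


def coefficient_ttests(X_selected, y) -> tuple[dict[str, float], dict[str, float]]:
    """Per-coefficient t-statistics and two-sided p-values from an
    unpenalized least-squares refit with intercept.

    SEs come from the residual variance times the diagonal of the inverse
    normal-equations matrix; p-values use Student's t with n − k − 1 degrees
    of freedom.  An exact fit (zero residuals) reports the smallest
    representable p.
    """
    Xm, names = _as_matrix(X_selected)
    yv = np.asarray(y, dtype=float).ravel()
    n, k = Xm.shape
    if n <= k + 1:
        raise InputError(f"need n > n_selected + 1 (n={n}, selected={k})")
    Xc = Xm - Xm.mean(axis=0)
    yc = yv - yv.mean()
    t, p, _ = _ttests(Xc, yc)
    return ({f: float(v) for f, v in zip(names, t)},
            {f: float(v) for f, v in zip(names, p)})


def sparsity_sweep(X, y, betas: Sequence[float], **fit_kwargs) -> SparsitySweepResult:
    """Fit one MLR-EM model per sparsity value β (strictly increasing).

    Standardization is shared across fits because it is a deterministic
    function of X alone.
    """
    betas = [float(b) for b in betas]
    if not betas:
        raise ParameterError("betas must be non-empty")
    if any(b < 0 for b in betas):
        raise ParameterError("betas must be non-negative")
    if any(b2 <= b1 for b1, b2 in zip(betas, betas[1:])):
        raise ParameterError("betas must be strictly increasing")
    entries = []
    for b in betas:
        model = fit_mlrem(X, y, beta_sparsity=b, **fit_kwargs)
        entries.append((b, model.n_selected, model))
    return SparsitySweepResult(entries)


def predict(model: SparseLinearModel, X_new) -> np.ndarray:
    """Continuous (un-rounded) predictions; rounding to class codes is the
    evaluation module's job."""
    if model.degenerate:
        if isinstance(X_new, pd.DataFrame):
            n = len(X_new)
        else:
            arr = np.asarray(X_new, dtype=float)
            n = arr.shape[0] if arr.ndim > 1 else arr.shape[0]
        return np.full(n, model.y_mean)
    if isinstance(X_new, pd.DataFrame):
        missing = [f for f in model.selected_features if f not in X_new.columns]
        if missing:
            raise InputError(f"X_new lacks selected feature(s) {missing}")
        Xm = X_new[model.selected_features].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X_new, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        if Xm.shape[1] == model.n_input_columns and model.selected_indices:
            Xm = Xm[:, model.selected_indices]
        elif Xm.shape[1] != len(model.selected_features):
            raise InputError(
                f"X_new has {Xm.shape[1]} columns; model selected "
                f"{len(model.selected_features)} feature(s) {model.selected_features}"
            )
    mu = np.array([model.column_means[f] for f in model.selected_features])
    sd = np.array([model.column_sds[f] for f in model.selected_features])
    w = np.array([model.coefficients[f] for f in model.selected_features])
    return model.y_mean + ((Xm - mu) / sd) @ w
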