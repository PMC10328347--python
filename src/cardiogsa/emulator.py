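"""Gaussian-process emulators with a linear prior mean.

One emulator per scalar simulator output.  The prior is

    E[f(x)]      = beta_0 + sum_i beta_i x_i
    C[f(x),f(x')] = k(x, x')

with k an anisotropic (ARD) exponentiated-quadratic or Matern-5/2
kernel plus an optional nugget.  Inputs are standardised to the unit
box and outputs centred/scaled before fitting; kernel hyperparameters
maximise the profile marginal likelihood (the mean coefficients beta
are profiled out by generalised least squares), with seeded random
restarts.  Predictions include the universal-kriging variance
correction for the uncertainty in beta.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

JITTER = 1e-8


def _chol_escalate(K: np.ndarray, start: float = 1e-11):
    """Cholesky with escalating diagonal jitter; returns (L, jitter used)."""
    jit = start
    for _ in range(8):
        try:
            return cholesky(K + jit * np.eye(len(K)), lower=True), jit
        except np.linalg.LinAlgError:
            jit *= 100.0
    raise np.linalg.LinAlgError("kernel matrix not positive definite")

__all__ = [
    "EmulatorModel",
    "PosteriorPrediction",
    "CVReport",
    "fit_gpe",
    "cross_validate",
    "coefficient_of_determination",
    "independent_standard_error",
]


@dataclass
class PosteriorPrediction:
    """Posterior mean E[f(x)|D] and standard deviation sigma[f(x)|D]."""

    mean: np.ndarray
    sd: np.ndarray


@dataclass
class CVReport:
    """Per-fold and mean cross-validation scores."""

    r2: list[float]
    ise: list[float]
    seed: int

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2))

    @property
    def mean_ise(self) -> float:
        return float(np.mean(self.ise))


def _sq_dists(X1: np.ndarray, X2: np.ndarray, ls: np.ndarray) -> np.ndarray:
    """Pairwise squared distances scaled per dimension by lengthscales."""
    A = X1 / ls
    B = X2 / ls
    d2 = (
        (A**2).sum(1)[:, None] + (B**2).sum(1)[None, :] - 2.0 * A @ B.T
    )
    return np.maximum(d2, 0.0)


def _kernel(X1, X2, ls, sig2, kind):
    d2 = _sq_dists(X1, X2, ls)
    if kind == "exp-quadratic":
        return sig2 * np.exp(-0.5 * d2)
    if kind == "matern-5/2":
        d = np.sqrt(d2)
        s5 = np.sqrt(5.0)
        return sig2 * (1.0 + s5 * d + 5.0 * d2 / 3.0) * np.exp(-s5 * d)
    raise ValueError(f"unknown kernel {kind!r}")


class EmulatorModel:
    """Trained GP emulator for one scalar output.

    Not constructed directly; use :func:`fit_gpe`.
    """

    def __init__(
        self,
        X_raw: np.ndarray,
        y_raw: np.ndarray,
        x_lo: np.ndarray,
        x_hi: np.ndarray,
        kernel: str,
        lengthscales: np.ndarray,
        signal_var: float,
        nugget: float,
        constant: bool = False,
        warn_flags: Sequence[str] = (),
    ):
        self.X_raw = np.asarray(X_raw, float)
        self.y_raw = np.asarray(y_raw, float)
        self.x_lo, self.x_hi = np.asarray(x_lo, float), np.asarray(x_hi, float)
        self.kernel = kernel
        self.lengthscales = np.asarray(lengthscales, float)
        self.signal_var = float(signal_var)
        self.nugget = float(nugget)
        self.constant = bool(constant)
        self.warn_flags = list(warn_flags)
        self.y_mean = float(self.y_raw.mean())
        ystd = float(self.y_raw.std())
        self.y_std = ystd if ystd > 0 else 1.0
        self._factorise()

    # -- internals ----------------------------------------------------------
    def _unit(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.x_hi > self.x_lo, self.x_hi - self.x_lo, 1.0)
        return (np.asarray(X, float) - self.x_lo) / span

    def _basis(self, U: np.ndarray) -> np.ndarray:
        return np.hstack([np.ones((U.shape[0], 1)), U])

    def _factorise(self) -> None:
        U = self._unit(self.X_raw)
        self._U = U
        y = (self.y_raw - self.y_mean) / self.y_std
        if self.constant:
            self.beta_scaled = np.zeros(U.shape[1] + 1)
            self.beta = self._beta_native(self.beta_scaled)
            return
        K = _kernel(U, U, self.lengthscales, self.signal_var, self.kernel)
        K[np.diag_indices_from(K)] += self.nugget
        self._L, _ = _chol_escalate(K)
        H = self._basis(U)
        Kinv_H = cho_solve((self._L, True), H)
        Kinv_y = cho_solve((self._L, True), y)
        A = H.T @ Kinv_H
        self._A_chol = cho_factor(A)
        self.beta_scaled = cho_solve(self._A_chol, H.T @ Kinv_y)
        resid = y - H @ self.beta_scaled
        self._alpha = cho_solve((self._L, True), resid)
        self._Kinv_H = Kinv_H
        self.beta = self._beta_native(self.beta_scaled)

    def _beta_native(self, b: np.ndarray) -> np.ndarray:
        """Mean coefficients on the raw output / raw input scale."""
        span = np.where(self.x_hi > self.x_lo, self.x_hi - self.x_lo, 1.0)
        slopes = b[1:] * self.y_std / span
        intercept = self.y_mean + b[0] * self.y_std - slopes @ self.x_lo
        return np.concatenate([[intercept], slopes])

    # -- public API ---------------------------------------------------------
    @property
    def D(self) -> int:
        return self.X_raw.shape[1]

    def predict(self, X_star: np.ndarray) -> PosteriorPrediction:
        X_star = np.atleast_2d(np.asarray(X_star, float))
        if X_star.size == 0:
            return PosteriorPrediction(np.empty(0), np.empty(0))
        if X_star.shape[1] != self.D:
            raise ValueError(
                f"expected {self.D} input dimensions, got {X_star.shape[1]}"
            )
        Us = self._unit(X_star)
        if self.constant:
            m = np.full(len(Us), self.y_mean)
            return PosteriorPrediction(m, np.zeros(len(Us)))
        Ks = _kernel(Us, self._U, self.lengthscales, self.signal_var, self.kernel)
        Hs = self._basis(Us)
        mean = Hs @ self.beta_scaled + Ks @ self._alpha
        v = solve_triangular(self._L, Ks.T, lower=True)
        var = self.signal_var - (v**2).sum(0)
        # universal-kriging correction for the uncertainty in beta
        R = Hs.T - self._Kinv_H.T @ Ks.T
        var = var + (R * cho_solve(self._A_chol, R)).sum(0)
        var = np.maximum(var, 0.0)
        return PosteriorPrediction(
            mean * self.y_std + self.y_mean, np.sqrt(var) * self.y_std
        )

    def predict_cov(self, X_star: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and full covariance matrix (raw output scale)."""
        X_star = np.atleast_2d(np.asarray(X_star, float))
        Us = self._unit(X_star)
        if self.constant:
            return (
                np.full(len(Us), self.y_mean),
                np.zeros((len(Us), len(Us))),
            )
        Ks = _kernel(Us, self._U, self.lengthscales, self.signal_var, self.kernel)
        Kss = _kernel(Us, Us, self.lengthscales, self.signal_var, self.kernel)
        Hs = self._basis(Us)
        mean = Hs @ self.beta_scaled + Ks @ self._alpha
        v = solve_triangular(self._L, Ks.T, lower=True)
        cov = Kss - v.T @ v
        R = Hs.T - self._Kinv_H.T @ Ks.T
        cov = cov + R.T @ cho_solve(self._A_chol, R)
        return mean * self.y_std + self.y_mean, cov * self.y_std**2

    def sample_posterior(
        self, X_star: np.ndarray, n_draws: int, seed: int
    ) -> np.ndarray:
        """Joint posterior draws; shape (n_draws, n_points)."""
        if n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        mean, cov = self.predict_cov(X_star)
        rng = np.random.default_rng(seed)
        cov = cov + np.eye(len(mean)) * JITTER * max(self.y_std**2, 1.0)
        L = cholesky(cov, lower=True)
        z = rng.standard_normal((n_draws, len(mean)))
        draws = mean[None, :] + z @ L.T
        if self.constant:
            draws = np.tile(mean, (n_draws, 1))
        return draws

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel,
            "lengthscales": self.lengthscales.tolist(),
            "signal_var": self.signal_var,
            "nugget": self.nugget,
            "constant": self.constant,
            "warn_flags": self.warn_flags,
            "x_lo": self.x_lo.tolist(),
            "x_hi": self.x_hi.tolist(),
            "X": self.X_raw.tolist(),
            "y": self.y_raw.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "EmulatorModel":
        return cls(
            np.array(d["X"]),
            np.array(d["y"]),
            np.array(d["x_lo"]),
            np.array(d["x_hi"]),
            d["kernel"],
            np.array(d["lengthscales"]),
            d["signal_var"],
            d["nugget"],
            d["constant"],
            d.get("warn_flags", ()),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EmulatorModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _nll_and_grad(theta, U, y, H, kind, fit_nugget, fixed_nugget):
    D = U.shape[1]
    ls = np.exp(theta[:D])
    sig2 = np.exp(theta[D])
    nug = np.exp(theta[D + 1]) if fit_nugget else fixed_nugget
    n = len(y)
    K = _kernel(U, U, ls, sig2, kind)
    Kn = K + (nug + JITTER) * np.eye(n)
    try:
        L = cholesky(Kn, lower=True)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    Kinv_H = cho_solve((L, True), H)
    Kinv_y = cho_solve((L, True), y)
    A = H.T @ Kinv_H
    try:
        Ac = cho_factor(A)
    except np.linalg.LinAlgError:
        return 1e10, np.zeros_like(theta)
    beta = cho_solve(Ac, H.T @ Kinv_y)
    r = y - H @ beta
    alpha = cho_solve((L, True), r)
    nll = 0.5 * r @ alpha + np.log(np.diag(L)).sum() + 0.5 * n * np.log(2 * np.pi)

    # gradient of the profile likelihood (envelope theorem: d beta terms drop)
    Kinv = cho_solve((L, True), np.eye(n))
    W = Kinv - np.outer(alpha, alpha)  # tr(W dK)/2 is the gradient kernel
    grad = np.zeros_like(theta)
    d2 = _sq_dists(U, U, ls)
    if kind == "exp-quadratic":
        base = K  # sig2 * exp(-d2/2)
        for j in range(D):
            diff = (U[:, j : j + 1] - U[:, j : j + 1].T) ** 2 / ls[j] ** 2
            dK = base * diff  # d/dlog ls_j
            grad[j] = 0.5 * (W * dK).sum()
    else:  # matern-5/2
        d = np.sqrt(d2)
        s5 = np.sqrt(5.0)
        # dk/d(d2) = -sig2 * 5/6 * (1 + s5 d) exp(-s5 d);  d(d2)/dlog ls_j = -2 diff
        dk_dd2 = -sig2 * (5.0 / 6.0) * (1.0 + s5 * d) * np.exp(-s5 * d)
        for j in range(D):
            diff = (U[:, j : j + 1] - U[:, j : j + 1].T) ** 2 / ls[j] ** 2
            dK = dk_dd2 * (-2.0 * diff)
            grad[j] = 0.5 * (W * dK).sum()
    grad[D] = 0.5 * (W * K).sum()  # d/dlog sig2
    if fit_nugget:
        grad[D + 1] = 0.5 * np.trace(W) * nug
    return float(nll), grad


def fit_gpe(
    X: np.ndarray,
    y: np.ndarray,
    bounds: np.ndarray | None = None,
    kernel: str = "exp-quadratic",
    n_restarts: int = 5,
    fit_nugget: bool = True,
    nugget_max_frac: float = 1e-4,
    seed: int = 0,
) -> EmulatorModel:
    """Fit a GP emulator to training inputs X (N, D) and outputs y (N,).

    ``bounds`` (D, 2) defines the unit-box standardisation; by default the
    min/max of the training inputs is used.  Hyperparameters maximise the
    profile marginal likelihood with ``n_restarts`` seeded restarts.  A
    constant output is fitted with zero signal variance and flagged.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if X.shape[0] != len(y):
        raise ValueError("X and y length mismatch")
    if not np.isfinite(y).all() or not np.isfinite(X).all():
        raise ValueError("non-finite training data")
    if bounds is not None:
        b = np.asarray(bounds, float)
        x_lo, x_hi = b[:, 0], b[:, 1]
    else:
        x_lo, x_hi = X.min(0), X.max(0)

    if np.ptp(y) == 0.0 or y.std() < 1e-14 * max(1.0, abs(y.mean())):
        warnings.warn("constant training output; fitting a degenerate emulator")
        return EmulatorModel(
            X, y, x_lo, x_hi, kernel, np.ones(X.shape[1]), 0.0, 0.0,
            constant=True, warn_flags=["constant-output"],
        )

    span = np.where(x_hi > x_lo, x_hi - x_lo, 1.0)
    U = (X - x_lo) / span
    ys = (y - y.mean()) / y.std()
    H = np.hstack([np.ones((len(ys), 1)), U])
    D = X.shape[1]

    lo = np.concatenate([np.full(D, np.log(0.05)), [np.log(1e-6)]])
    hi = np.concatenate([np.full(D, np.log(30.0)), [np.log(1e3)]])
    if fit_nugget:
        lo = np.concatenate([lo, [np.log(1e-10)]])
        hi = np.concatenate([hi, [np.log(max(nugget_max_frac, 1e-10))]])
    rng = np.random.default_rng(seed)

    best = None
    x0 = np.concatenate([np.zeros(D), [0.0]])
    # a near-degenerate start lets the optimizer find the linear-trend
    # solution (tiny signal variance) when the data is close to linear
    x1 = np.concatenate([np.full(D, np.log(10.0)), [np.log(1e-5)]])
    if fit_nugget:
        x0 = np.concatenate([x0, [np.log(1e-8)]])
        x1 = np.concatenate([x1, [np.log(1e-9)]])
    starts = [x0, x1] + [
        lo + rng.random(len(lo)) * (hi - lo) for _ in range(max(n_restarts - 1, 0))
    ]
    for s in starts:
        res = optimize.minimize(
            _nll_and_grad,
            s,
            args=(U, ys, H, kernel, fit_nugget, 0.0),
            jac=True,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    ls = np.exp(theta[:D])
    sig2 = float(np.exp(theta[D]))
    nug = float(np.exp(theta[D + 1])) if fit_nugget else 0.0
    return EmulatorModel(X, y, x_lo, x_hi, kernel, ls, sig2, nug)


# ---------------------------------------------------------------------------
# validation metrics
# ---------------------------------------------------------------------------

def coefficient_of_determination(y: np.ndarray, mean: np.ndarray) -> float:
    """R^2 = 1 - RSS/TSS on held-out observations."""
    y = np.asarray(y, float)
    mean = np.asarray(mean, float)
    rss = ((y - mean) ** 2).sum()
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return 1.0 if rss == 0 else -np.inf
    return float(1.0 - rss / tss)


def independent_standard_error(
    y: np.ndarray, mean: np.ndarray, sd: np.ndarray
) -> float:
    """Percentage of points with |mean - y| < 2 * sd."""
    y, mean, sd = (np.asarray(a, float) for a in (y, mean, sd))
    return float(100.0 * np.mean(np.abs(mean - y) < 2.0 * sd))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> CVReport:
    """k-fold cross-validation returning per-fold R^2 and ISE."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = len(y)
    if n < k_folds:
        raise ValueError("not enough rows for the requested folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k_folds)
    r2s, ises = [], []
    for hold in folds:
        train = np.setdiff1d(perm, hold)
        model = fit_gpe(X[train], y[train], seed=seed, **fit_kwargs)
        pred = model.predict(X[hold])
        r2s.append(coefficient_of_determination(y[hold], pred.mean))
        ises.append(independent_standard_error(y[hold], pred.mean, pred.sd))
    return CVReport(r2s, ises, seed)
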