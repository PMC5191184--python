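"""Bayesian linear regression with automatic relevance determination (ARD).

The model is ``v = w0 + w^T x + eps`` with Gaussian noise of precision
``alpha`` and an independent zero-mean Gaussian prior of precision ``beta_i``
on every weight.  For fixed hyperparameters the weight posterior is Gaussian
with

    mu    = alpha * Sigma * Phi^T v
    Sigma = (B + alpha * Phi^T Phi)^{-1},   B = diag(beta)

and the hyperparameters are chosen by maximizing the marginal likelihood
through the classical fixed-point updates

    gamma_i = 1 - beta_i * Sigma_ii
    beta_i  = gamma_i / mu_i^2
    1/alpha = ||v - Phi mu||^2 / (N - sum_i gamma_i).

Weights whose prior precision grows without bound are irrelevant: after each
update cycle, features whose ``beta_i`` exceeds ``200 * alpha`` are pruned
from the active set and never re-enter.  The bias column is exempt from
pruning.  The optimizer contains no randomness, so a fit is fully
deterministic given the data and settings.

Features are standardized internally (the stored moments are re-applied at
prediction time) so that the prior precisions of features with heterogeneous
units are comparable and the pruning threshold is meaningful.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "ARDLinearRegression",
    "ARDResults",
    "PredictiveDistribution",
    "design_matrix",
    "posterior",
    "log_marginal_likelihood",
    "PRUNE_FACTOR",
]

#: prior precisions larger than this multiple of the noise precision mark a
#: feature as irrelevant
PRUNE_FACTOR = 200.0

_ALPHA_MAX = 1e12
_BETA_MIN = 1e-12
_BETA_MAX = 1e16


def design_matrix(X: np.ndarray):
    """Augment with a leading column of ones and standardize the features.

    Returns ``(Phi, means, sds)`` where ``Phi`` is ``N x (d+1)`` and the
    stored per-column moments reproduce the transformation at prediction
    time.  Zero-variance columns are retained unscaled with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    means = X.mean(axis=0) if X.shape[0] else np.zeros(X.shape[1])
    sds = X.std(axis=0) if X.shape[0] else np.ones(X.shape[1])
    zero_var = sds == 0
    if np.any(zero_var):
        warnings.warn(
            f"{np.count_nonzero(zero_var)} zero-variance feature columns "
            "retained unscaled",
            stacklevel=2,
        )
        means = np.where(zero_var, 0.0, means)
        sds = np.where(zero_var, 1.0, sds)
    Phi = np.column_stack([np.ones(X.shape[0]), (X - means) / sds])
    return Phi, means, sds


def posterior(Phi: np.ndarray, v: np.ndarray, beta: np.ndarray, alpha: float):
    """Gaussian weight posterior ``(mu, Sigma)`` for fixed hyperparameters.

    Solved via a symmetric (Cholesky) factorization of
    ``A = B + alpha Phi^T Phi``; no explicit inverse of A is formed for mu.
    """
    Phi = np.asarray(Phi, dtype=float)
    v = np.asarray(v, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if alpha <= 0 or np.any(beta <= 0):
        raise ValueError("alpha and all beta must be positive")
    A = np.diag(beta) + alpha * (Phi.T @ Phi)
    try:
        chol = cho_factor(A, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"posterior system numerically singular "
            f"(condition number {np.linalg.cond(A):.3e})"
        ) from exc
    Sigma = cho_solve(chol, np.eye(A.shape[0]))
    mu = alpha * cho_solve(chol, Phi.T @ v)
    return mu, Sigma


def log_marginal_likelihood(
    Phi: np.ndarray, v: np.ndarray, beta: np.ndarray, alpha: float
) -> float:
    """Log evidence ``-0.5 * (N ln 2pi + ln|C| + v^T C^{-1} v)`` with
    ``C = alpha^{-1} I + Phi B^{-1} Phi^T``.

    Evaluated through the posterior factorization rather than the N x N
    matrix C: ``ln|C| = -N ln alpha - sum ln beta + ln|A|`` and
    ``v^T C^{-1} v = alpha ||v - Phi mu||^2 + mu^T B mu`` with
    ``A = B + alpha Phi^T Phi``.
    """
    Phi = np.asarray(Phi, dtype=float)
    v = np.asarray(v, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if alpha <= 0 or np.any(beta <= 0):
        raise ValueError("alpha and all beta must be positive (C must be PD)")
    n = v.size
    A = np.diag(beta) + alpha * (Phi.T @ Phi)
    try:
        chol = cho_factor(A, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance C is not positive definite") from exc
    mu = alpha * cho_solve(chol, Phi.T @ v)
    logdet_A = 2.0 * np.sum(np.log(np.diag(chol[0])))
    logdet_C = -n * np.log(alpha) - np.sum(np.log(beta)) + logdet_A
    resid = v - Phi @ mu
    quad = alpha * (resid @ resid) + (mu * beta) @ mu
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet_C + quad)


@dataclass(frozen=True)
class PredictiveDistribution:
    """Gaussian predictive distribution; the variance is the noise variance
    ``1/alpha`` plus the posterior-weight uncertainty, so it is never below
    ``1/alpha``."""

    mean: np.ndarray
    variance: np.ndarray

    @property
    def std(self) -> np.ndarray:
        return np.sqrt(self.variance)


class ARDLinearRegression:
    """ARD Bayesian linear regression model.

    Parameters
    ----------
    X : array_like, shape (N, d)
        Feature matrix.
    y : array_like, shape (N,)
        Regression targets (m/s when predicting the average progression
        velocity).
    feature_names : sequence of str, optional
        Labels for the d features; generated when omitted.

    Examples
    --------
    >>> model = ARDLinearRegression(X, y, feature_names=names)
    >>> res = model.fit()
    >>> res.predict(X_new).mean
    """

    def __init__(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if y.shape != (X.shape[0],):
            raise ValueError("y must be a vector with one entry per row of X")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("X and y must be finite")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 observations")
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
        elif len(feature_names) != X.shape[1]:
            raise ValueError("feature_names must match the number of columns")
        if X.shape[0] < X.shape[1] + 1:
            warnings.warn(
                "fewer observations than parameters; the posterior relies "
                "entirely on the prior for identification",
                stacklevel=2,
            )
        self.X = X
        self.y = y
        self.feature_names = list(feature_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str, features=None):
        if features is None:
            features = [c for c in df.columns if c != target]
        return cls(
            df[list(features)].to_numpy(dtype=float),
            df[target].to_numpy(dtype=float),
            feature_names=list(features),
        )

    def fit(
        self,
        tol: float = 1e-6,
        max_iter: int = 1000,
        prune_factor: float = PRUNE_FACTOR,
    ) -> "ARDResults":
        """Evidence maximization by fixed-point hyperparameter updates.

        Iterates posterior -> (gamma, beta, alpha) updates, pruning features
        whose updated prior precision exceeds ``prune_factor`` times the
        noise precision that produced the current posterior (the pre-update
        alpha of the cycle), until the largest relative hyperparameter
        change falls below ``tol`` or ``max_iter`` cycles have run.

        Comparing against the pre-update noise precision applies the
        threshold along the hyperparameter trajectory: the precisions of
        irrelevant weights diverge within the first cycles, while the noise
        precision is still rising from its conservative start at
        ``1 / var(v)``, so irrelevant features are removed reliably instead
        of occasionally surviving on chance correlations once the noise
        precision has converged.
        """
        Phi, means, sds = design_matrix(self.X)
        n, d1 = Phi.shape
        v = self.y

        active = np.ones(d1, dtype=bool)  # index 0 is the bias column
        beta = np.ones(d1)
        var_v = v.var()
        alpha = 1.0 / var_v if var_v > 0 else 1.0

        gamma = np.zeros(d1)
        mu_full = np.zeros(d1)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            beta_old = beta.copy()
            alpha_old = alpha

            Phi_a = Phi[:, active]
            mu_a, Sigma_a = posterior(Phi_a, v, beta[active], alpha)
            gamma_a = 1.0 - beta[active] * np.diag(Sigma_a)

            beta_a = np.empty_like(gamma_a)
            nonzero = mu_a != 0.0
            beta_a[nonzero] = np.clip(
                gamma_a[nonzero] / mu_a[nonzero] ** 2, _BETA_MIN, _BETA_MAX
            )
            # an exactly-zero posterior mean marks the weight as irrelevant
            beta_a[~nonzero] = prune_factor * alpha_old * (1.0 + 1e-9)

            resid = v - Phi_a @ mu_a
            denom = n - gamma_a.sum()
            if denom <= 0:
                warnings.warn(
                    "effective degrees of freedom non-positive; skipping the "
                    "noise-precision update this iteration",
                    stacklevel=2,
                )
            else:
                rss = resid @ resid
                alpha = min(denom / max(rss, denom / _ALPHA_MAX), _ALPHA_MAX)

            beta[active] = beta_a
            over_threshold = beta_a > prune_factor * alpha_old
            over_threshold[0] = False  # bias column (always active) is exempt
            prune = np.flatnonzero(active)[over_threshold]

            gamma[:] = 0.0
            gamma[active] = gamma_a
            mu_full[:] = 0.0
            mu_full[active] = mu_a

            if prune.size:
                active[prune] = False

            rel_beta = np.max(
                np.abs(beta[active] - beta_old[active])
                / np.maximum(np.abs(beta_old[active]), 1e-300)
            )
            rel_alpha = abs(alpha - alpha_old) / max(abs(alpha_old), 1e-300)
            if prune.size == 0 and max(rel_beta, rel_alpha) < tol:
                converged = True
                break

        # final posterior consistent with the returned hyperparameters
        Phi_a = Phi[:, active]
        mu_a, Sigma_a = posterior(Phi_a, v, beta[active], alpha)
        gamma[:] = 0.0
        gamma[active] = 1.0 - beta[active] * np.diag(Sigma_a)
        mu_full[:] = 0.0
        mu_full[active] = mu_a
        Sigma_full = np.zeros((d1, d1))
        Sigma_full[np.ix_(active, active)] = Sigma_a

        return ARDResults(
            model=self,
            mu=mu_full,
            Sigma=Sigma_full,
            beta=beta,
            alpha=alpha,
            gamma=gamma,
            active_mask=active,
            n_iterations=n_iter,
            converged=converged,
            feature_means=means,
            feature_sds=sds,
        )


@dataclass
class ARDResults:
    """Fitted ARD regression: weight posterior, hyperparameters and the
    retained-feature mask.  Coefficients are on the internal standardized
    feature scale; :meth:`predict` applies the stored moments."""

    model: ARDLinearRegression | None
    mu: np.ndarray
    Sigma: np.ndarray
    beta: np.ndarray
    alpha: float
    gamma: np.ndarray
    active_mask: np.ndarray
    n_iterations: int
    converged: bool
    feature_means: np.ndarray
    feature_sds: np.ndarray
    feature_names: list = field(default=None)

    def __post_init__(self) -> None:
        if self.feature_names is None:
            if self.model is not None:
                self.feature_names = list(self.model.feature_names)
            else:
                self.feature_names = [f"x{j}" for j in range(self.mu.size - 1)]

    @property
    def params(self) -> np.ndarray:
        """Posterior mean weights (bias first), standardized scale."""
        return self.mu

    @property
    def bse(self) -> np.ndarray:
        """Posterior standard deviations of the weights."""
        return np.sqrt(np.diag(self.Sigma))

    @property
    def active_features(self) -> list:
        """Names of the retained (non-pruned) features."""
        return [
            name
            for name, keep in zip(self.feature_names, self.active_mask[1:])
            if keep
        ]

    @property
    def n_active(self) -> int:
        """Number of retained features, bias excluded."""
        return int(np.count_nonzero(self.active_mask[1:]))

    def _design_rows(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        X = np.atleast_2d(X)
        if X.shape[1] != self.feature_means.size:
            raise ValueError(
                f"expected {self.feature_means.size} features, got {X.shape[1]}"
            )
        if not np.isfinite(X).all():
            raise ValueError("inputs must be finite")
        Phi = np.column_stack(
            [np.ones(X.shape[0]), (X - self.feature_means) / self.feature_sds]
        )
        return Phi, single

    def predict(self, X) -> PredictiveDistribution:
        """Gaussian predictive distribution at new inputs.

        ``mean = mu^T phi(x)`` and ``variance = 1/alpha + phi(x)^T Sigma
        phi(x)``; pruned coordinates contribute nothing.
        """
        Phi, single = self._design_rows(X)
        Phi_a = Phi[:, self.active_mask]
        mu_a = self.mu[self.active_mask]
        Sigma_a = self.Sigma[np.ix_(self.active_mask, self.active_mask)]
        mean = Phi_a @ mu_a
        variance = 1.0 / self.alpha + np.einsum(
            "ij,jk,ik->i", Phi_a, Sigma_a, Phi_a
        )
        if single:
            return PredictiveDistribution(float(mean[0]), float(variance[0]))
        return PredictiveDistribution(mean, variance)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "ARD Bayesian linear regression",
            f"  observations: {self.model.X.shape[0] if self.model is not None else 'n/a'}",
            f"  iterations:   {self.n_iterations} "
            f"({'converged' if self.converged else 'not converged'})",
            f"  noise precision alpha: {self.alpha:.6g} "
            f"(sigma = {1.0 / np.sqrt(self.alpha):.4g})",
            f"  retained features: {self.n_active} / {len(self.feature_names)}",
            "",
            f"  {'term':<14}{'kept':>5}{'coef':>12}{'post sd':>12}"
            f"{'beta':>12}{'gamma':>8}",
        ]
        names = ["bias"] + list(self.feature_names)
        sds = self.bse
        for j, name in enumerate(names):
            kept = "yes" if self.active_mask[j] else "no"
            lines.append(
                f"  {name:<14}{kept:>5}{self.mu[j]:>12.4f}{sds[j]:>12.4f}"
                f"{self.beta[j]:>12.4g}{self.gamma[j]:>8.3f}"
            )
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "Sigma": self.Sigma.tolist(),
            "beta": self.beta.tolist(),
            "alpha": float(self.alpha),
            "gamma": self.gamma.tolist(),
            "active_mask": self.active_mask.astype(int).tolist(),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "feature_names": list(self.feature_names),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "ARDResults":
        return cls(
            model=None,
            mu=np.asarray(d["mu"], dtype=float),
            Sigma=np.asarray(d["Sigma"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            alpha=float(d["alpha"]),
            gamma=np.asarray(d["gamma"], dtype=float),
            active_mask=np.asarray(d["active_mask"], dtype=bool),
            n_iterations=int(d["n_iterations"]),
            converged=bool(d["converged"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            feature_names=list(d["feature_names"]),
        )

    @classmethod
    def from_json(cls, path) -> "ARDResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
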