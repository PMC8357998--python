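"""Model-implied moments and Gaussian full-information likelihood.

The latent levels are linear in the individual effects: stacking the
occasions, ``levels = L @ (y0, ya)`` with a loading matrix built from
powers of ``M = I + A`` and their partial geometric sums.  The observed
vector therefore has mean ``L @ (mu0, mua)`` and covariance
``L phi L' + Q + R``, where Q accumulates innovation covariance through
the dynamics (zero for deterministic models) and R places the
measurement-error covariance on each occasion's block diagonal.

Two independent likelihood routes are provided: direct full-information
evaluation on the implied moments (missing entries marginalized out
case-wise), and a linear-Gaussian state-space (Kalman filter) route with
the latent levels and additive components as the state.  They agree to
numerical precision and cross-validate each other.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .model_spec import ModelSpec, ParameterSet, dynamics_matrix, validate
from .simulate import PanelData, simulate_panel

__all__ = [
    "ImpliedMoments",
    "loading_matrix",
    "implied_moments",
    "mc_moments",
    "row_loglik",
    "minus_two_loglik",
    "kalman_loglik",
]

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ImpliedMoments:
    """Implied mean vector and covariance matrix of the stacked observed vector.

    Ordering matches :class:`~latentchange.simulate.PanelData`: time-major,
    process fastest (x[0], y[0], x[1], y[1], ...).
    """

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if not np.all(np.isfinite(mean)):
            raise ValueError("implied mean must be finite")
        if cov.shape != (mean.shape[0], mean.shape[0]):
            raise ValueError("covariance shape does not match mean length")
        if not np.allclose(cov, cov.T, atol=1e-10, rtol=0.0):
            raise ValueError("implied covariance must be symmetric")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", (cov + cov.T) / 2.0)


def _power_sums(M: np.ndarray, T: int) -> Tuple[list, list]:
    """Powers M^t and partial geometric sums S_t = sum_{k<t} M^k for t = 0..T-1."""
    p = M.shape[0]
    powers = [np.eye(p)]
    sums = [np.zeros((p, p))]
    for t in range(1, T):
        sums.append(sums[-1] + powers[-1])
        powers.append(powers[-1] @ M)
    return powers, sums


def loading_matrix(spec: ModelSpec, params: ParameterSet) -> np.ndarray:
    """(pT) x 2p matrix mapping (initial levels, additive components) to levels.

    Occasion-t block is ``[M^t, S_t]`` with ``S_t = sum_{k=0}^{t-1} M^k``;
    univariate this is ``((1+beta)^t, ((1+beta)^t - 1)/beta)`` with limit
    ``(1, t)`` as beta -> 0.
    """
    p, T = spec.n_processes, spec.n_occasions
    M = np.eye(p) + dynamics_matrix(params)
    powers, sums = _power_sums(M, T)
    L = np.zeros((p * T, 2 * p))
    for t in range(T):
        L[t * p : (t + 1) * p, :p] = powers[t]
        L[t * p : (t + 1) * p, p:] = sums[t]
    return L


def implied_moments(spec: ModelSpec, params: ParameterSet) -> ImpliedMoments:
    """Implied mean and covariance of the observed vector under the model."""
    validate(spec, params)
    p, T = spec.n_processes, spec.n_occasions
    L = loading_matrix(spec, params)
    mean = L @ np.concatenate([params.mu0, params.mua])
    cov = L @ params.phi @ L.T
    if spec.stochastic:
        M = np.eye(p) + dynamics_matrix(params)
        powers, _ = _power_sums(M, T)
        psi = params.psi
        # Q[t, s] = sum_{k=1}^{min(t, s)} M^{t-k} psi M'^{s-k}
        for t in range(T):
            for s in range(T):
                block = np.zeros((p, p))
                for k in range(1, min(t, s) + 1):
                    block += powers[t - k] @ psi @ powers[s - k].T
                cov[t * p : (t + 1) * p, s * p : (s + 1) * p] += block
    for t in range(T):
        cov[t * p : (t + 1) * p, t * p : (t + 1) * p] += params.theta
    return ImpliedMoments(mean=mean, covariance=(cov + cov.T) / 2.0)


def mc_moments(
    spec: ModelSpec, params: ParameterSet, n: int, seed
) -> Tuple[np.ndarray, np.ndarray]:
    """Empirical mean and covariance of a simulated panel (brute-force oracle)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    panel = simulate_panel(spec, params, n, seed)
    obs = panel.observed
    return obs.mean(axis=0), np.cov(obs, rowvar=False, ddof=1)


def _gauss_m2ll(dev: np.ndarray, cov: np.ndarray) -> float:
    """-2 log N(dev; 0, cov) for one deviation vector, via Cholesky."""
    try:
        factor = cho_factor(cov, lower=True)
    except np.linalg.LinAlgError:
        logger.warning("covariance factorization failed; adding 1e-10 jitter")
        factor = cho_factor(cov + 1e-10 * np.eye(cov.shape[0]), lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
    maha = float(dev @ cho_solve(factor, dev))
    return len(dev) * LOG2PI + logdet + maha


def row_loglik(row: np.ndarray, moments: ImpliedMoments) -> float:
    """Log-density of one observed row under the implied moments.

    Missing entries (NaN) are marginalized out: the density is evaluated
    on the observed subvector against the matching submatrix.
    """
    row = np.asarray(row, dtype=float)
    mask = ~np.isnan(row)
    if not mask.any():
        raise ValueError("row has no observed entries")
    dev = row[mask] - moments.mean[mask]
    cov = moments.covariance[np.ix_(mask, mask)]
    return -0.5 * _gauss_m2ll(dev, cov)


def _pattern_groups(observed: np.ndarray):
    """Group row indices by missingness pattern; drops all-missing rows."""
    mask = ~np.isnan(observed)
    keep = mask.any(axis=1)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} all-missing row(s) from the likelihood",
            stacklevel=3,
        )
    patterns: dict = {}
    for i in np.flatnonzero(keep):
        patterns.setdefault(mask[i].tobytes(), (mask[i], []))[1].append(i)
    return patterns


def minus_two_loglik(spec: ModelSpec, params: ParameterSet, panel: PanelData) -> float:
    """-2 x summed casewise Gaussian log-likelihood of the panel (FIML).

    Rows are grouped by missingness pattern so each pattern's covariance
    is factorized once; within a pattern the quadratic form is evaluated
    through its sufficient statistics.
    """
    moments = implied_moments(spec, params)
    return _m2ll_from_moments(moments, panel.observed)


def _m2ll_from_moments(moments: ImpliedMoments, observed: np.ndarray) -> float:
    total = 0.0
    for mask, rows in _pattern_groups(observed).values():
        data = observed[np.ix_(rows, np.flatnonzero(mask))]
        dev = data - moments.mean[mask]
        cov = moments.covariance[np.ix_(mask, mask)]
        try:
            factor = cho_factor(cov, lower=True)
        except np.linalg.LinAlgError:
            logger.warning("covariance factorization failed; adding 1e-10 jitter")
            factor = cho_factor(cov + 1e-10 * np.eye(cov.shape[0]), lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
        maha = float(np.sum(dev * cho_solve(factor, dev.T).T))
        total += len(rows) * (mask.sum() * LOG2PI + logdet) + maha
    return total


def kalman_loglik(spec: ModelSpec, params: ParameterSet, panel: PanelData) -> float:
    """-2 log-likelihood via the prediction-error decomposition of a Kalman filter.

    State vector: (latent levels, additive components).  Transition
    ``[[M, I], [0, I]]`` with process noise psi on the level block (zero
    for deterministic models); observation picks the levels with error
    covariance theta.  Initial state mean ``(mu0, mua)`` with covariance
    phi.  Independent of the moment-expansion route; agrees with
    :func:`minus_two_loglik` to numerical precision.
    """
    validate(spec, params)
    p, T = spec.n_processes, spec.n_occasions
    M = np.eye(p) + dynamics_matrix(params)
    F = np.zeros((2 * p, 2 * p))
    F[:p, :p] = M
    F[:p, p:] = np.eye(p)
    F[p:, p:] = np.eye(p)
    Q = np.zeros((2 * p, 2 * p))
    if spec.stochastic:
        Q[:p, :p] = params.psi
    H_full = np.zeros((p, 2 * p))
    H_full[:, :p] = np.eye(p)

    x0 = np.concatenate([params.mu0, params.mua])
    total = 0.0
    for row in panel.observed:
        if not np.any(~np.isnan(row)):
            continue
        x, P = x0.copy(), params.phi.copy()
        for t in range(T):
            if t > 0:
                x = F @ x
                P = F @ P @ F.T + Q
            obs = row[t * p : (t + 1) * p]
            mask = ~np.isnan(obs)
            if not mask.any():
                continue
            H = H_full[mask]
            R = params.theta[np.ix_(mask, mask)]
            innov = obs[mask] - H @ x
            S = H @ P @ H.T + R
            total += _gauss_m2ll(innov, S)
            K = P @ H.T @ np.linalg.inv(S)
            x = x + K @ innov
            P = P - K @ H @ P
            P = (P + P.T) / 2.0
    return total
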