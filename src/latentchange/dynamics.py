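"""Deterministic dynamics of the latent change score system.

The mean dynamics form a linear-affine system.  In discrete time the level
vector obeys the recursion ``y[t] = (I + A) y[t-1] + mu_a`` where A has the
self-feedbacks on the diagonal and the couplings off it; in continuous time
``dy/dt = a + b y`` with drift matrix b.  The two metrics are related by the
matrix exponential over the time lag, and the univariate solution is the
exponential curve ``y(t) = y_As - (y_As - y(t0)) exp(-r t)`` with rate
``r = -b`` and asymptote ``y_As = a / r``.

This module provides the exponential closed form, the ordinary differential
equation right-hand side, the additive-component/asymptote identity
``y_a = y_As * (-beta)``, CT<->DT conversion, the mean trajectory, fixed
points, and qualitative shape classification in one and two dimensions.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.linalg import expm, logm

from .model_spec import (
    CTParameterSet,
    ModelSpec,
    ParameterSet,
    ShapeClass,
    dynamics_matrix,
)

__all__ = [
    "MeanTrajectory",
    "BivariateShape",
    "exponential_level",
    "ct_derivative",
    "additive_from_asymptote",
    "asymptote_from_additive",
    "ct_to_dt",
    "dt_to_ct",
    "mean_trajectory",
    "fixed_point",
    "classify_univariate",
    "classify_bivariate",
]

DEFAULT_TOL = 1e-8


@dataclass(frozen=True)
class MeanTrajectory:
    """Implied mean latent levels over occasions.

    ``levels[t, j]`` is the mean level of process j at occasion t;
    ``levels[0]`` equals the initial-level means.
    """

    times: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.levels)):
            raise ValueError("trajectory levels must be finite")


@dataclass(frozen=True)
class BivariateShape:
    """Classification of a bivariate system's mean dynamics.

    ``label`` is the single system-level shape; for non-oscillatory
    systems ``per_process`` additionally carries one label per process
    (matching the univariate classifier exactly when both couplings are
    zero).  ``convergent`` is True iff the spectral radius of I + A is
    below 1, ``modulus`` is the largest eigenvalue modulus.
    """

    label: ShapeClass
    convergent: bool
    oscillatory: bool
    modulus: float
    eigenvalues: Tuple[complex, complex]
    per_process: Optional[Tuple[ShapeClass, ShapeClass]] = None


def exponential_level(asymptote: float, initial: float, rate: float, time: float) -> float:
    """Level of the exponential trajectory at ``time``.

    ``y(t) = y_As - (y_As - y(t0)) * exp(-r t)``: positive rates approach
    the asymptote, negative rates move away from it; at t = 0 the value is
    the initial level regardless of asymptote and rate.
    """
    return asymptote - (asymptote - initial) * np.exp(-rate * time)


def ct_derivative(level: np.ndarray, ct: CTParameterSet) -> np.ndarray:
    """Instantaneous change ``dy/dt = a + b y`` of the continuous-time system."""
    level = np.atleast_1d(np.asarray(level, dtype=float))
    if level.shape != (ct.p,):
        raise ValueError(f"level must have length {ct.p}, got shape {level.shape}")
    return ct.ct_additive + ct.drift @ level


def additive_from_asymptote(asymptote: float, beta: float) -> float:
    """Additive component implied by an asymptote: ``y_a = y_As * (-beta)``."""
    return asymptote * (-beta)


def asymptote_from_additive(additive: float, beta: float) -> float:
    """Asymptote implied by an additive component: ``y_As = y_a / (-beta)``.

    Raises
    ------
    ZeroDivisionError
        If ``beta`` is 0: the linear regime has no finite asymptote.
    """
    if beta == 0:
        raise ZeroDivisionError("beta = 0: linear regime, no finite asymptote")
    return additive / (-beta)


def ct_to_dt(ct: CTParameterSet, lag: float) -> Tuple[np.ndarray, np.ndarray]:
    """Rescale continuous-time dynamics to the discrete-time metric of ``lag``.

    Returns the change matrix ``A_dt = expm(b * lag) - I`` and additive
    vector ``a_dt = \\int_0^lag expm(b s) ds @ a``, such that iterating
    ``y[t] = y[t-1] + A_dt y[t-1] + a_dt`` matches the continuous-time
    solution at multiples of the lag.  The integral is evaluated through an
    augmented matrix exponential, which also covers singular drift (for
    zero drift it reduces to ``a * lag``).
    """
    if not (lag > 0):
        raise ValueError("lag must be positive")
    b = ct.drift
    a = ct.ct_additive
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(a))):
        raise ValueError("non-finite continuous-time parameters")
    p = ct.p
    dt_dynamics = expm(b * lag) - np.eye(p)
    # [[b, I], [0, 0]] exponentiates to [[e^{b lag}, \int_0^lag e^{b s} ds], [0, I]]
    aug = np.zeros((2 * p, 2 * p))
    aug[:p, :p] = b
    aug[:p, p:] = np.eye(p)
    integral = expm(aug * lag)[:p, p:]
    return dt_dynamics, integral @ a


def dt_to_ct(dt_dynamics: np.ndarray, dt_additive: np.ndarray, lag: float) -> CTParameterSet:
    """Continuous-time dynamics whose ``lag``-discretization is the given pair.

    Inverse of :func:`ct_to_dt`: ``b = logm(I + A_dt) / lag`` via the
    principal matrix logarithm, then the additive input is recovered by
    inverting the accumulation integral.

    Raises
    ------
    ValueError
        If ``I + A_dt`` has an eigenvalue on the closed negative real
        axis, in which case no real continuous-time equivalent exists.
    """
    if not (lag > 0):
        raise ValueError("lag must be positive")
    dt_dynamics = np.atleast_2d(np.asarray(dt_dynamics, dtype=float))
    dt_additive = np.atleast_1d(np.asarray(dt_additive, dtype=float))
    p = dt_additive.shape[0]
    M = np.eye(p) + dt_dynamics
    eig = np.linalg.eigvals(M)
    if np.any((eig.real <= 0) & (np.abs(eig.imag) < 1e-14)):
        raise ValueError(
            "I + dt_dynamics has an eigenvalue on the closed negative real axis; "
            "no real continuous-time equivalent"
        )
    b = np.real_if_close(logm(M), tol=1e6) / lag
    b = np.asarray(b, dtype=float)
    aug = np.zeros((2 * p, 2 * p))
    aug[:p, :p] = b
    aug[:p, p:] = np.eye(p)
    integral = expm(aug * lag)[:p, p:]
    a = np.linalg.solve(integral, dt_additive)
    return CTParameterSet(drift=b, ct_additive=a, time_lag=lag)


def mean_trajectory(spec: ModelSpec, params: ParameterSet, horizon: int) -> MeanTrajectory:
    """Iterate the mean change recursion for ``horizon`` steps.

    Returns levels at occasions 0 .. horizon, starting from the
    initial-level means and applying
    ``level[t] = level[t-1] + A level[t-1] + mu_a``.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    A = dynamics_matrix(params)
    M = np.eye(params.p) + A
    levels = np.empty((horizon + 1, params.p))
    levels[0] = params.mu0
    for t in range(1, horizon + 1):
        levels[t] = M @ levels[t - 1] + params.mua
    return MeanTrajectory(times=np.arange(horizon + 1), levels=levels)


def fixed_point(params: ParameterSet) -> np.ndarray:
    """Equilibrium of the mean dynamics: the solution of ``A y* + mu_a = 0``.

    Univariate, this is the asymptote ``mu_a / (-beta)``.  In coupled
    bivariate systems the equilibrium depends on both additive components
    and all four dynamic parameters, so the univariate identity
    ``y_As = y_a / (-beta)`` does not carry over.

    Raises
    ------
    ValueError
        If the dynamics matrix is singular (no isolated equilibrium).
    """
    A = dynamics_matrix(params)
    if abs(np.linalg.det(A)) < 1e-14:
        raise ValueError("dynamics matrix is singular: no isolated equilibrium")
    return np.linalg.solve(A, -params.mua)


def classify_univariate(params: ParameterSet, tol: float = DEFAULT_TOL) -> ShapeClass:
    """Qualitative shape of the univariate mean trajectory.

    Negative self-feedback gives decelerated change toward the asymptote,
    positive gives accelerated change away from it, and growth versus
    decline is decided by the position of the initial level relative to
    the asymptote — not by the sign of the additive component.  With
    ``|beta| <= tol`` the trajectory is linear with slope ``mu_a``
    (constant if that is also within ``tol`` of zero), and a trajectory
    starting within ``tol`` of its asymptote is constant.
    """
    if params.p != 1:
        raise ValueError("classify_univariate requires a univariate parameter set")
    beta = float(params.beta[0])
    mu0 = float(params.mu0[0])
    mua = float(params.mua[0])
    if abs(beta) <= tol:
        if abs(mua) <= tol:
            return ShapeClass.CONSTANT
        return ShapeClass.LINEAR_GROWTH if mua > 0 else ShapeClass.LINEAR_DECLINE
    y_as = asymptote_from_additive(mua, beta)
    if abs(y_as - mu0) <= tol:
        return ShapeClass.CONSTANT
    if beta < 0:
        return ShapeClass.DECELERATED_GROWTH if y_as > mu0 else ShapeClass.DECELERATED_DECLINE
    return ShapeClass.ACCELERATED_GROWTH if y_as < mu0 else ShapeClass.ACCELERATED_DECLINE


def _univariate_slice(params: ParameterSet, j: int) -> ParameterSet:
    """Marginal univariate parameter set for process j of a decoupled system."""
    idx = [j, 2 + j]
    return ParameterSet(
        mu0=params.mu0[j : j + 1],
        mua=params.mua[j : j + 1],
        phi=params.phi[np.ix_(idx, idx)],
        beta=params.beta[j : j + 1],
        theta=params.theta[j : j + 1, j : j + 1],
    )


def classify_bivariate(params: ParameterSet, tol: float = DEFAULT_TOL) -> BivariateShape:
    """Qualitative behavior of the bivariate system from the eigenvalues of I + A.

    A complex eigenvalue pair means oscillation: damped if the modulus is
    below ``1 - tol``, explosive above ``1 + tol``, sustained in between.
    Real eigenvalues give non-oscillatory dynamics, convergent iff the
    spectral radius is below 1; each process then also receives a
    growth/decline label from the direction of its mean trajectory.  With
    both couplings (numerically) zero the per-process labels coincide with
    the univariate classifier applied to each margin.
    """
    if params.p != 2:
        raise ValueError("classify_bivariate requires a bivariate parameter set")
    A = dynamics_matrix(params)
    M = np.eye(2) + A
    eig = np.linalg.eigvals(M)
    modulus = float(np.max(np.abs(eig)))
    convergent = modulus < 1.0
    oscillatory = bool(np.any(np.abs(eig.imag) > tol))
    eig_pair = (complex(eig[0]), complex(eig[1]))
    if oscillatory:
        if modulus < 1.0 - tol:
            label = ShapeClass.OSCILLATORY_DAMPED
        elif modulus > 1.0 + tol:
            label = ShapeClass.OSCILLATORY_EXPLOSIVE
        else:
            label = ShapeClass.OSCILLATORY_SUSTAINED
        return BivariateShape(label, convergent, True, modulus, eig_pair)

    decoupled = params.gamma is None or np.all(np.abs(params.gamma) <= tol)
    if decoupled:
        per = tuple(classify_univariate(_univariate_slice(params, j), tol) for j in range(2))
    else:
        per = tuple(_coupled_process_label(params, A, j, tol, convergent) for j in range(2))
    # system label: the more "dynamic" process decides growth vs decline
    label = per[0] if per[0] is not ShapeClass.CONSTANT else per[1]
    return BivariateShape(label, convergent, False, modulus, eig_pair, per_process=per)


def _coupled_process_label(
    params: ParameterSet, A: np.ndarray, j: int, tol: float, convergent: bool
) -> ShapeClass:
    """Growth/decline direction of process j read off the mean trajectory."""
    traj = mean_trajectory(
        ModelSpec(n_processes=2, n_occasions=3), params, horizon=25
    ).levels[:, j]
    move = traj[-1] - traj[0]
    if abs(move) <= tol:
        return ShapeClass.CONSTANT
    if convergent:
        return ShapeClass.DECELERATED_GROWTH if move > 0 else ShapeClass.DECELERATED_DECLINE
    return ShapeClass.ACCELERATED_GROWTH if move > 0 else ShapeClass.ACCELERATED_DECLINE
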