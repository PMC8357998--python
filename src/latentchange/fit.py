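"""Maximum-likelihood estimation and parameter-recovery studies.

Estimation minimizes the full-information -2 log-likelihood over an
unconstrained coordinate system: means and dynamic parameters enter
directly, covariance blocks through Cholesky factors with log-transformed
diagonals, so every coordinate vector maps to a valid (positive-definite)
parameter set.  The optimizer runs from a moment-based start plus jittered
restarts; standard errors come from the numeric Hessian at the optimum,
delta-method-mapped to the natural scale.

The internal objective is the per-row deviance (-2LL / N); convergence is
declared when the optimizer reports success and the gradient norm of that
objective falls below 1e-5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model_spec import (
    ModelSpec,
    ParameterSet,
    count_free_parameters,
    validate,
)
from .likelihood import ImpliedMoments, implied_moments, _pattern_groups, LOG2PI
from .simulate import PanelData, simulate_panel

__all__ = [
    "ParameterTransform",
    "FitOptions",
    "FitResult",
    "RecoveryReport",
    "to_unconstrained",
    "from_unconstrained",
    "parameter_names",
    "fit_ml",
    "standard_errors",
    "recovery_study",
]

logger = logging.getLogger(__name__)

GRAD_TOL = 1e-5
LOG_DIAG_BOUND = 12.0


def _effect_labels(p: int) -> List[str]:
    return ["y0", "ya"] if p == 1 else ["x0", "y0", "xa", "ya"]


def _tri_names(labels: List[str], prefix_var: str, prefix_cov: str) -> List[str]:
    names = []
    for i in range(len(labels)):
        for j in range(i + 1):
            if i == j:
                names.append(f"{prefix_var}{labels[i]}")
            else:
                names.append(f"{prefix_cov}{labels[j]}_{labels[i]}")
    return names


def _safe_cholesky(mat: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Cholesky factor, with an eigenvalue floor for boundary (PSD) inputs."""
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        lam, vec = np.linalg.eigh(mat)
        lam = np.clip(lam, floor, None)
        return np.linalg.cholesky((vec * lam) @ vec.T)


class ParameterTransform:
    """Bijection between a ParameterSet and an unconstrained coordinate vector.

    Coordinate layout: means (mu0, mua), phi as a log-Cholesky block,
    self-feedbacks, free couplings, theta, psi.  Covariance blocks with a
    free off-diagonal use a full log-Cholesky parameterization; blocks
    with the covariance fixed at zero use per-process log variances.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        p = spec.n_processes
        self.p = p
        labels = _effect_labels(p)
        proc = ("",) if p == 1 else ("_x", "_y")
        self.names: List[str] = []
        self._log_diag: List[bool] = []

        def scalar(name: str, is_log: bool = False) -> None:
            self.names.append(name)
            self._log_diag.append(is_log)

        for lab in labels[:p]:
            scalar(f"mu_{lab}")
        for lab in labels[p:]:
            scalar(f"mu_{lab}")
        for i in range(2 * p):
            for j in range(i + 1):
                if i == j:
                    scalar(f"var_{labels[i]}", is_log=True)
                else:
                    scalar(f"cov_{labels[j]}_{labels[i]}")
        for s in proc:
            scalar(f"beta{s}")
        self._free_gamma = (False, False)
        if p == 2:
            self._free_gamma = spec.free_couplings
            for flag, s in zip(spec.free_couplings, ("_x", "_y")):
                if flag:
                    scalar(f"gamma{s}")
        self._theta_full = p == 2 and bool(spec.error_covariance)
        if self._theta_full:
            for i in range(p):
                for j in range(i + 1):
                    if i == j:
                        scalar(f"var_e{proc[i]}", is_log=True)
                    else:
                        scalar(f"cov_e{proc[j]}{proc[i]}")
        else:
            for s in proc:
                scalar(f"var_e{s}", is_log=True)
        self._psi_full = False
        if spec.stochastic:
            self._psi_full = p == 2 and bool(spec.innovation_covariance)
            if self._psi_full:
                for i in range(p):
                    for j in range(i + 1):
                        if i == j:
                            scalar(f"var_d{proc[i]}", is_log=True)
                        else:
                            scalar(f"cov_d{proc[j]}{proc[i]}")
            else:
                for s in proc:
                    scalar(f"var_d{s}", is_log=True)
        self.dim = len(self.names)
        assert self.dim == count_free_parameters(spec)
        self.log_diag_mask = np.array(self._log_diag)

    # -- packing helpers ---------------------------------------------------

    @staticmethod
    def _pack_block(mat: np.ndarray) -> List[float]:
        L = _safe_cholesky(mat)
        out = []
        for i in range(mat.shape[0]):
            for j in range(i + 1):
                out.append(np.log(max(L[i, i], 1e-300)) if i == j else L[i, j])
        return out

    @staticmethod
    def _unpack_block(coords: np.ndarray, d: int) -> np.ndarray:
        L = np.zeros((d, d))
        k = 0
        for i in range(d):
            for j in range(i + 1):
                L[i, j] = np.exp(coords[k]) if i == j else coords[k]
                k += 1
        return L @ L.T

    # -- API ---------------------------------------------------------------

    def to_unconstrained(self, params: ParameterSet) -> np.ndarray:
        validate(self.spec, params)
        p = self.p
        u: List[float] = list(params.mu0) + list(params.mua)
        u += self._pack_block(params.phi)
        u += list(params.beta)
        if p == 2:
            for flag, g in zip(self._free_gamma, params.gamma):
                if flag:
                    u.append(g)
        if self._theta_full:
            u += self._pack_block(params.theta)
        else:
            u += [np.log(max(params.theta[i, i], 1e-300)) for i in range(p)]
        if self.spec.stochastic:
            if self._psi_full:
                u += self._pack_block(params.psi)
            else:
                u += [np.log(max(params.psi[i, i], 1e-300)) for i in range(p)]
        return np.asarray(u, dtype=float)

    def from_unconstrained(self, u: np.ndarray) -> ParameterSet:
        u = np.asarray(u, dtype=float)
        if u.shape != (self.dim,):
            raise ValueError(f"expected vector of length {self.dim}, got shape {u.shape}")
        p = self.p
        k = 0

        def take(m: int) -> np.ndarray:
            nonlocal k
            out = u[k : k + m]
            k += m
            return out

        mu0 = take(p)
        mua = take(p)
        phi = self._unpack_block(take((2 * p) * (2 * p + 1) // 2), 2 * p)
        beta = take(p)
        gamma = None
        if p == 2:
            gamma = np.zeros(2)
            for idx, flag in enumerate(self._free_gamma):
                if flag:
                    gamma[idx] = take(1)[0]
        if self._theta_full:
            theta = self._unpack_block(take(3), 2)
        else:
            theta = np.diag(np.exp(take(p)))
        psi = None
        if self.spec.stochastic:
            if self._psi_full:
                psi = self._unpack_block(take(3), 2)
            else:
                psi = np.diag(np.exp(take(p)))
        assert k == self.dim
        return ParameterSet(
            mu0=mu0, mua=mua, phi=phi, beta=beta, gamma=gamma, theta=theta, psi=psi
        )

    def natural(self, params: ParameterSet) -> np.ndarray:
        """Natural-scale parameter vector in the same order as ``names``."""
        p = self.p
        vals: List[float] = list(params.mu0) + list(params.mua)
        for i in range(2 * p):
            for j in range(i + 1):
                vals.append(params.phi[i, j])
        vals += list(params.beta)
        if p == 2:
            for flag, g in zip(self._free_gamma, params.gamma):
                if flag:
                    vals.append(g)
        if self._theta_full:
            for i in range(p):
                for j in range(i + 1):
                    vals.append(params.theta[i, j])
        else:
            vals += [params.theta[i, i] for i in range(p)]
        if self.spec.stochastic:
            if self._psi_full:
                for i in range(p):
                    for j in range(i + 1):
                        vals.append(params.psi[i, j])
            else:
                vals += [params.psi[i, i] for i in range(p)]
        return np.asarray(vals, dtype=float)


def to_unconstrained(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    """Map a parameter set to unconstrained optimization coordinates."""
    return ParameterTransform(spec).to_unconstrained(params)


def from_unconstrained(u: np.ndarray, spec: ModelSpec) -> ParameterSet:
    """Map unconstrained coordinates back to a (PSD-guaranteed) parameter set."""
    return ParameterTransform(spec).from_unconstrained(u)


def parameter_names(spec: ModelSpec) -> List[str]:
    """Natural-scale parameter names in estimation order."""
    return list(ParameterTransform(spec).names)


# ---------------------------------------------------------------------------
# Objective with pattern-wise sufficient statistics


class _Objective:
    """Per-row FIML deviance, precomputing missingness-pattern statistics."""

    def __init__(self, spec: ModelSpec, panel: PanelData):
        self.spec = spec
        self.transform = ParameterTransform(spec)
        self.stats = []
        n_used = 0
        for mask, rows in _pattern_groups(panel.observed).values():
            data = panel.observed[np.ix_(rows, np.flatnonzero(mask))]
            n_p = data.shape[0]
            ybar = data.mean(axis=0)
            dev = data - ybar
            scatter = dev.T @ dev / n_p
            self.stats.append((mask, n_p, ybar, scatter))
            n_used += n_p
        self.n = n_used

    def m2ll(self, params: ParameterSet) -> float:
        moments = implied_moments(self.spec, params)
        total = 0.0
        for mask, n_p, ybar, scatter in self.stats:
            cov = moments.covariance[np.ix_(mask, mask)]
            try:
                L = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                return np.inf
            logdet = 2.0 * np.sum(np.log(np.diag(L)))
            cov_inv = np.linalg.inv(cov)
            diff = ybar - moments.mean[mask]
            total += n_p * (
                mask.sum() * LOG2PI
                + logdet
                + float(np.sum(cov_inv * scatter))
                + float(diff @ cov_inv @ diff)
            )
        return total

    def __call__(self, u: np.ndarray) -> float:
        try:
            params = self.transform.from_unconstrained(u)
            value = self.m2ll(params) / self.n
        except (ValueError, FloatingPointError):
            return np.inf
        return value if np.isfinite(value) else np.inf


def _numeric_gradient(f, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    g = np.zeros_like(x)
    for i in range(x.size):
        step = h * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += step
        xm[i] -= step
        g[i] = (f(xp) - f(xm)) / (2 * step)
    return g


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.zeros((n, n))
    steps = h * np.maximum(1.0, np.abs(x))
    f0 = f(x)
    fp = np.zeros(n)
    fm = np.zeros(n)
    for i in range(n):
        xp, xm = x.copy(), x.copy()
        xp[i] += steps[i]
        xm[i] -= steps[i]
        fp[i], fm[i] = f(xp), f(xm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / steps[i] ** 2
    for i in range(n):
        for j in range(i):
            xpp = x.copy()
            xpp[[i, j]] += steps[[i, j]]
            xmm = x.copy()
            xmm[[i, j]] -= steps[[i, j]]
            H[i, j] = H[j, i] = (
                f(xpp) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + f(xmm)
            ) / (2 * steps[i] * steps[j])
    return H


# ---------------------------------------------------------------------------
# Fit machinery


@dataclass
class FitOptions:
    """Optimizer settings for :func:`fit_ml`.

    ``n_starts`` jittered restarts (the first start is moment-based),
    ``jitter`` the relative spread of the restarts, ``seed`` makes the
    whole fit deterministic, ``start_params`` overrides the moment-based
    start.
    """

    n_starts: int = 5
    seed: int = 0
    jitter: float = 0.2
    max_iter: int = 1000
    start_params: Optional[ParameterSet] = None
    compute_se: bool = True


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    spec: ModelSpec
    estimates: ParameterSet
    unconstrained_vector: np.ndarray
    names: List[str]
    minus2ll: float
    aic: float
    bic: float
    n_obs: int
    k: int
    converged: bool
    n_starts_used: int
    gradient_norm: float
    se: Optional[pd.Series] = None
    message: str = ""

    @property
    def natural_estimates(self) -> pd.Series:
        return pd.Series(
            ParameterTransform(self.spec).natural(self.estimates), index=self.names
        )

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({"estimate": self.natural_estimates})
        df["se"] = self.se if self.se is not None else np.nan
        return df


def _moment_start(spec: ModelSpec, panel: PanelData) -> ParameterSet:
    """Crude moment-based starting values: occasion means for the level and
    additive means, a log-ratio of successive mean changes for the
    self-feedback, and an even split of the first-occasion variance."""
    p, T = spec.n_processes, spec.n_occasions
    obs = panel.observed.reshape(panel.n, T, p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(obs, axis=0)  # T x p
        v0 = np.nanvar(obs[:, 0, :], axis=0)
    v0 = np.where(np.isfinite(v0) & (v0 > 1e-8), v0, 1.0)
    beta = np.zeros(p)
    mua = np.zeros(p)
    for j in range(p):
        d = np.diff(m[:, j])
        ratios = d[1:] / np.where(np.abs(d[:-1]) > 1e-8, d[:-1], np.nan)
        ratios = ratios[np.isfinite(ratios)]
        b = float(np.median(ratios)) - 1.0 if ratios.size else -0.1
        beta[j] = float(np.clip(b, -1.8, 1.5))
        mua[j] = d[0] - beta[j] * m[0, j] if d.size else 0.1
    phi = np.diag(np.concatenate([0.5 * v0, 0.1 * v0 + 0.05]))
    theta = np.diag(0.5 * v0)
    gamma = np.zeros(2) if p == 2 else None
    psi = np.diag(0.1 * v0 + 0.05) if spec.stochastic else None
    return ParameterSet(
        mu0=m[0], mua=mua, phi=phi, beta=beta, gamma=gamma, theta=theta, psi=psi
    )


def fit_ml(spec: ModelSpec, panel: PanelData, options: Optional[FitOptions] = None) -> FitResult:
    """Fit an LCS model by full-information maximum likelihood.

    Runs L-BFGS-B from a moment-based start and jittered restarts, keeps
    the best solution, and reports -2LL, AIC/BIC, convergence diagnostics
    and (when converged) delta-method standard errors.
    """
    options = options or FitOptions()
    if panel.n_processes != spec.n_processes or panel.n_occasions != spec.n_occasions:
        raise ValueError("panel shape does not match spec")
    if spec.n_occasions == 3:
        warnings.warn("T = 3 gives weak identification for dual-change dynamics")
    obj = _Objective(spec, panel)
    k = count_free_parameters(spec)
    if obj.n < k:
        warnings.warn(f"only {obj.n} usable rows for {k} free parameters")

    start = options.start_params or _moment_start(spec, panel)
    u0 = obj.transform.to_unconstrained(start)
    rng = np.random.default_rng(options.seed)
    starts = [u0]
    scale = options.jitter * np.maximum(np.abs(u0), 0.5)
    for _ in range(max(0, options.n_starts - 1)):
        starts.append(u0 + scale * rng.standard_normal(u0.size))

    bounds = [
        (-LOG_DIAG_BOUND, LOG_DIAG_BOUND) if is_log else (None, None)
        for is_log in obj.transform.log_diag_mask
    ]
    best = None
    n_used = 0
    for u_start in starts:
        n_used += 1
        res = minimize(
            obj,
            u_start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": options.max_iter, "ftol": 1e-12, "gtol": 1e-8},
        )
        if np.isfinite(res.fun):
            # restart once from the solution: resets the limited-memory
            # Hessian and reliably tightens the gradient
            res2 = minimize(
                obj,
                res.x,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": options.max_iter, "ftol": 1e-14, "gtol": 1e-9},
            )
            if res2.fun <= res.fun:
                res = res2
        if best is None or res.fun < best.fun:
            best = res

    grad_norm = float(np.linalg.norm(_numeric_gradient(obj, best.x), ord=np.inf))
    converged = bool(best.success) and np.isfinite(best.fun) and grad_norm < GRAD_TOL
    m2ll = float(best.fun * obj.n)
    estimates = obj.transform.from_unconstrained(best.x)
    result = FitResult(
        spec=spec,
        estimates=estimates,
        unconstrained_vector=best.x.copy(),
        names=list(obj.transform.names),
        minus2ll=m2ll,
        aic=m2ll + 2 * k,
        bic=m2ll + k * np.log(obj.n),
        n_obs=obj.n,
        k=k,
        converged=converged,
        n_starts_used=n_used,
        gradient_norm=grad_norm,
        message=str(best.message),
    )
    if converged and options.compute_se:
        try:
            result.se = standard_errors(spec, result, panel)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("standard-error computation failed: %s", exc)
            result.se = None
    return result


def standard_errors(spec: ModelSpec, fit: FitResult, panel: PanelData) -> Optional[pd.Series]:
    """Delta-method standard errors on the natural parameter scale.

    Uses the numeric Hessian of -2LL at the optimum; the observed
    information is half that Hessian, its inverse the coordinate
    covariance, which the Jacobian of the natural-parameter map carries to
    the reporting scale.  Returns None (flagged) when the Hessian is not
    positive definite.
    """
    obj = _Objective(spec, panel)
    u = fit.unconstrained_vector
    H = _numeric_hessian(lambda x: obj(x) * obj.n, u)
    lam = np.linalg.eigvalsh((H + H.T) / 2.0)
    if lam.min() <= 0:
        logger.warning("Hessian not positive definite; standard errors withheld")
        return None
    cov_u = 2.0 * np.linalg.inv((H + H.T) / 2.0)

    def natural(x: np.ndarray) -> np.ndarray:
        return obj.transform.natural(obj.transform.from_unconstrained(x))

    n_par = u.size
    J = np.zeros((n_par, n_par))
    for i in range(n_par):
        step = 1e-6 * max(1.0, abs(u[i]))
        xp, xm = u.copy(), u.copy()
        xp[i] += step
        xm[i] -= step
        J[:, i] = (natural(xp) - natural(xm)) / (2 * step)
    var = np.diag(J @ cov_u @ J.T)
    return pd.Series(np.sqrt(np.clip(var, 0.0, None)), index=fit.names)


# ---------------------------------------------------------------------------
# Recovery studies


@dataclass
class RecoveryReport:
    """Per-parameter recovery summaries over simulate-and-refit replications."""

    table: pd.DataFrame          # true, mean_est, bias, rmse, coverage, mc_se
    convergence_rate: float
    n_reps: int
    n_converged: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.convergence_rate <= 1.0):
            raise ValueError("convergence rate must be in [0, 1]")


def recovery_study(
    spec: ModelSpec,
    true_params: ParameterSet,
    n: int,
    reps: int,
    seed: int,
    options: Optional[FitOptions] = None,
) -> RecoveryReport:
    """Simulate ``reps`` panels of size ``n`` at the true parameters and refit.

    Reports per-parameter bias, RMSE, the Monte-Carlo standard error of
    the mean estimate, and coverage of the nominal 95% (±1.96 SE)
    intervals, plus the convergence rate.
    """
    validate(spec, true_params)
    options = options or FitOptions()
    transform = ParameterTransform(spec)
    truth = transform.natural(true_params)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(reps)
    estimates, covered = [], []
    n_converged = 0
    for r in range(reps):
        panel = simulate_panel(spec, true_params, n, children[r])
        opt_r = replace(options, seed=int(children[r].generate_state(1)[0] % 2**31))
        fit = fit_ml(spec, panel, opt_r)
        if not fit.converged:
            continue
        n_converged += 1
        est = transform.natural(fit.estimates)
        estimates.append(est)
        if fit.se is not None:
            se = fit.se.to_numpy()
            covered.append(np.abs(est - truth) <= 1.96 * se)
    est_arr = np.array(estimates) if estimates else np.empty((0, transform.dim))
    mean_est = est_arr.mean(axis=0) if len(est_arr) else np.full(transform.dim, np.nan)
    sd_est = est_arr.std(axis=0, ddof=1) if len(est_arr) > 1 else np.full(transform.dim, np.nan)
    table = pd.DataFrame(
        {
            "true": truth,
            "mean_est": mean_est,
            "bias": mean_est - truth,
            "rmse": np.sqrt(np.mean((est_arr - truth) ** 2, axis=0))
            if len(est_arr)
            else np.full(transform.dim, np.nan),
            "mc_se": sd_est / np.sqrt(max(len(est_arr), 1)),
            "coverage": np.mean(covered, axis=0) if covered else np.full(transform.dim, np.nan),
        },
        index=transform.names,
    )
    return RecoveryReport(
        table=table,
        convergence_rate=n_converged / reps,
        n_reps=reps,
        n_converged=n_converged,
    )
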