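"""Structural specification and parameterization of latent change score models.

A dual latent change score (LCS) model describes a repeatedly measured
process through occasion-to-occasion latent changes,

    Delta y[t] = y_a + beta * y[t-1],

where ``y_a`` is an individual-specific additive component and ``beta`` the
self-feedback of the previous latent level on the next change.  The initial
level ``y_0`` and the additive component are jointly normal across
individuals, and observed scores add Gaussian measurement error at each
occasion.  The bivariate extension adds couplings ``gamma_x`` (level of y
drives changes in x) and ``gamma_y`` (level of x drives changes in y); the
stochastic variant adds latent innovations with covariance ``psi`` whose
effect, unlike measurement error, propagates through the dynamics.

This module defines the structural choices (:class:`ModelSpec`), the
population parameters (:class:`ParameterSet`), the continuous-time
parameterization (:class:`CTParameterSet`), trajectory-shape labels
(:class:`ShapeClass`), free-parameter accounting, validation, and a plain
dictionary config representation with blocks ``spec``, ``means``, ``phi``,
``dynamics``, ``theta``, ``psi``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "PSD_TOL",
    "ModelSpec",
    "ParameterSet",
    "CTParameterSet",
    "ShapeClass",
    "count_free_parameters",
    "validate",
    "dynamics_matrix",
    "to_config",
    "from_config",
]

#: Smallest eigenvalue tolerated when checking positive semi-definiteness.
PSD_TOL = 1e-10

PROCESS_NAMES = {1: ("y",), 2: ("x", "y")}


class ShapeClass(enum.Enum):
    """Qualitative trajectory shapes of the linear-affine change system."""

    DECELERATED_GROWTH = "decelerated_growth"
    DECELERATED_DECLINE = "decelerated_decline"
    ACCELERATED_GROWTH = "accelerated_growth"
    ACCELERATED_DECLINE = "accelerated_decline"
    LINEAR_GROWTH = "linear_growth"
    LINEAR_DECLINE = "linear_decline"
    CONSTANT = "constant"
    OSCILLATORY_DAMPED = "oscillatory_damped"
    OSCILLATORY_EXPLOSIVE = "oscillatory_explosive"
    OSCILLATORY_SUSTAINED = "oscillatory_sustained"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices of an LCS model.

    Parameters
    ----------
    n_processes
        1 (univariate) or 2 (bivariate).
    stochastic
        Whether latent innovations (dynamic errors) are included.
    n_occasions
        Number of equally spaced measurement occasions ``T`` (>= 3),
        indexed 0 .. T-1.
    time_lag
        Spacing between occasions in the discrete-time metric (default 1).
    free_couplings
        Bivariate only: which of (gamma_x, gamma_y) are freely estimated.
        Couplings not free are fixed at 0.
    error_covariance
        Bivariate only: whether the within-occasion measurement errors of
        the two processes covary (default True).
    innovation_covariance
        Stochastic bivariate only: whether the two innovations covary
        within an occasion (default True).
    """

    n_processes: int = 1
    stochastic: bool = False
    n_occasions: int = 5
    time_lag: float = 1.0
    free_couplings: Optional[Tuple[bool, bool]] = None
    error_covariance: Optional[bool] = None
    innovation_covariance: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.n_processes not in (1, 2):
            raise ValueError(f"n_processes must be 1 or 2, got {self.n_processes}")
        if self.n_occasions < 3:
            raise ValueError(f"n_occasions must be >= 3, got {self.n_occasions}")
        if not (self.time_lag > 0):
            raise ValueError(f"time_lag must be positive, got {self.time_lag}")
        if self.n_processes == 1:
            for name in ("free_couplings", "error_covariance"):
                if getattr(self, name) is not None:
                    raise ValueError(f"{name} is bivariate-only, but n_processes = 1")
            if self.innovation_covariance is not None:
                raise ValueError("innovation_covariance requires a stochastic bivariate spec")
        else:
            if self.free_couplings is None:
                object.__setattr__(self, "free_couplings", (True, True))
            else:
                fc = tuple(bool(b) for b in self.free_couplings)
                if len(fc) != 2:
                    raise ValueError("free_couplings must be a pair of booleans")
                object.__setattr__(self, "free_couplings", fc)
            if self.error_covariance is None:
                object.__setattr__(self, "error_covariance", True)
            if self.stochastic:
                if self.innovation_covariance is None:
                    object.__setattr__(self, "innovation_covariance", True)
            elif self.innovation_covariance is not None:
                raise ValueError("innovation_covariance requires a stochastic spec")

    @property
    def p(self) -> int:
        """Number of processes (alias for ``n_processes``)."""
        return self.n_processes

    @property
    def process_names(self) -> Tuple[str, ...]:
        return PROCESS_NAMES[self.n_processes]


def _as_matrix(value, p: int, name: str) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(value, dtype=float))
    if arr.shape != (p, p):
        raise ValueError(f"{name} must be {p} x {p}, got shape {arr.shape}")
    return arr


def _check_psd(mat: np.ndarray, name: str) -> None:
    if not np.allclose(mat, mat.T, atol=1e-12, rtol=0.0):
        raise ValueError(f"{name} must be symmetric")
    lam = np.linalg.eigvalsh(mat)
    if lam.min() < -PSD_TOL:
        raise ValueError(f"{name} is not positive semi-definite (min eigenvalue {lam.min():.3g})")


@dataclass(frozen=True)
class ParameterSet:
    """Population parameters of an LCS model.

    The random-effect covariance ``phi`` is over the stacked vector of
    initial levels followed by additive components — (y0, ya) in the
    univariate case, (x0, y0, xa, ya) in the bivariate case.  The loading
    ``alpha`` of the additive component on each change is fixed at 1 and is
    not a parameter.

    Attributes
    ----------
    mu0, mua : (p,) arrays
        Means of initial levels and additive components.
    phi : (2p, 2p) array
        Covariance of the individual effects, symmetric PSD.
    beta : (p,) array
        Self-feedbacks.
    gamma : (2,) array or None
        Couplings (gamma_x: y -> x, gamma_y: x -> y); bivariate only.
    theta : (p, p) array
        Measurement-error covariance per occasion, symmetric PSD.
    psi : (p, p) array or None
        Innovation covariance per change; stochastic models only.
    """

    mu0: np.ndarray
    mua: np.ndarray
    phi: np.ndarray
    beta: np.ndarray
    theta: np.ndarray
    gamma: Optional[np.ndarray] = None
    psi: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu0", np.atleast_1d(np.asarray(self.mu0, dtype=float)))
        object.__setattr__(self, "mua", np.atleast_1d(np.asarray(self.mua, dtype=float)))
        p = self.mu0.shape[0]
        if p not in (1, 2):
            raise ValueError(f"mu0 must have length 1 or 2, got {p}")
        if self.mua.shape != (p,):
            raise ValueError(f"mua must have length {p}, got shape {self.mua.shape}")
        object.__setattr__(self, "phi", _as_matrix(self.phi, 2 * p, "phi"))
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        if self.beta.shape != (p,):
            raise ValueError(f"beta must have length {p}, got shape {self.beta.shape}")
        object.__setattr__(self, "theta", _as_matrix(self.theta, p, "theta"))
        if self.gamma is not None:
            g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
            if p == 1:
                raise ValueError("gamma supplied for a univariate parameter set")
            if g.shape != (2,):
                raise ValueError(f"gamma must have length 2, got shape {g.shape}")
            object.__setattr__(self, "gamma", g)
        if self.psi is not None:
            object.__setattr__(self, "psi", _as_matrix(self.psi, p, "psi"))

    @property
    def p(self) -> int:
        return self.mu0.shape[0]

    @property
    def alpha(self) -> float:
        """Loading of the additive component on each change; fixed at 1."""
        return 1.0


@dataclass(frozen=True)
class CTParameterSet:
    """Continuous-time parameterization of the deterministic mean dynamics.

    ``dy/dt = ct_additive + drift @ y``.  In the univariate exponential
    form the drift is ``-r`` (minus the rate of change) and the additive
    input is ``r * y_As`` (rate times asymptote).
    """

    drift: np.ndarray
    ct_additive: np.ndarray
    time_lag: float = 1.0

    def __post_init__(self) -> None:
        add = np.atleast_1d(np.asarray(self.ct_additive, dtype=float))
        p = add.shape[0]
        object.__setattr__(self, "ct_additive", add)
        object.__setattr__(self, "drift", _as_matrix(self.drift, p, "drift"))
        if p not in (1, 2):
            raise ValueError(f"CTParameterSet supports 1 or 2 processes, got {p}")
        if not (self.time_lag > 0):
            raise ValueError("time_lag must be positive")

    @property
    def p(self) -> int:
        return self.ct_additive.shape[0]


def dynamics_matrix(params: ParameterSet) -> np.ndarray:
    """Discrete-time change matrix A: diagonal self-feedbacks, off-diagonal couplings.

    Row ordering follows the process order (x, y) bivariate / (y,)
    univariate, so ``A = [[beta_x, gamma_x], [gamma_y, beta_y]]``.
    """
    if params.p == 1:
        return params.beta.reshape(1, 1)
    gx, gy = (0.0, 0.0) if params.gamma is None else tuple(params.gamma)
    bx, by = params.beta
    return np.array([[bx, gx], [gy, by]])


def count_free_parameters(spec: ModelSpec) -> int:
    """Number of freely estimated parameters implied by the spec.

    Independent of the number of occasions: means (2p), distinct entries
    of phi (2p(2p+1)/2), dynamics (p self-feedbacks plus free couplings),
    distinct entries of theta and, for stochastic models, of psi.  The
    univariate deterministic dual model has 7; the full stochastic
    bivariate model with error and innovation covariances has 24.
    """
    p = spec.n_processes
    n = 2 * p                                   # means
    n += (2 * p) * (2 * p + 1) // 2             # phi block
    n += p                                      # self-feedbacks
    if p == 2:
        n += sum(spec.free_couplings)
        n += p + (1 if spec.error_covariance else 0)
    else:
        n += 1                                  # sigma_e^2
    if spec.stochastic:
        n += p
        if p == 2 and spec.innovation_covariance:
            n += 1
    return n


def validate(spec: ModelSpec, params: ParameterSet) -> ParameterSet:
    """Check that ``params`` is consistent with ``spec``; return it unchanged.

    Raises
    ------
    ValueError
        On dimension mismatch, non-PSD phi/theta/psi, innovations supplied
        for a deterministic spec (or missing for a stochastic one), or
        couplings supplied for a univariate spec.
    """
    if params.p != spec.n_processes:
        raise ValueError(
            f"parameter dimension {params.p} does not match spec n_processes {spec.n_processes}"
        )
    _check_psd(params.phi, "phi")
    _check_psd(params.theta, "theta")
    if spec.stochastic:
        if params.psi is None:
            raise ValueError("stochastic spec requires an innovation covariance psi")
        _check_psd(params.psi, "psi")
    elif params.psi is not None:
        raise ValueError("psi supplied for a deterministic spec")
    if spec.n_processes == 2:
        if params.gamma is None:
            raise ValueError("bivariate spec requires couplings gamma (use zeros for none)")
    elif params.gamma is not None:
        raise ValueError("gamma supplied for a univariate spec")
    if spec.n_processes == 2 and not spec.error_covariance and params.theta[0, 1] != 0.0:
        raise ValueError("spec fixes the measurement-error covariance to 0 but theta is non-diagonal")
    if (
        spec.stochastic
        and spec.n_processes == 2
        and not spec.innovation_covariance
        and params.psi[0, 1] != 0.0
    ):
        raise ValueError("spec fixes the innovation covariance to 0 but psi is non-diagonal")
    return params


# ---------------------------------------------------------------------------
# Config (de)serialization


def to_config(spec: ModelSpec, params: ParameterSet) -> dict:
    """Serialize a (spec, params) pair to a plain nested dict.

    The layout uses the named blocks ``spec``, ``means``, ``phi``,
    ``dynamics``, ``theta`` and (stochastic only) ``psi`` and survives a
    YAML or JSON round trip.
    """
    spec_block = {
        "n_processes": spec.n_processes,
        "stochastic": spec.stochastic,
        "n_occasions": spec.n_occasions,
        "time_lag": spec.time_lag,
    }
    if spec.n_processes == 2:
        spec_block["free_couplings"] = list(spec.free_couplings)
        spec_block["error_covariance"] = spec.error_covariance
        if spec.stochastic:
            spec_block["innovation_covariance"] = spec.innovation_covariance
    dynamics: dict = {"beta": params.beta.tolist()}
    if params.gamma is not None:
        dynamics["gamma"] = params.gamma.tolist()
    cfg = {
        "spec": spec_block,
        "means": {"mu0": params.mu0.tolist(), "mua": params.mua.tolist()},
        "phi": params.phi.tolist(),
        "dynamics": dynamics,
        "theta": params.theta.tolist(),
    }
    if params.psi is not None:
        cfg["psi"] = params.psi.tolist()
    return cfg


def from_config(cfg: Mapping) -> Tuple[ModelSpec, ParameterSet]:
    """Parse the nested-dict config layout back into a validated pair."""
    try:
        spec_block = dict(cfg["spec"])
        means = cfg["means"]
        phi = cfg["phi"]
        dynamics = cfg["dynamics"]
        theta = cfg["theta"]
    except KeyError as exc:  # pragma: no cover - message path
        raise ValueError(f"config missing required block: {exc}") from exc
    if "free_couplings" in spec_block and spec_block["free_couplings"] is not None:
        spec_block["free_couplings"] = tuple(spec_block["free_couplings"])
    spec = ModelSpec(**spec_block)
    params = ParameterSet(
        mu0=means["mu0"],
        mua=means["mua"],
        phi=phi,
        beta=dynamics["beta"],
        gamma=dynamics.get("gamma"),
        theta=theta,
        psi=cfg.get("psi"),
    )
    return spec, validate(spec, params)
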