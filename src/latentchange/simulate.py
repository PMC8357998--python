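"""Simulation of individual latent trajectories and observed panels.

Each individual draws an initial level and an additive component from a
joint normal distribution, then unfolds deterministically through the
change recursion — plus, in stochastic models, an independent Gaussian
innovation on every change, whose effect persists through the dynamics.
Observed scores add occasion-wise measurement error, which does not
persist.  A registry of named scenarios reproduces the illustrative
parameter configurations used throughout the documentation (exponential
trajectories with a fixed asymptote, self-feedback ladders, variance
fan-out/fan-in, and the six bivariate dynamic regimes).

One master seed spawns independent substreams for the three sources of
randomness (between-person effects, innovations, measurement errors), so
e.g. changing the error covariance does not perturb the latent draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .model_spec import ModelSpec, ParameterSet, dynamics_matrix, validate
from . import dynamics as dyn

__all__ = [
    "PanelData",
    "IndividualEffects",
    "draw_between_effects",
    "simulate_latent",
    "observe",
    "simulate_panel",
    "fixture",
    "fixture_config",
    "fixture_names",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class PanelData:
    """Observed repeated measures for N individuals.

    ``observed`` is N x (p*T), time-major with the process varying fastest
    within an occasion (x[0], y[0], x[1], y[1], ...); missing values are
    NaN.  ``latent`` (same shape, optional) holds the error-free levels
    and is populated by the simulator only.
    """

    ids: np.ndarray
    n_processes: int
    n_occasions: int
    observed: np.ndarray
    latent: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.observed = np.asarray(self.observed, dtype=float)
        expected = self.n_processes * self.n_occasions
        if self.observed.ndim != 2 or self.observed.shape[1] != expected:
            raise ValueError(
                f"observed must be N x {expected}, got shape {self.observed.shape}"
            )
        if self.observed.shape[0] != self.ids.shape[0]:
            raise ValueError("ids and observed row counts differ")
        if self.latent is not None:
            self.latent = np.asarray(self.latent, dtype=float)
            if self.latent.shape != self.observed.shape:
                raise ValueError("latent and observed shapes differ")
            if np.any(np.isnan(self.latent)):
                raise ValueError("missing markers are only allowed in observed scores")

    @property
    def n(self) -> int:
        return self.observed.shape[0]

    @property
    def occasions(self) -> np.ndarray:
        return np.arange(self.n_occasions)

    @property
    def process_names(self) -> Tuple[str, ...]:
        return ("y",) if self.n_processes == 1 else ("x", "y")

    @property
    def column_names(self) -> list:
        return [
            f"{v}_{t}" for t in range(self.n_occasions) for v in self.process_names
        ]


@dataclass(frozen=True)
class IndividualEffects:
    """Per-individual draws of initial levels and additive components (N x 2p)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[1] not in (2, 4):
            raise ValueError(f"effects must be N x 2p with p in (1, 2), got {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("effects must be finite")
        object.__setattr__(self, "values", vals)

    @property
    def p(self) -> int:
        return self.values.shape[1] // 2

    @property
    def initial_levels(self) -> np.ndarray:
        return self.values[:, : self.p]

    @property
    def additive_components(self) -> np.ndarray:
        return self.values[:, self.p :]


def draw_between_effects(params: ParameterSet, n: int, seed: SeedLike) -> IndividualEffects:
    """Draw N joint-normal (initial level, additive component) vectors.

    Mean ``(mu0, mua)`` and covariance ``phi``; a zero phi returns the
    mean for every individual.  Reproducible given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lam = np.linalg.eigvalsh(params.phi)
    if lam.min() < -1e-10:
        raise ValueError("phi is not positive semi-definite")
    rng = _rng(seed)
    mean = np.concatenate([params.mu0, params.mua])
    draws = rng.multivariate_normal(mean, params.phi, size=n, method="eigh", check_valid="ignore")
    return IndividualEffects(draws)


def simulate_latent(
    spec: ModelSpec, params: ParameterSet, effects: IndividualEffects, seed: SeedLike
) -> np.ndarray:
    """Unfold the change recursion for each individual; returns N x T x p levels.

    ``level[i, t] = level[i, t-1] + A level[i, t-1] + additive_i + d[i, t]``
    with innovations ``d ~ N(0, psi)`` drawn independently for each of the
    T - 1 changes when the spec is stochastic, and zero otherwise.
    """
    if effects.p != spec.n_processes:
        raise ValueError("effects dimension does not match spec")
    n, p, T = effects.values.shape[0], spec.n_processes, spec.n_occasions
    M = np.eye(p) + dynamics_matrix(params)
    latent = np.empty((n, T, p))
    latent[:, 0, :] = effects.initial_levels
    add = effects.additive_components
    if spec.stochastic:
        rng = _rng(seed)
        innov = rng.multivariate_normal(
            np.zeros(p), params.psi, size=(n, T - 1), method="eigh", check_valid="ignore"
        )
    else:
        innov = np.zeros((n, T - 1, p))
    for t in range(1, T):
        latent[:, t, :] = latent[:, t - 1, :] @ M.T + add + innov[:, t - 1, :]
    return latent


def observe(latent: np.ndarray, theta: np.ndarray, seed: SeedLike) -> PanelData:
    """Add occasion-wise measurement error to latent levels.

    Errors are N(0, theta), independent across individuals and occasions
    (within-occasion covariance allowed through theta's off-diagonal).
    """
    latent = np.asarray(latent, dtype=float)
    n, T, p = latent.shape
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    lam = np.linalg.eigvalsh(theta)
    if lam.min() < -1e-10:
        raise ValueError("theta is not positive semi-definite")
    rng = _rng(seed)
    errors = rng.multivariate_normal(
        np.zeros(p), theta, size=(n, T), method="eigh", check_valid="ignore"
    )
    observed = latent + errors
    return PanelData(
        ids=np.arange(n),
        n_processes=p,
        n_occasions=T,
        observed=observed.reshape(n, T * p),
        latent=latent.reshape(n, T * p),
    )


def simulate_panel(spec: ModelSpec, params: ParameterSet, n: int, seed: SeedLike) -> PanelData:
    """Simulate a complete observed panel: effects -> latent recursion -> errors."""
    validate(spec, params)
    if isinstance(seed, np.random.Generator):
        ss = seed.bit_generator.seed_seq  # type: ignore[attr-defined]
    elif isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    s_eff, s_innov, s_err = ss.spawn(3)
    effects = draw_between_effects(params, n, np.random.default_rng(s_eff))
    latent = simulate_latent(spec, params, effects, np.random.default_rng(s_innov))
    return observe(latent, params.theta, np.random.default_rng(s_err))


# ---------------------------------------------------------------------------
# Named scenario registry
#
# Each entry documents a canonical illustrative configuration.  Printed
# quantities (rates, asymptote, self-feedback ladders, variances, the six
# bivariate dynamic regimes) are fixed; unprinted quantities use the
# documented defaults below, chosen to visually match the intended curves.

_DEF_VAR0 = 1.0        # default initial-level variance
_DEF_VARA = 0.1        # default additive-component variance
_DEF_ERR = 0.5         # default measurement-error variance
_ASYMPTOTE = 5.0       # shared asymptote of the exponential scenarios
_T = 5                 # default number of occasions


def _uni(mu0, mua, beta, var0=_DEF_VAR0, vara=_DEF_VARA, cov0a=0.0, err=_DEF_ERR, T=_T):
    spec = ModelSpec(n_processes=1, n_occasions=T)
    params = ParameterSet(
        mu0=[mu0], mua=[mua], phi=[[var0, cov0a], [cov0a, vara]], beta=[beta], theta=[[err]]
    )
    return spec, params


def _uni_from_exponential(rate, initial, asymptote=_ASYMPTOTE, **kw):
    """Discrete-time (lag 1) equivalent of an exponential-curve configuration."""
    from .model_spec import CTParameterSet

    ct = CTParameterSet(drift=[[-rate]], ct_additive=[rate * asymptote])
    A, a = dyn.ct_to_dt(ct, lag=1.0)
    return _uni(mu0=initial, mua=float(a[0]), beta=float(A[0, 0]), **kw)


def _biv(beta_x, beta_y, gamma_x, gamma_y, mu0=(0.0, 0.0), mua=(1.0, 1.0), T=_T):
    spec = ModelSpec(n_processes=2, n_occasions=T)
    phi = np.diag([_DEF_VAR0, _DEF_VAR0, _DEF_VARA, _DEF_VARA])
    theta = np.eye(2) * _DEF_ERR
    params = ParameterSet(
        mu0=list(mu0),
        mua=list(mua),
        phi=phi,
        beta=[beta_x, beta_y],
        gamma=[gamma_x, gamma_y],
        theta=theta,
    )
    return spec, params


# The six bivariate regimes: (beta_x, beta_y, gamma_x [y->x], gamma_y [x->y])
TABLE1_DYNAMICS: Dict[str, Tuple[float, float, float, float]] = {
    "A": (-0.3, -0.3, -0.2, 0.0),
    "B": (-0.3, 0.3, 0.2, 0.0),
    "C": (0.3, -0.7, 0.6, -0.5),
    "D": (0.3, 0.0, 0.2, 0.2),
    "E": (0.9, -0.9, 1.1, -1.1),
    "F": (-0.8, -0.3, -0.8, 0.8),
}

_FIXTURES = {
    # exponential curves: rate r in {4, -0.4}, initial level in {0, 10}, asymptote 5
    "fig2_decelerated_growth": lambda: _uni_from_exponential(rate=4.0, initial=0.0),
    "fig2_decelerated_decline": lambda: _uni_from_exponential(rate=4.0, initial=10.0),
    "fig2_accelerated_growth": lambda: _uni_from_exponential(rate=-0.4, initial=10.0),
    "fig2_accelerated_decline": lambda: _uni_from_exponential(rate=-0.4, initial=0.0),
    # self-feedback ladders: decelerated growth (negative) toward asymptote 5,
    # accelerated decay (positive) away from an asymptote above the start
    "fig4_low_seb": lambda: _uni(mu0=0.0, mua=dyn.additive_from_asymptote(5.0, -0.2), beta=-0.2),
    "fig4_medium_seb": lambda: _uni(mu0=0.0, mua=dyn.additive_from_asymptote(5.0, -0.5), beta=-0.5),
    "fig4_high_seb": lambda: _uni(mu0=0.0, mua=dyn.additive_from_asymptote(5.0, -1.0), beta=-1.0),
    "fig4_mistakes_low_seb": lambda: _uni(mu0=10.0, mua=dyn.additive_from_asymptote(15.0, 0.2), beta=0.2),
    "fig4_mistakes_medium_seb": lambda: _uni(mu0=10.0, mua=dyn.additive_from_asymptote(15.0, 0.5), beta=0.5),
    "fig4_mistakes_high_seb": lambda: _uni(mu0=10.0, mua=dyn.additive_from_asymptote(15.0, 1.0), beta=1.0),
    # variance fan-in/fan-out: sigma_y0^2 = 10 with additive variance 0 or 12
    "fig5_A": lambda: _uni(mu0=0.0, mua=1.5, beta=-0.3, var0=10.0, vara=0.0),
    "fig5_B": lambda: _uni(mu0=0.0, mua=1.5, beta=-0.3, var0=10.0, vara=12.0),
    "fig5_C": lambda: _uni(mu0=0.0, mua=1.5, beta=0.3, var0=10.0, vara=0.0),
    "fig5_D": lambda: _uni(mu0=0.0, mua=1.5, beta=0.3, var0=10.0, vara=12.0),
}
for _col, _dyn in TABLE1_DYNAMICS.items():
    _FIXTURES[f"table1_{_col}"] = (lambda d: (lambda: _biv(*d)))(_dyn)


def fixture_names() -> list:
    """Names of all registered scenarios."""
    return sorted(_FIXTURES)


def fixture_config(name: str) -> Tuple[ModelSpec, ParameterSet]:
    """Spec and parameter values of a named scenario."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; known: {', '.join(fixture_names())}"
        ) from None
    spec, params = builder()
    return spec, validate(spec, params)


def fixture(name: str, n: int, seed: SeedLike) -> Tuple[ParameterSet, PanelData]:
    """Parameter values of a named scenario plus a simulated panel of size n."""
    spec, params = fixture_config(name)
    return params, simulate_panel(spec, params, n, seed)
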