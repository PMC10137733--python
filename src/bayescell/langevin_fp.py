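"""Langevin simulation and the hierarchical Fokker-Planck reduction.

The cell-microenvironment pair (X, Y) is modelled as a two-variable Ito
diffusion: Y is the fast microenvironmental variable with drift K1(y, x, t)
and diffusion sigma11, X the slow internal state with drift K2(x) and
constant diffusion sigma22, coupled through sigma12.  Under timescale
separation (an explicit ratio ``epsilon`` scaling the fast rates) the joint
Fokker-Planck equation splits into

* a fast equation for the conditional law P(Y, t | X) at frozen X,
* a slow equation ``-K2(x) P(x) + sigma22 dP/dx = 0`` whose 1-D stationary
  solution is ``P(x) propto exp( int^x K2(u)/sigma22 du )``,
* a coupling constraint ``2 d/dy[sigma12 P(y|x)] + sigma22 d/dy P(y|x) = 0``
  (satisfied identically by the constant choice sigma12 = -sigma22/2).

Diffusion convention: the Fokker-Planck coefficients are
``sigma_pq = (Sigma Sigma^T)_pq / 2`` where Sigma is the Langevin noise
matrix, so an Ornstein-Uhlenbeck slow variable with K2 = -k x has stationary
variance sigma22 / k.  This dictionary is locked in by tests.

The bridge back to Bayesian learning: the drift
``K2(x) = -beta sigma22 S(Y|X=x) - beta' sigma22`` built from the
microenvironmental conditional-entropy profile makes the slow stationary
solution coincide with the Gibbs steady state of the learning dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .distributions import Grid1D, GridDensity1D, normalize
from .steady_state import SensitivityParams

__all__ = [
    "SDESpec",
    "SDETrajectory",
    "FPStationary",
    "euler_maruyama",
    "stationary_solution_1d",
    "drift_from_entropy",
    "simulate_slow_stationary",
    "SlowSimulationReport",
    "fast_conditional_density",
    "coupling_residual",
    "slow_equation_residual",
    "ks_distance",
]


class BlowUpError(RuntimeError):
    """The Euler-Maruyama state became non-finite."""


def _as_array_fn(f: Callable, n_args: int = 1) -> Callable:
    """Wrap a scalar-or-array function so array evaluation is used if valid."""

    def wrapped(*args):
        try:
            out = np.asarray(f(*args), dtype=float)
            if out.shape == np.broadcast(*(np.asarray(a) for a in args)).shape:
                return out
        except Exception:
            pass
        return np.vectorize(f, otypes=[float])(*args)

    return wrapped


@dataclass
class SDESpec:
    """Two-variable Ito SDE specification (slow x, fast y).

    Drifts: ``drift_K1(y, x, t)`` for the fast variable, ``drift_K2(x)`` for
    the slow one.  Diffusions are Fokker-Planck coefficients (see module
    docstring); ``sigma22`` is a constant, ``sigma11``/``sigma12`` may
    depend on (y, x).  ``epsilon`` scales the fast drift and diffusion by
    ``1/epsilon``.
    """

    drift_K1: Callable[[float, float, float], float]
    drift_K2: Callable[[float], float]
    sigma11: Union[float, Callable[[np.ndarray, np.ndarray], np.ndarray]] = 0.5
    sigma12: Union[float, Callable[[np.ndarray, np.ndarray], np.ndarray]] = 0.0
    sigma22: float = 0.5
    epsilon: float = 1.0
    dt: float = 0.01
    n_steps: int = 1000
    n_paths: int = 1
    seed: int = 0
    initial: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.sigma22 < 0:
            raise ValueError("sigma22 must be >= 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    def _eval(self, coeff, y, x):
        if callable(coeff):
            return np.asarray(coeff(y, x), dtype=float)
        return np.full_like(np.asarray(y, dtype=float), float(coeff))


@dataclass
class SDETrajectory:
    times: np.ndarray
    x: np.ndarray  # (n_paths, n_steps + 1)
    y: np.ndarray
    seed: int


def euler_maruyama(spec: SDESpec) -> SDETrajectory:
    """Ito-Euler integration of the two-variable system, vectorized over paths.

    Per-step the Langevin noise matrix is the Cholesky factor of twice the
    Fokker-Planck diffusion matrix, with the fast row scaled by 1/epsilon.
    Independent Wiener increments drive the two components.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_paths, spec.n_steps
    x = np.empty((n, m + 1))
    y = np.empty((n, m + 1))
    x[:, 0] = spec.initial[0]
    y[:, 0] = spec.initial[1]
    dt = spec.dt
    sqdt = math.sqrt(dt)
    k1 = _as_array_fn(spec.drift_K1)
    k2 = _as_array_fn(spec.drift_K2)

    for t in range(m):
        xt, yt = x[:, t], y[:, t]
        a = 2.0 * spec._eval(spec.sigma11, yt, xt) / spec.epsilon
        c = 2.0 * spec._eval(spec.sigma12, yt, xt)
        d = 2.0 * spec.sigma22
        if np.any(a < 0) or d < 0:
            raise ValueError("diffusion coefficients must be nonnegative")
        l11 = np.sqrt(a)
        with np.errstate(divide="ignore", invalid="ignore"):
            l21 = np.where(l11 > 0, c / np.clip(l11, 1e-300, None), 0.0)
        rad = d - l21**2
        if np.any(rad < -1e-12):
            raise ValueError(
                "diffusion matrix not positive semidefinite "
                "(sigma12^2 > sigma11 * sigma22 * epsilon ... )"
            )
        l22 = np.sqrt(np.clip(rad, 0.0, None))
        dw1 = rng.standard_normal(n) * sqdt
        dw2 = rng.standard_normal(n) * sqdt
        y[:, t + 1] = yt + (k1(yt, xt, np.full_like(yt, t * dt)) / spec.epsilon) * dt + l11 * dw1
        x[:, t + 1] = xt + k2(xt) * dt + l21 * dw1 + l22 * dw2
        if not (np.all(np.isfinite(x[:, t + 1])) and np.all(np.isfinite(y[:, t + 1]))):
            raise BlowUpError(
                f"non-finite state at step {t + 1}; reduce dt or check drifts"
            )
    times = np.arange(m + 1) * dt
    return SDETrajectory(times=times, x=x, y=y, seed=spec.seed)


def stationary_variance_report(
    traj: SDETrajectory, burn_in: float = 0.2
) -> Tuple[float, float]:
    """Long-run variance of the slow variable with an honest standard error.

    Second moments are taken around the ensemble grand mean (a per-path mean
    over a window short relative to the relaxation time would absorb
    low-frequency variance and bias the estimate down); the standard error
    is the spread of the independent per-path estimates.
    """
    m = traj.x.shape[1] - 1
    keep = traj.x[:, int(burn_in * m):]
    grand = keep.mean()
    per_path = ((keep - grand) ** 2).mean(axis=1)
    n_paths = per_path.size
    se = per_path.std(ddof=1) / math.sqrt(n_paths) if n_paths > 1 else math.inf
    return float(per_path.mean()), float(se)


@dataclass
class FPStationary:
    density: GridDensity1D
    f0: float  # normalizer of the unshifted exponent
    source: Optional[SDESpec] = None


def stationary_solution_1d(
    K2: Callable[[np.ndarray], np.ndarray],
    sigma22: float,
    domain: Grid1D,
) -> FPStationary:
    """Stationary solution of the slow Fokker-Planck equation in 1-D.

    ``P(x) propto exp( int^x K2(u)/sigma22 du )`` by cumulative trapezoid;
    for constant sigma22 the ``-ln sigma22`` term is an absorbed constant.
    """
    if sigma22 <= 0:
        raise ValueError("sigma22 must be > 0 for a stationary density")
    x = domain.x
    k2v = _as_array_fn(K2)(x)
    if not np.all(np.isfinite(k2v)):
        raise ValueError("drift must be finite on the domain")
    exponent = cumulative_trapezoid(k2v / sigma22, dx=domain.spacing, initial=0.0)
    shift = exponent.max()
    raw = np.exp(exponent - shift)
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-integrable stationary exponent")
    z = float(np.trapezoid(raw, dx=domain.spacing))
    return FPStationary(density=GridDensity1D(domain, raw / z), f0=1.0 / z)


def drift_from_entropy(
    entropy_profile: Callable[[np.ndarray], np.ndarray],
    params: SensitivityParams,
    sigma22: float,
) -> Callable[[np.ndarray], np.ndarray]:
    """Slow drift reproducing the entropy-driven Gibbs steady state.

    ``K2(x) = -beta sigma22 S(Y|X=x) - beta' sigma22``: feeding this into
    :func:`stationary_solution_1d` recovers
    ``P propto exp(-beta int S - beta' x)``.
    """

    def K2(x):
        return (
            -params.beta * sigma22 * np.asarray(entropy_profile(x), dtype=float)
            - params.beta_prime * sigma22
        )

    return K2


def ks_distance(samples: np.ndarray, cdf_x: np.ndarray, cdf_vals: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance between samples and a tabulated CDF."""
    s = np.sort(np.asarray(samples, dtype=float))
    n = s.size
    f = np.interp(s, cdf_x, cdf_vals, left=0.0, right=1.0)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(np.abs(ecdf_hi - f)), np.max(np.abs(f - ecdf_lo))))


def _simulate_slow_1d(
    K2: Callable[[np.ndarray], np.ndarray],
    sigma22: float,
    domain: Tuple[float, float],
    n_paths: int,
    n_steps: int,
    dt: float,
    seed: int,
    burn_in: float = 0.2,
) -> np.ndarray:
    """Reflecting-boundary Euler-Maruyama for the slow variable alone.

    Returns retained samples (post burn-in), flattened over paths and time.
    """
    lo, hi = domain
    rng = np.random.default_rng(seed)
    amp = math.sqrt(2.0 * sigma22 * dt)
    k2 = _as_array_fn(K2)
    x = rng.uniform(lo, hi, size=n_paths)
    keep_from = int(burn_in * n_steps)
    kept = np.empty((n_steps - keep_from, n_paths))
    for t in range(n_steps):
        x = x + k2(x) * dt + amp * rng.standard_normal(n_paths)
        # reflecting boundaries (may need several folds for large excursions)
        for _ in range(10):
            below = x < lo
            above = x > hi
            if not (below.any() or above.any()):
                break
            x = np.where(below, 2 * lo - x, x)
            x = np.where(above, 2 * hi - x, x)
        if not np.all(np.isfinite(x)):
            raise BlowUpError(f"non-finite slow state at step {t + 1}")
        if t >= keep_from:
            kept[t - keep_from] = x
    return kept.ravel()


@dataclass
class SlowSimulationReport:
    empirical: GridDensity1D
    analytic: FPStationary
    ks: float
    n_retained: int
    degenerate: bool = False


def simulate_slow_stationary(
    entropy_profile: Callable[[np.ndarray], np.ndarray],
    params: SensitivityParams,
    sigma22: float,
    domain: Grid1D,
    n_paths: int = 400,
    n_steps: int = 8000,
    dt: float = 0.01,
    seed: int = 0,
    burn_in: float = 0.2,
    max_retained: int = 400_000,
) -> SlowSimulationReport:
    """Simulate the slow variable under the entropy-derived drift.

    Runs reflecting-boundary Euler-Maruyama, discards the burn-in, thins to
    at most ``max_retained`` samples, histograms the remainder on the
    domain grid and returns the Kolmogorov-Smirnov distance to the
    stationary quadrature solution.  With ``sigma22 = 0`` the dynamics are
    deterministic; the report is flagged degenerate and not compared.
    """
    K2 = drift_from_entropy(entropy_profile, params, sigma22)
    if sigma22 == 0.0:
        # deterministic limit: mass collapses onto the drift's fixed point
        empirical = GridDensity1D(domain, np.zeros(domain.n_points))
        analytic = FPStationary(
            density=GridDensity1D(domain, np.full(domain.n_points, 1.0 / (domain.upper - domain.lower))),
            f0=1.0,
        )
        return SlowSimulationReport(empirical, analytic, math.nan, 0, degenerate=True)

    samples = _simulate_slow_1d(
        K2, sigma22, (domain.lower, domain.upper), n_paths, n_steps, dt, seed, burn_in
    )
    if samples.size > max_retained:
        stride = int(math.ceil(samples.size / max_retained))
        samples = samples[::stride]
    analytic = stationary_solution_1d(K2, sigma22, domain)
    edges = np.linspace(domain.lower, domain.upper, domain.n_points + 1)
    counts, _ = np.histogram(samples, bins=edges, density=True)
    # node-centered empirical density: average adjacent bin heights
    node_vals = np.empty(domain.n_points)
    node_vals[0] = counts[0]
    node_vals[-1] = counts[-1]
    node_vals[1:-1] = 0.5 * (counts[:-2] + counts[1:-1])
    empirical = normalize(GridDensity1D(domain, node_vals))
    ks = ks_distance(samples, domain.x, analytic.density.cdf())
    return SlowSimulationReport(empirical, analytic, ks, int(samples.size))


def fast_conditional_density(
    spec: SDESpec,
    x_frozen: float,
    grid: Grid1D,
    burn_in: float = 0.2,
) -> GridDensity1D:
    """Empirical quasi-steady density of the fast variable at frozen X.

    Integrates only the fast component (drift K1/epsilon, diffusion
    sigma11/epsilon) with X held at ``x_frozen``, discards the burn-in and
    histograms the retained samples on ``grid``.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_paths, spec.n_steps
    dt = spec.dt
    y = np.full(n, float(spec.initial[1]))
    xf = np.full(n, float(x_frozen))
    k1 = _as_array_fn(lambda yy: spec.drift_K1(yy, x_frozen, 0.0))
    keep_from = int(burn_in * m)
    kept = np.empty((m - keep_from, n))
    for t in range(m):
        a = 2.0 * spec._eval(spec.sigma11, y, xf) / spec.epsilon
        y = y + (k1(y) / spec.epsilon) * dt + np.sqrt(a * dt) * rng.standard_normal(n)
        if not np.all(np.isfinite(y)):
            raise BlowUpError(f"non-finite fast state at step {t + 1}")
        if t >= keep_from:
            kept[t - keep_from] = y
    samples = kept.ravel()
    edges = np.linspace(grid.lower, grid.upper, grid.n_points + 1)
    counts, _ = np.histogram(samples, bins=edges, density=True)
    node_vals = np.empty(grid.n_points)
    node_vals[0] = counts[0]
    node_vals[-1] = counts[-1]
    node_vals[1:-1] = 0.5 * (counts[1:-1] + counts[:-2])
    total = np.trapezoid(node_vals, dx=grid.spacing)
    if total <= 0:
        raise ValueError("no fast samples landed on the requested grid")
    return GridDensity1D(grid, node_vals / total)


def coupling_residual(
    sigma12: Union[float, Callable[[np.ndarray], np.ndarray]],
    sigma22: float,
    cond_density: GridDensity1D,
) -> Tuple[np.ndarray, float]:
    """Residual of the fast-slow coupling constraint on the Y-grid.

    Evaluates ``2 d/dy[sigma12(y) P(y|x)] + sigma22 d/dy P(y|x)`` with
    central differences on interior nodes; returns (profile, sup-norm).
    The constant choice ``sigma12 = -sigma22/2`` makes it vanish for any
    smooth density.
    """
    y = cond_density.x
    p = cond_density.values
    h = cond_density.grid.spacing
    s12 = np.asarray(sigma12(y), dtype=float) if callable(sigma12) else np.full_like(y, float(sigma12))
    prod = s12 * p
    d_prod = (prod[2:] - prod[:-2]) / (2.0 * h)
    d_p = (p[2:] - p[:-2]) / (2.0 * h)
    profile = 2.0 * d_prod + sigma22 * d_p
    return profile, float(np.max(np.abs(profile)))


def slow_equation_residual(
    solution: FPStationary,
    K2: Callable[[np.ndarray], np.ndarray],
    sigma22: float,
) -> float:
    """Sup-norm residual of the slow stationary equation, density-scaled.

    ``-K2(x) P(x) + sigma22 dP/dx`` on interior nodes, divided by max P.
    """
    d = solution.density
    p = d.values
    h = d.grid.spacing
    k2v = _as_array_fn(K2)(d.x[1:-1])
    dp = (p[2:] - p[:-2]) / (2.0 * h)
    resid = -k2v * p[1:-1] + sigma22 * dp
    return float(np.max(np.abs(resid)) / p.max())
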