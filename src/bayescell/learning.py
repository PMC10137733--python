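"""Discrete-time Bayesian learning of the internal-state distribution.

Each decision step the cell observes an environment sample y, forms the
posterior ``P(x|y) propto P(y|x) P(x)`` and adopts it as the next prior.
Two identities organize the module:

* fluctuation-dissipation: the Y-expected Kullback-Leibler divergence
  between consecutive priors equals the mutual information between the cell
  and its microenvironment, ``E_Y[KL(posterior || prior)] = I(Y, X)``;
* Fisher quadratic form: for a small shift ``delta`` of the internal-state
  density, ``KL(p(. - delta) || p) ~= (1/2) delta^2 F(p)`` with ``F`` the
  Fisher information.

Trajectories are recorded step by step (KL, mutual information, prior
variance, cell-environment covariance, conditional entropy via the averaged
variance law ``sigma_{Y|X}^2 = b^2 + g^2 sigma_x^2``), exhibiting the
monotone decay of microenvironmental uncertainty toward ``ln b +
(1/2) ln(2 pi e)`` as learning sharpens the prior.

Update modes
------------
``observed``
    draws one y per step from the environment-truth density (by default the
    model-implied evidence of the current prior) — the per-decision update.
``averaged``
    replaces the stochastic step by the exact Y-averaged log-likelihood
    update ``P'(x) propto P(x) exp(E_{P(Y)}[ln P(y|x)])``, the deterministic
    surrogate whose conjugate-Gaussian chain reproduces the exact
    posterior-precision recursion while leaving the prior mean unchanged.

Randomness: one root seed; the step-t stream is ``default_rng([seed, t])``
so trajectories are reproducible and extendable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .distributions import (
    Grid1D,
    GridDensity1D,
    JointTable,
    fisher_information,
    kl_divergence,
    normalize,
)
from .sensing import SensingModel

__all__ = [
    "LearningConfig",
    "LearningStep",
    "LearningTrajectory",
    "bayes_update",
    "expected_update_divergence",
    "mutual_information_grid",
    "beta_tilde",
    "fisher_quadratic_form",
    "FisherQuadraticReport",
    "iterate_learning",
    "entropy_decay_report",
    "pointwise_mi_given_x",
    "product_form_pmi",
]


class DegenerateEvidenceError(ValueError):
    """The observation is incompatible with the prior (evidence ~ 0)."""


class CoverageError(ValueError):
    """The y-grid does not capture enough evidence mass for quadrature."""


#: minimum evidence mass the y-grid must capture
EVIDENCE_COVERAGE = 0.999


def _gaussian_likelihood(sensing: SensingModel, x: np.ndarray, y: float) -> np.ndarray:
    mu = sensing.conditional_mean(x)
    sd = sensing.conditional_sd(x)
    return np.exp(-0.5 * ((y - mu) / sd) ** 2) / (sd * math.sqrt(2.0 * math.pi))


def bayes_update(
    prior: GridDensity1D, sensing: SensingModel, y_obs: float
) -> GridDensity1D:
    """One Bayesian update: posterior propto likelihood(x; y_obs) * prior."""
    x = prior.x
    like = _gaussian_likelihood(sensing, x, y_obs)
    product = like * prior.values
    evidence = float(np.trapezoid(product, dx=prior.grid.spacing))
    if not np.isfinite(evidence) or evidence < 1e-300:
        raise DegenerateEvidenceError(
            f"evidence {evidence!r} for observation y={y_obs}"
        )
    return GridDensity1D(prior.grid, product / evidence)


def _likelihood_matrix(
    sensing: SensingModel, x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """L[i, j] = P(y_j | x_i) for the Gaussian channel."""
    mu = np.asarray(sensing.conditional_mean(x))[:, None]
    sd = np.asarray(sensing.conditional_sd(x))[:, None]
    return np.exp(-0.5 * ((y[None, :] - mu) / sd) ** 2) / (
        sd * math.sqrt(2.0 * math.pi)
    )


def _evidence(
    prior: GridDensity1D, like: np.ndarray, y_grid: Grid1D
) -> np.ndarray:
    return np.trapezoid(like * prior.values[:, None], dx=prior.grid.spacing, axis=0)


def _check_coverage(evidence: np.ndarray, y_grid: Grid1D) -> None:
    mass = float(np.trapezoid(evidence, dx=y_grid.spacing))
    if mass < EVIDENCE_COVERAGE:
        raise CoverageError(
            f"y-grid captures only {mass:.6f} of the evidence mass "
            f"(need >= {EVIDENCE_COVERAGE})"
        )


def expected_update_divergence(
    prior: Union[GridDensity1D, JointTable],
    sensing: Optional[SensingModel] = None,
    y_grid: Optional[Grid1D] = None,
) -> float:
    """Y-expected KL divergence between posterior and prior, in nats.

    ``E_{P(Y)}[ KL(P(X|y) || P(X)) ]`` — by the fluctuation-dissipation
    identity this equals the mutual information of the induced joint.

    Accepts either a :class:`JointTable` (discrete case, exact cell
    summation) or a grid prior with a sensing model and a y-quadrature grid.
    """
    if isinstance(prior, JointTable):
        joint = prior
        px = joint.marginal_x()
        py = joint.marginal_y()
        total = 0.0
        for j, pyj in enumerate(py):
            if pyj <= 0:
                continue
            post = joint.probs[:, j] / pyj
            mask = post > 0
            total += pyj * float(
                np.sum(post[mask] * np.log(post[mask] / px[mask]))
            )
        return total

    if sensing is None or y_grid is None:
        raise TypeError("grid form requires a sensing model and a y-grid")
    x = prior.x
    y = y_grid.x
    like = _likelihood_matrix(sensing, x, y)
    evidence = _evidence(prior, like, y_grid)
    _check_coverage(evidence, y_grid)

    hx = prior.grid.spacing
    total = np.zeros_like(y)
    pos = evidence > 1e-300
    post = like[:, pos] * prior.values[:, None] / evidence[pos][None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(post > 0, post / prior.values[:, None], 1.0)
        integrand = np.where(post > 0, post * np.log(ratio), 0.0)
    total[pos] = np.trapezoid(integrand, dx=hx, axis=0)
    return float(np.trapezoid(evidence * total, dx=y_grid.spacing))


def mutual_information_grid(
    prior: GridDensity1D, sensing: SensingModel, y_grid: Grid1D
) -> float:
    """Mutual information of the induced joint P(y|x) P(x), in nats.

    Computed in the opposite Fubini order to
    :func:`expected_update_divergence` — as the prior-weighted average of
    the per-x channel divergence ``KL(P(Y|x) || P(Y))`` — so the pair forms
    a genuine two-route identity check.
    """
    x = prior.x
    y = y_grid.x
    like = _likelihood_matrix(sensing, x, y)
    evidence = _evidence(prior, like, y_grid)
    _check_coverage(evidence, y_grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(like > 0, like / np.clip(evidence[None, :], 1e-300, None), 1.0)
        integrand = np.where(like > 0, like * np.log(ratio), 0.0)
    per_x = np.trapezoid(integrand, dx=y_grid.spacing, axis=1)
    return float(np.trapezoid(prior.values * per_x, dx=prior.grid.spacing))


def pointwise_mi_given_x(
    sensing: SensingModel,
    prior: GridDensity1D,
    x: float,
    y_grid: Grid1D,
) -> float:
    """Y-averaged pointwise mutual information at internal state x.

    ``int P(y|x) ln[P(y|x)/P(y)] dy = KL(P(Y|x) || P(Y)) >= 0``, with the
    evidence P(y) induced by the prior.
    """
    y = y_grid.x
    like_x = _likelihood_matrix(sensing, np.array([x]), y)[0]
    own_mass = float(np.trapezoid(like_x, dx=y_grid.spacing))
    if own_mass < EVIDENCE_COVERAGE:
        raise CoverageError(
            f"y-grid captures only {own_mass:.6f} of P(Y|x={x})"
        )
    like = _likelihood_matrix(sensing, prior.x, y)
    evidence = _evidence(prior, like, y_grid)
    _check_coverage(evidence, y_grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(like_x > 0, like_x / np.clip(evidence, 1e-300, None), 1.0)
        integrand = np.where(like_x > 0, like_x * np.log(ratio), 0.0)
    return float(np.trapezoid(integrand, dx=y_grid.spacing))


def product_form_pmi(components: Sequence[float]) -> float:
    """Aggregate pointwise mutual information of independent components.

    Under mutual independence of the internal components the pointwise
    mutual information factorizes additively: ``i(X:Y) = sum_i i(X_i:Y)``.
    """
    comps = np.asarray(list(components), dtype=float)
    if comps.size and not np.all(np.isfinite(comps)):
        raise ValueError("component values must be finite")
    return float(comps.sum())


def _window_mass(values: np.ndarray, grid: Grid1D, lo: float, hi: float, axis: int = 0) -> np.ndarray:
    """Trapezoidal mass of `values` over [lo, hi] along `axis`.

    Uses the cumulative trapezoid with linear interpolation at the window
    edges, so partial grid cells are weighted correctly.
    """
    from scipy.integrate import cumulative_trapezoid

    c = cumulative_trapezoid(values, dx=grid.spacing, axis=axis, initial=0.0)
    x = grid.x

    def at(pos):
        p = min(max(pos, x[0]), x[-1])
        i = min(int((p - x[0]) / grid.spacing), grid.n_points - 2)
        frac = (p - x[i]) / grid.spacing
        c_i = np.take(c, i, axis=axis)
        c_j = np.take(c, i + 1, axis=axis)
        return c_i + frac * (c_j - c_i)

    return at(hi) - at(lo)


def beta_tilde(
    supports_xprime: tuple,
    supports_xy: tuple,
    sensing: SensingModel,
    prior: GridDensity1D,
    y_grid: Grid1D,
) -> float:
    """Windowed-quadrature diagnostic for the update-normalization ratio.

    The ratio of (a) the evidence-averaged posterior mass captured by the
    declared x'-window to (b) the prior-and-channel mass captured by the
    declared (x, y)-window, each normalized by its full-support mass.  Both
    factors are 1 when the windows capture the full mass, so the ratio is 1
    on fully normalized supports; truncating the numerator window to a
    fraction of the posterior mass scales the ratio by that fraction.
    """
    xp_lo, xp_hi = supports_xprime
    (x_lo, x_hi), (y_lo, y_hi) = supports_xy
    if xp_lo >= xp_hi or x_lo >= x_hi or y_lo >= y_hi:
        raise ValueError("empty truncation window")
    x = prior.x
    y = y_grid.x
    like = _likelihood_matrix(sensing, x, y)
    evidence = _evidence(prior, like, y_grid)
    _check_coverage(evidence, y_grid)

    hx, hy = prior.grid.spacing, y_grid.spacing
    # numerator: E_{P(y)} [ posterior mass inside the x' window ]
    post = like * prior.values[:, None] / np.clip(evidence[None, :], 1e-300, None)
    num_per_y = _window_mass(post, prior.grid, xp_lo, xp_hi, axis=0)
    numerator = float(np.trapezoid(evidence * num_per_y, dx=hy))

    # denominator: windowed prior x channel mass over full prior mass
    chan_mass = _window_mass(like, y_grid, y_lo, y_hi, axis=1)
    denominator = float(
        _window_mass(prior.values * chan_mass, prior.grid, x_lo, x_hi)
        / np.trapezoid(prior.values, dx=hx)
    )
    if denominator <= 0:
        raise ValueError("denominator window captures no mass")
    return numerator / denominator


@dataclass
class FisherQuadraticReport:
    """Quadratic KL approximation and its exact companion for a shift delta."""

    delta: float
    fisher: float
    quadratic_form: float
    exact_kl: float


def fisher_quadratic_form(
    density: GridDensity1D, delta: float
) -> FisherQuadraticReport:
    """Quadratic (Fisher) approximation to the KL cost of a small shift.

    Returns ``(1/2) delta^2 F(p)`` together with the exact
    ``KL(p(. - delta) || p)`` computed on the grid.  The shift is applied by
    exact node translation when ``delta`` is (numerically) an integer
    multiple of the grid spacing, and by interpolation of ``ln p``
    otherwise; the mass pushed off-grid must be below 1e-10.
    """
    h = density.grid.spacing
    if delta == 0.0:
        return FisherQuadraticReport(0.0, fisher_information(density), 0.0, 0.0)
    p = density.values
    n = len(p)
    k_float = delta / h
    k = int(round(k_float))
    if abs(k_float - k) < 1e-9 and 0 < abs(k) < n:
        shifted = np.zeros_like(p)
        if k > 0:
            shifted[k:] = p[:-k]
            lost = float(np.trapezoid(p[-k:], dx=h))
        else:
            shifted[:k] = p[-k:]
            lost = float(np.trapezoid(p[:-k], dx=h))
    else:
        logp = np.log(np.clip(p, 1e-300, None))
        shifted_log = np.interp(
            density.x - delta, density.x, logp, left=-750.0, right=-750.0
        )
        shifted = np.exp(shifted_log)
        shifted[shifted < 1e-290] = 0.0
        lost = float(abs(1.0 - np.trapezoid(shifted, dx=h)))
    if lost > 1e-10:
        raise ValueError(
            f"shift by {delta} pushes {lost:.3e} probability mass off-grid"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((shifted > 0) & (p > 0), shifted / p, 1.0)
        integrand = np.where(shifted > 0, shifted * np.log(ratio), 0.0)
    exact = float(np.trapezoid(integrand, dx=h))
    fisher = fisher_information(density)
    return FisherQuadraticReport(delta, fisher, 0.5 * delta**2 * fisher, exact)


# ---------------------------------------------------------------------------
# Learning trajectories


@dataclass
class LearningConfig:
    """Configuration of a Bayesian learning run."""

    prior: GridDensity1D
    sensing: SensingModel
    y_grid: Grid1D
    n_steps: int = 10
    tau: float = 1.0  # decision time, bookkeeping only
    seed: int = 0
    update_mode: str = "observed"
    environment_truth: Optional[GridDensity1D] = None  # defaults to evidence

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.tau <= 0:
            raise ValueError("decision time tau must be > 0")
        if self.update_mode not in ("observed", "averaged"):
            raise ValueError(f"unknown update_mode {self.update_mode!r}")
        lo, hi = self.sensing.admissible_interval()
        g = self.prior.grid
        if g.lower < lo - 1e-12 or g.upper > hi + 1e-12:
            raise ValueError(
                "prior grid extends outside the sensing model's admissible "
                f"interval [{lo}, {hi}]"
            )


@dataclass
class LearningStep:
    step: int
    y_obs: float  # nan in averaged mode
    kl: float
    mi: float
    sigma_x2: float
    cond_entropy: float
    cov_xy: float
    prior_snapshot: Optional[np.ndarray] = None


@dataclass
class LearningTrajectory:
    steps: List[LearningStep]
    final_prior: GridDensity1D
    config: LearningConfig

    def __len__(self) -> int:
        return len(self.steps)

    def sigma_x2_series(self) -> np.ndarray:
        return np.array([s.sigma_x2 for s in self.steps])

    def to_rows(self) -> List[dict]:
        return [
            {
                "step": s.step,
                "y_obs": s.y_obs,
                "kl": s.kl,
                "mi": s.mi,
                "sigma_x2": s.sigma_x2,
                "cond_entropy": s.cond_entropy,
                "cov_xy": s.cov_xy,
            }
            for s in self.steps
        ]


def _cov_xy(prior: GridDensity1D, sensing: SensingModel) -> float:
    """cov(X, Y) under the joint P(y|x) P(x); E[Y|x] = F(x)."""
    h = prior.grid.spacing
    fx = np.asarray(sensing.conditional_mean(prior.x))
    ex = prior.mean()
    ey = float(np.trapezoid(fx * prior.values, dx=h))
    exy = float(np.trapezoid(prior.x * fx * prior.values, dx=h))
    return exy - ex * ey


def _sample_from_density(density: GridDensity1D, rng: np.random.Generator) -> float:
    u = rng.uniform()
    cdf = density.cdf()
    return float(np.interp(u, cdf, density.x))


def iterate_learning(
    config: LearningConfig, keep_snapshots: bool = False
) -> LearningTrajectory:
    """Run the Bayesian learning chain and record per-step statistics."""
    prior = normalize(config.prior)
    sensing = config.sensing
    steps: List[LearningStep] = []
    hy = config.y_grid.spacing

    for t in range(config.n_steps):
        like = _likelihood_matrix(sensing, prior.x, config.y_grid.x)
        evidence_vals = _evidence(prior, like, config.y_grid)
        _check_coverage(evidence_vals, config.y_grid)
        evidence = GridDensity1D(
            config.y_grid, evidence_vals / np.trapezoid(evidence_vals, dx=hy)
        )

        sigma_x2 = prior.variance()
        cond_var = sensing.averaged_conditional_variance(sigma_x2)
        cond_entropy = 0.5 * math.log(2.0 * math.pi * math.e * cond_var)
        mi = expected_update_divergence(prior, sensing, config.y_grid)
        cov = _cov_xy(prior, sensing)

        if config.update_mode == "observed":
            truth = config.environment_truth or evidence
            rng = np.random.default_rng([config.seed, t])
            y_obs = _sample_from_density(truth, rng)
            try:
                posterior = bayes_update(prior, sensing, y_obs)
            except DegenerateEvidenceError as err:
                raise DegenerateEvidenceError(
                    f"degenerate evidence at step {t}: {err}"
                ) from err
        else:
            y_obs = math.nan
            truth = config.environment_truth or evidence
            mu = np.asarray(sensing.conditional_mean(prior.x))[:, None]
            sd = np.asarray(sensing.conditional_sd(prior.x))[:, None]
            loglike = (
                -0.5 * ((config.y_grid.x[None, :] - mu) / sd) ** 2
                - np.log(sd)
                - 0.5 * math.log(2.0 * math.pi)
            )
            avg_loglike = np.trapezoid(
                truth.values[None, :] * loglike, dx=hy, axis=1
            )
            weights = np.exp(avg_loglike - avg_loglike.max())
            posterior = normalize(GridDensity1D(prior.grid, prior.values * weights))

        kl = kl_divergence(posterior, prior)
        steps.append(
            LearningStep(
                step=t,
                y_obs=y_obs,
                kl=kl,
                mi=mi,
                sigma_x2=sigma_x2,
                cond_entropy=cond_entropy,
                cov_xy=cov,
                prior_snapshot=prior.values.copy() if keep_snapshots else None,
            )
        )
        prior = posterior

    return LearningTrajectory(steps=steps, final_prior=prior, config=config)


def entropy_decay_report(
    traj: LearningTrajectory, sensing: SensingModel
) -> dict:
    """Microenvironmental-uncertainty decay along a learning trajectory.

    Recomputes the per-step conditional variance ``b^2 + g^2 sigma_x,t^2``
    and entropy, reports whether both are nonincreasing and the gap between
    the final conditional variance and its learning limit ``b^2``.
    """
    if len(traj) < 2:
        return {
            "verdict": "insufficient data",
            "n_steps": len(traj),
            "cond_var": [
                sensing.averaged_conditional_variance(s.sigma_x2)
                for s in traj.steps
            ],
        }
    sigma_x2 = traj.sigma_x2_series()
    cond_var = sensing.b**2 + sensing.g**2 * sigma_x2
    entropies = 0.5 * np.log(2.0 * math.pi * math.e * cond_var)
    diffs = np.diff(cond_var)
    monotone = bool(np.all(diffs <= 1e-9))
    return {
        "verdict": "nonincreasing" if monotone else "non-monotone",
        "n_steps": len(traj),
        "cond_var": cond_var.tolist(),
        "cond_entropy": entropies.tolist(),
        "limit_gap": float(abs(cond_var[-1] - sensing.b**2)),
        "entropy_limit": math.log(sensing.b) + 0.5 * math.log(2.0 * math.pi * math.e),
    }
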