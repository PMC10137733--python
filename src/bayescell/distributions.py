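"""Grid-based probability densities and information-theoretic functionals.

Everything downstream (Bayesian updates, Gibbs steady states, Fokker-Planck
stationary solutions) is built on normalized densities over uniform 1-D grids,
integrated with the trapezoid rule.  All entropies, divergences and
informations are in nats.

Conventions
-----------
* ``0 * ln 0 := 0``; densities are clipped at ``CLIP_FLOOR`` before taking
  logarithms, and clip events are logged once per call.
* The Fisher information is computed with the standard sign convention
  ``F = E[-d^2 ln p / dx^2]`` so that a Gaussian of standard deviation sigma
  yields ``+1/sigma^2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Grid1D",
    "GridDensity1D",
    "JointTable",
    "normalize",
    "entropy",
    "kl_divergence",
    "mutual_information",
    "fisher_information",
]

logger = logging.getLogger(__name__)

#: densities are clipped at this floor before logs, to keep 0*log(0) = 0 finite
CLIP_FLOOR = 1e-300

#: tolerance on |integral - 1| for a density to count as normalized
NORMALIZATION_TOL = 1e-6


class InvalidDensityError(ValueError):
    """Raised for all-zero, negative or non-finite density values."""


class SupportError(ValueError):
    """Raised when KL divergence is requested with p > 0 where q = 0."""


@dataclass(frozen=True)
class Grid1D:
    """A uniform 1-D grid on ``[lower, upper]`` with ``n_points`` nodes."""

    lower: float
    upper: float
    n_points: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("grid bounds must be finite")
        if self.lower >= self.upper:
            raise ValueError(f"lower ({self.lower}) must be < upper ({self.upper})")
        if self.n_points < 8:
            raise ValueError(f"n_points must be >= 8, got {self.n_points}")

    @property
    def spacing(self) -> float:
        return (self.upper - self.lower) / (self.n_points - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(self.lower, self.upper, self.n_points)

    def __len__(self) -> int:
        return self.n_points


@dataclass
class GridDensity1D:
    """A nonnegative density (per unit of x) sampled on a :class:`Grid1D`.

    The values need not integrate to one at construction; call
    :func:`normalize` (or the :meth:`normalize` method) to rescale.
    """

    grid: Grid1D
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_points,):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.grid.n_points},)"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidDensityError("density values must be finite")
        if np.any(self.values < 0):
            raise InvalidDensityError("density values must be nonnegative")

    @property
    def x(self) -> np.ndarray:
        return self.grid.x

    def integral(self) -> float:
        return float(np.trapezoid(self.values, dx=self.grid.spacing))

    def is_normalized(self, tol: float = NORMALIZATION_TOL) -> bool:
        return abs(self.integral() - 1.0) <= tol

    def normalize(self) -> "GridDensity1D":
        return normalize(self)

    def mean(self) -> float:
        """First moment (assumes normalized values)."""
        return float(np.trapezoid(self.x * self.values, dx=self.grid.spacing))

    def variance(self) -> float:
        m = self.mean()
        return float(
            np.trapezoid((self.x - m) ** 2 * self.values, dx=self.grid.spacing)
        )

    def cdf(self) -> np.ndarray:
        """Cumulative distribution evaluated on the grid nodes."""
        from scipy.integrate import cumulative_trapezoid

        c = cumulative_trapezoid(self.values, dx=self.grid.spacing, initial=0.0)
        return c / c[-1]


@dataclass
class JointTable:
    """A discrete joint distribution over labelled (x, y) states."""

    x_states: list = field(default_factory=list)
    y_states: list = field(default_factory=list)
    probs: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be a 2-D matrix")
        nx, ny = self.probs.shape
        if not self.x_states:
            self.x_states = list(range(nx))
        if not self.y_states:
            self.y_states = list(range(ny))
        if len(self.x_states) != nx or len(self.y_states) != ny:
            raise ValueError("state labels do not match probs shape")
        if np.any(self.probs < 0):
            raise ValueError("joint probabilities must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError(
                f"joint probabilities must sum to 1 within 1e-12, "
                f"got {self.probs.sum()!r}"
            )

    def marginal_x(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    def marginal_y(self) -> np.ndarray:
        return self.probs.sum(axis=0)


def normalize(density: GridDensity1D) -> GridDensity1D:
    """Rescale a density so its trapezoidal integral over the grid is 1.

    Raises :class:`InvalidDensityError` for all-zero or non-finite input.
    """
    total = density.integral()
    if not np.isfinite(total) or total <= 0.0:
        raise InvalidDensityError(
            f"cannot normalize density with integral {total!r}"
        )
    return GridDensity1D(density.grid, density.values / total)


def _safe_log(values: np.ndarray, context: str) -> np.ndarray:
    clipped = np.clip(values, CLIP_FLOOR, None)
    n_clipped = int(np.sum(values < CLIP_FLOOR))
    if n_clipped:
        logger.debug("%s: clipped %d values at %g before log", context, n_clipped, CLIP_FLOOR)
    return np.log(clipped)


def entropy(density: GridDensity1D) -> float:
    """Differential entropy -int p ln p dx in nats, by the trapezoid rule.

    The input must already be normalized (integral 1 within
    ``NORMALIZATION_TOL``); ``0 ln 0`` contributes zero.
    """
    if not density.is_normalized():
        raise InvalidDensityError(
            f"entropy requires a normalized density; integral is "
            f"{density.integral()!r}"
        )
    p = density.values
    integrand = np.where(p > 0, -p * _safe_log(p, "entropy"), 0.0)
    return float(np.trapezoid(integrand, dx=density.grid.spacing))


def kl_divergence(p: GridDensity1D, q: GridDensity1D) -> float:
    """Kullback-Leibler divergence int p ln(p/q) dx in nats.

    Both densities must live on the same grid and be normalized, and q must
    be positive wherever p is (otherwise :class:`SupportError`).
    """
    if p.grid != q.grid:
        raise ValueError("p and q must share a grid")
    for name, d in (("p", p), ("q", q)):
        if not d.is_normalized():
            raise InvalidDensityError(f"{name} is not normalized")
    pv, qv = p.values, q.values
    violation = (pv > 0) & (qv <= 0)
    if np.any(violation):
        raise SupportError(
            f"p > 0 where q = 0 at {int(violation.sum())} grid nodes"
        )
    integrand = np.where(
        pv > 0,
        pv * (_safe_log(pv, "kl:p") - _safe_log(qv, "kl:q")),
        0.0,
    )
    return float(np.trapezoid(integrand, dx=p.grid.spacing))


def mutual_information(joint: JointTable) -> float:
    """Mutual information of a discrete joint table, in nats.

    ``I = sum_{x,y} p(x,y) ln[p(x,y) / (p(x) p(y))]``; zero cells contribute
    zero.  Nonnegative up to rounding; exactly zero for product tables.
    """
    pxy = joint.probs
    px = joint.marginal_x()[:, None]
    py = joint.marginal_y()[None, :]
    mask = pxy > 0
    ratio = np.ones_like(pxy)
    ratio[mask] = pxy[mask] / (px * py + CLIP_FLOOR)[mask]
    return float(np.sum(pxy[mask] * np.log(ratio[mask])))


def fisher_information(density: GridDensity1D, zero_tol: float = 1e-290) -> float:
    """Fisher information of the location family generated by the density.

    Computes ``E_p[-d^2 ln p / dx^2]`` with central second differences on
    ``ln p`` over the interior nodes, averaged under ``p`` by the trapezoid
    rule.  The density must be strictly positive on the evaluation window
    (all interior nodes); a Gaussian of standard deviation sigma yields
    ``1/sigma^2``.
    """
    p = density.values
    if density.grid.n_points < 5:
        raise ValueError("need at least 3 interior points")
    if np.any(p <= zero_tol):
        raise InvalidDensityError(
            "fisher_information requires a strictly positive density on the "
            "evaluation window"
        )
    h = density.grid.spacing
    logp = np.log(p)
    d2 = (logp[2:] - 2.0 * logp[1:-1] + logp[:-2]) / h**2
    integrand = -p[1:-1] * d2
    return float(np.trapezoid(integrand, dx=h))
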