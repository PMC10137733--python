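"""The cell-sensing channel P(Y|X).

A cell senses its microenvironment Y through an (unknown) sensing function F
of its internal state x.  Linearizing F around the mean internal state Xbar
gives the two coarse parameters that matter:

* ``b`` — the sensing bias, ``F(Xbar) - Ybar``;
* ``g`` — the linear response, ``|dF/dx|`` at ``Xbar``.

The conditional law is Gaussian with mean ``F(x)`` and a conditional standard
deviation linear in the internal state, ``sigma_{Y|X}(x) = b + g (x - Xbar)``.
With that law the microenvironmental conditional entropy is the Gaussian
closed form ``S(Y|X=x) = ln sigma_{Y|X}(x) + (1/2) ln(2 pi e)``, and
averaging the conditional variance over ``x ~ N(Xbar, sigma_x^2)`` gives
``<sigma_{Y|X}^2> = b^2 + g^2 sigma_x^2``.

An alternative ``variance_literal`` mode (conditional variance
``b + g (x - Xbar)^2``) is exposed for exploration only; the linear-sd
reading is the one consistent with the entropy and averaged-variance laws
above and is the default everywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Tuple

import numpy as np

__all__ = [
    "SensingModel",
    "linearize_sensing",
    "conditional_sd",
    "conditional_entropy_at",
    "sample_environment",
    "averaged_conditional_variance",
    "HALF_LN_2PIE",
]

logger = logging.getLogger(__name__)

HALF_LN_2PIE = 0.5 * math.log(2.0 * math.pi * math.e)

#: smallest admissible conditional standard deviation
SIGMA_MIN = 1e-6


def linearize_sensing(
    F: Callable[[float], float],
    x_bar: float,
    y_bar: float,
    h: float = 1e-5,
) -> Tuple[float, float]:
    """Linearize a sensing function around the mean internal state.

    Returns ``(b, g)`` with ``b = F(x_bar) - y_bar`` and
    ``g = |dF/dx(x_bar)|`` by a central difference of step ``h``.
    """
    f0 = F(x_bar)
    fp = F(x_bar + h)
    fm = F(x_bar - h)
    if not all(np.isfinite(v) for v in (f0, fp, fm)):
        raise ValueError(f"sensing function non-finite near x_bar={x_bar}")
    b = float(f0 - y_bar)
    g = float(abs((fp - fm) / (2.0 * h)))
    return b, g


@dataclass
class SensingModel:
    """Gaussian conditional law of the environment given the internal state.

    Parameters
    ----------
    F : callable
        Sensing function ``x -> sensed mean``.  Defaults to the identity.
    b, g : float
        Bias and linear response.  If either is None it is filled in by
        linearizing ``F`` at ``x_bar``.  ``b`` must be positive and ``g``
        nonnegative for a valid standard deviation.
    x_bar, y_bar : float
        Mean internal state and mean environment used in the linearization.
    domain : (float, float)
        Requested x-domain.  It is truncated (with a logged warning) to the
        region where the conditional sd stays >= ``sigma_min``.
    variance_mode : {"sd_linear", "variance_literal"}
        ``sd_linear`` (default): sd = b + g (x - x_bar).
        ``variance_literal``: variance = b + g (x - x_bar)^2.
    """

    F: Callable[[float], float] = None  # type: ignore[assignment]
    b: float = None  # type: ignore[assignment]
    g: float = None  # type: ignore[assignment]
    x_bar: float = 0.0
    y_bar: float = 0.0
    domain: Tuple[float, float] = (-10.0, 10.0)
    sigma_min: float = SIGMA_MIN
    variance_mode: str = "sd_linear"
    noise_family: str = field(default="gaussian")

    def __post_init__(self) -> None:
        if self.F is None:
            self.F = lambda x: x
        if self.b is None or self.g is None:
            b, g = linearize_sensing(self.F, self.x_bar, self.y_bar)
            if self.b is None:
                self.b = b
            if self.g is None:
                self.g = g
        self.b = float(self.b)
        self.g = float(self.g)
        if self.b <= 0:
            raise ValueError(
                f"bias b must be > 0 for a valid conditional sd, got {self.b}"
            )
        if self.g < 0:
            raise ValueError(f"linear response g must be >= 0, got {self.g}")
        if self.variance_mode not in ("sd_linear", "variance_literal"):
            raise ValueError(f"unknown variance_mode {self.variance_mode!r}")
        if self.noise_family != "gaussian":
            raise NotImplementedError(
                "only the gaussian noise family is implemented"
            )
        self.domain = self._truncate_domain(tuple(map(float, self.domain)))

    def _truncate_domain(self, dom: Tuple[float, float]) -> Tuple[float, float]:
        lo, hi = dom
        if lo >= hi:
            raise ValueError("domain must satisfy lo < hi")
        if self.variance_mode == "variance_literal" or self.g == 0:
            return (lo, hi)
        # sd = b + g(x - x_bar) >= sigma_min  <=>  x >= x_bar + (sigma_min-b)/g
        x_min = self.x_bar + (self.sigma_min - self.b) / self.g
        if lo < x_min:
            logger.warning(
                "sensing domain truncated from [%g, %g] to [%g, %g] to keep "
                "the conditional sd >= %g",
                lo, hi, x_min, hi, self.sigma_min,
            )
            lo = x_min
        if lo >= hi:
            raise ValueError(
                f"domain entirely below the positivity threshold x >= {x_min}"
            )
        return (lo, hi)

    # ------------------------------------------------------------------
    def admissible_interval(self) -> Tuple[float, float]:
        return self.domain

    def _check_domain(self, x: np.ndarray) -> None:
        lo, hi = self.domain
        xa = np.atleast_1d(x)
        if np.any(xa < lo - 1e-12) or np.any(xa > hi + 1e-12):
            raise ValueError(
                f"x outside the admissible interval [{lo}, {hi}]"
            )

    def conditional_sd(self, x):
        """sigma_{Y|X}(x); strictly positive on the admissible interval."""
        self._check_domain(np.asarray(x, dtype=float))
        xa = np.asarray(x, dtype=float)
        if self.variance_mode == "sd_linear":
            sd = self.b + self.g * (xa - self.x_bar)
        else:
            sd = np.sqrt(self.b + self.g * (xa - self.x_bar) ** 2)
        if np.any(sd < self.sigma_min * (1 - 1e-9)):
            lo, hi = self.domain
            raise ValueError(
                f"conditional sd below sigma_min inside [{lo}, {hi}]"
            )
        return sd if np.ndim(x) else float(sd)

    def conditional_entropy_at(self, x):
        """Gaussian conditional entropy S(Y|X=x) = ln sigma(x) + (1/2)ln(2 pi e)."""
        return np.log(self.conditional_sd(x)) + HALF_LN_2PIE

    def conditional_mean(self, x):
        xa = np.asarray(x, dtype=float)
        out = np.vectorize(self.F, otypes=[float])(xa)
        return out if np.ndim(x) else float(out)

    def sample_environment(self, x: float, n: int, seed: int) -> np.ndarray:
        """Draw ``n`` environment samples Y ~ N(F(x), sigma(x)^2)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        return rng.normal(self.conditional_mean(x), self.conditional_sd(x), size=n)

    def averaged_conditional_variance(self, sigma_x2: float) -> float:
        """E[sigma_{Y|X}^2] under x ~ N(x_bar, sigma_x2): b^2 + g^2 sigma_x2."""
        if sigma_x2 < 0:
            raise ValueError(f"sigma_x2 must be >= 0, got {sigma_x2}")
        return self.b**2 + self.g**2 * sigma_x2


# Thin functional wrappers -------------------------------------------------

def conditional_sd(model: SensingModel, x):
    return model.conditional_sd(x)


def conditional_entropy_at(model: SensingModel, x):
    return model.conditional_entropy_at(x)


def sample_environment(model: SensingModel, x: float, n: int, seed: int) -> np.ndarray:
    return model.sample_environment(x, n, seed)


def averaged_conditional_variance(model: SensingModel, sigma_x2: float) -> float:
    return model.averaged_conditional_variance(sigma_x2)
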