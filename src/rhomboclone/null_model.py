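"""Lognormal null model of clone radii and the boundary-crossing probability L(x).

Under the null hypothesis of no boundary effect, a clone's centre is uniform
on the unit rhombomere [0, 1] and its radius R is lognormal and independent
of position: ln R ~ Normal(mu, sigma).  The probability that a clone centred
at x in (0, 1/2] crosses its nearest boundary is then

    L(x) = P(R > x) = 1 - Phi((ln x - mu) / sigma),

with L(x) = L(1 - x) on [1/2, 1) by symmetry and L(0) = L(1) = 1 (a centre
sitting on the boundary always crosses).  Integrating L over a uniform
position gives the chance-crossing probability; a measurement-error margin
delta splits the non-crossing mass into boundary-respecting (abutting within
delta) and middle clones.

Default parameters mu = -1.34, sigma = 0.64 are the field-standard values
for pooled mouse hindbrain clones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "DEFAULT_MU",
    "DEFAULT_SIGMA",
    "LognormalRadiusModel",
    "CategoryProbabilities",
    "fit_lognormal",
    "crossing_probability",
    "category_probabilities",
    "calibrate_delta",
]

DEFAULT_MU = -1.34
DEFAULT_SIGMA = 0.64

#: absolute tolerance requested from (and enforced on) the quadrature
INTEGRATION_TOL = 1e-6
_QUAD_EPSABS = 1e-9  # we ask for more than we promise


@dataclass(frozen=True)
class CategoryProbabilities:
    """Null-model probabilities of (cross, respect, middle); sum to 1."""

    p_cross: float
    p_respect: float
    p_middle: float

    def __post_init__(self):
        for name in ("p_cross", "p_respect", "p_middle"):
            v = getattr(self, name)
            if not (-1e-9 <= v <= 1.0 + 1e-9):
                raise ValueError(f"{name} must be a probability, got {v}")
        if abs(self.p_cross + self.p_respect + self.p_middle - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1 within 1e-9")

    def as_array(self) -> np.ndarray:
        """Probabilities in canonical (cross, respect, middle) order."""
        return np.array([self.p_cross, self.p_respect, self.p_middle])


@dataclass(frozen=True)
class LognormalRadiusModel:
    """Parameters of the log-radius normal distribution.

    ``mu`` and ``sigma`` are the mean and standard deviation of ln(radius),
    radius measured as a fraction of rhombomere AP length; ``sigma > 0``.
    """

    mu: float = DEFAULT_MU
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self):
        if not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu}")
        if not (self.sigma > 0) or not np.isfinite(self.sigma):
            raise ValueError(f"sigma must be finite and > 0, got {self.sigma}")

    @property
    def radius_distribution(self) -> stats.rv_continuous:
        """The frozen scipy lognormal distribution of R."""
        return stats.lognorm(s=self.sigma, scale=np.exp(self.mu))

    @property
    def mean_radius(self) -> float:
        """Arithmetic mean radius implied by the model, exp(mu + sigma^2/2)."""
        return float(np.exp(self.mu + self.sigma**2 / 2.0))

    # convenience methods mirroring the module-level functions
    def crossing_probability(self, x):
        return crossing_probability(self, x)

    def category_probabilities(self, delta: float) -> CategoryProbabilities:
        return category_probabilities(self, delta)

    def calibrate_delta(self, target_p_respect: float) -> float:
        return calibrate_delta(self, target_p_respect)


def fit_lognormal(radii: Sequence[float]) -> LognormalRadiusModel:
    """Fit the model from observed radii: mu and sigma are the mean and sample
    (n-1 denominator) standard deviation of ln(radius).

    Raises on non-positive radii, fewer than two observations, or a
    degenerate sample (all radii equal, sigma = 0).
    """
    r = np.asarray(radii, dtype=float)
    if r.ndim != 1:
        r = r.ravel()
    if r.size < 2:
        raise ValueError(f"need at least 2 radii to estimate sigma, got {r.size}")
    if not np.all(np.isfinite(r)) or np.any(r <= 0):
        bad = np.flatnonzero(~np.isfinite(r) | (r <= 0))[:5]
        raise ValueError(f"radii must be positive and finite; offending indices {bad.tolist()}")
    logr = np.log(r)
    mu = float(np.mean(logr))
    sigma = float(np.std(logr, ddof=1))
    if sigma == 0.0:
        raise ValueError("degenerate sample: all radii identical, sigma = 0")
    return LognormalRadiusModel(mu=mu, sigma=sigma)


def crossing_probability(model: LognormalRadiusModel, x) -> float | np.ndarray:
    """Evaluate L(x), the null probability that a clone centred at x crosses.

    Vectorized over ``x``; scalar in, scalar out.  Defined on [0, 1]; the
    endpoints return 1 exactly.
    """
    xa = np.asarray(x, dtype=float)
    if np.any((xa < 0.0) | (xa > 1.0)):
        raise ValueError("positions must lie in [0, 1]")
    d = np.minimum(xa, 1.0 - xa)
    # sf of the lognormal at the nearest-boundary distance; sf(0) = 1 handles
    # the endpoint convention automatically
    out = model.radius_distribution.sf(d)
    if np.isscalar(x) or xa.ndim == 0:
        return float(out)
    return out


def category_probabilities(
    model: LognormalRadiusModel, delta: float
) -> CategoryProbabilities:
    """Null probabilities of crossing / respecting / middle at margin ``delta``.

    With F the lognormal CDF of R and d(x) = min(x, 1-x):

        p_cross   = 2 * int_0^1/2 P(R > x) dx
        p_respect = 2 * int_0^1/2 [F(x) - F(max(x - delta, 0))] dx
        p_middle  = 1 - p_cross - p_respect

    Adaptive quadrature, absolute tolerance 1e-6 (enforced; the integrand is
    continuous at 0 by extension since F(0) = 0 and P(R > 0) = 1).
    """
    if not (0.0 <= delta < 0.5):
        raise ValueError(f"delta must lie in [0, 0.5), got {delta}")
    dist = model.radius_distribution

    val_c, err_c = integrate.quad(dist.sf, 0.0, 0.5, epsabs=_QUAD_EPSABS, limit=200)
    p_cross = 2.0 * val_c
    if delta == 0.0:
        p_respect, err_r = 0.0, 0.0
    else:
        # kink at x = delta where max(x - delta, 0) departs from 0
        f = lambda x: dist.cdf(x) - dist.cdf(max(x - delta, 0.0))
        val_r, err_r = integrate.quad(
            f, 0.0, 0.5, epsabs=_QUAD_EPSABS, limit=200, points=[min(delta, 0.5)]
        )
        p_respect = 2.0 * val_r
    if 2.0 * (err_c + err_r) > INTEGRATION_TOL:
        raise RuntimeError(
            f"quadrature did not reach the required absolute tolerance "
            f"{INTEGRATION_TOL:g} (error estimate {2.0 * (err_c + err_r):.2e})"
        )
    p_middle = 1.0 - p_cross - p_respect
    return CategoryProbabilities(
        p_cross=p_cross, p_respect=p_respect, p_middle=max(p_middle, 0.0)
    )


def calibrate_delta(
    model: LognormalRadiusModel, target_p_respect: float, tol: float = 1e-10
) -> float:
    """Find the margin delta at which p_respect equals ``target_p_respect``.

    p_respect is continuous, strictly increasing in delta and 0 at delta = 0,
    so a bracketed root on [0, 0.5) is unique.  Raises with the feasible
    range when the target cannot be reached.
    """
    if target_p_respect == 0.0:
        return 0.0
    delta_max = 0.5 - 1e-9
    p_max = category_probabilities(model, delta_max).p_respect
    if not (0.0 < target_p_respect <= p_max):
        raise ValueError(
            f"target p_respect = {target_p_respect} is outside the feasible "
            f"range (0, {p_max:.6f}] for this model"
        )
    g = lambda d: category_probabilities(model, d).p_respect - target_p_respect
    return float(optimize.brentq(g, 0.0, delta_max, xtol=tol))
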