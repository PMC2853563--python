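"""Tests of observed clone behaviour against the null model.

Covers the trinomial chi-square goodness-of-fit of observed category counts
against the model's (cross, respect, middle) probabilities, Kolmogorov-
Smirnov checks of the model's distributional assumptions, the size-position
independence check, and empirical crossing-probability curves: a binned
(step) estimate and a circular binomial spline smooth of the binary crossing
indicator against clone position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.gam.api import BSplines, CyclicCubicSplines, GLMGam

from .clone_data import CategoryCounts
from .null_model import CategoryProbabilities, LognormalRadiusModel, crossing_probability

__all__ = [
    "GofResult",
    "CrossingCurve",
    "CurveComparison",
    "KsCheck",
    "chisq_gof",
    "ks_uniform_positions",
    "ks_lognormal_radii",
    "size_position_correlation",
    "theoretical_curve",
    "binned_crossing_fraction",
    "smooth_crossing_probability",
    "compare_curves",
]

#: below this, chi-square p-values are reported as a bound in formatted output
P_VALUE_FLOOR = 1e-15

_CATEGORY_ORDER = ("cross", "respect", "middle")


@dataclass(frozen=True)
class GofResult:
    """Chi-square goodness of fit of observed trinomial counts.

    Per-category arrays follow (cross, respect, middle) order.  ``p_value``
    is the exact float; :meth:`p_label` formats it, replacing anything under
    1e-15 by the bound "p < 1e-15".
    """

    chi2: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    discrepancy: np.ndarray
    categories: tuple[str, ...] = _CATEGORY_ORDER

    def p_label(self) -> str:
        if self.p_value < P_VALUE_FLOOR:
            return f"p < {P_VALUE_FLOOR:g}"
        return f"p = {self.p_value:.3g}"

    def reject(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha

    def as_frame(self) -> pd.DataFrame:
        """Table-style layout: one row per category plus a total row."""
        df = pd.DataFrame(
            {
                "category": list(self.categories),
                "observed": self.observed,
                "expected": self.expected,
                "chi2_discrepancy": self.discrepancy,
            }
        )
        total = pd.DataFrame(
            {
                "category": ["total"],
                "observed": [self.observed.sum()],
                "expected": [self.expected.sum()],
                "chi2_discrepancy": [self.chi2],
            }
        )
        return pd.concat([df, total], ignore_index=True)


class KsCheck(NamedTuple):
    """One-sample Kolmogorov-Smirnov result."""

    statistic: float
    p_value: float
    n: int


@dataclass(frozen=True)
class CrossingCurve:
    """P(cross | position) on a grid; ``kind`` is theoretical/binned/smoothed.

    Binned curves put NaN (not zero) at empty bins and carry ``bin_edges``;
    smoothed curves carry the spline basis dimension in ``smoother_df``.
    """

    grid: np.ndarray
    p: np.ndarray
    kind: str
    bin_edges: np.ndarray | None = None
    smoother_df: int | None = None

    def __post_init__(self):
        if self.kind not in ("theoretical", "binned", "smoothed"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        finite = self.p[np.isfinite(self.p)]
        if np.any((finite < -1e-9) | (finite > 1 + 1e-9)):
            raise ValueError("curve probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CurveComparison:
    """Grid-wise divergence between an empirical and a theoretical curve."""

    grid: np.ndarray
    diff: np.ndarray  # empirical - theoretical; NaN where empirical missing
    max_abs: float
    mean_abs: float
    frac_below: float  # fraction of valid grid points with empirical <= theoretical


def chisq_gof(
    observed: CategoryCounts, theoretical: CategoryProbabilities
) -> GofResult:
    """Classical chi-square goodness-of-fit of trinomial counts, df = 2.

    Expected counts are n_total * p (unrounded); the statistic is the sum of
    (obs - exp)^2 / exp and the p-value the chi-square upper tail.
    """
    obs = observed.as_array()
    n = obs.sum()
    if n <= 0:
        raise ValueError("observed counts are empty")
    p = theoretical.as_array()
    expected = n * p
    if np.any(expected == 0):
        zero = [c for c, e in zip(_CATEGORY_ORDER, expected) if e == 0]
        raise ValueError(f"expected count of zero for categories {zero}")
    discrepancy = (obs - expected) ** 2 / expected
    chi2 = float(discrepancy.sum())
    df = len(_CATEGORY_ORDER) - 1
    return GofResult(
        chi2=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        observed=obs,
        expected=expected,
        discrepancy=discrepancy,
    )


def ks_uniform_positions(positions: Sequence[float]) -> KsCheck:
    """KS test of clone-centre positions against Uniform(0, 1).

    Uses scipy's exact small-sample / asymptotic switching.  Requires n >= 5
    and all positions in [0, 1].
    """
    x = np.asarray(positions, dtype=float)
    if x.size < 5:
        raise ValueError(f"need at least 5 positions, got {x.size}")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("positions must lie in [0, 1]")
    res = stats.kstest(x, stats.uniform.cdf)
    return KsCheck(float(res.statistic), float(res.pvalue), x.size)


def ks_lognormal_radii(
    radii: Sequence[float], model: LognormalRadiusModel
) -> KsCheck:
    """KS test of radii against the model's lognormal CDF.

    When (mu, sigma) were estimated from these same radii the nominal
    p-value is approximate (anti-conservative in principle); it is reported
    as-is, matching common practice for this diagnostic.
    """
    r = np.asarray(radii, dtype=float)
    if r.size < 5:
        raise ValueError(f"need at least 5 radii, got {r.size}")
    if np.any(r <= 0):
        raise ValueError("radii must be positive")
    res = stats.kstest(r, model.radius_distribution.cdf)
    return KsCheck(float(res.statistic), float(res.pvalue), r.size)


def size_position_correlation(
    positions: Sequence[float], radii: Sequence[float]
) -> float:
    """Pearson correlation between clone position and radius.

    Near-zero values support the null model's independence assumption."""
    x = np.asarray(positions, dtype=float)
    r = np.asarray(radii, dtype=float)
    if x.size != r.size or x.size < 3:
        raise ValueError("positions and radii must be equal-length, n >= 3")
    return float(stats.pearsonr(x, r).statistic)


def theoretical_curve(
    model: LognormalRadiusModel, grid_size: int = 101
) -> CrossingCurve:
    """L(x) evaluated on an evenly spaced grid over [0, 1]."""
    grid = np.linspace(0.0, 1.0, grid_size)
    return CrossingCurve(grid=grid, p=crossing_probability(model, grid), kind="theoretical")


def binned_crossing_fraction(
    positions: Sequence[float], is_cross: Sequence[bool], bin_width: float = 0.1
) -> CrossingCurve:
    """Step estimate: per-bin fraction of crossing clones among all clones.

    ``bin_width`` must divide the unit interval evenly.  Empty bins yield
    NaN.  The curve's grid holds bin midpoints.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(is_cross, dtype=bool)
    if x.size != y.size:
        raise ValueError("positions and indicators must be equal length")
    n_bins = round(1.0 / bin_width)
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide [0, 1] evenly")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)  # x = 1 joins last bin
    frac = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = idx == b
        if m.any():
            frac[b] = y[m].mean()
    mid = (edges[:-1] + edges[1:]) / 2.0
    return CrossingCurve(grid=mid, p=frac, kind="binned", bin_edges=edges)


def smooth_crossing_probability(
    positions: Sequence[float],
    is_cross: Sequence[bool],
    smoother_df: int = 8,
    circular: bool = True,
    grid_size: int = 101,
) -> CrossingCurve:
    """Binomial spline smooth of the crossing indicator against position.

    Fits a logistic generalized additive model of y (1 = crosses) on a
    spline basis in x.  With ``circular`` (the default) the basis is
    periodic with period 1, identifying the anterior and posterior
    boundaries — all clones live in one idealised rhombomere whose posterior
    boundary is the next rhombomere's anterior one — so the fitted curve
    takes equal values at 0 and 1.  ``smoother_df`` is the spline basis
    dimension (default 8; see the methods note for the bias-variance
    rationale).  Requires at least 20 clones with both outcome classes; with
    a single outcome class a degenerate constant curve is returned with a
    warning, and if the fit itself fails (e.g. complete separation) the
    binned curve is returned with a warning.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(is_cross, dtype=float)
    if x.size != y.size:
        raise ValueError("positions and indicators must be equal length")
    if x.size < 20:
        raise ValueError(f"need at least 20 clones to smooth, got {x.size}")
    grid = np.linspace(0.0, 1.0, grid_size)
    if y.min() == y.max():
        warnings.warn(
            "only one outcome class present; returning a degenerate constant curve"
        )
        return CrossingCurve(
            grid=grid,
            p=np.full(grid_size, float(y[0])),
            kind="smoothed",
            smoother_df=smoother_df,
        )
    try:
        if circular:
            basis = CyclicCubicSplines(x[:, None], df=[smoother_df])
        else:
            basis = BSplines(x[:, None], df=[smoother_df], degree=[3])
        intercept = np.ones((x.size, 1))
        model = GLMGam(
            y, exog=intercept, smoother=basis, family=sm.families.Binomial()
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        # period-1 identification: evaluate x = 1 as x = 0 so the returned
        # curve is exactly periodic
        eval_grid = np.where(circular & (grid == 1.0), 0.0, grid)
        p = np.asarray(
            res.predict(exog=np.ones((grid_size, 1)), exog_smooth=eval_grid[:, None])
        )
        if not np.all(np.isfinite(p)):
            raise RuntimeError("non-finite fitted probabilities")
    except Exception as exc:  # separation or PIRLS failure
        warnings.warn(
            f"spline smoothing failed ({exc}); falling back to the binned curve"
        )
        return binned_crossing_fraction(x, y.astype(bool))
    return CrossingCurve(
        grid=grid,
        p=np.clip(p, 0.0, 1.0),
        kind="smoothed",
        smoother_df=smoother_df,
    )


def compare_curves(
    empirical: CrossingCurve, theoretical: CrossingCurve
) -> CurveComparison:
    """Grid-wise divergence summary of an empirical curve from the theoretical one.

    The theoretical curve is evaluated at the empirical curve's grid points
    by linear interpolation when the grids differ (exactly the same values
    when the empirical grid is a subset).  NaN entries of the empirical
    curve (empty bins) are excluded from the summaries.  ``frac_below`` is
    the fraction of valid grid points at which the empirical curve lies at
    or below the theoretical one — values near 1 indicate the deficit of
    crossing expected under boundary restriction.
    """
    if np.array_equal(empirical.grid, theoretical.grid):
        th = theoretical.p
    else:
        th = np.interp(empirical.grid, theoretical.grid, theoretical.p)
    diff = empirical.p - th
    valid = np.isfinite(diff)
    if not valid.any():
        raise ValueError("empirical curve has no valid grid points")
    return CurveComparison(
        grid=empirical.grid,
        diff=diff,
        max_abs=float(np.max(np.abs(diff[valid]))),
        mean_abs=float(np.mean(np.abs(diff[valid]))),
        frac_below=float(np.mean(diff[valid] <= 1e-12)),
    )
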