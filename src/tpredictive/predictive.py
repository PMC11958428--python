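"""Prior predictive distribution of the t statistic under a design prior.

Before any data exist, the design prior pi_d on the effect size induces a
marginal ("prior predictive") distribution of the future t statistic,

    p(t) = integral T_v(t | m * delta) pi_d(delta) d(delta),

and the probability that t falls in a region R is obtained by integrating
the exact noncentral-t CDF differences over the design prior (a single
1-D quadrature; the inner t-integral is never done numerically).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

from ._nct import nct_cdf
from .bayes_factor import TestLayout, log_marginal_t
from .priors import Prior

__all__ = ["TRegion", "predictive_density", "region_probability"]

_INF = math.inf


@dataclass(frozen=True)
class TRegion:
    """A union of disjoint open intervals on the extended real t axis."""

    intervals: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        prev_hi = -_INF
        first = True
        for lo, hi in self.intervals:
            if not lo < hi:
                raise ValueError(f"degenerate interval ({lo}, {hi})")
            if not first and lo < prev_hi:
                raise ValueError("intervals must be disjoint and ordered")
            prev_hi = hi
            first = False

    @classmethod
    def empty(cls) -> "TRegion":
        return cls(())

    @classmethod
    def whole_line(cls) -> "TRegion":
        return cls(((-_INF, _INF),))

    @classmethod
    def central(cls, c: float) -> "TRegion":
        """|t| < c."""
        return cls(((-c, c),))

    @classmethod
    def two_tailed(cls, c: float) -> "TRegion":
        """|t| > c."""
        return cls(((-_INF, -c), (c, _INF)))

    @property
    def is_empty(self) -> bool:
        return len(self.intervals) == 0

    def contains(self, t) -> np.ndarray:
        """Elementwise membership indicator."""
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape, dtype=bool)
        for lo, hi in self.intervals:
            out |= (t > lo) & (t < hi)
        return out

    def complement(self) -> "TRegion":
        """Closure-complement as a TRegion (boundary points carry no mass)."""
        pieces = []
        cursor = -_INF
        for lo, hi in self.intervals:
            if lo > cursor:
                pieces.append((cursor, lo))
            cursor = hi
        if cursor < _INF:
            pieces.append((cursor, _INF))
        return TRegion(tuple(pieces))

    @property
    def boundaries(self) -> Tuple[float, ...]:
        """Finite interval endpoints, in increasing order."""
        pts = [x for iv in self.intervals for x in iv if np.isfinite(x)]
        return tuple(sorted(pts))


def predictive_density(t: float, layout: TestLayout, design_prior: Prior) -> float:
    """Prior predictive density p(t) of the t statistic under the design prior.

    A point design prior at delta0 gives the noncentral-t density with
    ncp = m * delta0; the point prior at 0 is the null predictive (central t).
    """
    return math.exp(log_marginal_t(t, layout, design_prior))


def _region_mass_given_delta(region: TRegion, layout: TestLayout, delta) -> np.ndarray:
    v = layout.degrees_of_freedom
    m = layout.ncp_multiplier
    delta = np.asarray(delta, dtype=float)
    total = np.zeros(delta.shape, dtype=float)
    for lo, hi in region.intervals:
        upper = nct_cdf(hi, v, m * delta) if np.isfinite(hi) else 1.0
        lower = nct_cdf(lo, v, m * delta) if np.isfinite(lo) else 0.0
        total = total + (upper - lower)
    return np.clip(total, 0.0, 1.0)


def region_probability(region: TRegion, layout: TestLayout, design_prior: Prior) -> float:
    """Predictive probability that the t statistic falls in ``region``.

    Computed as an outer quadrature over the design prior of exact inner
    noncentral-t CDF differences.
    """
    if region.is_empty:
        return 0.0
    if design_prior.family == "point":
        return float(_region_mass_given_delta(region, layout, design_prior.location))
    val = design_prior.expect(lambda d: _region_mass_given_delta(region, layout, d),
                              epsabs=1e-11, epsrel=1e-9)
    return float(min(max(val, 0.0), 1.0))
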