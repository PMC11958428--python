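"""Proper prior distributions on the standardized effect size delta.

Four families are supported, each usable as an analysis prior (inside the
Bayes factor) or as a design prior (generating the prior predictive
distribution of the t statistic):

``point``
    a degenerate prior placing all mass on one effect size;
``scaled_t``
    location-scale Student t with df ``k`` (df = 1 gives the Cauchy prior of
    the default Bayesian t test);
``normal``
    mean ``location``, standard deviation ``scale``;
``normal_moment``
    the non-local normal-moment prior with density
    ``(d - mu)^2 / (sqrt(2 pi) tau^3) * exp(-(d - mu)^2 / (2 tau^2))``,
    which vanishes at its location and has modes at ``mu +/- sqrt(2) tau``.

Directional (one-sided) hypotheses are expressed by hard truncation of the
prior at delta = 0 with renormalization: ``side="positive"`` keeps delta > 0,
``side="negative"`` keeps delta < 0.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import integrate, special, stats

__all__ = ["Prior", "parse_prior", "PriorError"]

_FAMILIES = ("point", "scaled_t", "normal", "normal_moment")
_SIDES = ("two_sided", "positive", "negative")

# half-width of the quadrature window, in prior scale units, for the
# light-tailed families; the omitted mass is below exp(-800)
_CLIP_SIGMAS = 40.0


class PriorError(ValueError):
    """Invalid prior specification."""


def _nm_base_logpdf(z: np.ndarray) -> np.ndarray:
    # standardized normal-moment density (location 0, scale 1)
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore"):
        out = 2.0 * np.log(np.abs(z)) - 0.5 * z * z - 0.5 * math.log(2.0 * math.pi)
    return out


def _nm_base_cdf(z: np.ndarray) -> np.ndarray:
    # CDF of the symmetric normal-moment law: |Z| follows a Maxwell
    # (chi with 3 df) distribution, whose CDF is
    # erf(z/sqrt(2)) - sqrt(2/pi) z exp(-z^2/2)
    z = np.asarray(z, dtype=float)
    a = np.abs(z)
    maxwell = special.erf(a / math.sqrt(2.0)) - math.sqrt(2.0 / math.pi) * a * np.exp(-0.5 * a * a)
    return 0.5 + 0.5 * np.sign(z) * maxwell


@dataclass(frozen=True)
class Prior:
    """A proper prior on the standardized effect size delta.

    Parameters
    ----------
    family : {"point", "scaled_t", "normal", "normal_moment"}
    location : float
        Centre of the family (the fixed effect size for ``point``).
    scale : float, optional
        lambda for ``scaled_t``, sigma_delta for ``normal``, tau for
        ``normal_moment``; must be positive and absent for ``point``.
    df : float, optional
        Degrees of freedom ``k``; required (and positive) for ``scaled_t``.
    side : {"two_sided", "positive", "negative"}
        Directional truncation at delta = 0; ignored for ``point``.
    """

    family: str
    location: float
    scale: Optional[float] = None
    df: Optional[float] = None
    side: str = "two_sided"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise PriorError(f"unknown prior family {self.family!r}")
        if self.side not in _SIDES:
            raise PriorError(f"unknown side {self.side!r}")
        if not np.isfinite(self.location):
            raise PriorError("prior location must be finite")
        if self.family == "point":
            if self.scale is not None or self.df is not None:
                raise PriorError("point prior takes no scale or df")
        else:
            if self.scale is None or not np.isfinite(self.scale) or self.scale <= 0:
                raise PriorError("prior scale must be a positive real")
            if self.family == "scaled_t":
                if self.df is None or not np.isfinite(self.df) or self.df <= 0:
                    raise PriorError("scaled_t prior requires positive df")
            elif self.df is not None:
                raise PriorError(f"{self.family} prior takes no df")
        if self.family != "point" and self.side != "two_sided":
            if self._retained_mass() <= 1e-12:
                raise PriorError("truncated prior retains essentially no mass")

    # ------------------------------------------------------------------
    # untruncated building blocks
    # ------------------------------------------------------------------
    def _base_logpdf(self, delta: np.ndarray) -> np.ndarray:
        d = np.asarray(delta, dtype=float)
        if self.family == "scaled_t":
            return stats.t.logpdf(d, self.df, loc=self.location, scale=self.scale)
        if self.family == "normal":
            return stats.norm.logpdf(d, loc=self.location, scale=self.scale)
        if self.family == "normal_moment":
            z = (d - self.location) / self.scale
            return _nm_base_logpdf(z) - math.log(self.scale)
        raise PriorError("point prior has no density")

    def _base_cdf(self, delta: np.ndarray) -> np.ndarray:
        d = np.asarray(delta, dtype=float)
        if self.family == "point":
            return np.where(d >= self.location, 1.0, 0.0)
        if self.family == "scaled_t":
            return stats.t.cdf(d, self.df, loc=self.location, scale=self.scale)
        if self.family == "normal":
            return stats.norm.cdf(d, loc=self.location, scale=self.scale)
        return _nm_base_cdf((d - self.location) / self.scale)

    def _base_ppf(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if self.family == "scaled_t":
            return stats.t.ppf(q, self.df, loc=self.location, scale=self.scale)
        if self.family == "normal":
            return stats.norm.ppf(q, loc=self.location, scale=self.scale)
        # normal-moment: |Z| is Maxwell (chi with 3 df), so invert through
        # the Maxwell quantile function with a random sign
        upper = q >= 0.5
        z = np.where(upper, stats.maxwell.ppf(np.where(upper, 2.0 * q - 1.0, 0.5)),
                     -stats.maxwell.ppf(np.where(upper, 0.5, 1.0 - 2.0 * q)))
        return self.location + self.scale * z

    def _retained_mass(self) -> float:
        if self.side == "positive":
            return float(1.0 - self._base_cdf(0.0))
        if self.side == "negative":
            return float(self._base_cdf(0.0))
        return 1.0

    # ------------------------------------------------------------------
    # truncated prior
    # ------------------------------------------------------------------
    @property
    def support(self) -> Tuple[float, float]:
        """Support interval of the (possibly truncated) prior."""
        if self.family == "point":
            return (self.location, self.location)
        if self.side == "positive":
            return (0.0, math.inf)
        if self.side == "negative":
            return (-math.inf, 0.0)
        return (-math.inf, math.inf)

    def logpdf(self, delta) -> np.ndarray:
        """Log density of the truncated prior; -inf outside the support."""
        if self.family == "point":
            raise PriorError("point prior is a point mass; it has no density")
        d = np.asarray(delta, dtype=float)
        out = self._base_logpdf(d) - math.log(self._retained_mass())
        lo, hi = self.support
        out = np.where((d < lo) | (d > hi), -math.inf, out)
        if out.ndim == 0:
            return float(out)
        return out

    def pdf(self, delta) -> np.ndarray:
        """Density of the truncated prior (zero outside the support)."""
        out = np.exp(self.logpdf(delta))
        return out

    def cdf(self, delta) -> np.ndarray:
        """CDF of the truncated prior."""
        d = np.asarray(delta, dtype=float)
        if self.family == "point":
            out = np.where(d >= self.location, 1.0, 0.0)
        else:
            mass = self._retained_mass()
            base = self._base_cdf(d)
            if self.side == "positive":
                out = np.clip((base - self._base_cdf(0.0)) / mass, 0.0, 1.0)
            elif self.side == "negative":
                out = np.clip(base / mass, 0.0, 1.0)
            else:
                out = base
        if out.ndim == 0:
            return float(out)
        return out

    def sample(self, count: int, seed=None) -> np.ndarray:
        """Draw ``count`` i.i.d. effect sizes by inverse-CDF sampling."""
        if count < 1:
            raise PriorError("count must be >= 1")
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        if self.family == "point":
            return np.full(count, self.location, dtype=float)
        u = rng.uniform(size=count)
        mass = self._retained_mass()
        if self.side == "positive":
            q = self._base_cdf(0.0) + u * mass
        elif self.side == "negative":
            q = u * mass
        else:
            q = u
        return self._base_ppf(q)

    # ------------------------------------------------------------------
    # quadrature against the prior
    # ------------------------------------------------------------------
    def _window(self) -> Tuple[float, float]:
        """Finite integration window containing all non-negligible mass
        (light-tailed families only)."""
        lo, hi = self.support
        a = max(lo, self.location - _CLIP_SIGMAS * self.scale)
        b = min(hi, self.location + _CLIP_SIGMAS * self.scale)
        return (a, b)

    def expect(self, func: Callable[[np.ndarray], np.ndarray], *, epsabs: float = 1e-11,
               epsrel: float = 1e-9) -> float:
        """Integrate ``func(delta) * pdf(delta)`` over the prior support.

        Scaled-t priors are mapped through delta = loc + scale*tan(u) so the
        heavy Cauchy-like tails are integrated exactly over a finite
        u-interval; the light-tailed families use a clipped window.
        """
        if self.family == "point":
            return float(func(np.asarray(self.location)))
        if self.family == "scaled_t":
            lo, hi = self.support
            u_lo = math.atan((lo - self.location) / self.scale) if np.isfinite(lo) else -math.pi / 2
            u_hi = math.atan((hi - self.location) / self.scale) if np.isfinite(hi) else math.pi / 2

            def g(u: float) -> float:
                d = self.location + self.scale * math.tan(u)
                jac = self.scale / math.cos(u) ** 2
                return float(func(np.asarray(d))) * float(self.pdf(d)) * jac

            val, _ = integrate.quad(g, u_lo, u_hi, limit=300, epsabs=epsabs, epsrel=epsrel)
            return val
        a, b = self._window()
        pts = [p for p in (self.location,) if a < p < b]
        if self.family == "normal_moment":
            for p in (self.location - math.sqrt(2) * self.scale,
                      self.location + math.sqrt(2) * self.scale):
                if a < p < b:
                    pts.append(p)

        def g2(d: float) -> float:
            return float(func(np.asarray(d))) * float(self.pdf(d))

        val, _ = integrate.quad(g2, a, b, points=sorted(pts) or None, limit=300,
                                epsabs=epsabs, epsrel=epsrel)
        return val

    @property
    def is_symmetric_about_zero(self) -> bool:
        """True when the prior density is an even function of delta."""
        return self.family != "point" and self.side == "two_sided" and self.location == 0.0

    def __str__(self) -> str:
        if self.family == "point":
            body = f"point({self.location:g})"
        elif self.family == "scaled_t":
            body = f"t({self.location:g},{self.scale:g},{self.df:g})"
        elif self.family == "normal":
            body = f"normal({self.location:g},{self.scale:g})"
        else:
            body = f"nlp({self.location:g},{self.scale:g})"
        if self.side != "two_sided":
            body += f"[{self.side}]"
        return body


_PRIOR_RE = re.compile(r"^\s*([a-zA-Z_]+)\s*\(\s*([^)]*)\s*\)\s*$")

_FAMILY_ALIASES = {
    "point": "point",
    "cauchy": "scaled_t",
    "t": "scaled_t",
    "scaled_t": "scaled_t",
    "normal": "normal",
    "n": "normal",
    "nlp": "normal_moment",
    "normal_moment": "normal_moment",
    "moment": "normal_moment",
}


def parse_prior(text: str, side: str = "two_sided") -> Prior:
    """Parse a prior specification string.

    Grammar: ``family(arg1, arg2, ...)`` with positional arguments

    - ``point(delta)``
    - ``cauchy(loc, scale)``  (scaled t with df = 1)
    - ``t(loc, scale, df)``
    - ``normal(loc, scale)``
    - ``nlp(loc, scale)``  (normal-moment, non-local)

    The ``side`` flag applies the directional truncation at delta = 0.
    """
    m = _PRIOR_RE.match(text)
    if not m:
        raise PriorError(f"cannot parse prior specification {text!r}")
    name = m.group(1).lower()
    if name not in _FAMILY_ALIASES:
        raise PriorError(f"unknown prior family {name!r}")
    family = _FAMILY_ALIASES[name]
    try:
        args = [float(x) for x in m.group(2).split(",") if x.strip() != ""]
    except ValueError as exc:
        raise PriorError(f"non-numeric prior arguments in {text!r}") from exc

    if family == "point":
        if len(args) != 1:
            raise PriorError("point prior takes exactly one argument")
        return Prior("point", args[0], side=side)
    if name == "cauchy":
        if len(args) != 2:
            raise PriorError("cauchy prior takes (loc, scale)")
        return Prior("scaled_t", args[0], args[1], 1.0, side=side)
    if family == "scaled_t":
        if len(args) != 3:
            raise PriorError("t prior takes (loc, scale, df)")
        return Prior("scaled_t", args[0], args[1], args[2], side=side)
    if len(args) != 2:
        raise PriorError(f"{name} prior takes (loc, scale)")
    return Prior(family, args[0], args[1], side=side)
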