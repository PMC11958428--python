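"""Numerically safe noncentral-t density and CDF evaluations.

scipy (via Boost) covers the bulk of the parameter space, but its log-pdf
returns -inf in far tails and for large noncentrality parameters where the
true log-density is still representable in double precision.  Those regimes
matter here: heavy-tailed design priors routinely push the noncentrality
parameter ncp = m*delta past 100, and critical-region scans evaluate the
density at |t| of a few hundred.  The fallback integrates the defining
normal/chi mixture in log space:

    T = (Z + ncp) / sqrt(W / v),  Z ~ N(0,1),  W ~ chi^2_v

    f(t) = E_S[ S * phi(t*S - ncp) ],  S = sqrt(W / v)

with a peak-centred quadrature in x = log(s).
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = ["nct_logpdf", "nct_cdf"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _log_chi_scaled_pdf(s: np.ndarray, v: float) -> np.ndarray:
    # density of S = sqrt(W/v), W ~ chi^2_v
    half_v = 0.5 * v
    return (
        np.log(2.0)
        + half_v * np.log(half_v)
        - special.gammaln(half_v)
        + (v - 1.0) * np.log(s)
        - half_v * s * s
    )


def _logpdf_mixture_scalar(t: float, v: float, nc: float) -> float:
    """log f(t; v, nc) via log-space quadrature over the chi mixing variable."""

    def log_integrand(x):
        x = np.asarray(x, dtype=float)
        s = np.exp(x)
        z = t * s - nc
        # + x: Jacobian of s = e^x
        return _log_chi_scaled_pdf(s, v) + np.log(s) - 0.5 * z * z - _LOG_SQRT_2PI + x

    def neg_log_integrand(x: float) -> float:
        return -float(log_integrand(x))

    # bracket the peak on a grid first: the integrand can be extremely
    # narrow, and a bare bounded search may land on a flat underflowed part
    xs = np.linspace(-60.0, 6.0, 1321)
    with np.errstate(all="ignore"):
        vals = log_integrand(xs)
    if not np.any(np.isfinite(vals)):
        return -np.inf
    i = int(np.nanargmax(np.where(np.isfinite(vals), vals, -np.inf)))
    res = optimize.minimize_scalar(neg_log_integrand,
                                   bounds=(xs[max(i - 1, 0)], xs[min(i + 1, xs.size - 1)]),
                                   method="bounded", options={"xatol": 1e-10})
    x_hat = float(res.x)
    log_c = -float(res.fun)
    if not np.isfinite(log_c):
        x_hat, log_c = float(xs[i]), float(vals[i])

    def integrand(x: float) -> float:
        val = -neg_log_integrand(x) - log_c
        return np.exp(min(val, 700.0)) if val > -745.0 else 0.0

    lo, hi = x_hat - 50.0, x_hat + 50.0
    total, _ = integrate.quad(integrand, lo, hi, points=[x_hat], limit=200,
                              epsabs=1e-14, epsrel=1e-10)
    if total <= 0.0:
        return -np.inf
    return log_c + np.log(total)


def nct_logpdf(t, v, nc):
    """Log density of the noncentral t distribution, elementwise.

    Falls back to the normal/chi mixture integral wherever scipy yields a
    non-finite value for finite arguments.
    """
    t = np.asarray(t, dtype=float)
    nc = np.asarray(nc, dtype=float)
    try:
        with np.errstate(all="ignore"):
            out = np.asarray(stats.nct.logpdf(t, v, nc), dtype=float)
    except (OverflowError, RuntimeError):
        # Boost raises (rather than returns nan) for some extreme
        # argument combinations; retry elementwise
        t_b, nc_b = np.broadcast_arrays(t, nc)
        out = np.full(t_b.shape, -np.inf, dtype=float)
        flat_o = out.reshape(-1)
        for i, (ti, nci) in enumerate(zip(t_b.reshape(-1), nc_b.reshape(-1))):
            try:
                with np.errstate(all="ignore"):
                    flat_o[i] = stats.nct.logpdf(ti, v, nci)
            except (OverflowError, RuntimeError):
                flat_o[i] = -np.inf
    out = np.asarray(out, dtype=float)
    bad = ~np.isfinite(out)
    if np.any(bad):
        t_b, nc_b = np.broadcast_arrays(t, nc)
        flat = out.reshape(-1)
        idx = np.flatnonzero(bad.reshape(-1))
        tb = t_b.reshape(-1)
        ncb = nc_b.reshape(-1)
        for i in idx:
            ti, nci = float(tb[i]), float(ncb[i])
            if abs(nci) > 1e6 or abs(ti) > 1e7:
                # true log density is far below any relevant magnitude
                flat[i] = -np.inf
            else:
                flat[i] = _logpdf_mixture_scalar(ti, float(v), nci)
        out = flat.reshape(out.shape)
    if out.ndim == 0:
        return float(out)
    return out


def nct_cdf(t, v, nc):
    """CDF of the noncentral t distribution, elementwise.

    scipy/Boost returns hard 0/1 (rather than NaN) for extreme noncentrality;
    NaNs that do appear are replaced by the saddlepoint-free normal
    approximation F(t) ~ Phi((t(1 - 1/(4v)) - nc) / sqrt(1 + t^2/(2v))),
    adequate because they only arise when the true value is within rounding
    of 0 or 1.
    """
    t = np.asarray(t, dtype=float)
    nc = np.asarray(nc, dtype=float)
    with np.errstate(all="ignore"):
        out = stats.nct.cdf(t, v, nc)
    out = np.asarray(out, dtype=float)
    bad = ~np.isfinite(out)
    if np.any(bad):
        t_b, nc_b = np.broadcast_arrays(t, nc)
        approx = stats.norm.cdf(
            (t_b * (1.0 - 1.0 / (4.0 * v)) - nc_b) / np.sqrt(1.0 + t_b * t_b / (2.0 * v))
        )
        out = np.where(bad, approx, out)
    out = np.clip(out, 0.0, 1.0)
    if out.ndim == 0:
        return float(out)
    return out
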