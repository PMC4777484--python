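"""Numerical evaluation of the one-parameter Mittag-Leffler function.

E_eta(z) = sum_n z^n / Gamma(eta*n + 1) is the relaxation kernel of the
linear fractional gate equation; this artifact only needs it on the
negative real axis (0 < eta <= 1, z <= 0), where it is completely monotone
with 0 < E_eta(z) <= 1.

Strategy (per evaluation point, vectorized over z):

1. eta = 1: E_1(z) = e^z exactly.
2. Power series with compensated summation.  The series is accepted only if
   its estimated cancellation error (largest summand times unit roundoff,
   scaled by the term count) is below ``rtol`` relative to the sum; for
   moderately large |z| the alternating terms grow to ~exp(|z|^(1/eta))
   before decaying and double precision cannot deliver 10 digits.
3. Asymptotic expansion E_eta(z) ~ -sum_{n>=1} z^(-n)/Gamma(1 - eta*n) with
   optimal truncation (stop at the smallest term, which also bounds the
   error).
4. Points where neither double-precision route reaches ``rtol`` (moderate
   |z| with eta near 1) are evaluated with an arbitrary-precision series
   (mpmath), behind a per-eta Chebyshev interpolant so that dense time
   grids do not pay the mpmath cost per point.

The default ``rtol`` = 1e-11 exceeds the 10-significant-digit target on
z in [-50, 0].
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln, rgamma

from .errors import ConfigError, InputError, NumericError

_RTOL = 1e-11
_SERIES_NMAX = 6000
_ASYM_NMAX = 400

#: per-eta cache of Chebyshev interpolants for the hard middle region
_CHEB_CACHE: dict = {}


def _check_eta(eta: float) -> float:
    eta = float(eta)
    if not (0.0 < eta <= 1.0):
        raise ConfigError(f"fractional order eta must lie in (0, 1], got {eta}")
    return eta


def mittag_leffler(eta: float, z, rtol: float = _RTOL):
    """Evaluate E_eta(z) for real z <= 0 (any z when eta = 1).

    Parameters
    ----------
    eta : float in (0, 1]
    z : float or array_like, real, <= 0 for eta < 1
    rtol : float
        Target relative accuracy; a :class:`NumericError` is raised if it
        cannot be certified.

    Returns
    -------
    float or ndarray matching the shape of ``z``.
    """
    eta = _check_eta(eta)
    z_arr = np.asarray(z, dtype=float)
    scalar = z_arr.ndim == 0
    z_flat = np.atleast_1d(z_arr).ravel()
    if not np.all(np.isfinite(z_flat)):
        raise InputError("z must be finite")
    if eta == 1.0:
        out = np.exp(z_flat)
        return float(out[0]) if scalar else out.reshape(z_arr.shape)
    if np.any(z_flat > 0):
        raise InputError("only z <= 0 is supported for eta < 1")

    out = np.empty_like(z_flat)
    done = np.zeros(z_flat.shape, dtype=bool)

    zero = z_flat == 0.0
    out[zero] = 1.0
    done |= zero

    if not done.all():
        idx = ~done
        val, ok = _series(eta, z_flat[idx], rtol)
        out[idx] = val
        done[idx] = ok
    if not done.all():
        idx = ~done
        val, ok = _asymptotic(eta, z_flat[idx], rtol)
        out[idx] = np.where(ok, val, out[idx])
        done[idx] |= ok
    if not done.all():
        idx = ~done
        out[idx] = _gap_eval(eta, z_flat[idx], rtol)

    return float(out[0]) if scalar else out.reshape(z_arr.shape)


# ---------------------------------------------------------------------------
# double-precision routes
# ---------------------------------------------------------------------------

def _series(eta, z, rtol):
    """Taylor series with Kahan summation and a cancellation-error estimate."""
    ln_az = np.log(np.abs(z))
    s = np.ones_like(z)
    comp = np.zeros_like(z)
    max_term = np.ones_like(z)
    prev_mag = np.ones_like(z)
    n_terms = np.ones_like(z)
    # ln(max summand) ~ |z|^(1/eta); beyond ~37 the cancellation estimate
    # can never satisfy any sensible rtol, so skip those points outright
    with np.errstate(over="ignore"):
        ln_max = np.exp(np.clip(ln_az / eta, None, 10.0))
    feasible = ln_max < 37.0
    active = feasible.copy()
    if not active.any():
        return s, np.zeros(z.shape, dtype=bool)
    for n in range(1, _SERIES_NMAX + 1):
        if not active.any():
            break
        ia = np.flatnonzero(active)
        mag = np.exp(n * ln_az[ia] - gammaln(eta * n + 1.0))
        term = mag if n % 2 == 0 else -mag
        # Kahan step
        y = term - comp[ia]
        t = s[ia] + y
        comp[ia] = (t - s[ia]) - y
        s[ia] = t
        np.maximum.at(max_term, ia, mag)
        n_terms[ia] = n
        conv = (mag < 1e-17 * np.maximum(np.abs(s[ia]), 1e-300)) & \
               (mag <= prev_mag[ia])
        prev_mag[ia] = mag
        active[ia[conv | ~np.isfinite(mag)]] = False
    # cancellation estimate: unit roundoff per term, plus the error the
    # double rounding of eta*n injects through Gamma(eta*n + 1) (relative
    # ~ u * eta*n * psi(eta*n), largest at the peak summand where
    # eta*n ~ ln(max term))
    lm = np.log(np.maximum(max_term, 1.0))
    err = max_term * 1.1e-16 * (np.sqrt(n_terms) + lm * np.log(lm + 2.0))
    ok = feasible & (err <= rtol * np.abs(s)) & np.isfinite(s) & (s > 0)
    return s, ok


def _asymptotic(eta, z, rtol):
    """Algebraic tail expansion with optimal truncation."""
    inv = 1.0 / z
    s = np.zeros_like(z)
    best = np.full_like(z, np.inf)   # smallest term magnitude seen
    active = np.ones(z.shape, dtype=bool)
    power = np.ones_like(z)
    for n in range(1, _ASYM_NMAX + 1):
        if not active.any():
            break
        power = power * inv
        term = -power * rgamma(1.0 - eta * n)
        mag = np.abs(term)
        grow = (mag > best) & (mag > 0)
        take = active & ~grow
        s[take] += term[take]
        newbest = take & (mag < best) & (mag > 0)
        best[newbest] = mag[newbest]
        active &= ~grow
        # Gamma-pole terms are exactly zero and carry no information;
        # only a genuinely small nonzero term ends the summation
        tiny = (mag > 0) & (mag < 1e-18 * np.maximum(np.abs(s), 1e-300))
        active &= ~tiny
    ok = (best <= rtol * np.abs(s)) & np.isfinite(s) & (s > 0)
    return s, ok


# ---------------------------------------------------------------------------
# arbitrary-precision fallback
# ---------------------------------------------------------------------------

def _ml_mpmath(eta, z, dps_pad=25):
    """Scalar E_eta(z), z <= 0, by high-precision series.  Exact but slow."""
    from mpmath import mp, mpf

    az = abs(z)
    if az == 0.0:
        return 1.0
    # largest summand ~ exp(|z|^(1/eta)); add decimal digits to absorb it
    y = min(az ** (1.0 / eta), 800.0)
    dps = dps_pad + int(y / math.log(10.0)) + 5
    n_star = int(y / eta) + 10
    with mp.workdps(dps):
        zz = mpf(z)
        ee = mpf(eta)   # exact binary value; eta*n must not round in double
        s = mpf(1)
        n = 1
        eps = mpf(10) ** (-(dps - 5))
        while True:
            term = zz ** n / mp.gamma(ee * n + 1)
            s += term
            if abs(term) < eps * max(abs(s), mpf("1e-300")) and n > n_star:
                break
            n += 1
            if n > 100 * n_star + 10000:
                raise NumericError(
                    f"mpmath Mittag-Leffler series did not converge for "
                    f"eta={eta}, z={z}")
        return float(s)


def _gap_interval(eta):
    """Conservative z-interval containing every double-precision gap point."""
    lo = -(42.0 ** eta) - 1.0
    hi = -0.125
    return lo, hi


def _gap_eval(eta, z, rtol):
    """Evaluate gap points via a cached Chebyshev fit of the mpmath series."""
    lo, hi = _gap_interval(eta)
    inside = (z >= lo) & (z <= hi)
    out = np.empty_like(z)
    if inside.any():
        cheb = _get_cheb(eta, lo, hi, rtol)
        out[inside] = cheb(z[inside])
    if (~inside).any():
        out[~inside] = [_ml_mpmath(eta, float(zz)) for zz in z[~inside]]
    return out


def _get_cheb(eta, lo, hi, rtol):
    """Chebyshev interpolant of log E_eta on [lo, hi].

    Fitting the logarithm makes the interpolation error uniformly
    *relative* in E (which spans orders of magnitude over the interval),
    so double-precision coefficients suffice for 10-digit accuracy.
    """
    key = (round(eta, 12), round(lo, 9), round(hi, 9))
    if key in _CHEB_CACHE:
        return _CHEB_CACHE[key]
    from numpy.polynomial import chebyshev as C

    def logf(x):
        return np.array([math.log(_ml_mpmath(eta, float(v)))
                         for v in np.atleast_1d(x)])

    deg = 64
    while True:
        nodes = np.cos(np.pi * (np.arange(deg + 1) + 0.5) / (deg + 1))
        xs = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
        ys = logf(xs)
        coef = np.polynomial.chebyshev.chebfit(
            2.0 * (xs - lo) / (hi - lo) - 1.0, ys, deg)
        cpoly = C.Chebyshev(coef, domain=[lo, hi])
        # verify |Delta log E| (= relative error of E) at midpoints
        mids = 0.5 * (xs[:-1] + xs[1:])
        mids = mids[:: max(len(mids) // 9, 1)]
        check = np.abs(cpoly(mids) - logf(mids))
        if np.max(check) < 0.5 * rtol:
            break
        deg *= 2
        if deg > 1024:
            raise NumericError(
                f"Chebyshev fallback for E_eta failed to reach rtol={rtol} "
                f"on [{lo}, {hi}] at eta={eta}")

    def poly(x, _c=cpoly):
        return np.exp(_c(x))

    _CHEB_CACHE[key] = poly
    return poly
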