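"""Numba-compiled integration loops.

The hybrid scheme is O(N^2) in the number of steps (the L1 memory sum is a
full-history correlation), so the inner loops live here as scalar njit code.
The L1 weights depend only on the lag j = N - k:

    w = (N-k)^(1-eta) - (N-1-k)^(1-eta) = j^(1-eta) - (j-1)^(1-eta) =: b_j

which lets every step reuse one precomputed table ``b`` indexed by lag.

Sign/state conventions match :mod:`frachh.hh_core`: currents contribute to
C dV/dt with I_Na = gNa m^3 h (E_Na - V).
"""

import math

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DIVERGED = 1
STATUS_NONFINITE = 2
STATUS_EARLY_STOP = 3


@njit(cache=True, fastmath=True)
def _exp(x):
    # exponent clamp: keeps blown-up states finite-ish so divergence is
    # reported by the integrator checks instead of a range error mid-step
    if x > 700.0:
        x = 700.0
    return math.exp(x)


@njit(cache=True, fastmath=True)
def _rates(V, V0):
    u = V - V0
    s = 1.0 - 0.1 * u
    if abs(s) < 1e-8:
        an = 0.1 * (1.0 - 0.5 * s)
    else:
        an = 0.1 * s / (_exp(s) - 1.0)
    bn = 0.125 * _exp(-u / 80.0)
    s = 2.5 - 0.1 * u
    if abs(s) < 1e-8:
        am = 1.0 - 0.5 * s
    else:
        am = s / (_exp(s) - 1.0)
    bm = 4.0 * _exp(-u / 18.0)
    ah = 0.07 * _exp(-u / 20.0)
    bh = 1.0 / (1.0 + _exp(3.0 - 0.1 * u))
    return an, bn, am, bm, ah, bh


@njit(cache=True, fastmath=True)
def _deriv(V, n, m, h, I, C, gNa, gK, gm, ENa, EK, EL, V0, frozen):
    """Time derivatives of (V, n, m, h); gate ``frozen`` (0..2) held, -1 none."""
    INa = gNa * m * m * m * h * (ENa - V)
    IK = gK * n * n * n * n * (EK - V)
    IL = gm * (EL - V)
    dV = (INa + IK + IL + I) / C
    an, bn, am, bm, ah, bh = _rates(V, V0)
    dn = an * (1.0 - n) - bn * n
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    if frozen == 0:
        dn = 0.0
    elif frozen == 1:
        dm = 0.0
    elif frozen == 2:
        dh = 0.0
    return dV, dn, dm, dh


@njit(cache=True, fastmath=True)
def _rk4_step(V, n, m, h, t, dt, C, gNa, gK, gm, ENa, EK, EL, V0,
              amp, t_on, t_off, frozen):
    I1 = amp if (t_on <= t < t_off) else 0.0
    th = t + 0.5 * dt
    I2 = amp if (t_on <= th < t_off) else 0.0
    t2 = t + dt
    I3 = amp if (t_on <= t2 < t_off) else 0.0
    k1 = _deriv(V, n, m, h, I1, C, gNa, gK, gm, ENa, EK, EL, V0, frozen)
    k2 = _deriv(V + 0.5 * dt * k1[0], n + 0.5 * dt * k1[1],
                m + 0.5 * dt * k1[2], h + 0.5 * dt * k1[3], I2,
                C, gNa, gK, gm, ENa, EK, EL, V0, frozen)
    k3 = _deriv(V + 0.5 * dt * k2[0], n + 0.5 * dt * k2[1],
                m + 0.5 * dt * k2[2], h + 0.5 * dt * k2[3], I2,
                C, gNa, gK, gm, ENa, EK, EL, V0, frozen)
    k4 = _deriv(V + dt * k3[0], n + dt * k3[1],
                m + dt * k3[2], h + dt * k3[3], I3,
                C, gNa, gK, gm, ENa, EK, EL, V0, frozen)
    c = dt / 6.0
    return (V + c * (k1[0] + 2.0 * k2[0] + 2.0 * k3[0] + k4[0]),
            n + c * (k1[1] + 2.0 * k2[1] + 2.0 * k3[1] + k4[1]),
            m + c * (k1[2] + 2.0 * k2[2] + 2.0 * k3[2] + k4[2]),
            h + c * (k1[3] + 2.0 * k2[3] + 2.0 * k3[3] + k4[3]))


@njit(cache=True, fastmath=True)
def rk4_classic(V_init, n0, m0, h0, dt, n_steps,
                C, gNa, gK, gm, ENa, EK, EL, V0,
                amp, t_on, t_off, max_crossings, min_sep_ms):
    """Classic HH integration.  Returns (V, n, m, h, status, last_index)."""
    V = np.empty(n_steps + 1)
    n = np.empty(n_steps + 1)
    m = np.empty(n_steps + 1)
    h = np.empty(n_steps + 1)
    V[0], n[0], m[0], h[0] = V_init, n0, m0, h0
    crossings = 0
    last_cross_t = -1e18
    status = STATUS_OK
    i_done = n_steps
    for i in range(1, n_steps + 1):
        t = (i - 1) * dt
        V[i], n[i], m[i], h[i] = _rk4_step(
            V[i - 1], n[i - 1], m[i - 1], h[i - 1], t, dt,
            C, gNa, gK, gm, ENa, EK, EL, V0, amp, t_on, t_off, -1)
        if not math.isfinite(V[i]):
            return V, n, m, h, STATUS_NONFINITE, i
        if max_crossings > 0 and V[i - 1] < 0.0 <= V[i]:
            tc = i * dt
            if tc - last_cross_t >= min_sep_ms:
                crossings += 1
                last_cross_t = tc
                if crossings >= max_crossings:
                    return V, n, m, h, STATUS_EARLY_STOP, i
    return V, n, m, h, status, i_done


@njit(cache=True, fastmath=True)
def lag_weights(n_steps, eta):
    """b_j = j^(1-eta) - (j-1)^(1-eta) for j = 0..n_steps (b_0 unused)."""
    b = np.empty(n_steps + 1)
    b[0] = 0.0
    e = 1.0 - eta
    prev = 0.0
    for j in range(1, n_steps + 1):
        cur = j ** e
        b[j] = cur - prev
        prev = cur
    return b


@njit(cache=True, fastmath=True)
def hybrid_l1(V_init, n0, m0, h0, frac, eta, dt, n_steps, b, window,
              div_bound, C, gNa, gK, gm, ENa, EK, EL, V0,
              amp, t_on, t_off, max_crossings, min_sep_ms):
    """Hybrid integrator: gate ``frac`` (0=n,1=m,2=h) via the L1 scheme,
    everything else via RK4 with the fractional gate held at its fresh value.

    Returns (V, n, m, h, mem, max_dx, status, last_index).
    """
    V = np.empty(n_steps + 1)
    n = np.empty(n_steps + 1)
    m = np.empty(n_steps + 1)
    h = np.empty(n_steps + 1)
    mem = np.zeros(n_steps + 1)
    dx = np.empty(n_steps)
    V[0], n[0], m[0], h[0] = V_init, n0, m0, h0
    c0 = dt ** eta * math.gamma(2.0 - eta)
    has_mem = eta < 1.0
    # reversed weight table: b[i - k] == br[N - i + k], so the memory sum
    # is a contiguous forward dot product (BLAS) instead of a strided loop
    br = b[::-1].copy()
    N = n_steps
    max_dx = 0.0
    crossings = 0
    last_cross_t = -1e18
    for i in range(1, n_steps + 1):
        Vp = V[i - 1]
        an, bn, am, bm, ah, bh = _rates(Vp, V0)
        if frac == 0:
            a, bb, xp = an, bn, n[i - 1]
        elif frac == 1:
            a, bb, xp = am, bm, m[i - 1]
        else:
            a, bb, xp = ah, bh, h[i - 1]
        mv = 0.0
        if has_mem:
            k0 = 0
            if window > 0 and i - 1 - window > 0:
                k0 = i - 1 - window
            if i - 1 - k0 < 64:
                acc = 0.0
                for k in range(k0, i - 1):
                    acc += dx[k] * b[i - k]
            else:
                acc = np.dot(dx[k0:i - 1], br[N - i + k0:N - 1])
            mv = -acc
        xi = c0 * (a * (1.0 - xp) - bb * xp) + xp + mv
        mem[i] = mv
        if not math.isfinite(xi) or abs(xi) > div_bound:
            return V, n, m, h, mem, max_dx, STATUS_DIVERGED, i
        d = xi - xp
        dx[i - 1] = d
        if abs(d) > max_dx:
            max_dx = abs(d)
        # advance V and the two classic gates, fractional gate frozen at xi
        nv, mv2, hv = n[i - 1], m[i - 1], h[i - 1]
        if frac == 0:
            nv = xi
        elif frac == 1:
            mv2 = xi
        else:
            hv = xi
        t = (i - 1) * dt
        Vn, nn, mn, hn = _rk4_step(Vp, nv, mv2, hv, t, dt,
                                   C, gNa, gK, gm, ENa, EK, EL, V0,
                                   amp, t_on, t_off, frac)
        if frac == 0:
            nn = xi
        elif frac == 1:
            mn = xi
        else:
            hn = xi
        V[i], n[i], m[i], h[i] = Vn, nn, mn, hn
        if not math.isfinite(Vn):
            return V, n, m, h, mem, max_dx, STATUS_NONFINITE, i
        if max_crossings > 0 and Vp < 0.0 <= Vn:
            tc = i * dt
            if tc - last_cross_t >= min_sep_ms:
                crossings += 1
                last_cross_t = tc
                if crossings >= max_crossings:
                    return V, n, m, h, mem, max_dx, STATUS_EARLY_STOP, i
    return V, n, m, h, mem, max_dx, STATUS_OK, n_steps


@njit(cache=True, fastmath=True)
def gate_clamp_l1(x0, alpha, beta, eta, dt, n_steps, b, window, div_bound):
    """Isolated gate under the L1 scheme at a constant clamped voltage.

    Returns (x, mem, max_dx, status, last_index).
    """
    x = np.empty(n_steps + 1)
    mem = np.zeros(n_steps + 1)
    dx = np.empty(n_steps)
    x[0] = x0
    c0 = dt ** eta * math.gamma(2.0 - eta)
    has_mem = eta < 1.0
    br = b[::-1].copy()
    N = n_steps
    max_dx = 0.0
    for i in range(1, n_steps + 1):
        xp = x[i - 1]
        mv = 0.0
        if has_mem:
            k0 = 0
            if window > 0 and i - 1 - window > 0:
                k0 = i - 1 - window
            if i - 1 - k0 < 64:
                acc = 0.0
                for k in range(k0, i - 1):
                    acc += dx[k] * b[i - k]
            else:
                acc = np.dot(dx[k0:i - 1], br[N - i + k0:N - 1])
            mv = -acc
        xi = c0 * (alpha * (1.0 - xp) - beta * xp) + xp + mv
        mem[i] = mv
        if not math.isfinite(xi) or abs(xi) > div_bound:
            return x, mem, max_dx, STATUS_DIVERGED, i
        d = xi - xp
        dx[i - 1] = d
        if abs(d) > max_dx:
            max_dx = abs(d)
        x[i] = xi
    return x, mem, max_dx, STATUS_OK, n_steps
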