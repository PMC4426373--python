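"""Pólya-Gamma PG(1, z) sampling by the Devroye alternating-series method.

Used as the auxiliary variable that makes every conditional of the
logit-link threshold animal model conjugate.  Numba-compiled; the module
keeps its own RNG state through numba's np.random, seeded explicitly by
the samplers that use it.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_T = 0.64  # series switch point
_SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def _log_norm_cdf(x):
    return math.log(0.5 * math.erfc(-x / _SQRT2) + 1e-300)


@njit(cache=True)
def _mass_texpon(z):
    """p / (p + q): probability the proposal comes from the exponential tail."""
    t = _T
    fz = math.pi**2 / 8.0 + z * z / 2.0
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + _log_norm_cdf(b)
    xa = x0 + z + _log_norm_cdf(a)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z):
    """Inverse-Gaussian(1/z, 1) truncated to (0, t]."""
    t = _T
    z = abs(z)
    x = t + 1.0
    if z * t < 1.0:  # small tilt (incl. z=0): rejection from the chi-squared tail
        alpha = 0.0
        while np.random.random() > alpha:
            e1 = np.random.exponential(1.0)
            e2 = np.random.exponential(1.0)
            while e1 * e1 > 2.0 * e2 / t:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
            x = t / ((1.0 + t * e1) ** 2)
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.standard_normal()
            y = y * y
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _a_coef(n, x):
    t = _T
    if x <= t:
        return (
            math.pi
            * (n + 0.5)
            * (2.0 / (math.pi * x)) ** 1.5
            * math.exp(-2.0 * (n + 0.5) ** 2 / x)
        )
    return math.pi * (n + 0.5) * math.exp(-((n + 0.5) ** 2) * math.pi**2 * x / 2.0)


@njit(cache=True)
def sample_pg1(psi):
    """One draw of PG(1, psi)."""
    z = abs(psi) * 0.5
    fz = math.pi**2 / 8.0 + z * z / 2.0
    p_ratio = _mass_texpon(z)
    while True:
        if np.random.random() < p_ratio:
            x = _T + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return x / 4.0
            else:
                s += _a_coef(n, x)
                if y > s:
                    break  # reject; draw a new proposal


@njit(cache=True)
def sample_pg1_vec(psi, out):
    for i in range(psi.shape[0]):
        out[i] = sample_pg1(psi[i])


@njit(cache=True)
def seed_numba(seed):
    np.random.seed(seed)
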