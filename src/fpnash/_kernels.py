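"""Numba kernels for the transport sub-steps and tridiagonal solves.

The advection sweeps operate on 2-D arrays whose first axis is the sweep
direction (callers orient and flip so the Courant number is nonnegative).
The smooth face correction c(e, d) = e^2 d / (e^2 + d^2) and its
derivatives match the formulas documented in ``forward._correction``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_TINY = 1e-150


@njit(cache=True)
def advect_forward(g, a, n_sub, rec, record):
    """n_sub explicit substeps with Courant number a in [0, 1].

    ``rec`` (n_sub, n, m) receives each substep's input when ``record``;
    returns the advected field.
    """
    n, m = g.shape
    cur = g.copy()
    new = np.empty_like(cur)
    for s in range(n_sub):
        if record:
            rec[s] = cur
        for j in range(m):
            f_prev = 0.0
            for i in range(n):
                if i < n - 1:
                    d = cur[i + 1, j] - cur[i, j]
                    e = cur[i, j] - cur[i - 1, j] if i > 0 else 0.0
                    den = e * e + d * d + _TINY
                    flux = cur[i, j] + (1.0 - a) * (e * e * d / den)
                else:
                    flux = 0.0
                new[i, j] = cur[i, j] - a * (flux - f_prev)
                f_prev = flux
        cur, new = new, cur
    return cur.copy()


@njit(cache=True)
def advect_adjoint(rec, mu, a):
    """Transpose of the linearized substeps; returns (mu_in, dJ/da)."""
    n_sub, n, m = rec.shape
    cur = mu.copy()
    dJda = 0.0
    for s in range(n_sub - 1, -1, -1):
        g = rec[s]
        new = cur.copy()
        for j in range(m):
            for i in range(n - 1):
                d = g[i + 1, j] - g[i, j]
                e = g[i, j] - g[i - 1, j] if i > 0 else 0.0
                e2 = e * e
                d2 = d * d
                den = e2 + d2 + _TINY
                c = e2 * d / den
                den2 = den * den
                dc_de = 2.0 * e * d * d2 / den2
                dc_dd = e2 * (e2 - d2) / den2
                flux = g[i, j] + (1.0 - a) * c
                q = cur[i + 1, j] - cur[i, j]
                dJda += q * (flux - a * c)
                aq = a * q
                one_m_a = 1.0 - a
                new[i, j] += aq * (1.0 + one_m_a * (dc_de - dc_dd))
                new[i + 1, j] += aq * one_m_a * dc_dd
                if i > 0:
                    new[i - 1, j] -= aq * one_m_a * dc_de
        cur = new
    return cur, dJda


@njit(cache=True)
def thomas_factor(sub, diag, sup):
    """LU coefficients of a tridiagonal system (Thomas algorithm)."""
    n = diag.shape[0]
    cp = np.empty(n)
    w = np.empty(n)
    w[0] = 1.0 / diag[0]
    cp[0] = sup[0] * w[0]
    for i in range(1, n):
        w[i] = 1.0 / (diag[i] - sub[i] * cp[i - 1])
        cp[i] = sup[i] * w[i]
    return cp, w


@njit(cache=True)
def thomas_solve_axis0(cp, w, sub, rhs):
    """Solve the factored tridiagonal system along axis 0 for every column."""
    n, m = rhs.shape
    x = np.empty_like(rhs)
    for j in range(m):
        x[0, j] = rhs[0, j] * w[0]
        for i in range(1, n):
            x[i, j] = (rhs[i, j] - sub[i] * x[i - 1, j]) * w[i]
        for i in range(n - 2, -1, -1):
            x[i, j] -= cp[i] * x[i + 1, j]
    return x


@njit(cache=True)
def thomas_solve_axis1(cp, w, sub, rhs):
    """Solve the factored tridiagonal system along axis 1 for every row."""
    m, n = rhs.shape
    x = np.empty_like(rhs)
    for j in range(m):
        x[j, 0] = rhs[j, 0] * w[0]
        for i in range(1, n):
            x[j, i] = (rhs[j, i] - sub[i] * x[j, i - 1]) * w[i]
        for i in range(n - 2, -1, -1):
            x[j, i] -= cp[i] * x[j, i + 1]
    return x
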