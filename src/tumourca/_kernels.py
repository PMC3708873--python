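"""Numerical kernels (numba-compiled hot loops).

Two pieces of the simulator dominate run time: integrating the
six-variable cell-cycle network for every active cell at a 0.01 h micro
step, and relaxing the quasi-steady oxygen field once per macro step.
Both are implemented here as ``nopython`` kernels operating on plain
arrays; the public modules wrap them with typed interfaces.

Parameter-vector layout used by the cell-cycle kernels (see
``CellCycleParams.as_array``)::

    0..12  k1 k2' k2'' k3' k3'' k4 k5' k5'' k6 k7 k8 k9 k10
    13..17 J3 J4 J5 J7 J8
    18..21 n  Mad  mu  m*

State layout: [CycB, Cdh1, p55cdcT, p55cdcA, Plk1, mass].
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rhs_single", "advance_states", "relax_field", "fd_residual"]


@njit(cache=True)
def _rhs(y, p, hyp, out):
    cycb = max(y[0], 0.0)
    cdh1 = min(max(y[1], 0.0), 1.0)
    p55t = max(y[2], 0.0)
    p55a = min(max(y[3], 0.0), p55t)
    plk1 = min(max(y[4], 0.0), 1.0)
    m = max(y[5], 1e-12)

    out[0] = p[0] - (p[1] + p[2] * cdh1) * cycb
    out[1] = (p[3] + p[4] * p55a) * (1.0 - cdh1) / (p[13] + 1.0 - cdh1) \
        - p[5] * m * cycb * cdh1 / (p[14] + cdh1)
    u = cycb * m / p[15]
    if p[18] == 4.0:  # the published Hill exponent; avoids float pow
        u2 = u * u
        xi = u2 * u2
    else:
        xi = u ** p[18]
    out[2] = p[6] + p[7] * xi / (1.0 + xi) - p[8] * p55t
    out[3] = p[9] * plk1 * (p55t - p55a) / (p[16] + p55t - p55a) \
        - p[10] * p[19] * p55a / (p[17] + p55a) - p[8] * p55a
    out[4] = p[11] * m * cycb * (1.0 - plk1) - p[12] * plk1
    out[5] = hyp * p[20] * m * (1.0 - m / p[21])


def rhs_single(y: np.ndarray, p: np.ndarray, hyp: float) -> np.ndarray:
    """Derivative vector for one cell (thin wrapper for the library API)."""
    out = np.empty(6)
    _rhs(np.asarray(y, dtype=np.float64), np.asarray(p, dtype=np.float64),
         float(hyp), out)
    return out


@njit(cache=True)
def advance_states(states, hyp, p, nsteps, dt):
    """RK4-advance all rows of ``states`` in place by ``nsteps * dt`` hours.

    ``hyp`` holds the per-cell mass-growth factor (1 for normoxic).
    After every step the state is projected back onto its invariant set:
    all components >= 0, Cdh1 <= 1, active p55cdc <= total, mass > 0.
    The projection is what keeps the fixed-step integrator stable across
    the steep Goldbeter–Koshland switches of the network.
    """
    n = states.shape[0]
    k1 = np.empty(6)
    k2 = np.empty(6)
    k3 = np.empty(6)
    k4 = np.empty(6)
    yt = np.empty(6)
    for i in range(n):
        y = states[i]
        h = hyp[i]
        for _ in range(nsteps):
            _rhs(y, p, h, k1)
            for j in range(6):
                yt[j] = y[j] + 0.5 * dt * k1[j]
            _rhs(yt, p, h, k2)
            for j in range(6):
                yt[j] = y[j] + 0.5 * dt * k2[j]
            _rhs(yt, p, h, k3)
            for j in range(6):
                yt[j] = y[j] + dt * k3[j]
            _rhs(yt, p, h, k4)
            for j in range(6):
                y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            # projection onto the invariant set
            if y[0] < 0.0:
                y[0] = 0.0
            if y[1] < 0.0:
                y[1] = 0.0
            elif y[1] > 1.0:
                y[1] = 1.0
            if y[2] < 0.0:
                y[2] = 0.0
            if y[3] < 0.0:
                y[3] = 0.0
            elif y[3] > y[2]:
                y[3] = y[2]
            if y[4] < 0.0:
                y[4] = 0.0
            elif y[4] > 1.0:
                y[4] = 1.0
            if y[5] < 1e-12:
                y[5] = 1e-12


@njit(cache=True)
def relax_field(a_e, a_w, a_n, a_s, a_p, react, b, x, omega, tol, max_sweeps):
    """Red-black SOR for the 5-point system  aP·x − Σ aNb·x_nb = b.

    ``react`` is the zero-order (reaction) part of the diagonal,
    ``a_p = react + Σ aNb``.  Neighbour coefficients are zero across the
    domain boundary, which is exactly the zero-flux (mirrored ghost
    cell) closure.

    When the reaction term is small relative to diffusion the system is
    a near-Neumann Poisson problem whose global mode stalls plain SOR;
    each iteration therefore ends with a constant-mode (deflation)
    correction  x += Σr / Σreact,  which annihilates the summed
    residual.  For a conservative backward-Euler diffusion step
    (react ≡ 1/dt) this same correction makes the discrete update
    conserve total mass to round-off.

    Iteration stops when  max|r| / max|b|  < tol.  Returns
    (sweeps, relative residual).
    """
    rows, cols = b.shape
    bmax = 0.0
    react_sum = 0.0
    for i in range(rows):
        for j in range(cols):
            ab = abs(b[i, j])
            if ab > bmax:
                bmax = ab
            react_sum += react[i, j]
    if bmax == 0.0:
        for i in range(rows):
            for j in range(cols):
                x[i, j] = 0.0
        return 0, 0.0
    r = np.empty((rows, cols))
    sweeps = 0
    res = np.inf
    check_every = 4  # residual pass costs ~half a sweep; amortise it
    while sweeps < max_sweeps:
        for parity in range(2):
            for i in range(rows):
                jstart = (i + parity) % 2
                for j in range(jstart, cols, 2):
                    acc = b[i, j]
                    if j + 1 < cols:
                        acc += a_e[i, j] * x[i, j + 1]
                    if j > 0:
                        acc += a_w[i, j] * x[i, j - 1]
                    if i > 0:
                        acc += a_n[i, j] * x[i - 1, j]
                    if i + 1 < rows:
                        acc += a_s[i, j] * x[i + 1, j]
                    x[i, j] += omega * (acc / a_p[i, j] - x[i, j])
        sweeps += 1
        if sweeps % check_every and sweeps < max_sweeps:
            continue
        rsum = 0.0
        for i in range(rows):
            for j in range(cols):
                acc = b[i, j] - a_p[i, j] * x[i, j]
                if j + 1 < cols:
                    acc += a_e[i, j] * x[i, j + 1]
                if j > 0:
                    acc += a_w[i, j] * x[i, j - 1]
                if i > 0:
                    acc += a_n[i, j] * x[i - 1, j]
                if i + 1 < rows:
                    acc += a_s[i, j] * x[i + 1, j]
                r[i, j] = acc
                rsum += acc
        if react_sum > 0.0:
            alpha = rsum / react_sum
            res = 0.0
            for i in range(rows):
                for j in range(cols):
                    x[i, j] += alpha
                    ri = r[i, j] - react[i, j] * alpha
                    if abs(ri) > res:
                        res = abs(ri)
        else:
            res = 0.0
            for i in range(rows):
                for j in range(cols):
                    if abs(r[i, j]) > res:
                        res = abs(r[i, j])
        res /= bmax
        if res < tol:
            break
    return sweeps, res


@njit(cache=True)
def fd_residual(a_e, a_w, a_n, a_s, a_p, b, x):
    """Max-norm residual of the 5-point system at ``x`` (diagnostics)."""
    rows, cols = b.shape
    res = 0.0
    for i in range(rows):
        for j in range(cols):
            acc = b[i, j] - a_p[i, j] * x[i, j]
            if j + 1 < cols:
                acc += a_e[i, j] * x[i, j + 1]
            if j > 0:
                acc += a_w[i, j] * x[i, j - 1]
            if i > 0:
                acc += a_n[i, j] * x[i - 1, j]
            if i + 1 < rows:
                acc += a_s[i, j] * x[i + 1, j]
            if abs(acc) > res:
                res = abs(acc)
    return res
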