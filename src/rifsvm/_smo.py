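"""Sequential minimal optimization core for the box-and-equality dual QP.

Minimizes f(a) = 1/2 a'Qa - e'a subject to y'a = 0 and 0 <= a_i <= u_i,
with Q_ij = y_i y_j K_ij and per-instance upper bounds u_i = s_i C.

Pair selection is the second-order working-set rule: the first index is the
maximal KKT violator among the "up" set, the second minimizes the one-step
decrease estimate among "low" candidates. Stopping criterion is the maximal
violating-pair gap m - M < tol. Fully deterministic for a fixed input order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TAU = 1e-12


@njit(cache=True)
def smo_solve(Q, y, u, tol, max_iter):  # pragma: no cover - exercised via wrapper
    n = Q.shape[0]
    alpha = np.zeros(n)
    grad = np.full(n, -1.0)  # grad_i = (Q a)_i - 1

    it = 0
    m_val = 0.0
    M_val = 0.0
    while it < max_iter:
        # first index: maximal -y_i grad_i over I_up
        i = -1
        m_val = -1e300
        for t in range(n):
            if (y[t] > 0 and alpha[t] < u[t]) or (y[t] < 0 and alpha[t] > 0.0):
                v = -y[t] * grad[t]
                if v > m_val:
                    m_val = v
                    i = t
        # second index: second-order rule over I_low, track M for stopping
        j = -1
        M_val = 1e300
        best = 0.0
        if i >= 0:
            Qii = Q[i, i]
            for t in range(n):
                if (y[t] > 0 and alpha[t] > 0.0) or (y[t] < 0 and alpha[t] < u[t]):
                    v = -y[t] * grad[t]
                    if v < M_val:
                        M_val = v
                    b = m_val - v
                    if b > 0.0:
                        a = Qii + Q[t, t] - 2.0 * y[i] * y[t] * Q[i, t]
                        if a <= 0.0:
                            a = TAU
                        dec = -(b * b) / a
                        if dec < best:
                            best = dec
                            j = t
        if i < 0 or j < 0 or m_val - M_val < tol:
            break

        a = Q[i, i] + Q[j, j] - 2.0 * y[i] * y[j] * Q[i, j]
        if a <= 0.0:
            a = TAU
        step = (m_val - (-y[j] * grad[j])) / a
        # clip to keep both variables inside their boxes
        lim_i = (u[i] - alpha[i]) if y[i] > 0 else alpha[i]
        lim_j = alpha[j] if y[j] > 0 else (u[j] - alpha[j])
        if step > lim_i:
            step = lim_i
        if step > lim_j:
            step = lim_j
        alpha[i] += y[i] * step
        alpha[j] -= y[j] * step
        # Q is symmetric; index by row for contiguous access
        for t in range(n):
            grad[t] += step * (y[i] * Q[i, t] - y[j] * Q[j, t])
        it += 1

    return alpha, grad, m_val, M_val, it
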