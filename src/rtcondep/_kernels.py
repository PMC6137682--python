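"""Numba kernels for the kernel-weighted marginal likelihood.

The weighted likelihood for one (item, focal point) cell is maximized many
thousands of times inside the permutation and posterior-predictive loops,
so the objective and a small bounded Nelder-Mead live in compiled code.
The numpy reference implementation in :mod:`rtcondep.npmod` is the oracle
these kernels are tested against.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

CLIP = 8.0
ALPHA_LO, ALPHA_HI = 0.01, 5.0
BETA_LO, BETA_HI = -6.0, 6.0


@njit(cache=True, fastmath=True)
def _log_phi_pair(alpha, beta, theta_q, L1, L0):
    """Fill L1/L0 with ln Phi(+u_q) and ln Phi(-u_q), clipped at +-8."""
    for q in range(theta_q.size):
        u = alpha * theta_q[q] + beta
        if u > CLIP:
            u = CLIP
        elif u < -CLIP:
            u = -CLIP
        p = 0.5 * (1.0 + math.erf(u / math.sqrt(2.0)))
        L1[q] = math.log(p)
        L0[q] = math.log1p(-p)


@njit(cache=True, fastmath=True)
def weighted_nll(alpha, beta, theta_q, E, w, x):
    """Negative weighted log-likelihood up to a constant in (alpha, beta).

    ``E[p, q]`` holds exp(log GH weight + rest-of-test log-likelihood),
    row-shifted by an arbitrary per-person constant; ``w`` are the kernel
    weights of the active persons and ``x`` their 0/1 responses.
    """
    Q = theta_q.size
    L1 = np.empty(Q)
    L0 = np.empty(Q)
    _log_phi_pair(alpha, beta, theta_q, L1, L0)
    total = 0.0
    for p in range(w.size):
        wp = w[p]
        acc = 0.0
        if x[p] == 1:
            for q in range(Q):
                acc += E[p, q] * math.exp(wp * L1[q])
        else:
            for q in range(Q):
                acc += E[p, q] * math.exp(wp * L0[q])
        total += math.log(acc)
    return -total


@njit(cache=True, fastmath=True)
def _clipped(a, b):
    if a < ALPHA_LO:
        a = ALPHA_LO
    elif a > ALPHA_HI:
        a = ALPHA_HI
    if b < BETA_LO:
        b = BETA_LO
    elif b > BETA_HI:
        b = BETA_HI
    return a, b


@njit(cache=True, fastmath=True)
def maximize_weighted_loglik(a0, b0, theta_q, E, w, x, maxiter=200, ftol=1e-9,
                             xtol=1e-3):
    """Bounded Nelder-Mead over (alpha, beta) from a warm start.

    Candidates are projected into the box [0.01, 5] x [-6, 6].  Returns
    (alpha, beta, -nll_up_to_constant).
    """
    # initial simplex
    sa = np.empty(3)
    sb = np.empty(3)
    fv = np.empty(3)
    a0, b0 = _clipped(a0, b0)
    sa[0], sb[0] = a0, b0
    sa[1], sb[1] = _clipped(a0 + 0.25, b0)
    sa[2], sb[2] = _clipped(a0, b0 + 0.25)
    if sa[1] == sa[0]:
        sa[1] = sa[0] - 0.25
    if sb[2] == sb[0]:
        sb[2] = sb[0] - 0.25
    for v in range(3):
        fv[v] = weighted_nll(sa[v], sb[v], theta_q, E, w, x)

    for _ in range(maxiter):
        # order
        order = np.argsort(fv)
        sa, sb, fv = sa[order], sb[order], fv[order]
        spread = max(abs(sa[1] - sa[0]), abs(sa[2] - sa[0]),
                     abs(sb[1] - sb[0]), abs(sb[2] - sb[0]))
        if (fv[2] - fv[0] < ftol * (abs(fv[0]) + 1.0)) or spread < xtol:
            break
        ca = 0.5 * (sa[0] + sa[1])
        cb = 0.5 * (sb[0] + sb[1])
        # reflection
        ra, rb = _clipped(ca + (ca - sa[2]), cb + (cb - sb[2]))
        fr = weighted_nll(ra, rb, theta_q, E, w, x)
        if fr < fv[0]:
            # expansion
            ea, eb = _clipped(ca + 2.0 * (ca - sa[2]), cb + 2.0 * (cb - sb[2]))
            fe = weighted_nll(ea, eb, theta_q, E, w, x)
            if fe < fr:
                sa[2], sb[2], fv[2] = ea, eb, fe
            else:
                sa[2], sb[2], fv[2] = ra, rb, fr
        elif fr < fv[1]:
            sa[2], sb[2], fv[2] = ra, rb, fr
        else:
            # contraction
            xa, xb = _clipped(ca + 0.5 * (sa[2] - ca), cb + 0.5 * (sb[2] - cb))
            fc = weighted_nll(xa, xb, theta_q, E, w, x)
            if fc < fv[2]:
                sa[2], sb[2], fv[2] = xa, xb, fc
            else:
                # shrink toward best
                for v in range(1, 3):
                    sa[v], sb[v] = _clipped(sa[0] + 0.5 * (sa[v] - sa[0]),
                                            sb[0] + 0.5 * (sb[v] - sb[0]))
                    fv[v] = weighted_nll(sa[v], sb[v], theta_q, E, w, x)
    best = np.argmin(fv)
    return sa[best], sb[best], -fv[best]
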