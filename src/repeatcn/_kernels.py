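"""Numba kernels for the MCMC hot paths.

All beta-binomial evaluations here use the identity

    log pmf = log C(n, y) + lg(y + a) + lg(n - y + b) - lg(n + s)
                          - lg(a) - lg(b) + lg(s)

with a = s*c*m, b = s*(1 - c*m), valid because betaln(a, b) shares the
lg(a + b) = lg(s) term with betaln(y + a, n - y + b).  This is accurate for
the dispersion regimes the samplers visit; the extreme-s limit is handled
by the pure-python :func:`repeatcn.model.betabinom_logpmf`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG_INF = -1.0e300


@njit(cache=True)
def bb_logpmf_terms(y, n, cm, s, const):
    """Beta-binomial log pmf for one count; const = log C(n, y)."""
    if cm <= 0.0:
        return 0.0 if y == 0 else NEG_INF
    if cm >= 1.0:
        return NEG_INF
    a = s * cm
    b = s * (1.0 - cm)
    return (
        const
        + math.lgamma(y + a)
        + math.lgamma(n - y + b)
        - math.lgamma(n + s)
        - math.lgamma(a)
        - math.lgamma(b)
        + math.lgamma(s)
    )


@njit(cache=True)
def control_loglik_matrix(x, n, m, s, const):
    """(L, K) log-likelihood matrix for the control model (c = 1).

    x: (L, K) counts; n: (K,) totals; m: (L,) bias; s: (K,) dispersions;
    const: (L, K) precomputed log binomial coefficients.
    """
    L, K = x.shape
    out = np.empty((L, K))
    for l in range(L):
        for k in range(K):
            out[l, k] = bb_logpmf_terms(x[l, k], n[k], m[l], s[k], const[l, k])
    return out


@njit(cache=True)
def emission_matrix(y, n, m, s, c, const):
    """(L, K) log emissions: count y_l under state RCN c_u.

    y: (L,) counts; m: (L,) bias; c: (K,) state RCNs; const: (L,) log
    binomial coefficients.  Invalid combinations (c*m >= 1) get -inf.
    """
    L = y.shape[0]
    K = c.shape[0]
    out = np.empty((L, K))
    for l in range(L):
        for u in range(K):
            out[l, u] = bb_logpmf_terms(y[l], n, c[u] * m[l], s, const[l])
    return out


@njit(cache=True)
def bb_loglik_subset(y, m, const, n, c, s):
    """Sum of log pmf over a subset of loci sharing one state RCN c."""
    total = 0.0
    for i in range(y.shape[0]):
        v = bb_logpmf_terms(y[i], n, c * m[i], s, const[i])
        if v <= NEG_INF:
            return NEG_INF
        total += v
    return total


@njit(cache=True)
def bb_loglik_assigned(y, m, const, n, c_of_locus, s):
    """Sum of log pmf over all loci, each at its assigned state RCN."""
    total = 0.0
    for i in range(y.shape[0]):
        v = bb_logpmf_terms(y[i], n, c_of_locus[i] * m[i], s, const[i])
        if v <= NEG_INF:
            return NEG_INF
        total += v
    return total


@njit(cache=True)
def _logsumexp(v):
    hi = v[0]
    for i in range(1, v.shape[0]):
        if v[i] > hi:
            hi = v[i]
    if hi <= NEG_INF:
        return NEG_INF
    acc = 0.0
    for i in range(v.shape[0]):
        acc += math.exp(v[i] - hi)
    return hi + math.log(acc)


@njit(cache=True)
def forward_backward_sample(log_em, log_pi, log_pi0, uniforms):
    """Joint draw of a state path from its conditional posterior.

    Backward messages are accumulated in log space, then states are sampled
    forward; ``uniforms`` supplies one U(0,1) variate per locus so the call
    is deterministic given its inputs.
    """
    L, K = log_em.shape
    msg = np.zeros((L, K))  # msg[l, u] = log p(y_{l+1:L} | z_l = u)
    tmp = np.empty(K)
    for l in range(L - 2, -1, -1):
        for u in range(K):
            for v in range(K):
                tmp[v] = log_pi[u, v] + log_em[l + 1, v] + msg[l + 1, v]
            msg[l, u] = _logsumexp(tmp)
    z = np.empty(L, dtype=np.int64)
    probs = np.empty(K)
    for l in range(L):
        for u in range(K):
            prev = log_pi0[u] if l == 0 else log_pi[z[l - 1], u]
            probs[u] = prev + log_em[l, u] + msg[l, u]
        norm = _logsumexp(probs)
        if norm <= NEG_INF:
            raise ValueError("all states have zero posterior probability at a locus")
        acc = 0.0
        pick = K - 1
        for u in range(K):
            acc += math.exp(probs[u] - norm)
            if uniforms[l] < acc:
                pick = u
                break
        z[l] = pick
    return z
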