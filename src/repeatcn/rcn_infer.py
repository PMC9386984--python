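"""Sticky HDP-HMM sampler for a sample's relative copy number profile.

Each chromosome arm is an independent Markov chain over a shared set of
hidden copy-number states.  The state space is countably infinite in the
model; inference uses the weak-limit truncation at ``K_max`` states, with
blocked (forward-backward) resampling of the state path, auxiliary
table-count resampling of the global weights ``beta`` and the transition
rows, and Metropolis-Hastings updates for the state RCN values, the sample
dispersion, the self-transition weight ``rho`` and the total concentration
``alpha + kappa``.

The self-transition bonus ("stickiness") encodes the spatial persistence of
copy number along the genome: a priori

    E[pi_{u,v}] = (1 - rho) beta_v + rho delta_{u,v}

with rho close to 1 under the default Beta(100000, 100) prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

from ._kernels import (
    NEG_INF,
    bb_loglik_assigned,
    bb_loglik_subset,
    emission_matrix,
    forward_backward_sample as _fb_kernel,
)
from .control_fit import BiasModel
from .model import Hyperparams

__all__ = [
    "ChainDraw",
    "RCNTrace",
    "infer_rcn",
    "forward_backward_sample",
    "sticky_row_expectation",
    "log_joint",
]


@dataclass
class ChainDraw:
    """One MCMC state of the copy-number sampler."""

    z: np.ndarray  # (L,) state index per locus
    c: np.ndarray  # (K_max,) RCN per state
    beta: np.ndarray  # (K_max,) global state weights
    pi: np.ndarray  # (K_max, K_max) transition matrix
    pi0: np.ndarray  # (K_max,) initial distribution
    s_tilde: float
    rho: float
    alpha_plus_kappa: float

    @property
    def populated(self) -> np.ndarray:
        """States with at least one assigned locus."""
        return np.unique(self.z)


@dataclass
class RCNTrace:
    """Thinned post-burn-in draws plus run settings.

    ``z`` is (T, L), ``c``/``beta`` (T, K_max), ``pi`` (T, K_max, K_max);
    scalars are length-T vectors.  ``populated_counts[t]`` is the number of
    states with at least one assigned locus in draw t.
    """

    z: np.ndarray
    c: np.ndarray
    beta: np.ndarray
    pi: np.ndarray
    pi0: np.ndarray
    s_tilde: np.ndarray
    rho: np.ndarray
    alpha_plus_kappa: np.ndarray
    populated_counts: np.ndarray
    settings: dict = field(default_factory=dict)
    loci: pd.DataFrame | None = None

    @property
    def n_stored(self) -> int:
        return self.z.shape[0]

    def draw(self, t: int) -> ChainDraw:
        return ChainDraw(
            z=self.z[t].astype(np.int64),
            c=self.c[t],
            beta=self.beta[t],
            pi=self.pi[t].astype(float),
            pi0=self.pi0[t].astype(float),
            s_tilde=float(self.s_tilde[t]),
            rho=float(self.rho[t]),
            alpha_plus_kappa=float(self.alpha_plus_kappa[t]),
        )

    def locus_rcn_draws(self) -> np.ndarray:
        """(T, L) matrix of the RCN assigned to each locus in each draw."""
        return np.take_along_axis(self.c, self.z.astype(np.int64), axis=1)


def sticky_row_expectation(beta: np.ndarray, rho: float, u: int) -> np.ndarray:
    """Prior mean of transition row u: (1 - rho) beta + rho on the diagonal."""
    beta = np.asarray(beta, dtype=float)
    if not np.isclose(beta.sum(), 1.0):
        raise ValueError("beta must be a simplex")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    row = (1.0 - rho) * beta.copy()
    row[u] += rho
    return row


def forward_backward_sample(
    log_emissions: np.ndarray,
    pi: np.ndarray,
    pi0: np.ndarray,
    seed_or_rng=None,
) -> np.ndarray:
    """Exact joint draw of a state path given emissions and transitions.

    ``log_emissions`` is (L, K); ``pi`` a row-stochastic K x K matrix and
    ``pi0`` the initial distribution.  Backward messages then forward
    sampling, all in log space.
    """
    log_em = np.asarray(log_emissions, dtype=float)
    if np.any(np.all(np.isinf(log_em) & (log_em < 0), axis=1)):
        raise ValueError("a locus has -inf emission under every state")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.asarray(pi, dtype=float))
        log_pi0 = np.log(np.asarray(pi0, dtype=float))
    log_em = np.where(np.isfinite(log_em), log_em, NEG_INF)
    log_pi = np.where(np.isfinite(log_pi), log_pi, NEG_INF)
    log_pi0 = np.where(np.isfinite(log_pi0), log_pi0, NEG_INF)
    return _fb_kernel(log_em, log_pi, log_pi0, rng.random(log_em.shape[0]))


def _arm_slices(arms: Sequence[str]) -> list[np.ndarray]:
    """Indices of each arm's loci, preserving input (genomic) order."""
    arms = np.asarray(arms)
    out = []
    for arm in pd.unique(arms):
        out.append(np.flatnonzero(arms == arm))
    return out


def _crt_tables(n_uv: int, conc: float, rng: np.random.Generator) -> int:
    """Chinese-restaurant table count for n customers at concentration conc."""
    if n_uv == 0 or conc <= 0.0:
        return 0
    i = np.arange(n_uv, dtype=float)
    return int((rng.random(n_uv) < conc / (conc + i)).sum())


def _dirichlet_pos(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw guarded against exact zeros from tiny concentrations."""
    g = rng.gamma(np.maximum(alpha, 1e-12))
    g = np.maximum(g, 1e-300)
    return g / g.sum()


def _log_dirichlet_pdf(x: np.ndarray, alpha: np.ndarray) -> float:
    x = np.maximum(x, 1e-300)
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1.0) * np.log(x)).sum()
    )


def infer_rcn(
    y: np.ndarray,
    arms: Sequence[str],
    bias: BiasModel | np.ndarray,
    hp: Hyperparams | None = None,
    iters: int = 50000,
    burn: int = 20000,
    thin: int = 5,
    K_max: int = 25,
    seed: int | None = None,
    loci: pd.DataFrame | None = None,
) -> RCNTrace:
    """Blocked Gibbs sampler for the copy-number profile of one sample.

    Parameters
    ----------
    y : per-locus counts for the profiled sample (total n = y.sum()).
    arms : per-locus chromosome-arm labels; each arm is an independent chain.
    bias : fitted :class:`BiasModel` (or a bare bias vector summing to 1).
    iters, burn, thin : run length, burn-in and thinning of the stored chain.
    K_max : weak-limit truncation of the state space.

    One sweep comprises (i) forward-backward resampling of the state path
    arm by arm, (ii) auxiliary-count resampling of beta and the (sticky)
    transition rows, (iii) a log-scale random-walk update of each populated
    state's RCN and prior redraws for unpopulated states, (iv) an update of
    the sample dispersion, and (v) updates of rho and (alpha + kappa).
    """
    hp = hp or Hyperparams()
    y = np.asarray(y, dtype=np.int64)
    m = bias.m_hat if isinstance(bias, BiasModel) else np.asarray(bias, dtype=float)
    if len(y) != len(m):
        raise ValueError(f"{len(y)} counts but {len(m)} bias loci")
    if len(arms) != len(y):
        raise ValueError("arm labels must match loci")
    if burn >= iters:
        raise ValueError("burn-in must be shorter than the run")
    L = len(y)
    n = float(y.sum())
    rng = np.random.default_rng(seed)
    slices = _arm_slices(arms)

    lam_shape, lam_scale = hp.lam
    om_shape, om_scale = hp.omega
    apk_shape, apk_scale = hp.alpha_plus_kappa
    rho_a, rho_b = hp.rho

    const = gammaln(n + 1.0) - gammaln(y + 1.0) - gammaln(n - y + 1.0)

    # init: the null profile — one state at RCN 1, dispersion moment-matched
    z = np.zeros(L, dtype=np.int64)
    c = rng.gamma(lam_shape, lam_scale, size=K_max)
    c[0] = 1.0
    mu = n * m
    f = np.mean((y - mu) ** 2 / np.maximum(mu * (1.0 - m), 1e-12))
    s_tilde = max((n - 1.0) / (f - 1.0) - 1.0, 10.0) if f > 1.0 else 1e8
    rho = rho_a / (rho_a + rho_b)
    apk = apk_shape * apk_scale
    beta = np.full(K_max, 1.0 / K_max)
    pi = np.stack([sticky_row_expectation(beta, rho, u) for u in range(K_max)])
    pi0 = beta.copy()

    c_step = np.full(K_max, 0.05)
    s_step, rho_step, apk_step = 0.2, 0.5, 0.05
    adapt_window = 50
    win_c_acc = np.zeros(K_max)
    win_c_try = np.zeros(K_max)
    win = {"s": [0, 0], "rho": [0, 0], "apk": [0, 0]}

    n_store = (iters - burn) // thin
    out_z = np.empty((n_store, L), dtype=np.int16)
    out_c = np.empty((n_store, K_max))
    out_beta = np.empty((n_store, K_max))
    out_pi = np.empty((n_store, K_max, K_max), dtype=np.float32)
    out_pi0 = np.empty((n_store, K_max), dtype=np.float32)
    out_s = np.empty(n_store)
    out_rho = np.empty(n_store)
    out_apk = np.empty(n_store)
    out_pop = np.empty(n_store, dtype=np.int32)
    stored = 0

    def trans_log_density(pi_, pi0_, beta_, rho_, apk_):
        alpha_ = (1.0 - rho_) * apk_
        kappa_ = rho_ * apk_
        total = _log_dirichlet_pdf(pi0_, np.maximum(alpha_ * beta_, 1e-12))
        for u in range(K_max):
            a = alpha_ * beta_
            a = a.copy()
            a[u] += kappa_
            total += _log_dirichlet_pdf(pi_[u], np.maximum(a, 1e-12))
        return total

    for it in range(iters):
        # (i) blocked state-path update, arm by arm
        E = emission_matrix(y, n, m, s_tilde, c, const)
        with np.errstate(divide="ignore"):
            log_pi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), NEG_INF)
            log_pi0 = np.where(pi0 > 0, np.log(np.maximum(pi0, 1e-300)), NEG_INF)
        for idx in slices:
            if len(idx) == 1:
                probs = log_pi0 + E[idx[0]]
                probs -= probs.max()
                p = np.exp(probs)
                z[idx[0]] = rng.choice(K_max, p=p / p.sum())
            else:
                z[idx] = _fb_kernel(E[idx], log_pi, log_pi0, rng.random(len(idx)))

        # (ii) transition counts, table counts, then beta / pi / pi0
        n_uv = np.zeros((K_max, K_max), dtype=np.int64)
        n0 = np.zeros(K_max, dtype=np.int64)
        for idx in slices:
            zz = z[idx]
            n0[zz[0]] += 1
            np.add.at(n_uv, (zz[:-1], zz[1:]), 1)
        alpha = (1.0 - rho) * apk
        kappa = rho * apk
        m_bar = np.zeros((K_max, K_max))
        for u, v in zip(*np.nonzero(n_uv)):
            conc = alpha * beta[v] + (kappa if u == v else 0.0)
            t_uv = _crt_tables(int(n_uv[u, v]), conc, rng)
            if u == v and t_uv > 0:
                p_override = rho / (rho + beta[u] * (1.0 - rho))
                w = rng.binomial(t_uv, p_override)
                t_uv -= w
            m_bar[u, v] = t_uv
        m0 = np.zeros(K_max)
        for u in np.nonzero(n0)[0]:
            m0[u] = _crt_tables(int(n0[u]), alpha * beta[u], rng)
        beta = _dirichlet_pos(rng, hp.gamma / K_max + m_bar.sum(axis=0) + m0)
        for u in range(K_max):
            a = alpha * beta + n_uv[u]
            a[u] += kappa
            pi[u] = _dirichlet_pos(rng, a)
        pi0 = _dirichlet_pos(rng, alpha * beta + n0)

        # (iii) state RCN updates
        populated = np.unique(z)
        pop_set = set(populated.tolist())
        for u in range(K_max):
            if u in pop_set:
                idx = np.flatnonzero(z == u)
                cur = bb_loglik_subset(y[idx], m[idx], const[idx], n, c[u], s_tilde)
                prop = c[u] * np.exp(c_step[u] * rng.standard_normal())
                new = bb_loglik_subset(y[idx], m[idx], const[idx], n, prop, s_tilde)
                win_c_try[u] += 1
                if new > NEG_INF:
                    delta = (
                        new
                        - cur
                        + (lam_shape - 1.0) * (np.log(prop) - np.log(c[u]))
                        - (prop - c[u]) / lam_scale
                        + np.log(prop)
                        - np.log(c[u])
                    )
                    if np.log(rng.random()) < delta:
                        c[u] = prop
                        win_c_acc[u] += 1
            else:
                c[u] = rng.gamma(lam_shape, lam_scale)

        # (iv) sample dispersion
        c_of_locus = c[z]
        cur = bb_loglik_assigned(y, m, const, n, c_of_locus, s_tilde)
        prop = s_tilde * np.exp(s_step * rng.standard_normal())
        new = bb_loglik_assigned(y, m, const, n, c_of_locus, prop)
        win["s"][1] += 1
        if new > NEG_INF:
            delta = (
                new
                - cur
                + om_shape * (np.log(prop) - np.log(s_tilde))  # prior + jacobian
                - (prop - s_tilde) / om_scale
            )
            if np.log(rng.random()) < delta:
                s_tilde = prop
                win["s"][0] += 1

        # (v) rho and (alpha + kappa)
        cur_td = trans_log_density(pi, pi0, beta, rho, apk)
        logit_rho = np.log(rho) - np.log1p(-rho)
        rho_new = 1.0 / (1.0 + np.exp(-(logit_rho + rho_step * rng.standard_normal())))
        new_td = trans_log_density(pi, pi0, beta, rho_new, apk)
        delta = (
            new_td
            - cur_td
            + rho_a * (np.log(rho_new) - np.log(rho))  # Beta prior + jacobian
            + rho_b * (np.log1p(-rho_new) - np.log1p(-rho))
        )
        win["rho"][1] += 1
        if np.log(rng.random()) < delta:
            rho = rho_new
            cur_td = new_td
            win["rho"][0] += 1

        apk_new = apk * np.exp(apk_step * rng.standard_normal())
        new_td = trans_log_density(pi, pi0, beta, rho, apk_new)
        delta = (
            new_td
            - cur_td
            + apk_shape * (np.log(apk_new) - np.log(apk))  # prior + jacobian
            - (apk_new - apk) / apk_scale
        )
        win["apk"][1] += 1
        if np.log(rng.random()) < delta:
            apk = apk_new
            win["apk"][0] += 1

        if it < burn and (it + 1) % adapt_window == 0:
            tried = np.maximum(win_c_try, 1.0)
            c_step *= np.exp(0.3 * (win_c_acc / tried - 0.3))
            win_c_acc[:] = 0
            win_c_try[:] = 0
            for key, step_name in (("s", "s_step"), ("rho", "rho_step"), ("apk", "apk_step")):
                acc, tot = win[key]
                if tot:
                    factor = np.exp(0.3 * (acc / tot - 0.3))
                    if key == "s":
                        s_step *= factor
                    elif key == "rho":
                        rho_step *= factor
                    else:
                        apk_step *= factor
                win[key] = [0, 0]

        if it >= burn and (it - burn) % thin == 0 and stored < n_store:
            out_z[stored] = z
            out_c[stored] = c
            out_beta[stored] = beta
            out_pi[stored] = pi
            out_pi0[stored] = pi0
            out_s[stored] = s_tilde
            out_rho[stored] = rho
            out_apk[stored] = apk
            out_pop[stored] = len(np.unique(z))
            stored += 1

    if np.any(out_pop[:stored] == K_max):
        warnings.warn(
            f"the truncation level K_max={K_max} was fully populated in some "
            "iterations; rerun with a larger K_max",
            RuntimeWarning,
        )
    return RCNTrace(
        z=out_z[:stored],
        c=out_c[:stored],
        beta=out_beta[:stored],
        pi=out_pi[:stored],
        pi0=out_pi0[:stored],
        s_tilde=out_s[:stored],
        rho=out_rho[:stored],
        alpha_plus_kappa=out_apk[:stored],
        populated_counts=out_pop[:stored],
        settings={
            "iters": iters,
            "burn": burn,
            "thin": thin,
            "K_max": K_max,
            "seed": seed,
        },
        loci=loci.copy() if loci is not None else None,
    )


def log_joint(
    draw: ChainDraw,
    y: np.ndarray,
    arms: Sequence[str],
    bias: BiasModel | np.ndarray,
    hp: Hyperparams | None = None,
) -> float:
    """Log joint density of one chain state under the weak-limit model.

    Sum of the arm-wise chain terms, the theta-marginalised emissions and
    the fully-normalised prior densities for c, s~, rho, (alpha+kappa),
    beta and the transition rows.  Returns -inf when the draw violates
    c*m < 1 at an assigned locus.
    """
    hp = hp or Hyperparams()
    y = np.asarray(y, dtype=np.int64)
    m = bias.m_hat if isinstance(bias, BiasModel) else np.asarray(bias, dtype=float)
    n = float(y.sum())
    K = len(draw.c)
    const = gammaln(n + 1.0) - gammaln(y + 1.0) - gammaln(n - y + 1.0)
    em = bb_loglik_assigned(y, m, const, n, draw.c[draw.z], draw.s_tilde)
    if em <= NEG_INF:
        return -np.inf
    total = em
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.maximum(draw.pi, 1e-300))
        log_pi0 = np.log(np.maximum(draw.pi0, 1e-300))
    for idx in _arm_slices(arms):
        zz = draw.z[idx]
        total += log_pi0[zz[0]]
        total += log_pi[zz[:-1], zz[1:]].sum()
    def gamma_logpdf(x, shape, scale):
        return (shape - 1.0) * np.log(x) - x / scale - gammaln(shape) - shape * np.log(scale)

    lam_shape, lam_scale = hp.lam
    total += gamma_logpdf(draw.c, lam_shape, lam_scale).sum()
    om_shape, om_scale = hp.omega
    total += gamma_logpdf(draw.s_tilde, om_shape, om_scale)
    rho_a, rho_b = hp.rho
    total += (rho_a - 1.0) * np.log(draw.rho) + (rho_b - 1.0) * np.log1p(-draw.rho)
    total -= betaln(rho_a, rho_b)
    apk_shape, apk_scale = hp.alpha_plus_kappa
    total += gamma_logpdf(draw.alpha_plus_kappa, apk_shape, apk_scale)
    alpha = (1.0 - draw.rho) * draw.alpha_plus_kappa
    kappa = draw.rho * draw.alpha_plus_kappa
    total += _log_dirichlet_pdf(draw.beta, np.full(K, hp.gamma / K))
    total += _log_dirichlet_pdf(draw.pi0, np.maximum(alpha * draw.beta, 1e-12))
    for u in range(K):
        a = alpha * draw.beta
        a = a.copy()
        a[u] += kappa
        total += _log_dirichlet_pdf(draw.pi[u], np.maximum(a, 1e-12))
    return float(total)
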