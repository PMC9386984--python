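"""Posterior summaries of a copy-number trace.

Two summaries are produced, mirroring how the sampler's output is used:

1. a *marginal* profile: the state labels are marginalised out and each
   locus gets the posterior mode (kernel-density MAP) and an equal-tailed
   credible interval of its relative copy number;
2. a *state* profile: the modal number of populated states is found,
   iterations with exactly that many populated states are retained, the
   label-switching ambiguity is resolved (Stephens' relabeling with each
   assignment step solved by the Hungarian algorithm), and per-state MAP
   RCN values plus per-locus modal state assignments are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .control_fit import density_mode
from .rcn_infer import RCNTrace

__all__ = [
    "RCNProfile",
    "RelabeledTrace",
    "marginal_profile",
    "map_state_count",
    "filter_iterations",
    "relabel_states",
    "state_profile",
]


@dataclass
class RCNProfile:
    """Per-locus MAP RCN with credible intervals, plus optional state summary.

    ``per_locus`` columns: map_rcn, ci_lo, ci_hi (and state for the
    state-based method).  ``per_state`` columns (state method only):
    state, map_rcn, ci_lo, ci_hi.
    """

    per_locus: pd.DataFrame
    n_states: int
    method: str
    ci_level: float
    per_state: pd.DataFrame | None = None
    loci: pd.DataFrame | None = None

    def to_tsv(self, path) -> None:
        df = self.per_locus
        if self.loci is not None:
            df = pd.concat([self.loci.reset_index(drop=True), df], axis=1)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class RelabeledTrace:
    """Sub-trace with exactly k populated states, labels made consistent.

    ``z`` holds compact labels 0..k-1; ``c`` is (T, k); ``pi`` (T, k, k) the
    transition rows/columns restricted to the populated states.
    """

    z: np.ndarray
    c: np.ndarray
    pi: np.ndarray
    k: int


def _ci(samples: np.ndarray, level: float) -> tuple[float, float]:
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [tail, 1.0 - tail])
    return float(lo), float(hi)


def marginal_profile(trace: RCNTrace, ci_level: float = 0.95) -> RCNProfile:
    """State-marginalised per-locus summary.

    For each locus the draws of its assigned state's RCN are collected
    across the stored chain; the MAP is a kernel-density mode and the
    credible interval the equal-tailed quantiles at ``ci_level``.
    """
    if trace.n_stored == 0:
        raise ValueError("empty trace")
    draws = trace.locus_rcn_draws()  # (T, L)
    L = draws.shape[1]
    map_rcn = np.array([density_mode(draws[:, l]) for l in range(L)])
    tail = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(draws, [tail, 1.0 - tail], axis=0)
    # the KDE mode can sit a hair outside the quantile band on tiny traces
    lo = np.minimum(lo, map_rcn)
    hi = np.maximum(hi, map_rcn)
    per_locus = pd.DataFrame({"map_rcn": map_rcn, "ci_lo": lo, "ci_hi": hi})
    return RCNProfile(
        per_locus=per_locus,
        n_states=int(map_state_count(trace)),
        method="marginal",
        ci_level=ci_level,
        loci=trace.loci,
    )


def map_state_count(trace: RCNTrace) -> int:
    """Most frequent populated-state count across draws; ties to the smaller."""
    if trace.n_stored == 0:
        raise ValueError("empty trace")
    counts = np.bincount(trace.populated_counts)
    return int(np.argmax(counts))  # argmax takes the first (smallest) maximiser


def filter_iterations(trace: RCNTrace, k: int) -> RCNTrace:
    """Draws whose populated-state count is exactly k, order preserved."""
    if k < 1:
        raise ValueError("k must be at least 1")
    keep = trace.populated_counts == k
    if not keep.any():
        raise ValueError(
            f"no stored iteration has {k} populated states; run a longer chain"
        )
    return RCNTrace(
        z=trace.z[keep],
        c=trace.c[keep],
        beta=trace.beta[keep],
        pi=trace.pi[keep],
        pi0=trace.pi0[keep],
        s_tilde=trace.s_tilde[keep],
        rho=trace.rho[keep],
        alpha_plus_kappa=trace.alpha_plus_kappa[keep],
        populated_counts=trace.populated_counts[keep],
        settings=dict(trace.settings),
        loci=trace.loci,
    )


def _compact(trace: RCNTrace, k: int) -> RelabeledTrace:
    """Map each draw's populated states onto 0..k-1 (ascending original index)."""
    T, L = trace.z.shape
    z = np.empty((T, L), dtype=np.int64)
    c = np.empty((T, k))
    pi = np.empty((T, k, k))
    for t in range(T):
        states = np.unique(trace.z[t])
        if len(states) != k:
            raise ValueError("every draw must have exactly k populated states")
        lut = {int(s): a for a, s in enumerate(states)}
        z[t] = np.vectorize(lut.get)(trace.z[t])
        c[t] = trace.c[t, states]
        pi[t] = trace.pi[t][np.ix_(states, states)]
    return RelabeledTrace(z=z, c=c, pi=pi, k=k)


def relabel_states(trace: RCNTrace, k: int, max_rounds: int = 100) -> RelabeledTrace:
    """Resolve label switching over draws with k populated states.

    Stephens' iterative scheme on the hard state assignments: given the
    current labelling, form the average assignment distribution
    ``q_hat[l, b]``; for each draw choose the permutation minimising the
    Kullback-Leibler cost ``-sum_l log q_hat[l, sigma(z[l])]`` via the
    Hungarian algorithm; repeat to a fixed point.  Draws are first aligned
    by sorting states on their RCN value, which already resolves
    well-separated chains and leaves the KL rounds to polish the rest.
    """
    compact = _compact(trace, k)
    T, L = compact.z.shape
    # initial alignment: label states by ascending RCN within each draw
    perms = np.argsort(np.argsort(compact.c, axis=1), axis=1)  # sigma[t, a] -> new label
    eps = 1.0 / (T * k)
    for _ in range(max_rounds):
        z_rel = np.take_along_axis(perms, compact.z, axis=1)  # (T, L) relabeled
        q_hat = np.zeros((L, k))
        for b in range(k):
            q_hat[:, b] = (z_rel == b).mean(axis=0)
        log_q = np.log(q_hat + eps)
        changed = False
        for t in range(T):
            cost = np.zeros((k, k))
            for a in range(k):
                mask = compact.z[t] == a
                cost[a] = -log_q[mask].sum(axis=0)
            _, sigma = linear_sum_assignment(cost)
            if not np.array_equal(sigma, perms[t]):
                perms[t] = sigma
                changed = True
        if not changed:
            break
    else:
        warnings.warn("relabeling did not reach a fixed point; using best found", RuntimeWarning)
    z_rel = np.take_along_axis(perms, compact.z, axis=1)
    c_rel = np.empty_like(compact.c)
    pi_rel = np.empty_like(compact.pi)
    for t in range(T):
        inv = np.argsort(perms[t])
        c_rel[t] = compact.c[t, inv]
        pi_rel[t] = compact.pi[t][np.ix_(inv, inv)]
    return RelabeledTrace(z=z_rel, c=c_rel, pi=pi_rel, k=k)


def state_profile(
    relabeled: RelabeledTrace,
    ci_level: float = 0.95,
    loci: pd.DataFrame | None = None,
) -> RCNProfile:
    """Per-state MAP RCN and credible interval, per-locus modal state.

    Each locus is assigned the relabelled state it occupies most often
    across the filtered draws (ties to the lower state index) and inherits
    that state's MAP RCN and interval.
    """
    k = relabeled.k
    states = []
    for u in range(k):
        lo, hi = _ci(relabeled.c[:, u], ci_level)
        mp = density_mode(relabeled.c[:, u])
        states.append({"state": u, "map_rcn": mp, "ci_lo": min(lo, mp), "ci_hi": max(hi, mp)})
    per_state = pd.DataFrame(states)
    T, L = relabeled.z.shape
    freq = np.zeros((L, k))
    for u in range(k):
        freq[:, u] = (relabeled.z == u).sum(axis=0)
    modal = freq.argmax(axis=1)  # argmax resolves ties to the lower index
    per_locus = pd.DataFrame(
        {
            "map_rcn": per_state["map_rcn"].to_numpy()[modal],
            "ci_lo": per_state["ci_lo"].to_numpy()[modal],
            "ci_hi": per_state["ci_hi"].to_numpy()[modal],
            "state": modal,
        }
    )
    return RCNProfile(
        per_locus=per_locus,
        n_states=k,
        method="states",
        ci_level=ci_level,
        per_state=per_state,
        loci=loci,
    )
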