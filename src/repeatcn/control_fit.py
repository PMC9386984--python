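"""Control-panel inference of the locus bias vector m and dispersions s.

Controls are assumed diploid (relative copy number 1 at every locus), so
their counts identify the amplification bias ``m`` directly.  A
Metropolis-Hastings sampler targets the joint posterior of ``m`` (an
independent Beta prior per locus — no simplex constraint during sampling)
and the per-control inverse dispersions ``s_k`` (Gamma prior), under the
theta-marginalised beta-binomial likelihood.  Point estimates are posterior
modes from a kernel density estimate; the per-locus modes of ``m`` are
rescaled at the end to sum to one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._kernels import control_loglik_matrix
from .countmatrix import CountMatrix
from .model import Hyperparams

__all__ = ["ControlTrace", "BiasModel", "fit_controls", "density_mode", "summarise_bias"]


@dataclass
class ControlTrace:
    """Thinned post-burn-in draws of (m, s) plus run settings."""

    m: np.ndarray  # (T, L)
    s: np.ndarray  # (T, K)
    iters: int
    burn: int
    thin: int
    seed: int | None
    control_ids: list[str]
    accept_m: float = float("nan")
    accept_s: float = float("nan")
    loci: pd.DataFrame | None = None
    hyperparams: Hyperparams | None = None

    @property
    def n_stored(self) -> int:
        return self.m.shape[0]


@dataclass
class BiasModel:
    """MAP bias vector (rescaled to the simplex) and per-control dispersion modes."""

    m_hat: np.ndarray
    s_hat: np.ndarray
    control_ids: list[str]
    loci: pd.DataFrame | None = None
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.m_hat = np.asarray(self.m_hat, dtype=float)
        if np.any(self.m_hat <= 0):
            raise ValueError("bias estimates must be strictly positive")
        if not np.isclose(self.m_hat.sum(), 1.0):
            raise ValueError("bias estimates must sum to 1 after rescaling")

    def to_tsv(self, path: str | Path) -> None:
        df = self.loci.copy() if self.loci is not None else pd.DataFrame()
        df["m_hat"] = self.m_hat
        df.to_csv(path, sep="\t", index=False)
        side = Path(path).with_suffix(".json")
        side.write_text(
            json.dumps(
                {
                    "s_hat": list(map(float, self.s_hat)),
                    "control_ids": self.control_ids,
                    "settings": self.settings,
                },
                indent=2,
            )
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BiasModel":
        df = pd.read_csv(path, sep="\t")
        side = Path(path).with_suffix(".json")
        meta = json.loads(side.read_text()) if side.exists() else {}
        loci_cols = [c for c in ("chrom", "pos", "strand", "arm") if c in df.columns]
        return cls(
            m_hat=df["m_hat"].to_numpy(),
            s_hat=np.asarray(meta.get("s_hat", []), dtype=float),
            control_ids=meta.get("control_ids", []),
            loci=df[loci_cols] if loci_cols else None,
            settings=meta.get("settings", {}),
        )


def _moment_init_s(x: np.ndarray, n: np.ndarray, m0: np.ndarray) -> np.ndarray:
    """Method-of-moments start for s_k from the count overdispersion factor."""
    K = x.shape[1]
    s0 = np.empty(K)
    for k in range(K):
        mu = n[k] * m0
        binom_var = mu * (1.0 - m0)
        f = np.mean((x[:, k] - mu) ** 2 / np.maximum(binom_var, 1e-12))
        if f <= 1.0:
            s0[k] = 1e8
        else:
            s0[k] = max((n[k] - 1.0) / (f - 1.0) - 1.0, 1.0)
    return s0


def fit_controls(
    cm: CountMatrix,
    control_ids: Sequence[str],
    hp: Hyperparams | None = None,
    iters: int = 20000,
    burn: int = 5000,
    thin: int = 1,
    seed: int | None = None,
    init_m: np.ndarray | None = None,
    init_s: np.ndarray | None = None,
) -> ControlTrace:
    """Metropolis-Hastings sampler for the control model.

    Per iteration every ``m_l`` receives a logit-scale random-walk proposal
    (accepted locus-by-locus — the likelihood factorises over loci given
    ``s``) and every ``s_k`` a log-scale proposal (accepted per control).
    Step sizes adapt toward ~30% acceptance during burn-in and are frozen
    afterwards, so the retained chain is a valid MCMC.
    """
    hp = hp or Hyperparams()
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("at least one control sample is required")
    idx = [cm.samples.index(s) for s in control_ids]
    x = cm.counts[:, idx].astype(np.int64)
    if np.any(x == 0):
        raise ValueError(
            "controls contain zero counts at retained loci; run select_loci first"
        )
    n = x.sum(axis=0).astype(np.float64)
    L, K = x.shape
    if burn >= iters:
        raise ValueError("burn-in must be shorter than the run")

    rng = np.random.default_rng(seed)
    const = (
        gammaln(n[None, :] + 1.0) - gammaln(x + 1.0) - gammaln(n[None, :] - x + 1.0)
    )

    phi_c, phi_d = hp.phi
    psi_shape, psi_scale = hp.psi

    # empirical start: pooled proportions for m, moment-matched s
    m = np.clip(x.sum(axis=1) / n.sum(), 1e-12, 1.0 - 1e-12)
    s = _moment_init_s(x, n, m)
    if init_m is not None:
        m = np.clip(np.asarray(init_m, dtype=float).copy(), 1e-12, 1.0 - 1e-12)
    if init_s is not None:
        s = np.asarray(init_s, dtype=float).copy()

    ll = control_loglik_matrix(x, n, m, s, const)  # (L, K)
    m_step = np.full(L, 0.2)
    s_step = np.full(K, 0.3)
    acc_m = np.zeros(L)
    acc_s = np.zeros(K)
    adapt_window = 50
    win_m = np.zeros(L)
    win_s = np.zeros(K)

    n_store = (iters - burn) // thin
    m_out = np.empty((n_store, L))
    s_out = np.empty((n_store, K))
    stored = 0

    def log_prior_m(mv):
        return (phi_c - 1.0) * np.log(mv) + (phi_d - 1.0) * np.log1p(-mv)

    def log_prior_s(sv):
        return (psi_shape - 1.0) * np.log(sv) - sv / psi_scale

    for it in range(iters):
        # --- per-locus logit random walk on m ---
        logit = np.log(m) - np.log1p(-m)
        prop = logit + m_step * rng.standard_normal(L)
        m_new = 1.0 / (1.0 + np.exp(-prop))
        m_new = np.clip(m_new, 1e-300, 1.0 - 1e-16)
        ll_new = control_loglik_matrix(x, n, m_new, s, const)
        # jacobian of the logit transform: + log m + log(1 - m)
        delta = (
            ll_new.sum(axis=1)
            - ll.sum(axis=1)
            + log_prior_m(m_new)
            - log_prior_m(m)
            + np.log(m_new)
            + np.log1p(-m_new)
            - np.log(m)
            - np.log1p(-m)
        )
        accept = np.log(rng.random(L)) < delta
        m[accept] = m_new[accept]
        ll[accept] = ll_new[accept]
        acc_m += accept
        win_m += accept

        # --- per-control log random walk on s ---
        s_new = s * np.exp(s_step * rng.standard_normal(K))
        ll_new = control_loglik_matrix(x, n, m, s_new, const)
        delta = (
            ll_new.sum(axis=0)
            - ll.sum(axis=0)
            + log_prior_s(s_new)
            - log_prior_s(s)
            + np.log(s_new)
            - np.log(s)
        )
        accept = np.log(rng.random(K)) < delta
        s[accept] = s_new[accept]
        ll[:, accept] = ll_new[:, accept]
        acc_s += accept
        win_s += accept

        if it < burn and (it + 1) % adapt_window == 0:
            rate_m = win_m / adapt_window
            m_step *= np.exp(0.3 * (rate_m - 0.3))
            win_m[:] = 0.0
            rate_s = win_s / adapt_window
            s_step *= np.exp(0.3 * (rate_s - 0.3))
            win_s[:] = 0.0

        if it >= burn and (it - burn) % thin == 0 and stored < n_store:
            m_out[stored] = m
            s_out[stored] = s
            stored += 1

    return ControlTrace(
        m=m_out[:stored],
        s=s_out[:stored],
        iters=iters,
        burn=burn,
        thin=thin,
        seed=seed,
        control_ids=control_ids,
        accept_m=float(acc_m.mean() / iters),
        accept_s=float(acc_s.mean() / iters),
        loci=cm.loci.copy(),
        hyperparams=hp,
    )


def density_mode(samples: np.ndarray, grid_points: int = 401) -> float:
    """Posterior mode via a Gaussian KDE on a fixed grid over the sample range.

    Bandwidth is the Silverman/normal-reference rule
    0.9 min(sd, IQR/1.34) T^{-1/5}.  A constant trace returns the constant.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1 or samples.size == 0:
        raise ValueError("samples must be a non-empty 1-D array")
    sd = samples.std()
    if sd == 0.0:
        return float(samples[0])
    iqr = np.subtract(*np.percentile(samples, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = 0.9 * spread * samples.size ** (-0.2)
    grid = np.linspace(samples.min(), samples.max(), grid_points)
    dens = np.exp(
        -0.5 * ((grid[:, None] - samples[None, :]) / bw) ** 2
    ).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def summarise_bias(trace: ControlTrace) -> BiasModel:
    """Per-locus and per-control posterior modes; m modes rescaled to sum to 1."""
    if trace.n_stored == 0:
        raise ValueError("trace holds no post-burn-in draws")
    m_hat = np.array([density_mode(trace.m[:, l]) for l in range(trace.m.shape[1])])
    m_hat = m_hat / m_hat.sum()
    s_hat = np.array([density_mode(trace.s[:, k]) for k in range(trace.s.shape[1])])
    return BiasModel(
        m_hat=m_hat,
        s_hat=s_hat,
        control_ids=trace.control_ids,
        loci=trace.loci,
        settings={
            "iters": trace.iters,
            "burn": trace.burn,
            "thin": trace.thin,
            "seed": trace.seed,
        },
    )
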