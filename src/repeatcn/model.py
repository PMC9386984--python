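"""Core probability model: beta-binomial count emissions and hyperparameters.

The observation model for a count ``y`` at a locus is a binomial draw whose
success probability is itself beta-distributed:

    theta ~ Beta(s * c * m, s * (1 - c * m))
    y     ~ Binomial(n, theta)

where ``m`` is the locus count-proportion bias (the expected fraction of
aligned reads at the locus in a diploid control), ``c`` the relative copy
number and ``s`` an inverse-dispersion concentration: as ``s`` grows the
beta collapses onto its mean ``c * m`` and a plain binomial noise model is
recovered.  ``theta`` is always integrated out analytically, giving a
beta-binomial likelihood; theta is never sampled in any of the samplers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np
from scipy.special import gammaln


class DomainError(ValueError):
    """Raised when emission parameters leave the valid domain (c*m outside (0,1))."""


@dataclass
class Hyperparams:
    """Prior settings shared by the control fit and the copy-number sampler.

    All Gamma distributions are parameterised by (shape, scale).

    Attributes
    ----------
    psi : (shape, scale) of the Gamma prior on a control sample's inverse
        dispersion ``s_k``.
    phi : (c, d) of the Beta prior on each locus bias ``m_l``; the flat
        Beta(1, 1) default leaves ``m`` data-driven.
    gamma : concentration of the stick-breaking (GEM) prior on the global
        state weights; larger values favour more copy-number states.
    alpha_plus_kappa : (shape, scale) of the Gamma prior on the total
        transition concentration (alpha + kappa).
    rho : (a, b) of the Beta prior on the self-transition weight
        rho = kappa / (alpha + kappa); the default concentrates near
        rho ~ 0.999, encoding strong spatial persistence of states.
    lam : (shape, scale) of the Gamma base distribution H over the relative
        copy number of a hidden state.
    omega : (shape, scale) of the Gamma prior on the profiled sample's
        inverse dispersion ``s~``.
    """

    psi: Tuple[float, float] = (1.5, 1e6)
    phi: Tuple[float, float] = (1.0, 1.0)
    gamma: float = 1.0
    alpha_plus_kappa: Tuple[float, float] = (2000.0, 10.0)
    rho: Tuple[float, float] = (100000.0, 100.0)
    lam: Tuple[float, float] = (3.0, 1.0)
    omega: Tuple[float, float] = (1.5, 1e6)

    def __post_init__(self) -> None:
        for name in ("psi", "phi", "alpha_plus_kappa", "rho", "lam", "omega"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValueError(f"hyperparameter {name} must be positive, got {(a, b)}")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparams":
        kw = {k: tuple(v) if isinstance(v, (list, tuple)) else v for k, v in d.items()}
        return cls(**kw)


@dataclass
class EmissionParams:
    """Bundle of emission-side parameters for one sample.

    ``m`` is the full bias vector over retained loci (sums to 1), ``c`` the
    per-locus relative copy number, ``s`` the sample inverse dispersion and
    ``n`` the sample's total aligned reads.
    """

    s: float
    m: np.ndarray
    c: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.s <= 0:
            raise ValueError("inverse dispersion s must be positive")
        if self.m.shape != self.c.shape:
            raise ValueError("m and c must have equal length")

    @property
    def valid(self) -> bool:
        return validate_mean_constraint(self.c, self.m)


def _log_rising(x, k):
    """log of the rising factorial x (x+1) ... (x+k-1) for integer k >= 0.

    Uses lgamma(x+k) - lgamma(x) in the ordinary regime.  When x is several
    orders of magnitude larger than k that difference loses precision to
    cancellation, so an asymptotic expansion in k/x is used instead:

        sum_{i<k} log(x + i) = k log x + S1/x - S2/(2 x^2) + S3/(3 x^3) + ...

    with S_j = sum_{i<k} i^j in closed form.  The truncation error at the
    switch point x/k = 1e4 is below 1e-12, far under what the lgamma route
    achieves there.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(k, dtype=float)
    x, k = np.broadcast_arrays(x, k)
    out = np.zeros(x.shape, dtype=float)
    pos = k > 0
    big = pos & (x > 1e4 * k)
    ordinary = pos & ~big
    if np.any(ordinary):
        xo, ko = x[ordinary], k[ordinary]
        out[ordinary] = gammaln(xo + ko) - gammaln(xo)
    if np.any(big):
        xb, kb = x[big], k[big]
        s1 = kb * (kb - 1.0) / 2.0
        s2 = (kb - 1.0) * kb * (2.0 * kb - 1.0) / 6.0
        s3 = s1 * s1
        out[big] = kb * np.log(xb) + s1 / xb - s2 / (2.0 * xb**2) + s3 / (3.0 * xb**3)
    return out


def betabinom_logpmf(y, n, c, m, s):
    """Log-pmf of the beta-binomial count model with theta marginalised.

    Parameters broadcast against each other.  ``y`` is the observed count,
    ``n`` the sample total, and the beta parameters are
    ``(s*c*m, s*(1 - c*m))``.  For integer counts the pmf is evaluated
    through log-rising-factorials,

        log C(n, y) + logrf(a, y) + logrf(b, n - y) - logrf(a + b, n),

    which stays accurate in the near-binomial limit of very large ``s``
    (where formulations that difference two log-beta values lose the
    signal to rounding).

    Raises
    ------
    DomainError
        if ``c * m`` lies outside the open interval (0, 1), i.e. the
        implied beta parameters are not both positive.
    """
    y = np.asarray(y)
    n = np.asarray(n)
    cm = np.asarray(c, dtype=float) * np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(cm <= 0.0) or np.any(cm >= 1.0):
        raise DomainError("c*m must lie strictly inside (0, 1)")
    if np.any(s <= 0.0):
        raise DomainError("s must be positive")
    if np.any((y < 0) | (y > n)):
        raise ValueError("counts must satisfy 0 <= y <= n")
    a = s * cm
    b = s * (1.0 - cm)
    yf = np.asarray(y, dtype=float)
    nf = np.asarray(n, dtype=float)
    log_binom = gammaln(nf + 1.0) - gammaln(yf + 1.0) - gammaln(nf - yf + 1.0)
    out = log_binom + _log_rising(a, yf) + _log_rising(b, nf - yf) - _log_rising(s, nf)
    return out if out.shape else float(out)


def expected_count(n, c, m):
    """Expected count at a locus: n * c * m."""
    return np.asarray(n, dtype=float) * np.asarray(c, dtype=float) * np.asarray(m, dtype=float)


def count_variance(n, s, mu):
    """Variance of a count as a quadratic in its mean mu.

    The beta-binomial variance n p q (s+n)/(s+1) with p = mu/n rearranges to

        Var(y) = (1 + (n-1)/(s+1)) * (mu - mu^2 / n),

    i.e. the binomial variance inflated by the overdispersion factor
    (s+n)/(s+1).  In the limit s -> inf the binomial variance
    mu (1 - mu/n) is recovered.
    """
    n = np.asarray(n, dtype=float)
    s = np.asarray(s, dtype=float)
    mu = np.asarray(mu, dtype=float)
    over = 1.0 + (n - 1.0) / (s + 1.0)
    return over * (mu - mu**2 / n)


def validate_mean_constraint(c, m) -> bool:
    """True iff 0 < c_l * m_l < 1 at every locus (both beta parameters positive)."""
    cm = np.asarray(c, dtype=float) * np.asarray(m, dtype=float)
    return bool(np.all(cm > 0.0) and np.all(cm < 1.0))
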