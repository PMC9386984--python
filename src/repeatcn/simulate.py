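"""Synthetic count data drawn from the package's own generative model.

Every inference stage can be exercised without real sequencing data:
control-panel counts come from the diploid control model (bias ``m``,
inverse dispersion ``s``), copy-number samples from the arm-wise
piecewise-constant profile model, and tumour-purity dilution series from
count-level mixing of a tumour column with a control pool.

Dilution operates on counts rather than raw reads: subsampling reads
without replacement and re-counting per locus is, under unique alignment,
exactly a multivariate hypergeometric draw on the per-locus counts, so the
two routes agree in distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .countmatrix import CountMatrix, load_arm_table, sort_loci

__all__ = [
    "SegmentSpec",
    "DilutionSpec",
    "synthetic_loci",
    "simulate_bias",
    "simulate_control_counts",
    "simulate_rcn_sample",
    "simulate_study",
    "dilution_reads",
    "mix_counts",
]


@dataclass(frozen=True)
class DilutionSpec:
    """Target of one in-silico dilution.

    ``source_purity`` is the undiluted tumour sample's purity (the role the
    upstream caller's purity estimate plays for real data); reads drawn from
    that sample are "tumour reads" in the purity bookkeeping even though a
    fraction of them is normal DNA.
    """

    desired_purity: float
    required_total_reads: int
    source_purity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.desired_purity <= 1.0:
            raise ValueError("desired_purity must be in [0, 1]")
        if not 0.0 < self.source_purity <= 1.0:
            raise ValueError("source_purity must be in (0, 1]")
        if self.desired_purity > self.source_purity:
            raise ValueError(
                "cannot dilute upward: desired purity exceeds the source sample's purity"
            )
        if self.required_total_reads <= 0:
            raise ValueError("required_total_reads must be positive")


#: Per-arm-agnostic segment specification: an ordered list of
#: (number of loci, true RCN) pairs that must tile the loci exactly.
SegmentSpec = Sequence[tuple[int, float]]


def _check_segments(segments: SegmentSpec, L: int) -> None:
    if any(n <= 0 for n, _ in segments):
        raise ValueError("segment locus counts must be positive")
    if any(c < 0 for _, c in segments):
        raise ValueError("segment RCN values must be non-negative")
    total = sum(n for n, _ in segments)
    if total != L:
        raise ValueError(f"segments cover {total} loci but the sample has {L}")


def segments_to_rcn(segments: SegmentSpec, L: int) -> np.ndarray:
    """Expand (n_loci, rcn) pairs into a per-locus piecewise-constant vector."""
    _check_segments(segments, L)
    return np.concatenate([np.full(n, c, dtype=float) for n, c in segments])


def synthetic_loci(L: int, arms: Sequence[str] | None = None, seed: int | None = None) -> pd.DataFrame:
    """Scatter L loci across chromosome arms of the packaged GRCh38 table.

    Loci are split as evenly as possible over ``arms`` (default: both arms
    of chr1-chr4), with sorted uniform positions inside each arm interval.
    """
    if arms is None:
        arms = ["1p", "1q", "2p", "2q", "3p", "3q", "4p", "4q"]
    rng = np.random.default_rng(seed)
    table = load_arm_table().set_index("arm")
    rows = []
    base, extra = divmod(L, len(arms))
    for i, arm in enumerate(arms):
        k = base + (1 if i < extra else 0)
        if k == 0:
            continue
        b = table.loc[arm]
        pos = np.sort(rng.choice(np.arange(b["start"] + 1, b["end"] + 1), size=k, replace=False))
        strands = rng.choice(["+", "-"], size=k)
        for p, st in zip(pos, strands):
            rows.append({"chrom": b["chrom"], "pos": int(p), "strand": st, "arm": arm})
    return sort_loci(pd.DataFrame(rows))


def simulate_bias(
    L: int,
    seed: int | None = None,
    dist: str = "lognormal",
    sigma: float = 1.0,
    phi: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Draw a locus count-proportion bias vector (strictly positive, sums to 1).

    The default log-normal generator (sigma on the log scale) reproduces the
    orders-of-magnitude spread in per-locus amplification efficiency seen in
    repeat-amplicon data; ``dist="beta"`` instead draws independent
    Beta(phi) biases and normalises them.
    """
    if L < 2:
        raise ValueError("need at least two loci")
    rng = np.random.default_rng(seed)
    if dist == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=sigma, size=L)
    elif dist == "beta":
        raw = rng.beta(phi[0], phi[1], size=L)
        raw = np.clip(raw, 1e-12, None)
    else:
        raise ValueError(f"unknown bias distribution {dist!r}")
    return raw / raw.sum()


def simulate_control_counts(
    m: np.ndarray, s: float, n: int, seed: int | None = None
) -> np.ndarray:
    """Counts for one diploid control: theta_l ~ Beta(s m_l, s(1-m_l)), y_l ~ Bin(n, theta_l)."""
    m = np.asarray(m, dtype=float)
    if not np.isclose(m.sum(), 1.0):
        raise ValueError("bias vector must sum to 1")
    if s <= 0 or n <= 0:
        raise ValueError("s and n must be positive")
    rng = np.random.default_rng(seed)
    theta = rng.beta(s * m, s * (1.0 - m))
    return rng.binomial(n, theta)


def simulate_rcn_sample(
    m: np.ndarray,
    s_tilde: float,
    n: int,
    segments: SegmentSpec,
    purity: float = 1.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Counts plus true per-locus RCN for a piecewise-constant profile.

    The tumour profile in ``segments`` is mixed with a diploid background,
    ``c_eff = purity * c + (1 - purity)``, then rescaled so that
    ``sum(c_eff * m) = 1`` — pinning the profile to the "relative to the
    sample mean" scale the model infers.  Returns (counts, true rescaled RCN).
    """
    m = np.asarray(m, dtype=float)
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must be in [0, 1]")
    c = segments_to_rcn(segments, len(m))
    c_eff = purity * c + (1.0 - purity)
    c_eff = c_eff / np.dot(c_eff, m)
    cm = c_eff * m
    if np.any(cm >= 1.0):
        raise ValueError("c*m >= 1 at some locus; bias too concentrated for this profile")
    rng = np.random.default_rng(seed)
    theta = rng.beta(s_tilde * cm, s_tilde * (1.0 - cm))
    y = rng.binomial(n, theta)
    return y, c_eff


def simulate_study(
    L: int,
    n_controls: int,
    reads: int,
    s: float,
    seed: int,
    segments: SegmentSpec | None = None,
    purity: float = 1.0,
    s_tilde: float | None = None,
    arms: Sequence[str] | None = None,
    bias_sigma: float = 1.0,
) -> tuple[CountMatrix, np.ndarray, np.ndarray | None]:
    """Convenience generator: a control panel plus (optionally) one profiled sample.

    Returns (count matrix, true bias m, true RCN of the profiled sample or
    None).  Controls are named ``ctrl0..``; the profiled sample ``tumour``.
    """
    rng = np.random.default_rng(seed)
    loci = synthetic_loci(L, arms=arms, seed=int(rng.integers(2**31)))
    m = simulate_bias(L, seed=int(rng.integers(2**31)), sigma=bias_sigma)
    cols, names = [], []
    for k in range(n_controls):
        cols.append(simulate_control_counts(m, s, reads, seed=int(rng.integers(2**31))))
        names.append(f"ctrl{k}")
    truth = None
    if segments is not None:
        st = s if s_tilde is None else s_tilde
        y, truth = simulate_rcn_sample(
            m, st, reads, segments, purity, seed=int(rng.integers(2**31))
        )
        cols.append(y)
        names.append("tumour")
    cm = CountMatrix(loci, names, np.column_stack(cols))
    return cm, m, truth


def dilution_reads(spec: DilutionSpec) -> tuple[int, int]:
    """Reads to draw from the tumour sample and the control pool.

    tumour = round(desired_purity * total / source_purity); control = total - tumour.
    """
    tumour = int(round(spec.desired_purity * spec.required_total_reads / spec.source_purity))
    return tumour, spec.required_total_reads - tumour


def mix_counts(
    tumour: np.ndarray,
    control_pool: np.ndarray,
    spec: DilutionSpec,
    seed: int | None = None,
) -> np.ndarray:
    """Count-level dilution: hypergeometric subsamples of each column, summed.

    Subsamples ``tumour_reads`` of the tumour column and ``control_reads``
    of the pool column without replacement, so the output column total is
    exactly ``required_total_reads``.
    """
    tumour = np.asarray(tumour, dtype=np.int64)
    control_pool = np.asarray(control_pool, dtype=np.int64)
    t_reads, c_reads = dilution_reads(spec)
    if tumour.sum() < t_reads:
        raise ValueError(f"tumour column has {tumour.sum()} reads, needs {t_reads}")
    if control_pool.sum() < c_reads:
        raise ValueError(f"control pool has {control_pool.sum()} reads, needs {c_reads}")
    rng = np.random.default_rng(seed)
    t_part = rng.multivariate_hypergeometric(tumour, t_reads, method="marginals")
    c_part = rng.multivariate_hypergeometric(control_pool, c_reads, method="marginals")
    return t_part + c_part
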