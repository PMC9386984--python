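"""Cross-caller copy number comparison math.

Different callers report on different scales: allele-aware WGS callers give
total copy number (TCN) in contiguous segments, read-depth tools give log2
relative copy number in bins or segments, and this package gives relative
copy number (RCN) at discrete loci.  The helpers here put everything on a
common RCN scale — correcting TCN for normal-cell contamination and
dividing by the mean TCN — then summarise at gene level and compare
profiles by rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneInterval",
    "check_segments",
    "tcn_to_rcn",
    "log2_to_rcn",
    "rescale_rcn",
    "gene_rcn_segments",
    "gene_rcn_loci",
    "spearman",
]

SEGMENT_COLS = ["chrom", "start", "end", "value"]


@dataclass(frozen=True)
class GeneInterval:
    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")


def check_segments(segs: pd.DataFrame) -> pd.DataFrame:
    """Validate a segment table (1-based inclusive, non-overlapping per chrom)."""
    missing = [c for c in SEGMENT_COLS if c not in segs.columns]
    if missing:
        raise ValueError(f"segment table lacks columns {missing}")
    if (segs["end"] < segs["start"]).any():
        raise ValueError("segment end < start")
    for chrom, grp in segs.groupby("chrom"):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping segments on {chrom}")
    return segs


def _lengths(segs: pd.DataFrame) -> np.ndarray:
    return (segs["end"] - segs["start"] + 1).to_numpy(dtype=float)


def tcn_to_rcn(segs: pd.DataFrame, normal: float, weighting: str = "length") -> pd.DataFrame:
    """Convert TCN segments to RCN, correcting for normal contamination.

    RCN_i = ((1 - normal) * TCN_i + normal * 2) / meanTCN, where meanTCN is
    the length-weighted mean TCN (``weighting="length"``) or the unweighted
    mean over loci/fragments (``weighting="loci"``).
    """
    check_segments(segs)
    if not 0.0 <= normal < 1.0:
        raise ValueError("normal contamination must be in [0, 1)")
    tcn = segs["value"].to_numpy(dtype=float)
    if (tcn < 0).any():
        raise ValueError("TCN must be non-negative")
    if weighting == "length":
        w = _lengths(segs)
        mean_tcn = float(np.average(tcn, weights=w))
    elif weighting == "loci":
        mean_tcn = float(tcn.mean())
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if mean_tcn == 0.0:
        raise ValueError("mean TCN is zero")
    out = segs.copy()
    out["value"] = ((1.0 - normal) * tcn + normal * 2.0) / mean_tcn
    return out


def log2_to_rcn(values) -> np.ndarray:
    """Exponentiate log2-RCN caller output back to the RCN scale."""
    return np.exp2(np.asarray(values, dtype=float))


def rescale_rcn(values) -> np.ndarray:
    """Divide by the mean over the considered loci, so the subset mean is 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value vector")
    mean = v.mean()
    if mean <= 0.0:
        raise ValueError("mean RCN must be positive")
    return v / mean


def gene_rcn_segments(segs: pd.DataFrame, gene: GeneInterval) -> float:
    """Overlap-length-weighted mean RCN of the segments covering a gene.

    Returns NaN (flagged by a warning) when no segment overlaps the gene.
    """
    g = segs[segs["chrom"] == gene.chrom]
    start = np.maximum(g["start"].to_numpy(), gene.start)
    end = np.minimum(g["end"].to_numpy(), gene.end)
    lens = (end - start + 1).astype(float)
    hit = lens > 0
    if not hit.any():
        warnings.warn(f"no segment overlaps {gene.gene}", RuntimeWarning)
        return float("nan")
    vals = g["value"].to_numpy(dtype=float)[hit]
    return float(np.average(vals, weights=lens[hit]))


def gene_rcn_loci(loci: pd.DataFrame, gene: GeneInterval, value_col: str = "map_rcn") -> float:
    """Mean RCN over loci inside a gene, with flanking-locus fallback.

    With no in-gene locus, the nearest locus on each side is used (mean of
    the two; one-sided at a chromosome end).  Returns NaN when the
    chromosome is absent from the profile.
    """
    g = loci[loci["chrom"] == gene.chrom].sort_values("pos")
    if g.empty:
        warnings.warn(f"chromosome {gene.chrom} absent from profile", RuntimeWarning)
        return float("nan")
    pos = g["pos"].to_numpy()
    vals = g[value_col].to_numpy(dtype=float)
    inside = (pos >= gene.start) & (pos <= gene.end)
    if inside.any():
        return float(vals[inside].mean())
    flanks = []
    upstream = np.flatnonzero(pos < gene.start)
    if upstream.size:
        flanks.append(vals[upstream[-1]])
    downstream = np.flatnonzero(pos > gene.end)
    if downstream.size:
        flanks.append(vals[downstream[0]])
    return float(np.mean(flanks))


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks on ties); NaN if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 points")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        warnings.warn("zero variance: Spearman correlation undefined", RuntimeWarning)
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)
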