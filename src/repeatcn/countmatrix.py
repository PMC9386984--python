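"""Locus tables and count matrices.

The central container is :class:`CountMatrix`: integer counts at ``L``
genomic loci by ``S`` samples, with each locus identified by
(chromosome, 1-based position, strand) and, once assigned, a chromosome-arm
label.  Arms matter because the copy-number sampler models each arm as an
independent Markov chain.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LOCUS_COLS = ["chrom", "pos", "strand"]

_AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


def _chrom_rank(chrom: str) -> tuple:
    """Sort key placing chr1..chr22 numerically before anything else."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


def is_autosomal(chrom: str) -> bool:
    return chrom in _AUTOSOMES


def sort_loci(loci: pd.DataFrame) -> pd.DataFrame:
    """Return loci sorted by (chromosome, position), chromosomes in natural order."""
    key = loci["chrom"].map(_chrom_rank)
    order = pd.DataFrame({"k": key, "pos": loci["pos"]}).sort_values(["k", "pos"]).index
    return loci.loc[order].reset_index(drop=True)


def load_arm_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a chromosome-arm boundary table (BED-like, half-open 0-based).

    Columns: chrom, start, end, arm.  With no path, the packaged GRCh38
    table (autosomes, centromere-split p/q arms) is returned.
    """
    if path is None:
        ref = resources.files("repeatcn.data") / "grch38_arms.tsv"
        with resources.as_file(ref) as p:
            tab = pd.read_csv(p, sep="\t")
    else:
        tab = pd.read_csv(path, sep="\t")
    expected = {"chrom", "start", "end", "arm"}
    if not expected.issubset(tab.columns):
        raise ValueError(f"arm table must have columns {sorted(expected)}")
    return tab


def assign_arms(loci: pd.DataFrame, arm_bounds: pd.DataFrame) -> pd.DataFrame:
    """Label every locus with its chromosome arm and restore genomic order.

    ``arm_bounds`` intervals are half-open on the 0-based scale, so a locus
    with 1-based position ``pos`` falls in the arm with
    ``start <= pos - 1 < end``.  A locus outside every interval of its
    chromosome is an error (the arm table must cover all loci).
    """
    loci = sort_loci(loci.copy())
    arms = np.empty(len(loci), dtype=object)
    arms[:] = None
    for chrom, grp in loci.groupby("chrom", sort=False):
        bounds = arm_bounds[arm_bounds["chrom"] == chrom]
        pos0 = grp["pos"].to_numpy() - 1
        for _, row in bounds.iterrows():
            inside = (pos0 >= row["start"]) & (pos0 < row["end"])
            arms[grp.index[inside]] = row["arm"]
    missing = pd.isna(arms)
    if missing.any():
        bad = loci.loc[missing, LOCUS_COLS].head(10)
        raise ValueError(
            f"{int(missing.sum())} loci fall outside every arm interval, e.g.\n{bad}"
        )
    loci["arm"] = arms
    return loci


@dataclass
class CountMatrix:
    """Counts at L loci by S samples.

    ``loci`` carries chrom/pos/strand (and optionally arm); ``counts`` is an
    integer L x S array aligned with ``loci`` rows and ``samples`` columns.
    """

    loci: pd.DataFrame
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.loci), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def totals(self) -> np.ndarray:
        """Per-sample totals n_j over the retained loci (column sums)."""
        return self.counts.sum(axis=0)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        try:
            j = self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None
        return self.counts[:, j]

    def subset_samples(self, ids: Sequence[str]) -> "CountMatrix":
        idx = [self.samples.index(s) for s in ids]
        return CountMatrix(self.loci.copy(), list(ids), self.counts[:, idx])

    def to_frame(self) -> pd.DataFrame:
        out = self.loci[[c for c in ("chrom", "pos", "strand", "arm") if c in self.loci]].copy()
        for j, s in enumerate(self.samples):
            out[s] = self.counts[:, j]
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = [c for c in ("chrom", "pos", "strand", "arm") if c in df.columns]
        samples = [c for c in df.columns if c not in meta]
        loci = df[meta].copy()
        counts = df[samples].to_numpy(dtype=np.int64)
        return cls(loci, samples, counts)


def build_count_matrix(per_sample: dict) -> CountMatrix:
    """Assemble the count matrix over the union of loci across samples.

    ``per_sample`` maps sample id -> iterable of ((chrom, pos, strand), count)
    pairs, one per uniquely-aligned unique sequence.  A sample's count at a
    locus is the sum over its unique sequences aligning there (two distinct
    trimmed sequences may hit the same locus); loci a sample never hits get 0.
    """
    samples = list(per_sample)
    cells: dict[tuple, dict[str, int]] = {}
    for sid, pairs in per_sample.items():
        for locus, count in pairs:
            if count < 0:
                raise ValueError("negative unique-sequence count")
            cells.setdefault(tuple(locus), {}).setdefault(sid, 0)
            cells[tuple(locus)][sid] += int(count)
    loci = sort_loci(
        pd.DataFrame([{"chrom": c, "pos": p, "strand": st} for (c, p, st) in cells])
    )
    counts = np.zeros((len(loci), len(samples)), dtype=np.int64)
    for i, (c, p, st) in enumerate(zip(loci["chrom"], loci["pos"], loci["strand"])):
        row = cells[(c, p, st)]
        for sid, v in row.items():
            counts[i, samples.index(sid)] = v
    return CountMatrix(loci, samples, counts)


def select_loci(cm: CountMatrix, control_ids: Sequence[str]) -> CountMatrix:
    """Retain autosomal loci with a positive count in every control sample.

    Loci on X, Y or unplaced/unresolved contigs are discarded, as is any
    locus with a zero count in any one control.  Per-sample totals are then
    the column sums over the retained loci.
    """
    control_ids = list(control_ids)
    if not control_ids:
        raise ValueError("at least one control sample is required")
    missing = [s for s in control_ids if s not in cm.samples]
    if missing:
        raise KeyError(f"control ids not in matrix: {missing}")
    keep = cm.loci["chrom"].map(is_autosomal).to_numpy()
    ctrl_idx = [cm.samples.index(s) for s in control_ids]
    keep &= (cm.counts[:, ctrl_idx] > 0).all(axis=1)
    loci = cm.loci.loc[keep].reset_index(drop=True)
    return CountMatrix(loci, list(cm.samples), cm.counts[keep])
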