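"""Read processing: FASTQ to per-locus counts.

The amplicon protocol tags every fragment with a single forward primer, so
each read should begin (possibly after a few leading bases) with a near-copy
of that primer followed by genomic sequence from one repeat locus.  The
pipeline stages are:

1. locate the primer as the minimum-Hamming-distance window (reads whose
   best window exceeds 5 mismatches are discarded);
2. trim through the primer and truncate to ``100 - len(primer)`` bases,
   discarding reads left shorter than that;
3. discard reads containing any base under Phred 20 or any ambiguous ``N``;
4. collapse to unique sequences with multiplicities;
5. align the unique sequences externally (unique mappers only) and assemble
   the count matrix over the union of hit loci across samples.

Alignment itself is delegated: :func:`write_unique_fasta` emits the unique
sequences with their counts encoded in the header, and
:func:`read_alignments` consumes either a SAM/BAM file or a 4-column TSV
(seq-id, chrom, 1-based pos, strand) produced by any unique-mapping aligner.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .countmatrix import CountMatrix, build_count_matrix

__all__ = [
    "ReadRecord",
    "PrimerHit",
    "PipelineStats",
    "locate_primer",
    "trim_read",
    "qc_filter",
    "dedup_reads",
    "process_reads",
    "read_fastq",
    "write_unique_fasta",
    "read_alignments",
    "build_count_matrix",
]

_VALID_BASES = set("ACGTN")


@dataclass
class ReadRecord:
    id: str
    sequence: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.id}: negative Phred score")


@dataclass(frozen=True)
class PrimerHit:
    position: int  # 0-based offset of the primer start within the read
    distance: int  # Hamming mismatch count


@dataclass
class PipelineStats:
    """Per-sample read accounting; categories partition the input."""

    total: int = 0
    discarded_primer: int = 0
    discarded_length: int = 0
    discarded_qc: int = 0
    retained: int = 0

    def check_conservation(self) -> bool:
        return (
            self.retained
            + self.discarded_primer
            + self.discarded_length
            + self.discarded_qc
            == self.total
        )


def locate_primer(read: str, primer: str, max_distance: int = 5) -> PrimerHit | None:
    """Best full-overlap primer window by Hamming distance.

    Scans every offset at which the primer fits entirely inside the read and
    returns the leftmost window of minimum mismatch count, or ``None`` when
    that minimum exceeds ``max_distance``.
    """
    if not read or not primer:
        raise ValueError("read and primer must be non-empty")
    if not set(read) <= _VALID_BASES or not set(primer) <= _VALID_BASES:
        raise ValueError("sequences must be uppercase A/C/G/T/N")
    if len(primer) > len(read):
        raise ValueError("primer longer than read")
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(r, len(p))
    dists = (windows != p).sum(axis=1)
    best = int(dists.argmin())  # argmin takes the leftmost tie
    if int(dists[best]) > max_distance:
        return None
    return PrimerHit(position=best, distance=int(dists[best]))


def trim_read(
    read: ReadRecord, hit: PrimerHit, primer_len: int, target_len: int = 100
) -> ReadRecord | None:
    """Drop everything through the primer and truncate to target_len - primer_len.

    Returns ``None`` when fewer than ``target_len - primer_len`` bases remain
    after the primer.
    """
    keep = target_len - primer_len
    if keep <= 0:
        raise ValueError("target_len must exceed the primer length")
    start = hit.position + primer_len
    if len(read.sequence) - start < keep:
        return None
    return ReadRecord(
        id=read.id,
        sequence=read.sequence[start : start + keep],
        qualities=list(read.qualities[start : start + keep]),
    )


def qc_filter(read: ReadRecord, min_phred: int = 20) -> bool:
    """True iff every base has Phred >= min_phred and no base is N."""
    return all(q >= min_phred for q in read.qualities) and "N" not in read.sequence


def dedup_reads(reads: Iterable[str]) -> Counter:
    """Collapse trimmed sequences to unique sequences with multiplicities."""
    return Counter(reads)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Iterate a FASTQ file (Phred+33) as ReadRecords."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            id=rec.id,
            sequence=str(rec.seq).upper(),
            qualities=rec.letter_annotations["phred_quality"],
        )


def process_reads(
    reads: Iterable[ReadRecord],
    primer: str,
    max_distance: int = 5,
    target_len: int = 100,
    min_phred: int = 20,
) -> tuple[Counter, PipelineStats]:
    """Run primer search, trimming, QC and dedup over a read stream."""
    stats = PipelineStats()
    kept: list[str] = []
    plen = len(primer)
    for read in reads:
        stats.total += 1
        if len(read.sequence) < plen:
            stats.discarded_primer += 1
            continue
        hit = locate_primer(read.sequence, primer, max_distance)
        if hit is None:
            stats.discarded_primer += 1
            continue
        trimmed = trim_read(read, hit, plen, target_len)
        if trimmed is None:
            stats.discarded_length += 1
            continue
        if not qc_filter(trimmed, min_phred):
            stats.discarded_qc += 1
            continue
        stats.retained += 1
        kept.append(trimmed.sequence)
    return dedup_reads(kept), stats


def write_unique_fasta(uniq: Counter, path: str | Path) -> None:
    """Write unique sequences as FASTA; header is ``seq<i>_count=<n>``."""
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(sorted(uniq.items())):
            fh.write(f">seq{i}_count={count}\n{seq}\n")


def _count_from_header(name: str) -> int:
    if "_count=" not in name:
        raise ValueError(f"sequence id {name!r} lacks a _count= tag")
    return int(name.rsplit("_count=", 1)[1])


def read_alignments(path: str | Path) -> list[tuple[tuple[str, int, str], int]]:
    """Load unique-sequence alignments as ((chrom, pos, strand), count) pairs.

    Accepts SAM/BAM (positions taken from the 1-based leftmost coordinate,
    strand from the reverse flag, count parsed from the ``_count=`` tag in
    the query name; unmapped and secondary records ignored) or a
    tab-separated table with columns seq-id, chrom, pos (1-based), strand
    where seq-id carries the ``_count=`` tag.
    """
    path = Path(path)
    out: list[tuple[tuple[str, int, str], int]] = []
    if path.suffix.lower() in {".sam", ".bam"}:
        import pysam

        mode = "rb" if path.suffix.lower() == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                strand = "-" if aln.is_reverse else "+"
                locus = (aln.reference_name, aln.reference_start + 1, strand)
                out.append((locus, _count_from_header(aln.query_name)))
    else:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sid, chrom, pos, strand = line.split("\t")[:4]
                out.append(((chrom, int(pos), strand), _count_from_header(sid)))
    return out
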