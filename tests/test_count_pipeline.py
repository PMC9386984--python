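"""Read-processing pipeline: primer search, trimming, QC, dedup, assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from repeatcn.count_pipeline import (
    PipelineStats,
    PrimerHit,
    ReadRecord,
    dedup_reads,
    locate_primer,
    process_reads,
    qc_filter,
    read_alignments,
    read_fastq,
    trim_read,
    write_unique_fasta,
)
from repeatcn.countmatrix import (
    CountMatrix,
    assign_arms,
    build_count_matrix,
    select_loci,
    sort_loci,
)

PRIMER = "ACGTACGTACGTACGTACGT"  # 20 nt


def _hamming_oracle(read: str, primer: str):
    """Exhaustive sliding-window search (the brute-force reference)."""
    best = None
    for off in range(len(read) - len(primer) + 1):
        d = sum(a != b for a, b in zip(read[off : off + len(primer)], primer))
        if best is None or d < best[1]:
            best = (off, d)
    return best


class TestLocatePrimer:
    def test_exact_prefix(self):
        hit = locate_primer(PRIMER + "ACGT", PRIMER)
        assert hit == PrimerHit(position=0, distance=0)

    def test_offset_with_one_substitution(self):
        mutated = "T" + PRIMER[1:]  # one mismatch, still unique best
        read = "GGG" + mutated + "CCCCC"
        hit = locate_primer(read, PRIMER)
        assert (hit.position, hit.distance) == (3, 1)
        assert _hamming_oracle(read, PRIMER) == (3, 1)

    def test_distance_above_threshold_discarded(self):
        # read made of a single repeated base can never be within 5 of the primer
        read = "G" * 60
        assert locate_primer(read, PRIMER) is None

    def test_leftmost_tie_wins(self):
        read = PRIMER + PRIMER
        assert locate_primer(read, PRIMER).position == 0

    @given(st.text(alphabet="ACGT", min_size=25, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_exhaustive_oracle(self, read):
        hit = locate_primer(read, PRIMER, max_distance=len(PRIMER))
        assert (hit.position, hit.distance) == _hamming_oracle(read, PRIMER)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            locate_primer("", PRIMER)
        with pytest.raises(ValueError):
            locate_primer("ACGT", "")


class TestTrimRead:
    def _read(self, seq):
        return ReadRecord("r1", seq, list(range(30, 30 + len(seq))))

    def test_150nt_read_trims_to_80(self):
        read = self._read(PRIMER + "A" * 130)
        out = trim_read(read, PrimerHit(0, 0), primer_len=20, target_len=100)
        assert len(out.sequence) == 80
        assert out.sequence == "A" * 80

    def test_short_remainder_discarded(self):
        read = self._read(PRIMER + "A" * 79)
        assert trim_read(read, PrimerHit(0, 0), primer_len=20) is None

    def test_quality_pairing_preserved(self):
        read = self._read("GG" + PRIMER + "C" * 90)
        out = trim_read(read, PrimerHit(2, 0), primer_len=20)
        assert len(out.sequence) == len(out.qualities) == 80
        # qualities follow their bases through the trim
        assert out.qualities[0] == read.qualities[22]


class TestQcFilter:
    def test_clean_read_passes(self):
        assert qc_filter(ReadRecord("r", "ACGT", [30, 30, 30, 30]))

    def test_low_phred_fails(self):
        assert not qc_filter(ReadRecord("r", "ACGT", [30, 19, 30, 30]))

    def test_ambiguous_base_fails(self):
        assert not qc_filter(ReadRecord("r", "ACNT", [40, 40, 40, 40]))


class TestDedup:
    def test_basic_counts(self):
        assert dict(dedup_reads(["AAA", "AAA", "CCC"])) == {"AAA": 2, "CCC": 1}

    def test_empty(self):
        assert dict(dedup_reads([])) == {}

    @given(st.lists(st.sampled_from(["AA", "AC", "CC", "GT"]), max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_conserves_total_and_idempotent(self, seqs):
        uniq = dedup_reads(seqs)
        assert sum(uniq.values()) == len(seqs)
        again = dedup_reads(list(uniq.elements()))
        assert again == uniq


def _random_fastq(path, rng, n_reads=60):
    genome = "".join(rng.choice(list("ACGT"), 200))
    with open(path, "w") as fh:
        for i in range(n_reads):
            kind = rng.integers(4)
            if kind == 0:  # good read
                start = rng.integers(0, 100)
                seq = PRIMER + genome[start : start + 100]
                quals = "I" * len(seq)
            elif kind == 1:  # hopeless primer
                seq = "".join(rng.choice(list("ACGT"), 120))
                quals = "I" * len(seq)
            elif kind == 2:  # too short after trimming
                seq = PRIMER + genome[:40]
                quals = "I" * len(seq)
            else:  # low quality
                seq = PRIMER + genome[:100]
                quals = "I" * (len(seq) - 1) + "#"
            fh.write(f"@r{i}\n{seq}\n+\n{quals}\n")


class TestProcessReads:
    def test_read_conservation(self, tmp_path):
        rng = np.random.default_rng(0)
        fq = tmp_path / "sample.fastq"
        _random_fastq(fq, rng)
        uniq, stats = process_reads(read_fastq(fq), PRIMER)
        assert stats.check_conservation()
        assert stats.total == 60
        assert sum(uniq.values()) == stats.retained

    def test_deterministic(self, tmp_path):
        rng = np.random.default_rng(1)
        fq = tmp_path / "sample.fastq"
        _random_fastq(fq, rng)
        u1, s1 = process_reads(read_fastq(fq), PRIMER)
        u2, s2 = process_reads(read_fastq(fq), PRIMER)
        assert u1 == u2 and s1 == s2


class TestBuildCountMatrix:
    def test_single_sample(self):
        cm = build_count_matrix(
            {"s1": [(("chr1", 100, "+"), 5), (("chr2", 50, "-"), 7)]}
        )
        assert cm.counts.tolist() == [[5], [7]]

    def test_union_zero_fill_and_totals(self):
        cm = build_count_matrix(
            {
                "s1": [(("chr1", 100, "+"), 5), (("chr1", 200, "+"), 2)],
                "s2": [(("chr1", 100, "+"), 9)],
            }
        )
        assert cm.n_loci == 2
        assert cm.sample_counts("s2").tolist() == [9, 0]
        assert cm.totals.tolist() == [7, 9]

    def test_duplicate_locus_hits_are_summed(self):
        cm = build_count_matrix(
            {"s1": [(("chr1", 100, "+"), 5), (("chr1", 100, "+"), 3)]}
        )
        assert cm.counts.tolist() == [[8]]


class TestSelectLoci:
    def _matrix(self):
        loci = pd.DataFrame(
            {
                "chrom": ["chr1", "chrX", "chr2", "chr3", "chrUn_KI270302v1"],
                "pos": [100, 5, 200, 300, 10],
                "strand": ["+"] * 5,
            }
        )
        counts = np.array(
            [
                [10, 12, 9],
                [5, 5, 5],
                [3, 0, 8],  # zero in one control
                [7, 7, 7],
                [2, 2, 2],
            ]
        )
        return CountMatrix(loci, ["c1", "c2", "t1"], counts)

    def test_selection_rules(self):
        out = select_loci(self._matrix(), ["c1", "c2"])
        assert out.loci["chrom"].tolist() == ["chr1", "chr3"]
        assert out.totals.tolist() == [17, 19, 16]

    def test_positive_autosomal_locus_never_removed(self):
        out = select_loci(self._matrix(), ["c1", "c2"])
        assert ("chr3", 300) in set(zip(out.loci["chrom"], out.loci["pos"]))

    def test_empty_control_set_errors(self):
        with pytest.raises(ValueError):
            select_loci(self._matrix(), [])


class TestAssignArms:
    def _bounds(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 1000],
                "end": [1000, 2000],
                "arm": ["1p", "1q"],
            }
        )

    def test_basic_and_boundary(self):
        loci = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [500, 1001], "strand": ["+", "+"]}
        )
        out = assign_arms(loci, self._bounds())
        # 1-based position 1001 is 0-based 1000, the first base of 1q
        assert out["arm"].tolist() == ["1p", "1q"]

    def test_shuffled_input_restored_to_genomic_order(self):
        loci = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr1"], "pos": [1500, 2, 900], "strand": ["+"] * 3}
        )
        out = assign_arms(loci, self._bounds())
        assert out["pos"].tolist() == [2, 900, 1500]

    def test_locus_outside_arms_errors(self):
        loci = pd.DataFrame({"chrom": ["chr1"], "pos": [5000], "strand": ["+"]})
        with pytest.raises(ValueError, match="outside"):
            assign_arms(loci, self._bounds())


class TestAlignmentIo:
    def test_fasta_and_tsv_roundtrip(self, tmp_path):
        uniq = dedup_reads(["AAAA", "AAAA", "CCCC"])
        fa = tmp_path / "uniq.fasta"
        write_unique_fasta(uniq, fa)
        text = fa.read_text()
        assert ">seq0_count=2" in text and ">seq1_count=1" in text
        tsv = tmp_path / "aln.tsv"
        tsv.write_text("seq0_count=2\tchr1\t100\t+\nseq1_count=1\tchr2\t7\t-\n")
        pairs = read_alignments(tsv)
        assert pairs == [(("chr1", 100, "+"), 2), (("chr2", 7, "-"), 1)]

    def test_sam_parsing(self, tmp_path):
        sam = tmp_path / "aln.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "seq0_count=4\t0\tchr1\t100\t37\t4M\t*\t0\t0\tAAAA\tIIII\n"
            "seq1_count=2\t16\tchr1\t300\t37\t4M\t*\t0\t0\tCCCC\tIIII\n"
            "seq2_count=1\t4\t*\t0\t0\t*\t*\t0\t0\tGGGG\tIIII\n"
        )
        pairs = read_alignments(sam)
        assert (("chr1", 100, "+"), 4) in pairs
        assert (("chr1", 300, "-"), 2) in pairs
        assert len(pairs) == 2  # unmapped record skipped
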