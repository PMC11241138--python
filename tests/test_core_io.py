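"""Domain types, interval arithmetic and file format round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfmirnet.core_io import (
    GenomicInterval,
    ParseError,
    Peak,
    PFMMatrix,
    TSSRecord,
    ValidationError,
    interval_overlap,
    read_bed6,
    read_chrom_sizes,
    read_counts,
    read_fasta,
    read_narrowpeak,
    read_pfm,
    read_target_map,
    read_tss_table,
    write_bed6,
    write_chrom_sizes,
    write_counts,
    write_fasta,
    write_narrowpeak,
    write_pfm,
    write_target_map,
    write_tss_table,
)


def brute_overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Independent oracle: count individual covered base positions."""
    if a.chrom != b.chrom:
        return 0
    return len(set(range(a.start, a.end)) & set(range(b.start, b.end)))


class TestGenomicInterval:
    def test_rejects_inverted_and_negative_coordinates(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 300, 100)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -5, 100)
        with pytest.raises(ValidationError):
            GenomicInterval("", 0, 100)

    def test_length_is_end_minus_start(self):
        assert len(GenomicInterval("chr1", 100, 300)) == 200


class TestIntervalOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 100, 300), ("chr1", 200, 400), 100),
            (("chr1", 100, 200), ("chr1", 200, 300), 0),  # half-open abutment
            (("chr1", 100, 300), ("chr2", 100, 300), 0),  # chrom mismatch
            (("chr1", 0, 1000), ("chr1", 400, 500), 100),  # containment
        ],
    )
    def test_known_cases(self, a, b, expected):
        assert interval_overlap(GenomicInterval(*a), GenomicInterval(*b)) == expected

    def test_matches_per_base_enumeration(self, rng):
        for _ in range(1000):
            chrom_a = f"chr{rng.integers(1, 3)}"
            chrom_b = f"chr{rng.integers(1, 3)}"
            s1, s2 = rng.integers(0, 200, size=2)
            a = GenomicInterval(chrom_a, int(s1), int(s1 + rng.integers(1, 100)))
            b = GenomicInterval(chrom_b, int(s2), int(s2 + rng.integers(1, 100)))
            assert interval_overlap(a, b) == brute_overlap(a, b)
            assert interval_overlap(a, b) == interval_overlap(b, a)

    @settings(deadline=None, derandomize=True)
    @given(
        start=st.integers(0, 10_000),
        length=st.integers(1, 5_000),
    )
    def test_self_overlap_is_length(self, start, length):
        iv = GenomicInterval("chr1", start, start + length)
        assert interval_overlap(iv, iv) == len(iv)


class TestNarrowPeak:
    def test_field_mapping(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr1\t100\t300\tpk1\t0\t.\t5.0\t7.2\t6.1\t50\n")
        (peak,) = read_narrowpeak(path)
        assert peak.interval == GenomicInterval("chr1", 100, 300, ".", "pk1")
        assert peak.neg_log10_p == 7.2
        assert peak.summit_offset == 50
        assert peak.fold_enrichment == 5.0

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.narrowPeak"
        path.write_text("")
        assert read_narrowpeak(path) == []

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.narrowPeak"
        path.write_text(
            "chr1\t100\t300\tpk1\t0\t.\t5.0\t7.2\t6.1\t50\nchr1\t1\t2\n"
        )
        with pytest.raises(ParseError, match="line 2"):
            read_narrowpeak(path)

    def test_negative_coordinate_rejected(self, tmp_path):
        path = tmp_path / "neg.narrowPeak"
        path.write_text("chr1\t-5\t300\tpk1\t0\t.\t5.0\t7.2\t6.1\t50\n")
        with pytest.raises(ValidationError):
            read_narrowpeak(path)

    def test_round_trip_of_random_peaks(self, tmp_path, rng):
        peaks = []
        for i in range(100):
            start = int(rng.integers(0, 10_000))
            width = int(rng.integers(10, 500))
            peaks.append(
                Peak(
                    interval=GenomicInterval(
                        f"chr{rng.integers(1, 4)}", start, start + width, ".", f"p{i}"
                    ),
                    neg_log10_p=round(float(rng.uniform(0, 50)), 4),
                    summit_offset=int(rng.integers(0, width)),
                    fold_enrichment=round(float(rng.uniform(1, 20)), 4),
                )
            )
        path = tmp_path / "rt.narrowPeak"
        write_narrowpeak(peaks, path)
        assert read_narrowpeak(path) == peaks

    def test_chrom_map_normalizes_names(self, tmp_path):
        path = tmp_path / "ens.narrowPeak"
        path.write_text("1\t100\t300\tpk\t0\t.\t2.0\t4.0\t3.0\t-1\n")
        (peak,) = read_narrowpeak(path, chrom_map={"1": "chr1"})
        assert peak.interval.chrom == "chr1"
        assert peak.summit_offset is None


class TestBedAndSizes:
    def test_bed6_round_trip(self, tmp_path, rng):
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + 10, "+", f"x{i}")
            for i, s in enumerate(rng.integers(0, 1000, size=20))
        ]
        path = tmp_path / "a.bed"
        write_bed6(ivs, path)
        assert read_bed6(path) == ivs

    def test_chrom_sizes_round_trip(self, tmp_path):
        sizes = {"chr1": 1_000_000, "chr2": 500_000}
        path = tmp_path / "chrom.sizes"
        write_chrom_sizes(sizes, path)
        assert read_chrom_sizes(path) == sizes


class TestTssTable:
    def test_one_based_input_normalized(self, tmp_path):
        path = tmp_path / "tss.tsv"
        path.write_text(
            "feature_id\tgene_id\tchrom\ttss\tstrand\tbiotype\tcoordinate_base\n"
            "T1\tG1\t1\t1001\t+\tprotein_coding\t1\n"
            "PRI-1\t\tchr2\t500\t-\tpri_mirna\t0\n"
        )
        recs = read_tss_table(path, chrom_map={"1": "chr1"})
        assert recs[0] == TSSRecord("T1", "chr1", 1000, "+", "protein_coding", "G1")
        assert recs[1].position == 500
        assert recs[1].gene_id is None

    def test_round_trip(self, tmp_path):
        recs = [
            TSSRecord("T1", "chr1", 1000, "+", "protein_coding", "G1"),
            TSSRecord("PRI-1", "chr2", 42, "-", "pri_mirna", None),
        ]
        path = tmp_path / "tss.tsv"
        write_tss_table(recs, path)
        assert read_tss_table(path) == recs


class TestPFM:
    def test_single_column_pfm(self, tmp_path):
        path = tmp_path / "one.jaspar"
        path.write_text(">M1 m1\nA [ 4 ]\nC [ 0 ]\nG [ 0 ]\nT [ 0 ]\n")
        pfm = read_pfm(path)
        assert pfm.counts.shape == (4, 1)
        assert pfm.counts[0, 0] == 4

    def test_header_only_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.jaspar"
        path.write_text(">M1 m1\n")
        with pytest.raises(ParseError):
            read_pfm(path)

    def test_unequal_rows_is_format_error(self, tmp_path):
        path = tmp_path / "ragged.jaspar"
        path.write_text(">M1 m1\nA [ 1 2 ]\nC [ 1 ]\nG [ 1 2 ]\nT [ 1 2 ]\n")
        with pytest.raises(ParseError):
            read_pfm(path)

    def test_round_trip(self, tmp_path, rng):
        counts = rng.integers(0, 100, size=(4, 8)).astype(float)
        counts[0] += 1  # ensure positive column sums
        pfm = PFMMatrix(matrix_id="MX0001.1", counts=counts)
        path = tmp_path / "rt.jaspar"
        write_pfm(pfm, path)
        assert read_pfm(path) == pfm

    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            PFMMatrix("M", np.array([[1.0], [1.0], [1.0]]))  # 3 rows
        with pytest.raises(ValidationError):
            PFMMatrix("M", np.zeros((4, 2)))  # zero column sums
        with pytest.raises(ValidationError):
            PFMMatrix("M", np.ones((4, 2)), background=np.array([0.5, 0.5, 0.5, 0.5]))


class TestTables:
    def test_counts_round_trip(self, tmp_path, rng):
        import pandas as pd

        df = pd.DataFrame(
            rng.integers(0, 1000, size=(5, 4)),
            index=[f"G{i}" for i in range(5)],
            columns=["wt_1", "wt_2", "sh_1", "sh_2"],
        )
        path = tmp_path / "counts.tsv"
        write_counts(df, path)
        assert read_counts(path).equals(df)

    def test_target_map_round_trip(self, tmp_path):
        pairs = {("miR-1-5p", "G1"), ("miR-1-5p", "G2"), ("miR-2-3p", "G1")}
        path = tmp_path / "targets.tsv"
        write_target_map(pairs, path)
        assert read_target_map(path) == pairs

    def test_fasta_round_trip(self, tmp_path):
        seqs = {"PRI-1": "ACGTACGT", "PRI-2": "GGGGCCCC"}
        path = tmp_path / "p.fa"
        write_fasta(seqs, path)
        assert read_fasta(path) == seqs
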