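"""Peak assignment thresholds, gene-level merging, marks and PWM scanning."""

import numpy as np
import pytest

from tfmirnet.core_io import (
    GenomicInterval,
    Peak,
    PFMMatrix,
    interval_overlap,
)
from tfmirnet.binding import (
    annotate_marks,
    assign_peaks,
    bound_ids,
    pwm_consensus,
    pwm_log_odds,
    reverse_complement,
    scan_promoter,
)
from tfmirnet.promoters import PromoterRegion


def make_promoter(start, end, parent="T1", gene="G1", chrom="chr1"):
    return PromoterRegion(
        interval=GenomicInterval(chrom, start, end, "+", parent),
        parent_id=parent,
        gene_id=gene,
        biotype="protein_coding",
        halfwidth=2500,
    )


def make_peak(start, end, score, chrom="chr1", name="pk"):
    return Peak(
        interval=GenomicInterval(chrom, start, end, ".", name), neg_log10_p=score
    )


def random_instance(rng, n_prom=5, n_peaks=10, span=2_000):
    promoters = []
    for i in range(n_prom):
        s = int(rng.integers(0, span))
        promoters.append(
            make_promoter(
                s,
                s + int(rng.integers(50, 600)),
                parent=f"T{i}",
                gene=f"G{int(rng.integers(0, 3))}",
                chrom=f"chr{int(rng.integers(1, 3))}",
            )
        )
    peaks = [
        make_peak(
            int(s),
            int(s) + int(rng.integers(10, 400)),
            float(rng.uniform(0.01, 10)),
            chrom=f"chr{int(rng.integers(1, 3))}",
            name=f"pk{j}",
        )
        for j, s in enumerate(rng.integers(0, span, size=n_peaks))
    ]
    return peaks, promoters


def brute_assign(peaks, promoters, min_p, min_ov):
    """Independent all-pairs oracle for the gene-level merge."""
    per_gene = {}
    for prom in promoters:
        per_gene.setdefault(prom.group_id, {})
    for pi, peak in enumerate(peaks):
        for prom in promoters:
            ov = interval_overlap(peak.interval, prom.interval)
            if peak.neg_log10_p > min_p and ov > min_ov:
                g = per_gene[prom.group_id]
                g[pi] = max(g.get(pi, 0), ov)
    return per_gene


class TestAssignPeaks:
    def test_passing_peak_binds(self):
        prom = make_promoter(7_500, 12_500)
        peak = make_peak(9_000, 9_150, score=3.5)  # 150 bp overlap
        (ann,) = assign_peaks([peak], [prom])
        assert ann.bound and ann.n_passing_peaks == 1
        assert ann.total_overlap == 150

    def test_overlap_of_exactly_100_is_excluded(self):
        prom = make_promoter(7_500, 12_500)
        peak = make_peak(7_400, 7_600, score=9.0)  # exactly 100 bp inside
        (ann,) = assign_peaks([peak], [prom])
        assert not ann.bound

    def test_score_of_exactly_3_is_excluded(self):
        prom = make_promoter(7_500, 12_500)
        peak = make_peak(9_000, 9_500, score=3.0)
        (ann,) = assign_peaks([peak], [prom])
        assert not ann.bound

    def test_peak_shared_by_two_transcripts_counts_once_per_gene(self):
        p1 = make_promoter(7_500, 12_500, parent="T1", gene="G1")
        p2 = make_promoter(8_000, 13_000, parent="T2", gene="G1")
        peak = make_peak(9_000, 9_500, score=5.0)
        (ann,) = assign_peaks([peak], [p1, p2])
        assert ann.gene_or_mature_id == "G1"
        assert ann.n_passing_peaks == 1

    def test_gene_level_bound_is_union_of_transcript_level(self, rng):
        for _ in range(50):
            peaks, promoters = random_instance(rng)
            gene_ann = assign_peaks(peaks, promoters, 1.0, 50)
            # transcript-level: same promoters with gene identity removed
            solo = [
                PromoterRegion(p.interval, p.parent_id, None, p.biotype, p.halfwidth)
                for p in promoters
            ]
            tx_ann = assign_peaks(peaks, solo, 1.0, 50)
            tx_bound = bound_ids(tx_ann)
            expected = {
                p.gene_id for p in promoters if p.parent_id in tx_bound
            }
            assert bound_ids(gene_ann) == expected

    def test_matches_brute_force_with_zero_thresholds(self, rng):
        for _ in range(200):
            peaks, promoters = random_instance(rng)
            oracle = brute_assign(peaks, promoters, 0.0, 0)
            anns = {a.gene_or_mature_id: a for a in assign_peaks(peaks, promoters, 0.0, 0)}
            assert set(anns) == set(oracle)
            for g, hits in oracle.items():
                assert anns[g].n_passing_peaks == len(hits)
                assert anns[g].total_overlap == sum(hits.values())
                assert anns[g].bound == bool(hits)

    def test_monotone_in_both_thresholds(self, rng):
        for _ in range(30):
            peaks, promoters = random_instance(rng, n_peaks=20)
            prev = None
            for min_p in (0.0, 2.0, 5.0):
                bound = bound_ids(assign_peaks(peaks, promoters, min_p, 50))
                if prev is not None:
                    assert bound <= prev
                prev = bound
            prev = None
            for min_ov in (0, 100, 300):
                bound = bound_ids(assign_peaks(peaks, promoters, 1.0, min_ov))
                if prev is not None:
                    assert bound <= prev
                prev = bound

    def test_best_peak_maximises_score_then_overlap(self):
        prom = make_promoter(0, 5_000)
        weak = make_peak(0, 1_000, score=4.0, name="weak")
        strong = make_peak(2_000, 2_400, score=9.0, name="strong")
        (ann,) = assign_peaks([weak, strong], [prom])
        assert ann.best_peak.interval.name == "strong"
        assert ann.total_overlap == 1_000 + 400


class TestAnnotateMarks:
    def test_single_base_overlap_counts(self):
        prom = make_promoter(1_000, 2_000)
        k27 = [make_peak(999, 1_001, score=5.0)]  # 1 bp overlap
        k4 = [make_peak(1_200, 1_700, score=5.0)]
        (flags,) = annotate_marks([prom], k27, k4)
        assert flags == (True, True)

    def test_no_chrom_match_means_absent(self):
        prom = make_promoter(1_000, 2_000, chrom="chr1")
        marks = [make_peak(1_000, 2_000, score=5.0, chrom="chr2")]
        (flags,) = annotate_marks([prom], marks, marks)
        assert flags == (False, False)

    def test_matches_nested_loop_oracle(self, rng):
        for _ in range(100):
            _, promoters = random_instance(rng, n_prom=5)
            k27, _ = random_instance(rng, n_peaks=5)
            k4, _ = random_instance(rng, n_peaks=5)
            flags = annotate_marks(promoters, k27, k4)
            for prom, (f27, f4) in zip(promoters, flags):
                assert f27 == any(
                    interval_overlap(p.interval, prom.interval) >= 1 for p in k27
                )
                assert f4 == any(
                    interval_overlap(p.interval, prom.interval) >= 1 for p in k4
                )


class TestPwmLogOdds:
    def test_uniform_column_scores_zero(self):
        pfm = PFMMatrix("M", np.full((4, 3), 10.0))
        assert np.allclose(pwm_log_odds(pfm), 0.0)

    def test_single_base_column_approaches_two_bits(self):
        counts = np.zeros((4, 1))
        counts[0, 0] = 1_000.0
        pfm = PFMMatrix("M", counts, pseudocount=1e-9)
        lo = pwm_log_odds(pfm)
        assert lo[0, 0] == pytest.approx(2.0, abs=1e-3)  # log2(4) under uniform bg

    def test_matches_elementwise_formula(self, rng):
        counts = rng.integers(1, 50, size=(4, 6)).astype(float)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pfm = PFMMatrix("M", counts, background=bg, pseudocount=0.8)
        lo = pwm_log_odds(pfm)
        for b in range(4):
            for j in range(6):
                phat = (counts[b, j] + 0.8 * bg[b]) / (counts[:, j].sum() + 0.8)
                assert lo[b, j] == pytest.approx(np.log2(phat / bg[b]))


def brute_scan(sequence, pwm, rel_threshold):
    """Exhaustive per-window rescan with an independently coded scorer."""
    m = pwm.shape[1]
    smax = sum(max(pwm[b][j] for b in range(4)) for j in range(m))
    smin = sum(min(pwm[b][j] for b in range(4)) for j in range(m))
    span = smax - smin if smax > smin else 1.0
    smin_eff = smin if smax > smin else smax - 1.0
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for strand, seq in (("+", sequence), ("-", reverse_complement(sequence))):
        for j in range(len(seq) - m + 1):
            window = seq[j : j + m]
            if "N" in window:
                continue
            score = sum(pwm[idx[c]][k] for k, c in enumerate(window))
            rel = (score - smin_eff) / span
            if rel >= rel_threshold:
                pos = j if strand == "+" else len(sequence) - m - j
                hits.append((pos, strand))
    return sorted(hits)


class TestScanPromoter:
    @pytest.fixture()
    def pwm(self, rng):
        counts = rng.integers(1, 20, size=(4, 6)).astype(float)
        counts[rng.integers(0, 4, size=6), np.arange(6)] += 60
        return pwm_log_odds(PFMMatrix("M", counts))

    def test_consensus_scores_relative_one_on_plus_strand(self, pwm):
        cons = pwm_consensus(pwm)
        hits = scan_promoter(cons, pwm, rel_threshold=0.99)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        assert plus[0].position == 0
        assert plus[0].rel_score == pytest.approx(1.0)

    def test_reverse_complement_found_on_minus_strand_at_offset(self, pwm, rng):
        cons = pwm_consensus(pwm)
        k = 13
        base = "".join(rng.choice(list("ACGT"), size=40))
        seq = base[:k] + reverse_complement(cons) + base[k + len(cons):]
        hits = scan_promoter(seq, pwm, rel_threshold=0.99)
        minus = [h for h in hits if h.strand == "-"]
        assert any(h.position == k for h in minus)

    def test_sequence_shorter_than_motif_gives_no_hits(self, pwm):
        assert scan_promoter("ACG", pwm) == []

    def test_windows_containing_n_are_skipped(self, pwm):
        cons = pwm_consensus(pwm)
        seq = cons[:-1] + "N"
        assert scan_promoter(seq, pwm, rel_threshold=0.01) == []

    def test_matches_exhaustive_enumeration(self, pwm, rng):
        for _ in range(1000 // 4):
            for thr in (0.6, 0.75, 0.9, 1.0):
                seq = "".join(rng.choice(list("ACGTN"), p=[0.24] * 4 + [0.04], size=50))
                got = sorted((h.position, h.strand) for h in scan_promoter(seq, pwm, thr))
                assert got == brute_scan(seq, pwm, thr)

    def test_hit_count_invariant_under_reverse_complement(self, pwm, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            a = scan_promoter(seq, pwm, 0.7)
            b = scan_promoter(reverse_complement(seq), pwm, 0.7)
            assert len(a) == len(b)
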