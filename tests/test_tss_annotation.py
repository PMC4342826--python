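import numpy as np
import pytest

from bactx import genome_model as gm
from bactx.tss_annotation import (
    NovelTranscript,
    TssRecord,
    annotate_tss,
    assign_multiplicity,
    classify_tss,
    compute_utr_stats,
    delineate_novel_transcript,
    estimate_three_prime_utrs,
    propose_tls_corrections,
    revcomp,
    utr_intervals,
)
from bactx.tss_detection import TssCandidate


def cand(pos, strand, replicon="chr", reads=20):
    return TssCandidate(
        replicon_id=replicon, position=pos, strand=strand,
        read_starts=reads, prev_read_starts=0, ratio=float("inf"),
    )


def cov(length, intervals, strand="+"):
    arrs = {s: np.zeros(length + 1, dtype=np.int64) for s in "+-"}
    for lo, hi in intervals:
        arrs[strand][lo : hi + 1] += 1
    return arrs


class TestClassifyTss:
    def test_upstream_tss_is_utr(self, toy_annotation):
        r = classify_tss(cand(150, "+"), toy_annotation)
        assert (r.tss_class, r.assigned_feature, r.utr_length) == ("utr", "geneA", 50)

    def test_tss_inside_sense_cds_is_intragenic(self, toy_annotation):
        r = classify_tss(cand(250, "+"), toy_annotation)
        assert (r.tss_class, r.assigned_feature) == ("intragenic", "geneA")

    def test_tss_over_opposite_strand_gene_is_antisense(self, toy_annotation):
        r = classify_tss(cand(300, "-"), toy_annotation)
        assert (r.tss_class, r.assigned_feature) == ("antisense", "geneA")

    def test_tss_over_opposite_utr_is_antisense(self, toy_annotation):
        utrs = [(150, 199, "+")]  # detected 5'-UTR of geneA
        r = classify_tss(cand(160, "-"), toy_annotation, detected_utrs=utrs)
        assert r.tss_class == "antisense"

    def test_far_from_everything_is_intergenic(self, toy_annotation):
        r = classify_tss(cand(4500, "+"), toy_annotation)
        assert r.tss_class == "intergenic"

    def test_utr_wins_over_antisense(self, toy_annotation):
        # 100 nt upstream of geneC's TLS (1600, '-') and not inside any '-' CDS
        r = classify_tss(cand(1700, "-"), toy_annotation)
        assert r.tss_class == "utr" and r.assigned_feature == "geneC"

    def test_every_tss_gets_exactly_one_class(self, sim):
        from bactx.tss_detection import detect_tss

        res = detect_tss(sim["primary"], sim["annotation"], sim["coverage"])
        records, _ = annotate_tss(res.candidates, sim["annotation"], sim["coverage"])
        classes = [r.tss_class for r in records]
        assert len(records) == res.n_final
        assert set(classes) <= {"utr", "intragenic", "antisense", "intergenic"}

    def test_planted_tss_all_classify_as_utr(self, sim):
        from bactx.tss_detection import detect_tss

        res = detect_tss(sim["primary"], sim["annotation"], sim["coverage"])
        records, _ = annotate_tss(res.candidates, sim["annotation"], sim["coverage"])
        true_pos = {(t.position, t.strand) for t in sim["truth"].tss}
        planted = [r for r in records if (r.position, r.strand) in true_pos]
        assert planted and all(r.tss_class == "utr" for r in planted)


class TestMultiplicity:
    def test_counts_per_gene(self, toy_annotation):
        records = [
            classify_tss(cand(p, "+"), toy_annotation) for p in (150, 170, 480)
        ] + [classify_tss(cand(1700, "-"), toy_annotation)]
        assign_multiplicity(records)
        # geneA has two utr TSSs -> multiple; geneB and geneC one each -> single
        assert [r.multiplicity for r in records] == ["multiple", "multiple", "single", "single"]


class TestTlsCorrections:
    def _genome(self, length=1000):
        seq = list("C" * length)  # no chance start codons
        return seq

    def test_in_frame_start_downstream_proposed(self, toy_annotation):
        seq = self._genome(5000)
        seq[159:162] = "ATG"  # in frame with geneA start 100? frame of 200-based CDS
        # geneA spans [200, 400]; plant in-frame ATG at 260 (offset 60, divisible by 3)
        seq[259:262] = "ATG"
        genome = "".join(seq)
        rec = classify_tss(cand(250, "+"), toy_annotation)
        proposals = propose_tls_corrections([rec], toy_annotation, genome)
        assert proposals == [("geneA", 200, 260)]

    def test_tss_in_second_half_ignored(self, toy_annotation):
        genome = "".join(self._genome(5000))
        rec = classify_tss(cand(350, "+"), toy_annotation)  # past midpoint of [200,400]
        assert propose_tls_corrections([rec], toy_annotation, genome) == []

    def test_no_start_codon_before_midpoint(self, toy_annotation):
        genome = "".join(self._genome(5000))  # all C: no ATG/GTG/TTG anywhere
        rec = classify_tss(cand(250, "+"), toy_annotation)
        assert propose_tls_corrections([rec], toy_annotation, genome) == []

    def test_minus_strand_correction(self, toy_annotation):
        seq = self._genome(5000)
        # geneC [1200,1600] '-'; TLS at 1600; in-frame codon start (first base on
        # sense strand) at 1450: genomic [1448,1450] must read CAT (revcomp ATG)
        seq[1447:1450] = "CAT"
        genome = "".join(seq)
        rec = classify_tss(cand(1500, "-"), toy_annotation)
        assert propose_tls_corrections([rec], toy_annotation, genome) == [
            ("geneC", 1600, 1450)
        ]


class TestUtrStats:
    def test_median_of_three(self):
        s = compute_utr_stats([50, 51, 52])
        assert s.median == 51

    def test_even_n_takes_lower_central(self):
        assert compute_utr_stats([10, 20, 30, 40]).median == 20

    def test_binning_and_leaderless(self):
        s = compute_utr_stats([3, 27, 33, 501])
        assert s.histogram["1-5"] == 1
        assert s.histogram["26-30"] == 1
        assert s.histogram["31-35"] == 1
        assert s.histogram[">500"] == 1
        assert s.leaderless_count == 1
        assert sum(s.histogram.values()) == 4

    def test_histogram_matches_direct_tally(self):
        rng = np.random.default_rng(5)
        lengths = (12 + rng.gamma(1.6, 35.0, size=10_000)).astype(int).tolist()
        s = compute_utr_stats(lengths)
        for lo in range(1, 501, 5):
            expected = sum(1 for l in lengths if lo <= l <= lo + 4)
            assert s.histogram[f"{lo}-{lo + 4}"] == expected
        assert s.histogram[">500"] == sum(1 for l in lengths if l > 500)
        assert sum(s.histogram.values()) == len(lengths)


class TestNovelTranscripts:
    def test_antisense_over_cds(self, toy_annotation):
        # '-' TSS inside geneA ('+'); transcript extends toward lower coords
        coverage = cov(5000, [(241, 390)], strand="-")
        rec = classify_tss(cand(390, "-"), toy_annotation)
        nt = delineate_novel_transcript(rec, coverage, toy_annotation)
        assert nt.category == "antisense"
        assert nt.antisense_subtype == "cds_overlap"
        assert nt.length == 150

    def test_short_transcript_suppressed(self, toy_annotation):
        coverage = cov(5000, [(376, 390)], strand="-")  # 15 nt
        rec = classify_tss(cand(390, "-"), toy_annotation)
        assert delineate_novel_transcript(rec, coverage, toy_annotation) is None

    def test_gap_of_four_is_bridged(self, toy_annotation):
        coverage = cov(5000, [(4000, 4029), (4034, 4063)], strand="+")
        rec = classify_tss(cand(4000, "+"), toy_annotation)
        nt = delineate_novel_transcript(rec, coverage, toy_annotation)
        assert (nt.start, nt.end, nt.length) == (4000, 4063, 64)

    def test_gap_of_six_ends_transcript(self, toy_annotation):
        coverage = cov(5000, [(4000, 4029), (4036, 4099)], strand="+")
        rec = classify_tss(cand(4000, "+"), toy_annotation)
        nt = delineate_novel_transcript(rec, coverage, toy_annotation)
        assert (nt.start, nt.end) == (4000, 4029)

    def test_three_prime_utr_estimation(self, toy_annotation):
        coverage = cov(5000, [(200, 450)], strand="+")  # runs past geneA stop (400)
        utrs = estimate_three_prime_utrs(toy_annotation, coverage)
        assert (401, 450, "+") in utrs
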