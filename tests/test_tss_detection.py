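import math

import numpy as np
import pytest

from bactx import genome_model as gm
from bactx.synthetic_data import evaluate_calls
from bactx.tss_detection import (
    TssCandidate,
    TssDetectionParams,
    detect_candidates,
    detect_tss,
    drop_stable_rna_tss,
    find_near_misses,
    flag_false_positives,
    rescue_candidates,
)
from .conftest import make_profile


def brute_force_calls(profile, annotation, T=6, R=6.0, X=500):
    """Independent per-position evaluation of the three detection criteria."""
    calls = []
    for strand in "+-":
        for pos, c in profile.counts[strand].items():
            if not c > T:
                continue
            prev = profile.counts[strand].get(pos - 1 if strand == "+" else pos + 1, 0)
            if prev != 0 and not c / prev > R:
                continue
            near_tls = False
            for f in annotation.cds():
                if f.strand != strand:
                    continue
                tls = f.start if strand == "+" else f.end
                d = tls - pos if strand == "+" else pos - tls
                if 0 <= d <= X:
                    near_tls = True
                    break
            if near_tls:
                calls.append((pos, strand))
    return sorted(calls)


def random_instance(rng, length=10_000, n_positions=500, n_genes=8):
    counts = {"+": {}, "-": {}}
    for _ in range(n_positions):
        strand = "+" if rng.random() < 0.5 else "-"
        pos = int(rng.integers(1, length + 1))
        counts[strand][pos] = int(rng.integers(1, 25))
    profile = gm.ReadStartProfile(replicon_id="chr", counts=counts)
    feats = []
    for i in range(n_genes):
        start = int(rng.integers(1, length - 600))
        feats.append(
            gm.GeneFeature(f"g{i}_{start}", "chr", start, start + 500, "+" if rng.random() < 0.5 else "-", "CDS")
        )
    ann = gm.GenomeAnnotation("chr", length, feats)
    return profile, ann


class TestDetectCandidates:
    def test_sharp_step_called(self, toy_annotation):
        profile = make_profile([(100, "+", 7), (99, "+", 1)])
        # TLS of geneA at 200 is 100 nt downstream
        calls = detect_candidates(profile, toy_annotation)
        assert [(c.position, c.strand) for c in calls if c.tls_within_x] == [(100, "+")]
        assert calls[0].ratio == 7.0

    def test_ratio_at_boundary_fails(self, toy_annotation):
        profile = make_profile([(100, "+", 7), (99, "+", 2)])  # 3.5 <= 6
        calls = detect_candidates(profile, toy_annotation)
        assert calls == []

    def test_count_at_threshold_fails(self, toy_annotation):
        profile = make_profile([(100, "+", 6)])  # needs > 6
        assert detect_candidates(profile, toy_annotation) == []

    def test_zero_previous_passes_ratio(self, toy_annotation):
        profile = make_profile([(100, "+", 7)])
        calls = detect_candidates(profile, toy_annotation)
        assert len(calls) == 1 and math.isinf(calls[0].ratio)

    def test_minus_strand_direction(self, toy_annotation):
        # geneC is '-' with TLS at 1600; upstream direction is +1
        profile = make_profile([(1650, "-", 10), (1651, "-", 1)])
        calls = detect_candidates(profile, toy_annotation)
        assert [(c.position, c.strand) for c in calls] == [(1650, "-")]
        assert calls[0].tls_distance == 50

    def test_replicon_mismatch_rejected(self, toy_annotation):
        profile = make_profile([(100, "+", 7)], replicon="other")
        with pytest.raises(ValueError, match="replicon|annotation"):
            detect_candidates(profile, toy_annotation)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            profile, ann = random_instance(rng)
            expected = brute_force_calls(profile, ann)
            got = sorted(
                (c.position, c.strand)
                for c in detect_candidates(profile, ann)
                if c.tls_within_x
            )
            assert got == expected

    def test_raising_thresholds_never_adds_candidates(self):
        rng = np.random.default_rng(7)
        profile, ann = random_instance(rng)
        base = {
            (c.position, c.strand)
            for c in detect_candidates(profile, ann, TssDetectionParams())
        }
        for T, R in [(8, 6.0), (6, 9.0), (10, 12.0)]:
            stricter = {
                (c.position, c.strand)
                for c in detect_candidates(profile, ann, TssDetectionParams(T=T, R=R))
            }
            assert stricter <= base


class TestRescue:
    def _coverage(self, length=5000, lo=1, hi=5000, depth=3):
        arr = np.zeros(length + 1, dtype=np.int64)
        arr[lo : hi + 1] = depth
        return {"+": arr, "-": np.zeros(length + 1, dtype=np.int64)}

    def test_one_read_below_threshold_with_support_rescued(self, toy_annotation):
        profile = make_profile([(100, "+", 6)])  # fails (a) by one read
        near = find_near_misses(profile, toy_annotation)
        assert [(c.position, c.strand) for c in near] == [(100, "+")]
        rescued = rescue_candidates(near, profile, self._coverage(), None)
        assert len(rescued) == 1 and rescued[0].detection_mode == "rescued"

    def test_no_downstream_support_not_rescued(self, toy_annotation):
        profile = make_profile([(100, "+", 6)])
        near = find_near_misses(profile, toy_annotation)
        no_cov = self._coverage(depth=0)
        assert rescue_candidates(near, profile, no_cov, None) == []

    def test_two_reads_below_never_rescued(self, toy_annotation):
        profile = make_profile([(100, "+", 5)])
        assert find_near_misses(profile, toy_annotation) == []

    def test_failing_both_criteria_not_a_near_miss(self, toy_annotation):
        profile = make_profile([(100, "+", 6), (99, "+", 3)])  # (a) and (b) both fail
        assert find_near_misses(profile, toy_annotation) == []


class TestFalsePositiveFlag:
    def test_minor_peak_in_uneven_gradient_flagged(self, toy_annotation):
        rows = [(100, "+", 12), (99, "+", 1), (110, "+", 400), (115, "+", 30),
                (120, "+", 25), (130, "+", 9)]
        profile = make_profile(rows)
        cands = detect_candidates(profile, toy_annotation)
        flagged = flag_false_positives(cands, profile)
        c100 = next(c for c in flagged if c.position == 100)
        assert "false_positive" in c100.flags

    def test_isolated_peak_not_flagged(self, toy_annotation):
        profile = make_profile([(100, "+", 12)])
        flagged = flag_false_positives(detect_candidates(profile, toy_annotation), profile)
        assert flagged[0].flags == set()

    def test_two_supra_threshold_neighbors_is_below_boundary(self, toy_annotation):
        rows = [(100, "+", 12), (110, "+", 400), (115, "+", 30)]
        profile = make_profile(rows)
        flagged = flag_false_positives(detect_candidates(profile, toy_annotation), profile)
        c100 = next(c for c in flagged if c.position == 100)
        assert "false_positive" not in c100.flags


class TestStableRnaRemoval:
    def test_tss_upstream_of_trna_removed(self, toy_annotation):
        profile = make_profile([(1960, "+", 20)])  # 40 nt upstream of trnaD at 2000
        cands = detect_candidates(profile, toy_annotation)
        kept, removed = drop_stable_rna_tss(cands, toy_annotation)
        assert removed == 1 and kept == []

    def test_tss_upstream_of_cds_kept(self, toy_annotation):
        profile = make_profile([(160, "+", 20)])
        cands = detect_candidates(profile, toy_annotation)
        kept, removed = drop_stable_rna_tss(cands, toy_annotation)
        assert removed == 0 and len(kept) == 1

    def test_tss_without_downstream_feature_kept(self, toy_annotation):
        profile = make_profile([(4500, "+", 20)])
        cands = detect_candidates(profile, toy_annotation)
        kept, removed = drop_stable_rna_tss(cands, toy_annotation)
        assert removed == 0 and len(kept) == 1


class TestPipelineBookkeeping:
    def test_set_arithmetic(self, sim):
        res = detect_tss(sim["primary"], sim["annotation"], sim["coverage"])
        assert (
            res.n_automatic - res.n_false_positive - res.n_stable_rna + res.n_rescued
            == res.n_final
        )

    def test_synthetic_recovery(self, sim):
        res = detect_tss(sim["primary"], sim["annotation"], sim["coverage"])
        m = evaluate_calls(res.candidates, sim["truth"], tolerance=0)
        assert m.recall >= 0.95
        assert m.precision >= 0.95
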