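"""Synthetic annotated genome and RNA-seq libraries with known ground truth.

The generator emulates the statistical structure the detection procedures
assume, for a desk-scale bacterial replicon:

* non-overlapping (poly)cistronic transcription units on both strands, each
  with a promoter (-35 element, spacer, -10 element, spacer, TSS), a
  5'-UTR whose length distribution peaks around 26-35 nt with a long right
  tail, and a ribosome binding site a short spacer before each TLS;
* a 5'-enriched library showing sharp Poisson read-start peaks at true
  TSSs over a low positional background confined mostly to transcribed
  intervals (residual processed 5' ends), plus a small uniform genomic
  floor;
* a whole-transcriptome library of paired fragments of 100-800 nt sampled
  within transcripts, with planted per-junction bridging depth, whose 5'
  start profile drives abundance quantification;
* per-unit abundance tiers whose fragment-start rates place the resulting
  log-RPKM values in the low/middle/high/very-high class bands.

The simulated replicon is far smaller than a real genome, so the
whole-transcriptome profile's ``total_mapped`` is set to an effective
library size parameter, modeling the profile as the in-region subsample of
a full sequencing library.

All randomness derives from a single integer seed; identical parameters
give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .genome_model import (
    GeneFeature,
    GenomeAnnotation,
    PairedFragment,
    ReadStartProfile,
    Strand,
    PRIMARY_LIBRARY,
    WHOLE_LIBRARY,
    fragment_start_profile,
)

logger = logging.getLogger(__name__)

_BASES = "ACGT"


def consensus_pwm(
    consensus: str, conservation: float | Sequence[float] = 0.85
) -> np.ndarray:
    """PWM putting ``conservation`` on the consensus base, rest uniform.

    ``conservation`` may be a per-position sequence to grade the motif
    (e.g. a weakly conserved second half).
    """
    if isinstance(conservation, (int, float)):
        conservation = [float(conservation)] * len(consensus)
    pwm = np.empty((len(consensus), 4))
    for i, (b, c) in enumerate(zip(consensus.upper(), conservation)):
        pwm[i] = (1 - c) / 3
        pwm[i, _BASES.index(b)] = c
    return pwm


class SizingError(ValueError):
    """Replicon too short for the requested transcription units."""


@dataclass
class SimulationParams:
    """Generator knobs; defaults are the study conditions the pipeline assumes."""

    n_transcription_units: int = 100
    replicon_length: Optional[int] = None  # auto-sized when None
    replicon_id: str = "synth1"
    #: P(operon size = k); skewed toward mono- and bicistronic units
    operon_size_probs: dict[int, float] = field(
        default_factory=lambda: {
            1: 0.55, 2: 0.25, 3: 0.10, 4: 0.05, 5: 0.02, 6: 0.015, 7: 0.0075, 8: 0.0075,
        }
    )
    gene_length_range: tuple[int, int] = (200, 1200)
    #: 5'-UTR length = utr_min + Gamma(shape, scale): mode ~30 nt, long right tail
    utr_min: int = 12
    utr_shape: float = 1.6
    utr_scale: float = 35.0
    intergenic_within_operon: tuple[int, int] = (20, 80)
    inter_unit_gap: tuple[int, int] = (150, 400)
    # 5'-enriched library
    tss_peak_rate: float = 50.0
    background_rate: float = 0.2
    genomic_floor_rate: float = 0.01
    overdispersion: Optional[float] = None  # NB dispersion for the TSS peak; off by default
    # whole-transcriptome library
    fragment_size_range: tuple[int, int] = (100, 800)
    junction_depth_range: tuple[int, int] = (6, 12)
    effective_library_size: int = 1_000_000
    #: fragment 5'-start rate per transcript position, by abundance tier;
    #: chosen so expected log-RPKM lands mid-band under the default depth
    tier_start_rate: dict[str, float] = field(
        default_factory=lambda: {"low": 0.006, "middle": 0.06, "high": 0.6, "very_high": 6.0}
    )
    tier_probs: dict[str, float] = field(
        default_factory=lambda: {"low": 0.05, "middle": 0.53, "high": 0.40, "very_high": 0.02}
    )
    #: TSS peak-rate multiplier by tier (5'-enrichment flattens dynamic range)
    tier_peak_multiplier: dict[str, float] = field(
        default_factory=lambda: {"low": 0.5, "middle": 1.0, "high": 2.0, "very_high": 4.0}
    )
    # planted motifs
    #: planted motifs are strongly conserved (~8.8 bits at width 6), the
    #: regime in which EM recovery of sites is near-complete; lower the
    #: conservation to emulate weakly conserved elements
    minus10_pwm: np.ndarray = field(default_factory=lambda: consensus_pwm("TATAAT", 0.92))
    minus35_pwm: np.ndarray = field(default_factory=lambda: consensus_pwm("TTGACA", 0.92))
    rbs_pwm: np.ndarray = field(default_factory=lambda: consensus_pwm("AGGAGG", 0.92))
    spacer_minus10_tss: tuple[int, int] = (4, 10)  # uniform
    spacer_rbs_tls: tuple[int, int] = (5, 10)  # uniform
    spacer_minus35_minus10: tuple[int, int, int] = (15, 17, 19)  # triangular (lo, mode, hi)
    extended_minus10_fraction: float = 0.33
    start_codon_probs: dict[str, float] = field(
        default_factory=lambda: {"ATG": 0.755, "TTG": 0.139, "GTG": 0.106}
    )
    gc_content: float = 0.386
    promoter_upstream: int = 70
    three_prime_trailer: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcription_units < 1:
            raise ValueError("need at least one transcription unit")
        for rate in (self.tss_peak_rate, self.background_rate, self.genomic_floor_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        for lo, hi in (
            self.gene_length_range,
            self.fragment_size_range,
            self.intergenic_within_operon,
        ):
            if not (0 < lo < hi):
                raise ValueError("ranges must be non-degenerate")

    def base_probs(self) -> np.ndarray:
        gc = self.gc_content
        return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


@dataclass
class TrueTss:
    position: int
    strand: Strand
    unit_index: int
    tier: str


@dataclass
class TrueUnit:
    unit_index: int
    strand: Strand
    tss_position: int
    gene_ids: list[str]
    transcript_start: int  # leftmost genomic coordinate
    transcript_end: int  # rightmost genomic coordinate
    tier: str
    minus10: tuple[int, int]  # genomic interval of the planted -10 element
    minus35: tuple[int, int]
    extended: bool
    spacer_minus10_tss: int
    spacer_minus35_minus10: int
    rbs_sites: dict[str, tuple[int, int]]  # gene_id -> genomic interval
    rbs_spacers: dict[str, int]  # gene_id -> planted RBS-TLS spacer


@dataclass
class GroundTruth:
    replicon_id: str
    units: list[TrueUnit]
    tss: list[TrueTss]
    gene_tiers: dict[str, str]

    @property
    def operons(self) -> list[list[str]]:
        return [u.gene_ids for u in self.units if len(u.gene_ids) >= 2]


def _sample_pwm(rng: np.random.Generator, pwm: np.ndarray) -> str:
    return "".join(_BASES[rng.choice(4, p=row)] for row in pwm)


def _random_seq(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    return "".join(_BASES[i] for i in rng.choice(4, size=n, p=probs))


def _triangular_int(rng: np.random.Generator, lo: int, mode: int, hi: int) -> int:
    vals = np.arange(lo, hi + 1)
    w = np.minimum(vals - lo + 1, hi - vals + 1).astype(float)
    return int(rng.choice(vals, p=w / w.sum()))


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def generate_genome(
    params: SimulationParams,
) -> tuple[GenomeAnnotation, str, GroundTruth]:
    """Build an annotated replicon with planted promoters, RBSs and operons."""
    rng = np.random.default_rng([params.seed, 0])
    probs = params.base_probs()
    sizes = np.array(sorted(params.operon_size_probs))
    size_p = np.array([params.operon_size_probs[int(k)] for k in sizes], dtype=float)
    size_p /= size_p.sum()
    tiers = sorted(params.tier_probs)
    tier_p = np.array([params.tier_probs[t] for t in tiers], dtype=float)
    tier_p /= tier_p.sum()
    codons = sorted(params.start_codon_probs)
    codon_p = np.array([params.start_codon_probs[c] for c in codons], dtype=float)
    codon_p /= codon_p.sum()

    chunks: list[str] = []
    features: list[GeneFeature] = []
    units: list[TrueUnit] = []
    tss_list: list[TrueTss] = []
    gene_tiers: dict[str, str] = {}
    cursor = 0  # 0-based genomic offset of the next chunk
    gene_counter = 0

    lead = _random_seq(rng, int(rng.integers(*params.inter_unit_gap)), probs)
    chunks.append(lead)
    cursor += len(lead)

    for ui in range(params.n_transcription_units):
        n_genes = int(rng.choice(sizes, p=size_p))
        tier = tiers[int(rng.choice(len(tiers), p=tier_p))]
        strand: Strand = "+" if rng.random() < 0.5 else "-"

        # --- build the unit on its sense strand (0-based local indices) ---
        up = params.promoter_upstream
        s10 = int(rng.integers(params.spacer_minus10_tss[0], params.spacer_minus10_tss[1] + 1))
        s35 = _triangular_int(rng, *params.spacer_minus35_minus10)
        extended = bool(rng.random() < params.extended_minus10_fraction)
        upstream = list(_random_seq(rng, up, probs))
        m10_start = up - s10 - 6  # local index of the -10 element's first base
        m10_seq = _sample_pwm(rng, params.minus10_pwm)
        upstream[m10_start : m10_start + 6] = m10_seq
        if extended:
            upstream[m10_start - 2 : m10_start] = "TG"
        else:
            # keep the planted extended fraction exact: no chance TG here
            while "".join(upstream[m10_start - 2 : m10_start]) == "TG":
                upstream[m10_start - 2 : m10_start] = _random_seq(rng, 2, probs)
        m35_start = m10_start - s35 - 6
        m35_seq = _sample_pwm(rng, params.minus35_pwm)
        upstream[m35_start : m35_start + 6] = m35_seq
        local = "".join(upstream)
        tss_local = up  # TSS = first transcribed base, local index `up`

        gene_spans: list[tuple[int, int]] = []  # local, 0-based inclusive
        rbs_spans: list[tuple[int, int]] = []
        rbs_spacers: list[int] = []
        body = ""

        for gi in range(n_genes):
            if gi == 0:
                leader_len = params.utr_min + int(rng.gamma(params.utr_shape, params.utr_scale))
            else:
                leader_len = int(rng.integers(*params.intergenic_within_operon))
            s_rbs = int(rng.integers(params.spacer_rbs_tls[0], params.spacer_rbs_tls[1] + 1))
            s_rbs = min(s_rbs, leader_len - 6)
            leader = list(_random_seq(rng, leader_len, probs))
            rbs_seq = _sample_pwm(rng, params.rbs_pwm)
            rbs_off = leader_len - s_rbs - 6
            leader[rbs_off : rbs_off + 6] = rbs_seq
            glen = int(rng.integers(*params.gene_length_range)) // 3 * 3
            start_codon = codons[int(rng.choice(len(codons), p=codon_p))]
            coding = start_codon + _random_seq(rng, glen - 6, probs) + "TAA"
            gene_start_local = tss_local + len(body) + leader_len
            gene_spans.append((gene_start_local, gene_start_local + glen - 1))
            rbs_abs = tss_local + len(body) + rbs_off
            rbs_spans.append((rbs_abs, rbs_abs + 5))
            rbs_spacers.append(s_rbs)
            body += "".join(leader) + coding

        trailer = _random_seq(rng, params.three_prime_trailer, probs)
        local_seq = local + body + trailer
        tx_end_local = tss_local + len(body) + params.three_prime_trailer - 1

        # --- paste into the genome, mirroring for '-' units ---
        ulen = len(local_seq)
        if strand == "+":
            chunks.append(local_seq)
            def g(idx: int) -> int:  # local 0-based -> genomic 1-based
                return cursor + idx + 1
        else:
            chunks.append(local_seq.translate(_COMPLEMENT)[::-1])
            def g(idx: int) -> int:
                return cursor + (ulen - idx)

        gene_ids = []
        rbs_sites: dict[str, tuple[int, int]] = {}
        rbs_sp: dict[str, int] = {}
        for (a, b), (ra, rb), sp in zip(gene_spans, rbs_spans, rbs_spacers):
            gene_counter += 1
            gid = f"g{gene_counter:04d}"
            gene_ids.append(gid)
            lo, hi = sorted((g(a), g(b)))
            features.append(
                GeneFeature(gid, params.replicon_id, lo, hi, strand, "CDS")
            )
            rbs_sites[gid] = tuple(sorted((g(ra), g(rb))))
            rbs_sp[gid] = sp
            gene_tiers[gid] = tier

        tss_g = g(tss_local)
        units.append(
            TrueUnit(
                unit_index=ui,
                strand=strand,
                tss_position=tss_g,
                gene_ids=gene_ids,
                transcript_start=min(tss_g, g(tx_end_local)),
                transcript_end=max(tss_g, g(tx_end_local)),
                tier=tier,
                minus10=tuple(sorted((g(m10_start), g(m10_start + 5)))),
                minus35=tuple(sorted((g(m35_start), g(m35_start + 5)))),
                extended=extended,
                spacer_minus10_tss=s10,
                spacer_minus35_minus10=s35,
                rbs_sites=rbs_sites,
                rbs_spacers=rbs_sp,
            )
        )
        tss_list.append(TrueTss(tss_g, strand, ui, tier))
        cursor += ulen

        gap = _random_seq(rng, int(rng.integers(*params.inter_unit_gap)), probs)
        chunks.append(gap)
        cursor += len(gap)

    sequence = "".join(chunks)
    if params.replicon_length is not None:
        if params.replicon_length < len(sequence):
            raise SizingError(
                f"replicon_length {params.replicon_length} too short: "
                f"{params.n_transcription_units} units need {len(sequence)} nt"
            )
        sequence += _random_seq(rng, params.replicon_length - len(sequence), probs)
    annotation = GenomeAnnotation(
        replicon_id=params.replicon_id, length=len(sequence), features=features
    )
    truth = GroundTruth(
        replicon_id=params.replicon_id, units=units, tss=tss_list, gene_tiers=gene_tiers
    )
    return annotation, sequence, truth


# ---------------------------------------------------------------------------
# Libraries
# ---------------------------------------------------------------------------


def simulate_primary_library(
    truth: GroundTruth, params: SimulationParams, replicon_length: Optional[int] = None
) -> ReadStartProfile:
    """5'-enriched read-start profile: Poisson peaks at true TSSs over background.

    Background read starts land within transcribed intervals at
    ``background_rate`` per position, plus a uniform genomic floor at
    ``genomic_floor_rate``.
    """
    rng = np.random.default_rng([params.seed, 1])
    length = replicon_length or (max(u.transcript_end for u in truth.units) + 500)
    counts: dict[Strand, dict[int, int]] = {"+": {}, "-": {}}

    def bump(pos: int, strand: Strand, c: int) -> None:
        if c > 0 and 1 <= pos <= length:
            counts[strand][pos] = counts[strand].get(pos, 0) + int(c)

    for t in truth.tss:
        rate = params.tss_peak_rate * params.tier_peak_multiplier[t.tier]
        if params.overdispersion:
            k = params.overdispersion
            c = rng.negative_binomial(k, k / (k + rate))
        else:
            c = rng.poisson(rate)
        bump(t.position, t.strand, c)

    for u in truth.units:
        span = np.arange(u.transcript_start, u.transcript_end + 1)
        bg = rng.poisson(params.background_rate, size=span.size)
        for pos, c in zip(span[bg > 0], bg[bg > 0]):
            bump(int(pos), u.strand, int(c))

    if params.genomic_floor_rate > 0:
        for strand in ("+", "-"):
            floor = rng.poisson(params.genomic_floor_rate, size=length)
            for pos in np.nonzero(floor)[0]:
                bump(int(pos) + 1, strand, int(floor[pos]))

    return ReadStartProfile(
        replicon_id=truth.replicon_id, library=PRIMARY_LIBRARY, counts=counts
    )


def simulate_whole_library(
    truth: GroundTruth,
    params: SimulationParams,
    annotation: Optional[GenomeAnnotation] = None,
) -> tuple[list[PairedFragment], ReadStartProfile]:
    """Paired fragments within transcripts plus their 5'-start profile.

    Expression fragments start uniformly within each transcript at the
    unit's tier-specific rate; lengths are uniform in
    ``fragment_size_range`` and truncated at the transcript 3' end.  Each
    internal gene junction additionally receives a planted number of
    bridging fragments drawn from ``junction_depth_range``.
    """
    rng = np.random.default_rng([params.seed, 2])
    fmin, fmax = params.fragment_size_range
    fragments: list[PairedFragment] = []
    truncated = 0
    genes = {f.feature_id: f for f in annotation} if annotation is not None else None

    for u in truth.units:
        lo, hi = u.transcript_start, u.transcript_end
        tx_len = hi - lo + 1
        rate = params.tier_start_rate[u.tier]
        n = int(rng.poisson(rate * tx_len))
        if tx_len < fmin:
            truncated += n
        starts5 = rng.integers(lo, hi + 1, size=n)  # 5' ends in genomic coords
        lens = rng.integers(fmin, fmax + 1, size=n)
        for s5, l in zip(starts5, lens):
            if u.strand == "+":
                end = min(int(s5) + int(l) - 1, hi)
                if end - int(s5) + 1 < l:
                    truncated += 1
                fragments.append(PairedFragment(truth.replicon_id, int(s5), end, "+"))
            else:
                start = max(int(s5) - int(l) + 1, lo)
                if int(s5) - start + 1 < l:
                    truncated += 1
                fragments.append(PairedFragment(truth.replicon_id, start, int(s5), "-"))

        # planted bridging depth at each internal junction
        if genes is not None and len(u.gene_ids) >= 2:
            order = u.gene_ids if u.strand == "+" else u.gene_ids
            for ga, gb in zip(order, order[1:]):
                fa, fb = genes[ga], genes[gb]
                if u.strand == "+":
                    a, b = fa.end, fb.start
                else:
                    a, b = fb.end, fa.start
                if a > b:
                    a = b
                depth = int(rng.integers(*params.junction_depth_range, endpoint=True))
                span_needed = b - a + 1
                for _ in range(depth):
                    l = int(rng.integers(max(fmin, span_needed), fmax + 1))
                    smin = max(lo, b - l + 1)
                    smax = min(a, hi - l + 1)
                    if smax < smin:
                        s = smin
                        l = min(l, hi - s + 1)
                        truncated += 1
                    else:
                        s = int(rng.integers(smin, smax + 1))
                    fragments.append(
                        PairedFragment(truth.replicon_id, s, min(s + l - 1, hi), u.strand)
                    )
    if truncated:
        logger.warning("%d fragments truncated to their transcript bounds", truncated)
    fragments.sort(key=lambda f: (f.strand, f.start, f.end))
    profile = fragment_start_profile(
        fragments, truth.replicon_id, total_mapped=params.effective_library_size
    )
    return fragments, profile


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------


@dataclass
class RecoveryMetrics:
    n_true: int
    n_predicted: int
    n_recovered: int
    precision: Optional[float]  # None when there are no predictions
    recall: float


def evaluate_calls(
    predicted: Sequence,
    truth: GroundTruth,
    tolerance: int = 0,
) -> RecoveryMetrics:
    """Precision/recall of predicted TSSs or operons against ground truth.

    TSS-like predictions (objects with ``position`` and ``strand``) count
    as recovered when a true TSS on the same strand lies within
    ``tolerance`` nt; each true TSS absorbs at most one prediction.
    Operon-like predictions (objects with ``member_gene_ids``) count only
    on an exact member-set match.
    """
    preds = list(predicted)
    if preds and hasattr(preds[0], "member_gene_ids"):
        true_sets = {frozenset(m) for m in truth.operons}
        pred_sets = [frozenset(p.member_gene_ids) for p in preds]
        tp = sum(1 for s in pred_sets if s in true_sets)
        recovered_true = len(true_sets & set(pred_sets))
        n_true = len(true_sets)
        return RecoveryMetrics(
            n_true=n_true,
            n_predicted=len(preds),
            n_recovered=recovered_true,
            precision=tp / len(preds),
            recall=recovered_true / n_true if n_true else float("nan"),
        )
    n_true = len(truth.tss)
    if not preds:
        return RecoveryMetrics(n_true, 0, 0, None, 0.0 if n_true else float("nan"))
    unmatched = {(t.position, t.strand) for t in truth.tss}
    tp = 0
    for p in sorted(preds, key=lambda p: (p.strand, p.position)):
        hit = None
        for d in range(-tolerance, tolerance + 1):
            key = (p.position + d, p.strand)
            if key in unmatched:
                hit = key
                break
        if hit is not None:
            unmatched.discard(hit)
            tp += 1
    return RecoveryMetrics(
        n_true=n_true,
        n_predicted=len(preds),
        n_recovered=tp,
        precision=tp / len(preds),
        recall=tp / n_true if n_true else float("nan"),
    )
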