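"""Classification of verified TSSs by genomic context and 5'-UTR statistics.

Every verified TSS receives exactly one class:

* ``utr`` — a same-strand protein-coding TLS lies downstream within the
  distance cutoff and the TSS sits outside all same-strand CDS bodies; the
  TSS then defines (one of) the gene's 5'-UTR(s).
* ``intragenic`` — the TSS falls within a same-strand CDS body.
* ``antisense`` — the TSS falls within an opposite-strand feature or its
  detected 5'-UTR / coverage-estimated 3'-UTR.
* ``intergenic`` — none of the above.

Precedence when several contexts apply is utr > intragenic > antisense >
intergenic: the gene-associated branch wins first.

Novel transcripts (intergenic, intragenic sense, antisense) are delineated
to their 3' ends by extending from the TSS while whole-transcriptome
coverage persists, tolerating short gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome_model import GenomeAnnotation, GeneFeature, Strand
from .tss_detection import TssCandidate, TssDetectionParams, nearest_downstream_tls, _tls_arrays

#: interval on a strand: (start, end, strand), 1-based inclusive
StrandInterval = tuple[int, int, str]

START_CODONS = ("ATG", "GTG", "TTG")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TssRecord:
    """A classified TSS."""

    candidate: TssCandidate
    tss_class: str  # utr | intragenic | antisense | intergenic
    assigned_feature: Optional[str] = None
    utr_length: Optional[int] = None
    multiplicity: Optional[str] = None  # single | multiple (utr class only)

    @property
    def position(self) -> int:
        return self.candidate.position

    @property
    def strand(self) -> Strand:
        return self.candidate.strand

    @property
    def replicon_id(self) -> str:
        return self.candidate.replicon_id


@dataclass
class NovelTranscript:
    tss: TssRecord
    start: int
    end: int
    strand: Strand
    category: str  # intergenic | intragenic_sense | antisense
    antisense_subtype: Optional[str] = None  # cds_overlap | utr_overlap | cds_and_utr_overlap

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class UtrStats:
    lengths: list[int]
    median: Optional[int]
    histogram: dict[str, int]
    leaderless_count: int


def classify_tss(
    tss: TssCandidate,
    annotation: GenomeAnnotation,
    detected_utrs: Sequence[StrandInterval] = (),
    params: TssDetectionParams | None = None,
) -> TssRecord:
    """Assign a genomic-context class to one TSS candidate.

    ``detected_utrs`` are UTR intervals (5' or estimated 3') consulted for
    the antisense class; pass the output of :func:`utr_intervals` /
    :func:`estimate_three_prime_utrs` once available.
    """
    params = params or TssDetectionParams()
    p, strand = tss.position, tss.strand
    sense_cds = [f for f in annotation.cds() if f.strand == strand and f.contains(p)]
    tls = _tls_arrays(annotation)
    positions, ids = tls[strand]
    fid, dist = nearest_downstream_tls(p, strand, positions, ids)
    if fid is not None and dist is not None and dist <= params.X and not sense_cds:
        return TssRecord(tss, "utr", assigned_feature=fid, utr_length=dist)
    if sense_cds:
        return TssRecord(tss, "intragenic", assigned_feature=sense_cds[0].feature_id)
    opp = "-" if strand == "+" else "+"
    for f in annotation.features:
        if f.strand == opp and f.contains(p):
            return TssRecord(tss, "antisense", assigned_feature=f.feature_id)
    for start, end, s in detected_utrs:
        if s == opp and start <= p <= end:
            return TssRecord(tss, "antisense")
    return TssRecord(tss, "intergenic")


def assign_multiplicity(records: Sequence[TssRecord]) -> list[TssRecord]:
    """Mark utr-class TSSs as single/multiple per assigned gene (in place)."""
    per_gene: dict[str, int] = {}
    for r in records:
        if r.tss_class == "utr" and r.assigned_feature:
            per_gene[r.assigned_feature] = per_gene.get(r.assigned_feature, 0) + 1
    for r in records:
        if r.tss_class == "utr" and r.assigned_feature:
            r.multiplicity = "multiple" if per_gene[r.assigned_feature] >= 2 else "single"
    return list(records)


def utr_intervals(records: Sequence[TssRecord]) -> list[StrandInterval]:
    """Genomic intervals of detected 5'-UTRs (TSS up to the base before the TLS)."""
    out: list[StrandInterval] = []
    for r in records:
        if r.tss_class != "utr" or not r.utr_length:
            continue
        if r.strand == "+":
            out.append((r.position, r.position + r.utr_length - 1, "+"))
        else:
            out.append((r.position - r.utr_length + 1, r.position, "-"))
    return out


def compute_utr_stats(utr_records: Sequence[TssRecord] | Sequence[int]) -> UtrStats:
    """5'-UTR length distribution: median, 5-nt binned histogram, leaderless count.

    The median is the lower of the two central values for even n.  Bins are
    1-5, 6-10, ..., 496-500 plus a final >500 bin; a length of 0 counts in
    the first bin.  Leaderless transcripts are those with length < 10 nt.
    """
    lengths = [
        r.utr_length if isinstance(r, TssRecord) else int(r) for r in utr_records
    ]
    lengths = [l for l in lengths if l is not None]
    hist: dict[str, int] = {}
    for lo in range(1, 501, 5):
        hist[f"{lo}-{lo + 4}"] = 0
    hist[">500"] = 0
    for l in lengths:
        if l > 500:
            hist[">500"] += 1
        else:
            lo = max(1, ((max(l, 1) - 1) // 5) * 5 + 1)
            hist[f"{lo}-{lo + 4}"] += 1
    median = None
    if lengths:
        s = sorted(lengths)
        median = s[(len(s) - 1) // 2]
    return UtrStats(
        lengths=lengths,
        median=median,
        histogram=hist,
        leaderless_count=sum(1 for l in lengths if l < 10),
    )


def propose_tls_corrections(
    intragenic_records: Sequence[TssRecord],
    annotation: GenomeAnnotation,
    genome: dict[str, str] | str,
) -> list[tuple[str, int, int]]:
    """Correct mis-annotated translation starts from intragenic sense TSSs.

    An intragenic sense TSS within the first half of a CDS implies the true
    start codon lies downstream of the annotated one.  For each such TSS
    the nearest in-frame ATG/GTG/TTG at or downstream of the TSS and before
    the CDS midpoint is proposed as the new TLS.

    Returns ``(feature_id, old_TLS, proposed_TLS)`` tuples.
    """
    out: list[tuple[str, int, int]] = []
    seen: set[str] = set()
    for r in intragenic_records:
        if r.tss_class != "intragenic" or not r.assigned_feature:
            continue
        feat = annotation.get(r.assigned_feature)
        if feat.feature_id in seen:
            continue
        seq = genome[feat.replicon_id] if isinstance(genome, dict) else genome
        half = feat.length / 2
        p = r.position
        if feat.strand == "+":
            if p - feat.start >= half:
                continue
            q = feat.start + ((p - feat.start + 2) // 3) * 3  # first in-frame codon at >= p
            while q - feat.start < half:
                codon = seq[q - 1 : q + 2]
                if codon in START_CODONS:
                    out.append((feat.feature_id, feat.start, q))
                    seen.add(feat.feature_id)
                    break
                q += 3
        else:
            if feat.end - p >= half:
                continue
            q = feat.end - ((feat.end - p + 2) // 3) * 3  # first in-frame codon start <= p
            while feat.end - q < half:
                codon = revcomp(seq[q - 3 : q])
                if codon in START_CODONS:
                    out.append((feat.feature_id, feat.end, q))
                    seen.add(feat.feature_id)
                    break
                q -= 3
    return out


def _extend_while_covered(
    start: int,
    strand: Strand,
    coverage: dict[Strand, np.ndarray],
    max_gap: int,
) -> Optional[int]:
    """Furthest covered position downstream of ``start`` tolerating gaps <= max_gap.

    Returns None when ``start`` itself is uncovered.
    """
    arr = coverage[strand]
    n = len(arr) - 1
    if not (1 <= start <= n) or arr[start] < 1:
        return None
    step = 1 if strand == "+" else -1
    pos = start
    last_covered = start
    gap = 0
    while True:
        pos += step
        if not (1 <= pos <= n):
            break
        if arr[pos] >= 1:
            last_covered = pos
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                break
    return last_covered


def estimate_three_prime_utrs(
    annotation: GenomeAnnotation,
    coverage: dict[Strand, np.ndarray],
    max_gap: int = 5,
) -> list[StrandInterval]:
    """Coverage-extended 3'-UTR intervals downstream of each CDS stop."""
    out: list[StrandInterval] = []
    for f in annotation.cds():
        step = 1 if f.strand == "+" else -1
        first = f.stop_position + step
        end = _extend_while_covered(first, f.strand, coverage, max_gap)
        if end is None:
            continue
        lo, hi = sorted((first, end))
        out.append((lo, hi, f.strand))
    return out


def delineate_novel_transcript(
    tss: TssRecord,
    whole_tx_coverage: dict[Strand, np.ndarray],
    annotation: GenomeAnnotation,
    min_len: int = 20,
    max_gap: int = 5,
    detected_utrs: Sequence[StrandInterval] = (),
) -> Optional[NovelTranscript]:
    """Delineate a novel transcript's 3' end from whole-transcriptome coverage.

    Extends downstream from the TSS while coverage >= 1, tolerating gaps of
    at most ``max_gap`` nt, and emits the transcript only if its length
    exceeds ``min_len`` (novel antisense transcripts shorter than that are
    suppressed).
    """
    if tss.tss_class not in ("intergenic", "intragenic", "antisense"):
        raise ValueError("only novel-path TSS classes can be delineated")
    end = _extend_while_covered(tss.position, tss.strand, whole_tx_coverage, max_gap)
    if end is None:
        return None
    lo, hi = sorted((tss.position, end))
    if hi - lo + 1 <= min_len:
        return None
    category = {
        "intergenic": "intergenic",
        "intragenic": "intragenic_sense",
        "antisense": "antisense",
    }[tss.tss_class]
    subtype = None
    if category == "antisense":
        opp = "-" if tss.strand == "+" else "+"
        cds_overlap = any(
            f.strand == opp and f.start <= hi and f.end >= lo for f in annotation.cds()
        )
        utr_overlap = any(
            s == opp and a <= hi and b >= lo for a, b, s in detected_utrs
        )
        if cds_overlap and utr_overlap:
            subtype = "cds_and_utr_overlap"
        elif cds_overlap:
            subtype = "cds_overlap"
        elif utr_overlap:
            subtype = "utr_overlap"
    return NovelTranscript(
        tss=tss, start=lo, end=hi, strand=tss.strand, category=category,
        antisense_subtype=subtype,
    )


def annotate_tss(
    candidates: Sequence[TssCandidate],
    annotation: GenomeAnnotation,
    whole_tx_coverage: Optional[dict[Strand, np.ndarray]] = None,
    params: TssDetectionParams | None = None,
    max_gap: int = 5,
) -> tuple[list[TssRecord], list[NovelTranscript]]:
    """Two-pass classification of a verified candidate set.

    The first pass finds utr/intragenic classes; detected 5'-UTRs (and,
    when coverage is given, estimated 3'-UTRs) then inform the antisense
    class in the second pass.  Novel-path TSSs are delineated to 3' ends
    when coverage is available.
    """
    params = params or TssDetectionParams()
    first = [classify_tss(c, annotation, (), params) for c in candidates]
    utrs = utr_intervals([r for r in first if r.tss_class == "utr"])
    if whole_tx_coverage is not None:
        utrs = utrs + estimate_three_prime_utrs(annotation, whole_tx_coverage, max_gap)
    records = [classify_tss(c, annotation, utrs, params) for c in candidates]
    assign_multiplicity(records)
    novels: list[NovelTranscript] = []
    if whole_tx_coverage is not None:
        for r in records:
            if r.tss_class in ("intergenic", "intragenic", "antisense"):
                nt = delineate_novel_transcript(
                    r, whole_tx_coverage, annotation, min_len=20,
                    max_gap=max_gap, detected_utrs=utrs,
                )
                if nt is not None:
                    novels.append(nt)
    return records, novels
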