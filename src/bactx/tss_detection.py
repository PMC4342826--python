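"""Automatic TSS calling from a 5'-enriched read-start profile.

A transcription start site shows up in a 5'-enriched library as a sharp
accumulation of read 5' ends over a low positional background.  A position
is called automatically when three criteria hold:

(a) its read-start count exceeds the background threshold ``T``;
(b) the ratio of its count to the count at the previous position (the
    adjacent position upstream in transcription direction) exceeds ``R``,
    where a previous count of zero passes by definition — a step from zero
    reads is the sharpest possible accumulation;
(c) a protein-coding TLS in the same orientation lies at most ``X`` nt
    downstream.

Candidates passing (a) and (b) but failing (c) are retained with
``tls_within_x=False`` for the novel-transcript path.  Both threshold
comparisons are strict: boundary values fail.

Two deterministic heuristics replace the study-style manual curation, so
every removal/addition is auditable: a near-miss rescue backed by
whole-transcriptome coverage, and a false-positive flag for candidates
sitting inside an uneven gradient of accumulated read starts.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .genome_model import (
    GeneFeature,
    GenomeAnnotation,
    ReadStartProfile,
    Strand,
    STRANDS,
)


@dataclass
class TssDetectionParams:
    """Thresholds for automatic TSS detection.

    ``T`` and ``R`` default to 6 and the TSS->TLS distance cutoff ``X`` to
    500 nt, values with a good signal-to-noise ratio for 5'-enriched
    bacterial libraries.
    """

    T: int = 6
    R: float = 6.0
    X: int = 500
    rescue_margin: int = 1
    fp_window: int = 50
    fp_peak_fraction: float = 0.5
    min_whole_tx_support: int = 1

    def __post_init__(self) -> None:
        if self.T < 0 or self.R <= 0 or self.X <= 0:
            raise ValueError("require T >= 0, R > 0, X > 0")


@dataclass
class TssCandidate:
    replicon_id: str
    position: int
    strand: Strand
    read_starts: int
    prev_read_starts: int
    ratio: float  # inf when the previous position carries no read starts
    detection_mode: str = "automatic"  # automatic | rescued | manual
    flags: set[str] = field(default_factory=set)
    tls_within_x: bool = False
    nearest_tls_feature: Optional[str] = None
    tls_distance: Optional[int] = None

    def __post_init__(self) -> None:
        if self.read_starts < 1:
            raise ValueError("an emitted candidate must carry >= 1 read starts")


def _prev_position(position: int, strand: Strand) -> int:
    """Adjacent position upstream in the direction of transcription."""
    return position - 1 if strand == "+" else position + 1


def _tls_arrays(annotation: GenomeAnnotation, types: tuple[str, ...] = ("CDS",)):
    """Sorted TLS positions and matching feature ids per strand."""
    out = {}
    for strand in STRANDS:
        feats = annotation.on_strand(strand, *types)
        pairs = sorted((f.tls, f.feature_id) for f in feats)
        out[strand] = ([p for p, _ in pairs], [i for _, i in pairs])
    return out


def nearest_downstream_tls(
    position: int,
    strand: Strand,
    tls_positions: Sequence[int],
    tls_ids: Sequence[str],
) -> tuple[Optional[str], Optional[int]]:
    """Nearest same-strand TLS at distance >= 0 downstream of ``position``.

    Distance is ``TLS - position`` on '+' and ``position - TLS`` on '-'.
    """
    if not tls_positions:
        return None, None
    if strand == "+":
        i = bisect_left(tls_positions, position)
        if i == len(tls_positions):
            return None, None
        return tls_ids[i], tls_positions[i] - position
    i = bisect_left(tls_positions, position + 1) - 1
    if i < 0:
        return None, None
    return tls_ids[i], position - tls_positions[i]


def detect_candidates(
    profile: ReadStartProfile,
    annotation: GenomeAnnotation,
    params: TssDetectionParams | None = None,
) -> list[TssCandidate]:
    """Evaluate the three detection criteria at every covered position.

    Returns candidates passing (a) and (b); criterion (c) is recorded in
    ``tls_within_x`` so callers can separate the gene-associated set from
    the novel-transcript path.
    """
    params = params or TssDetectionParams()
    if annotation.replicon_id != profile.replicon_id:
        raise ValueError(
            f"profile is for {profile.replicon_id!r}, annotation for {annotation.replicon_id!r}"
        )
    tls = _tls_arrays(annotation)
    out: list[TssCandidate] = []
    for strand in STRANDS:
        positions, ids = tls[strand]
        for pos in profile.positions(strand):
            c = profile.count(pos, strand)
            if c <= params.T:
                continue
            prev = profile.count(_prev_position(pos, strand), strand)
            ratio = math.inf if prev == 0 else c / prev
            if not (prev == 0 or c / prev > params.R):
                continue
            fid, dist = nearest_downstream_tls(pos, strand, positions, ids)
            within = dist is not None and 0 <= dist <= params.X
            out.append(
                TssCandidate(
                    replicon_id=profile.replicon_id,
                    position=pos,
                    strand=strand,
                    read_starts=c,
                    prev_read_starts=prev,
                    ratio=ratio,
                    tls_within_x=within,
                    nearest_tls_feature=fid if within else None,
                    tls_distance=dist if within else None,
                )
            )
    out.sort(key=lambda t: (t.strand, t.position))
    return out


def find_near_misses(
    profile: ReadStartProfile,
    annotation: GenomeAnnotation,
    params: TssDetectionParams | None = None,
) -> list[TssCandidate]:
    """Positions failing exactly one of criteria (a)/(b) by <= rescue_margin reads.

    Criterion (a) nearly holds when ``T - margin < count <= T``; criterion
    (b) nearly holds when ``(count + margin) / prev > R`` although
    ``count / prev <= R``.
    """
    params = params or TssDetectionParams()
    tls = _tls_arrays(annotation)
    out: list[TssCandidate] = []
    for strand in STRANDS:
        positions, ids = tls[strand]
        for pos in profile.positions(strand):
            c = profile.count(pos, strand)
            prev = profile.count(_prev_position(pos, strand), strand)
            pass_a = c > params.T
            pass_b = prev == 0 or c / prev > params.R
            near_a = (not pass_a) and c > params.T - params.rescue_margin
            near_b = (not pass_b) and (c + params.rescue_margin) / prev > params.R
            if (pass_a and near_b) or (pass_b and near_a):
                fid, dist = nearest_downstream_tls(pos, strand, positions, ids)
                within = dist is not None and 0 <= dist <= params.X
                out.append(
                    TssCandidate(
                        replicon_id=profile.replicon_id,
                        position=pos,
                        strand=strand,
                        read_starts=c,
                        prev_read_starts=prev,
                        ratio=math.inf if prev == 0 else c / prev,
                        detection_mode="rescued",
                        tls_within_x=within,
                        nearest_tls_feature=fid if within else None,
                        tls_distance=dist if within else None,
                    )
                )
    out.sort(key=lambda t: (t.strand, t.position))
    return out


def rescue_candidates(
    near_misses: Sequence[TssCandidate],
    profile: ReadStartProfile,
    whole_tx_profile,
    params: TssDetectionParams | None = None,
    support_window: int = 20,
) -> list[TssCandidate]:
    """Rescue near-miss candidates confirmed by whole-transcriptome coverage.

    A near miss is rescued iff the whole-transcriptome data supports a
    transcript there: coverage >= ``min_whole_tx_support`` at each of the
    first ``support_window`` positions starting at the putative TSS.

    ``whole_tx_profile`` may be a :class:`ReadStartProfile` or a per-strand
    coverage array dict as produced by
    :func:`bactx.genome_model.coverage_from_fragments`.
    """
    params = params or TssDetectionParams()

    if isinstance(whole_tx_profile, ReadStartProfile):
        def cov(pos: int, strand: Strand) -> int:
            return whole_tx_profile.count(pos, strand)
    else:
        def cov(pos: int, strand: Strand) -> int:
            arr = whole_tx_profile[strand]
            return int(arr[pos]) if 0 < pos < len(arr) else 0

    rescued: list[TssCandidate] = []
    for cand in near_misses:
        step = 1 if cand.strand == "+" else -1
        supported = all(
            cov(cand.position + step * k, cand.strand) >= params.min_whole_tx_support
            for k in range(support_window)
        )
        if supported:
            rescued.append(replace(cand, detection_mode="rescued"))
    return rescued


def flag_false_positives(
    candidates: Sequence[TssCandidate],
    profile: ReadStartProfile,
    params: TssDetectionParams | None = None,
) -> list[TssCandidate]:
    """Flag candidates sitting inside an uneven gradient of read starts.

    A candidate is flagged ``false_positive`` iff its count is below
    ``fp_peak_fraction`` of the maximum count within ``fp_window`` nt on
    either side AND at least 3 other positions in that window carry counts
    above ``T``.  Such patterns arise inside highly covered coding regions
    where no single position is a clear transcript 5' end.
    """
    params = params or TssDetectionParams()
    out: list[TssCandidate] = []
    for cand in candidates:
        strand_counts = profile.counts[cand.strand]
        lo, hi = cand.position - params.fp_window, cand.position + params.fp_window
        window = [
            (p, c) for p, c in strand_counts.items() if lo <= p <= hi
        ]
        window_max = max(c for _, c in window)
        n_supra = sum(
            1 for p, c in window if p != cand.position and c > params.T
        )
        flags = set(cand.flags)
        if cand.read_starts < params.fp_peak_fraction * window_max and n_supra >= 3:
            flags.add("false_positive")
        out.append(replace(cand, flags=flags))
    return out


def drop_stable_rna_tss(
    candidates: Sequence[TssCandidate],
    annotation: GenomeAnnotation,
    max_distance: Optional[int] = None,
) -> tuple[list[TssCandidate], int]:
    """Remove candidates whose nearest downstream feature is a rRNA or tRNA.

    Stable-RNA 5' ends survive the 5'-enrichment and would otherwise be
    reported as TSSs.  A candidate is removed iff the nearest same-strand
    feature within ``max_distance`` (default: the detection cutoff ``X``)
    downstream is of type rRNA or tRNA.
    """
    max_distance = max_distance if max_distance is not None else TssDetectionParams().X
    all_tls = _tls_arrays(annotation, types=("CDS", "rRNA", "tRNA", "sRNA"))
    types_by_id = {f.feature_id: f.feature_type for f in annotation}
    kept: list[TssCandidate] = []
    removed = 0
    for cand in candidates:
        positions, ids = all_tls[cand.strand]
        fid, dist = nearest_downstream_tls(cand.position, cand.strand, positions, ids)
        if (
            fid is not None
            and dist is not None
            and dist <= max_distance
            and types_by_id[fid] in ("rRNA", "tRNA")
        ):
            removed += 1
            continue
        kept.append(cand)
    return kept, removed


@dataclass
class TssDetectionResult:
    """Final candidate set plus the bookkeeping of each curation step.

    The arithmetic ``automatic - false_positive - stable_rna + rescued ==
    final`` always holds.
    """

    candidates: list[TssCandidate]
    n_automatic: int
    n_false_positive: int
    n_stable_rna: int
    n_rescued: int

    @property
    def n_final(self) -> int:
        return len(self.candidates)


def detect_tss(
    profile: ReadStartProfile,
    annotation: GenomeAnnotation,
    whole_tx_coverage=None,
    params: TssDetectionParams | None = None,
) -> TssDetectionResult:
    """Run the full detection chain: call, flag, drop stable RNAs, rescue."""
    params = params or TssDetectionParams()
    automatic = detect_candidates(profile, annotation, params)
    flagged = flag_false_positives(automatic, profile, params)
    n_fp = sum(1 for c in flagged if "false_positive" in c.flags)
    surviving = [c for c in flagged if "false_positive" not in c.flags]
    kept, n_stable = drop_stable_rna_tss(surviving, annotation, params.X)
    rescued: list[TssCandidate] = []
    if whole_tx_coverage is not None:
        near = find_near_misses(profile, annotation, params)
        rescued = rescue_candidates(near, profile, whole_tx_coverage, params)
    final = sorted(kept + rescued, key=lambda t: (t.strand, t.position))
    return TssDetectionResult(
        candidates=final,
        n_automatic=len(automatic),
        n_false_positive=n_fp,
        n_stable_rna=n_stable,
        n_rescued=len(rescued),
    )
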