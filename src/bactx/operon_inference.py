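"""Operon inference from paired-fragment bridging of same-strand gene junctions.

Two adjacent genes in the same orientation are joined when at least
``bridge_threshold`` paired fragments bridge their junction — i.e. a
fragment covers the last base of the upstream gene and the first base of
the downstream gene.  A fragment lying only inside the intergenic gap does
not connect the genes.  Transitive joining yields maximal chains (primary
operons); genes joined to no neighbor but overlapped by at least one
fragment are monocistronic; untouched genes are untranscribed.

Suboperons are suffixes of an operon's member list headed by a gene with
its own internal TSS.  The manual "functionally related" rescue of the
study becomes an explicit, optional, label-driven step so the pipeline
stays deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .genome_model import GenomeAnnotation, GeneFeature, PairedFragment, Strand, STRANDS
from .tss_annotation import TssRecord


@dataclass
class OperonParams:
    bridge_threshold: int = 4
    functional_rescue_margin: int = 1

    def __post_init__(self) -> None:
        if self.bridge_threshold < 1:
            raise ValueError("bridge_threshold must be >= 1")


@dataclass
class Suboperon:
    first_gene_id: str
    member_gene_ids: list[str]
    tss: Optional[TssRecord] = None


@dataclass
class OperonModel:
    """A primary operon: ordered member genes plus junction support.

    ``member_gene_ids`` are in transcription order (5' to 3');
    ``junction_support`` holds the bridging fragment count for each
    adjacent member pair, and ``rescued_junctions`` marks junctions joined
    by the functional rescue rather than the bridging threshold.
    """

    operon_id: str
    member_gene_ids: list[str]
    strand: Strand
    junction_support: list[int]
    rescued_junctions: list[bool] = field(default_factory=list)
    primary_tss: Optional[TssRecord] = None
    suboperons: list[Suboperon] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)


def _genes_in_transcription_order(
    annotation: GenomeAnnotation, strand: Strand
) -> list[GeneFeature]:
    genes = sorted(annotation.on_strand(strand, "CDS"), key=lambda f: f.start)
    return genes if strand == "+" else genes[::-1]


def junction_supports(
    annotation: GenomeAnnotation,
    fragments: Sequence[PairedFragment],
) -> dict[Strand, list[tuple[str, str, int]]]:
    """Bridging fragment count for every adjacent same-strand gene pair.

    Pairs are reported in transcription order as (upstream_gene,
    downstream_gene, count).  A fragment bridges iff it covers the flanking
    base of both genes; for overlapping genes any fragment covering the
    junction point counts.
    """
    frag_arrays: dict[Strand, tuple[np.ndarray, np.ndarray]] = {}
    for strand in STRANDS:
        fs = [f for f in fragments if f.strand == strand]
        frag_arrays[strand] = (
            np.array([f.start for f in fs], dtype=np.int64),
            np.array([f.end for f in fs], dtype=np.int64),
        )
    out: dict[Strand, list[tuple[str, str, int]]] = {}
    for strand in STRANDS:
        starts, ends = frag_arrays[strand]
        genes = _genes_in_transcription_order(annotation, strand)
        pairs: list[tuple[str, str, int]] = []
        for up, down in zip(genes, genes[1:]):
            # flanking bases of the junction: last base of the upstream gene
            # and first base of the downstream gene, in genomic coordinates
            if strand == "+":
                left_base, right_base = up.end, down.start
            else:
                left_base, right_base = down.end, up.start
            if left_base > right_base:  # overlapping genes: junction point
                left_base = right_base
            n = int(((starts <= left_base) & (ends >= right_base)).sum())
            pairs.append((up.feature_id, down.feature_id, n))
        out[strand] = pairs
    return out


def rescue_functional_pairs(
    junctions: Sequence[tuple[str, str, int]],
    functional_labels: Mapping[str, str],
    params: OperonParams | None = None,
) -> list[tuple[str, str]]:
    """Near-miss junctions joined because both genes share a functional label.

    A junction qualifies when its support falls short of the bridging
    threshold by at most ``functional_rescue_margin`` fragments and both
    genes carry the same (non-empty) functional label.
    """
    params = params or OperonParams()
    lo = params.bridge_threshold - params.functional_rescue_margin
    out = []
    for up, down, n in junctions:
        if lo <= n < params.bridge_threshold:
            lu, ld = functional_labels.get(up), functional_labels.get(down)
            if lu and lu == ld:
                out.append((up, down))
    return out


def infer_primary_operons(
    annotation: GenomeAnnotation,
    fragments: Sequence[PairedFragment],
    params: OperonParams | None = None,
    functional_labels: Optional[Mapping[str, str]] = None,
) -> tuple[list[OperonModel], list[str], list[str]]:
    """Build primary operons, monocistronic and untranscribed gene lists.

    Returns ``(operons, monocistronic_gene_ids, untranscribed_gene_ids)``.
    When ``functional_labels`` is given, near-miss junctions between
    same-labeled genes are additionally joined and flagged.
    """
    params = params or OperonParams()
    supports = junction_supports(annotation, fragments)
    rescued: set[tuple[str, str]] = set()
    if functional_labels:
        for strand in STRANDS:
            rescued.update(
                rescue_functional_pairs(supports[strand], functional_labels, params)
            )

    frag_by_strand = {
        s: [f for f in fragments if f.strand == s] for s in STRANDS
    }
    operons: list[OperonModel] = []
    in_operon: set[str] = set()
    counter = 0
    for strand in STRANDS:
        genes = _genes_in_transcription_order(annotation, strand)
        joined = []
        for up, down, n in supports[strand]:
            joined.append(n >= params.bridge_threshold or (up, down) in rescued)
        i = 0
        while i < len(genes):
            j = i
            while j < len(genes) - 1 and joined[j]:
                j += 1
            if j > i:
                counter += 1
                members = [g.feature_id for g in genes[i : j + 1]]
                operons.append(
                    OperonModel(
                        operon_id=f"operon_{counter:04d}",
                        member_gene_ids=members,
                        strand=strand,
                        junction_support=[supports[strand][k][2] for k in range(i, j)],
                        rescued_junctions=[
                            (supports[strand][k][0], supports[strand][k][1]) in rescued
                            for k in range(i, j)
                        ],
                    )
                )
                in_operon.update(members)
            i = j + 1

    monocistronic: list[str] = []
    untranscribed: list[str] = []
    for strand in STRANDS:
        fs = frag_by_strand[strand]
        starts = np.array([f.start for f in fs], dtype=np.int64)
        ends = np.array([f.end for f in fs], dtype=np.int64)
        for g in annotation.on_strand(strand, "CDS"):
            if g.feature_id in in_operon:
                continue
            covered = bool(((starts <= g.end) & (ends >= g.start)).any())
            (monocistronic if covered else untranscribed).append(g.feature_id)
    operons.sort(key=lambda o: o.operon_id)
    return operons, sorted(monocistronic), sorted(untranscribed)


def call_suboperons(
    operons: Sequence[OperonModel],
    tss_records: Sequence[TssRecord],
) -> list[OperonModel]:
    """Attach primary TSSs and call suboperons at internal TSSs (in place).

    For each utr-class TSS assigned to a non-first member gene, the
    suboperon runs from that gene to the operon's last gene.  A utr TSS of
    the first gene becomes the operon's primary TSS (the most upstream one
    when several exist).
    """
    by_gene: dict[str, list[TssRecord]] = {}
    for r in tss_records:
        if r.tss_class == "utr" and r.assigned_feature:
            by_gene.setdefault(r.assigned_feature, []).append(r)
    for op in operons:
        first = op.member_gene_ids[0]
        if first in by_gene:
            cands = by_gene[first]
            op.primary_tss = max(
                cands, key=lambda r: r.utr_length if r.utr_length is not None else -1
            )
        op.suboperons = []
        for k, gid in enumerate(op.member_gene_ids[1:], start=1):
            for r in by_gene.get(gid, []):
                op.suboperons.append(
                    Suboperon(
                        first_gene_id=gid,
                        member_gene_ids=op.member_gene_ids[k:],
                        tss=r,
                    )
                )
                break  # one suboperon per internal gene
    return list(operons)


@dataclass
class OrganizationSummary:
    n_monocistronic: int
    n_operons: int
    n_suboperons: int
    genes_in_operons: int
    operon_size_histogram: dict[int, int]
    n_genes_annotated: int
    n_genes_transcribed: int
    fraction_transcribed_percent: float


def summarize_organization(
    operons: Sequence[OperonModel],
    monocistronic: Sequence[str],
    annotation: GenomeAnnotation,
) -> OrganizationSummary:
    """Transcript-organization summary with the percentage of transcribed genes."""
    from .pipeline import percent

    hist: dict[int, int] = {}
    for op in operons:
        hist[op.size] = hist.get(op.size, 0) + 1
    genes_in_operons = sum(op.size for op in operons)
    n_annot = len(annotation.cds())
    n_tx = genes_in_operons + len(monocistronic)
    return OrganizationSummary(
        n_monocistronic=len(monocistronic),
        n_operons=len(operons),
        n_suboperons=sum(len(op.suboperons) for op in operons),
        genes_in_operons=genes_in_operons,
        operon_size_histogram=dict(sorted(hist.items())),
        n_genes_annotated=n_annot,
        n_genes_transcribed=n_tx,
        fraction_transcribed_percent=percent(n_tx, n_annot) if n_annot else 0.0,
    )
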