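"""Domain types and I/O for a bacterial replicon.

Coordinate convention: 1-based, fully inclusive on both ends (the GFF3
convention), everywhere in this package.  Strands are ``'+'`` and ``'-'``.

The interchange formats are deliberately plain text so the pipeline is
testable without alignment files:

* annotation: GFF3 (read via :func:`parse_annotation`)
* genome: FASTA (read via :func:`read_fasta`)
* read starts: ``readstarts.tsv`` with columns replicon, position, strand, count
* single mappings: ``mappings.tsv`` with columns replicon, start, end, strand, mate_id
* paired fragments: ``fragments.tsv`` with columns replicon, start, end, strand

All TSVs are tab-separated, UTF-8, with ``#`` comment lines.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

Strand = Literal["+", "-"]
STRANDS: tuple[Strand, Strand] = ("+", "-")

#: Feature types carried through annotation parsing.
FEATURE_TYPES = ("CDS", "rRNA", "tRNA", "sRNA", "novel")

PRIMARY_LIBRARY = "five_prime_enriched"
WHOLE_LIBRARY = "whole_transcriptome"


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GeneFeature:
    """An annotated feature with 1-based inclusive coordinates.

    ``start`` is always the leftmost and ``end`` the rightmost genomic
    position regardless of strand (GFF3 keeps leftmost-first).
    """

    feature_id: str
    replicon_id: str
    start: int
    end: int
    strand: Strand
    feature_type: str = "CDS"
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"feature {self.feature_id}: end ({self.end}) < start ({self.start})"
            )
        if self.start < 1:
            raise AnnotationError(f"feature {self.feature_id}: start < 1")
        if self.strand not in STRANDS:
            raise AnnotationError(f"feature {self.feature_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tls(self) -> int:
        """First base of the feature in transcription direction.

        For a CDS this is the first base of the start codon (the TLS).
        """
        return self.start if self.strand == "+" else self.end

    @property
    def stop_position(self) -> int:
        """Last base of the feature in transcription direction."""
        return self.end if self.strand == "+" else self.start

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class GenomeAnnotation:
    """All features of one replicon, sorted by leftmost coordinate."""

    replicon_id: str
    length: int
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.feature_id))
        seen: set[str] = set()
        for f in self.features:
            if f.replicon_id != self.replicon_id:
                raise AnnotationError(
                    f"feature {f.feature_id} on replicon {f.replicon_id!r}, "
                    f"annotation is for {self.replicon_id!r}"
                )
            if f.end > self.length:
                raise AnnotationError(
                    f"feature {f.feature_id} extends past replicon end ({self.length})"
                )
            if f.feature_id in seen:
                raise AnnotationError(f"duplicate feature id {f.feature_id}")
            seen.add(f.feature_id)
        self._by_id = {f.feature_id: f for f in self.features}

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, feature_id: str) -> GeneFeature:
        return self._by_id[feature_id]

    def of_type(self, *types: str) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_type in types]

    def cds(self) -> list[GeneFeature]:
        return self.of_type("CDS")

    def on_strand(self, strand: Strand, *types: str) -> list[GeneFeature]:
        types = types or FEATURE_TYPES
        return [f for f in self.features if f.strand == strand and f.feature_type in types]


@dataclass
class ReadStartProfile:
    """Sparse stranded map position -> read-start count for one replicon.

    ``total_mapped`` is the number of mapped reads contributing to the
    profile; by default the sum of stored counts, but it may be supplied
    explicitly (e.g. when the profile covers a subregion of the library).
    """

    replicon_id: str
    library: str = PRIMARY_LIBRARY
    counts: dict[Strand, dict[int, int]] = field(default_factory=lambda: {"+": {}, "-": {}})
    total_mapped: Optional[int] = None

    def __post_init__(self) -> None:
        for strand in STRANDS:
            self.counts.setdefault(strand, {})
            for pos, c in self.counts[strand].items():
                if c < 1:
                    raise ValueError(f"count at {pos}{strand} must be >= 1, got {c}")
                if pos < 1:
                    raise ValueError(f"position {pos} < 1")
        if self.total_mapped is None:
            self.total_mapped = sum(sum(d.values()) for d in self.counts.values())

    def count(self, position: int, strand: Strand) -> int:
        return self.counts[strand].get(position, 0)

    def positions(self, strand: Strand) -> list[int]:
        return sorted(self.counts[strand])

    def add(self, position: int, strand: Strand, count: int = 1) -> None:
        if count < 1:
            raise ValueError("count must be >= 1")
        self.counts[strand][position] = self.counts[strand].get(position, 0) + count

    @property
    def n_positions(self) -> int:
        return sum(len(d) for d in self.counts.values())


@dataclass(frozen=True)
class SingleMapping:
    """One mapped read (or mate) as a genomic interval."""

    replicon_id: str
    start: int
    end: int
    strand: Strand
    mate_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"mapping end ({self.end}) < start ({self.start})")


@dataclass(frozen=True)
class PairedFragment:
    """Outermost span of a combined mate pair: a proxy for one cDNA fragment."""

    replicon_id: str
    start: int
    end: int
    strand: Strand

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"fragment end ({self.end}) < start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end


# ---------------------------------------------------------------------------
# GFF3 / FASTA
# ---------------------------------------------------------------------------

_GFF_TYPE_MAP = {
    "CDS": "CDS",
    "gene": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "sRNA": "sRNA",
    "ncRNA": "sRNA",
    "novel": "novel",
}


def parse_annotation(
    gff3: str | io.TextIOBase,
    replicon_length: Optional[int] = None,
    replicon_id: Optional[str] = None,
) -> GenomeAnnotation:
    """Parse GFF3 text into a :class:`GenomeAnnotation`.

    Only CDS/rRNA/tRNA/sRNA records are retained.  The replicon length is
    taken from the ``##sequence-region`` pragma unless supplied.  Malformed
    lines raise :class:`AnnotationError` naming the line number.
    """
    text = gff3.read() if hasattr(gff3, "read") else gff3
    features: list[GeneFeature] = []
    seq_region: dict[str, int] = {}
    auto_id = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                seq_region[parts[1]] = int(parts[3])
            continue
        if line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise AnnotationError(
                f"malformed GFF3 at line {lineno}: expected 9 tab-separated columns"
            )
        try:
            raw = feature_from_line(line)
        except Exception as exc:  # gffutils raises various types
            raise AnnotationError(f"malformed GFF3 at line {lineno}: {exc}") from exc
        ftype = _GFF_TYPE_MAP.get(raw.featuretype)
        if ftype is None:
            continue
        attrs = raw.attributes
        fid = (attrs.get("ID") or attrs.get("locus_tag") or [None])[0]
        if fid is None:
            auto_id += 1
            fid = f"feature_{auto_id}"
        product = (attrs.get("product") or [None])[0]
        try:
            features.append(
                GeneFeature(
                    feature_id=fid,
                    replicon_id=raw.seqid,
                    start=int(raw.start),
                    end=int(raw.end),
                    strand=raw.strand,
                    feature_type=ftype,
                    product=product,
                )
            )
        except AnnotationError as exc:
            raise AnnotationError(f"line {lineno}: {exc}") from exc
    if not features and replicon_id is None and not seq_region:
        raise AnnotationError("empty annotation and no ##sequence-region pragma")
    rid = replicon_id or (features[0].replicon_id if features else next(iter(seq_region)))
    length = replicon_length or seq_region.get(rid)
    if length is None:
        raise AnnotationError(
            f"no ##sequence-region pragma for {rid!r}; supply replicon_length"
        )
    features = [f for f in features if f.replicon_id == rid]
    return GenomeAnnotation(replicon_id=rid, length=length, features=features)


def annotation_to_gff3(annotation: GenomeAnnotation) -> str:
    """Serialize an annotation back to GFF3 (round-trips with parse_annotation)."""
    lines = [
        "##gff-version 3",
        f"##sequence-region {annotation.replicon_id} 1 {annotation.length}",
    ]
    for f in annotation.features:
        attrs = f"ID={f.feature_id}"
        if f.product:
            attrs += f";product={f.product}"
        lines.append(
            "\t".join(
                [
                    f.replicon_id,
                    "bactx",
                    f.feature_type,
                    str(f.start),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def read_fasta(handle_or_text: str | io.TextIOBase) -> dict[str, str]:
    """Read a FASTA file/text into {replicon_id: uppercase sequence}."""
    if isinstance(handle_or_text, str):
        handle = io.StringIO(handle_or_text)
    else:
        handle = handle_or_text
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: dict[str, str], width: int = 70) -> str:
    out = []
    for rid, seq in sequences.items():
        out.append(f">{rid}")
        out.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------


def _read_tsv(source, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", comment="#", header=None, names=list(columns))
    return df


def load_read_starts(
    source,
    library: str = PRIMARY_LIBRARY,
    total_mapped: Optional[int] = None,
) -> ReadStartProfile:
    """Load a readstarts.tsv (replicon, position, strand, count) into a profile.

    ``total_mapped`` defaults to a ``# total_mapped:`` header comment when
    present (written by :func:`write_read_starts`), else the sum of counts.
    Duplicate (position, strand) rows and non-positive counts are rejected.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\t" in source:
        text = source
    else:
        from pathlib import Path

        text = Path(source).read_text()
    if total_mapped is None:
        for line in text.splitlines():
            if line.startswith("# total_mapped:"):
                total_mapped = int(line.split(":", 1)[1].strip())
                break
            if not line.startswith("#"):
                break
    source = io.StringIO(text)
    df = _read_tsv(source, ["replicon", "position", "strand", "count"])
    if df.empty:
        return ReadStartProfile(replicon_id="", library=library, total_mapped=total_mapped or 0)
    replicons = df["replicon"].unique()
    if len(replicons) != 1:
        raise ValueError(f"expected a single replicon per file, got {list(replicons)}")
    if (df["count"] <= 0).any():
        bad = df.loc[df["count"] <= 0].iloc[0]
        raise ValueError(f"non-positive count {bad['count']} at position {bad['position']}")
    if df.duplicated(subset=["position", "strand"]).any():
        bad = df.loc[df.duplicated(subset=["position", "strand"])].iloc[0]
        raise ValueError(f"duplicate row for position {bad['position']} strand {bad['strand']}")
    counts: dict[Strand, dict[int, int]] = {"+": {}, "-": {}}
    for strand in STRANDS:
        sub = df[df["strand"] == strand]
        counts[strand] = dict(zip(sub["position"].astype(int), sub["count"].astype(int)))
    return ReadStartProfile(
        replicon_id=str(replicons[0]),
        library=library,
        counts=counts,
        total_mapped=total_mapped,
    )


def write_read_starts(profile: ReadStartProfile) -> str:
    lines = [
        f"# library: {profile.library}",
        f"# total_mapped: {profile.total_mapped}",
        "# replicon\tposition\tstrand\tcount",
    ]
    for strand in STRANDS:
        for pos in profile.positions(strand):
            lines.append(
                f"{profile.replicon_id}\t{pos}\t{strand}\t{profile.counts[strand][pos]}"
            )
    return "\n".join(lines) + "\n"


def load_mappings(source) -> list[SingleMapping]:
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = _read_tsv(source, ["replicon", "start", "end", "strand", "mate_id"])
    return [
        SingleMapping(
            replicon_id=str(r.replicon),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            mate_id=None if pd.isna(r.mate_id) else str(r.mate_id),
        )
        for r in df.itertuples()
    ]


def load_fragments(source) -> list[PairedFragment]:
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = _read_tsv(source, ["replicon", "start", "end", "strand"])
    return [
        PairedFragment(str(r.replicon), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples()
    ]


def write_fragments(fragments: Iterable[PairedFragment]) -> str:
    lines = ["# replicon\tstart\tend\tstrand"]
    lines += [f"{f.replicon_id}\t{f.start}\t{f.end}\t{f.strand}" for f in fragments]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Read-pair combining
# ---------------------------------------------------------------------------


def combine_read_pairs(
    mates: Sequence[SingleMapping],
    max_distance: int = 1000,
) -> tuple[list[PairedFragment], list[SingleMapping], int]:
    """Combine mate pairs into fragments spanning their outermost coordinates.

    Mates are paired by ``mate_id``.  A pair whose outer span exceeds
    ``max_distance`` is discarded; mates without a partner (or whose partner
    maps to a different replicon) are retained as single mappings.  The
    fragment strand is taken from the first-in-pair mate, i.e. the
    orientation of the transcript.

    Returns ``(fragments, singles, discarded_pair_count)``.  The partition
    satisfies ``2*len(fragments) + len(singles) + 2*discarded == len(mates)``.
    """
    groups: dict[str, list[SingleMapping]] = {}
    singles: list[SingleMapping] = []
    order: list[str] = []
    for m in mates:
        if m.mate_id is None:
            singles.append(m)
            continue
        if m.mate_id not in groups:
            order.append(m.mate_id)
        groups.setdefault(m.mate_id, []).append(m)
    fragments: list[PairedFragment] = []
    discarded = 0
    for mid in order:
        pair = groups[mid]
        if len(pair) != 2 or pair[0].replicon_id != pair[1].replicon_id:
            singles.extend(pair)
            continue
        first, second = pair
        span_start = min(first.start, second.start)
        span_end = max(first.end, second.end)
        if span_end - span_start + 1 > max_distance:
            discarded += 1
            continue
        fragments.append(
            PairedFragment(first.replicon_id, span_start, span_end, first.strand)
        )
    return fragments, singles, discarded


# ---------------------------------------------------------------------------
# Derived per-position maps
# ---------------------------------------------------------------------------


def coverage_from_fragments(
    fragments: Iterable[PairedFragment], replicon_length: int
) -> dict[Strand, np.ndarray]:
    """Per-position fragment coverage depth, one 1-based array per strand.

    Index 0 of each array is unused; position ``p`` is ``array[p]``.
    """
    cov = {s: np.zeros(replicon_length + 2, dtype=np.int64) for s in STRANDS}
    for f in fragments:
        a = cov[f.strand]
        a[f.start] += 1
        a[min(f.end + 1, replicon_length + 1)] -= 1
    return {s: np.cumsum(a)[: replicon_length + 1] for s, a in cov.items()}


def fragment_start_profile(
    fragments: Iterable[PairedFragment],
    replicon_id: str,
    total_mapped: Optional[int] = None,
) -> ReadStartProfile:
    """Profile of fragment 5' start positions (whole-transcriptome library)."""
    counts: dict[Strand, dict[int, int]] = {"+": {}, "-": {}}
    n = 0
    for f in fragments:
        counts[f.strand][f.five_prime] = counts[f.strand].get(f.five_prime, 0) + 1
        n += 1
    return ReadStartProfile(
        replicon_id=replicon_id,
        library=WHOLE_LIBRARY,
        counts=counts,
        total_mapped=total_mapped if total_mapped is not None else n,
    )


def feature_length(start: int, end: int, inclusive: bool = True) -> int:
    """Length of an interval between two coordinates.

    ``inclusive=True`` gives ``|start - end| + 1`` (this package's
    convention); ``inclusive=False`` gives the bare coordinate difference, a
    compatibility mode for published feature tables that mix conventions.
    """
    diff = abs(start - end)
    return diff + 1 if inclusive else diff


def peptide_length(peptide: str) -> int:
    """Number of amino-acid residues in a printed peptide string.

    Trailing stop markers (``-Stop``, ``*``) and whitespace are ignored.
    """
    cleaned = peptide.strip().removesuffix("-Stop").rstrip("*").strip()
    return sum(1 for c in cleaned if c.isalpha())
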