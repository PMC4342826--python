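"""Normalized transcript abundance (log-RPKM) per annotated feature.

The abundance of a feature is computed from the whole-transcriptome
read-start profile in three steps.  Over the ``N`` feature positions that
carry at least one read start (same strand), the arithmetic mean of the
natural logarithms of the per-position counts is taken:

    x_bar = sum(ln(rs_p)) / N

The geometric-mean-based normalized read count is then

    R_norm = e^x_bar * N

and the final value is R_norm scaled by feature length in kilobases and
mapped reads in millions (the common RPKM denominator):

    value = R_norm / (length_kb * total_mapped / 1e6)

Averaging logarithms damps fragmentation and PCR pile-ups at single
positions, which would dominate a plain read-count sum.  Restricting the
mean to covered positions makes ln(0) terms impossible; an alternative
reading that divides by the feature length is available behind
``use_feature_length``.

Values fall into five classes: untranscribed (no covered position),
low (0, 16], middle (16, 160], high (160, 1600] and very_high (> 1600).
Totals are per replicon: cross-replicon comparison of these values is not
meaningful and is not offered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .genome_model import GenomeAnnotation, GeneFeature, ReadStartProfile


@dataclass
class AbundanceParams:
    class_boundaries: tuple[float, float, float] = (16.0, 160.0, 1600.0)
    strand_specific: bool = True
    use_feature_length: bool = False  # N := feature length instead of covered positions

    def __post_init__(self) -> None:
        b = self.class_boundaries
        if not (0 < b[0] < b[1] < b[2]):
            raise ValueError("class boundaries must be strictly increasing and positive")


CLASS_NAMES = ("untranscribed", "low", "middle", "high", "very_high")


@dataclass
class AbundanceRecord:
    feature_id: str
    n_covered: int
    x_bar: float
    r_norm: float
    value: float
    abundance_class: str


def classify_abundance(value: float, params: AbundanceParams | None = None) -> str:
    """Map a log-RPKM value to its abundance class (lower-exclusive bounds)."""
    params = params or AbundanceParams()
    if value < 0:
        raise ValueError("abundance value must be >= 0")
    b1, b2, b3 = params.class_boundaries
    if value == 0:
        return "untranscribed"
    if value <= b1:
        return "low"
    if value <= b2:
        return "middle"
    if value <= b3:
        return "high"
    return "very_high"


def log_rpkm(
    feature: GeneFeature,
    profile: ReadStartProfile,
    total_mapped: Optional[int] = None,
    params: AbundanceParams | None = None,
) -> AbundanceRecord:
    """Abundance record for one feature from the whole-transcriptome profile."""
    params = params or AbundanceParams()
    total = total_mapped if total_mapped is not None else profile.total_mapped
    if not total or total <= 0:
        raise ValueError("total_mapped must be > 0")
    strands = (feature.strand,) if params.strand_specific else ("+", "-")
    log_sum = 0.0
    n = 0
    for strand in strands:
        counts = profile.counts[strand]
        for pos in range(feature.start, feature.end + 1):
            c = counts.get(pos, 0)
            if c >= 1:
                log_sum += math.log(c)
                n += 1
    if n == 0:
        return AbundanceRecord(feature.feature_id, 0, 0.0, 0.0, 0.0, "untranscribed")
    x_bar = log_sum / n
    n_eff = feature.length if params.use_feature_length else n
    r_norm = math.exp(x_bar) * n_eff
    value = r_norm / ((feature.length / 1000.0) * (total / 1e6))
    return AbundanceRecord(
        feature.feature_id, n, x_bar, r_norm, value, classify_abundance(value, params)
    )


def abundance_table(
    annotation: GenomeAnnotation,
    profile: ReadStartProfile,
    params: AbundanceParams | None = None,
    total_mapped: Optional[int] = None,
) -> tuple[list[AbundanceRecord], dict[str, tuple[int, float]]]:
    """Abundance records for every feature plus a class tally with percentages.

    Percentages are rounded half away from zero to one decimal.
    """
    from .pipeline import percent

    params = params or AbundanceParams()
    records = [
        log_rpkm(f, profile, total_mapped=total_mapped, params=params)
        for f in annotation.cds()
    ]
    total = len(records)
    tally = {}
    for name in CLASS_NAMES:
        c = sum(1 for r in records if r.abundance_class == name)
        tally[name] = (c, percent(c, total) if total else float("nan"))
    n_detected = total - tally["untranscribed"][0]
    tally["transcribed"] = (n_detected, percent(n_detected, total) if total else float("nan"))
    return records, tally
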