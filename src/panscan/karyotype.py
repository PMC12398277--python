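"""Karyotype fusion-point detection and coordinate splitting.

Swamp buffalo (2n = 48) carry a fusion of river buffalo (2n = 50)
chromosomes 4 and 9 on their chromosome 1. Aligning the fused chromosome
against the river reference yields two alignment clusters, one per river
chromosome; the fusion point is the midpoint of the gap between them. The
fused chromosome can then be split at that point into two segments with a
trivially invertible coordinate lift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .variants import PafRecord

__all__ = [
    "FusionCall",
    "ChromosomeSplit",
    "find_fusion_point",
    "split_chromosome",
    "lift_coordinate",
    "unlift_coordinate",
]


@dataclass(frozen=True)
class FusionCall:
    query_chrom: str
    fusion_point: int  # 0-based bp on the fused (query) chromosome
    upstream_target: str
    upstream_span: tuple[int, int]  # query interval, 0-based half-open
    downstream_target: str
    downstream_span: tuple[int, int]
    gap_len: int  # may be <= 0 when the clusters overlap


@dataclass(frozen=True)
class Segment:
    name: str
    start: int  # 0-based half-open on the original chromosome
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ChromosomeSplit:
    chrom: str
    chrom_len: int
    fusion_point: int
    segment_a: Segment
    segment_b: Segment


def find_fusion_point(
    paf_records: Sequence[PafRecord],
    query_chrom: str,
    target_a: str,
    target_b: str,
    min_alignment_len: int = 10_000,
    interleave_tolerance: float = 0.01,
) -> FusionCall:
    """Locate the fusion point on ``query_chrom`` from its alignments to the
    two unfused target chromosomes.

    Alignments shorter than ``min_alignment_len`` on the query are discarded
    to suppress spurious hits. Records are clustered by target; the cluster
    with the smaller maximum query end is upstream. The fusion point is
    ``floor((gap_start + gap_end) / 2)`` where the gap runs from the upstream
    cluster's last base to the downstream cluster's first. Clusters may
    overlap by up to ``interleave_tolerance`` of the chromosome length
    (ragged alignments near the junction); larger overlaps raise.
    """
    recs = [
        r
        for r in paf_records
        if r.query_name == query_chrom
        and r.target_name in (target_a, target_b)
        and (r.query_end - r.query_start) >= min_alignment_len
    ]
    by_target: dict[str, list[PafRecord]] = {}
    for r in recs:
        by_target.setdefault(r.target_name, []).append(r)
    for t in (target_a, target_b):
        if not by_target.get(t):
            raise ValueError(
                f"no alignments of {query_chrom} to {t} "
                f"(after the {min_alignment_len} bp length filter)"
            )
    chrom_len = recs[0].query_len

    def span(t: str) -> tuple[int, int]:
        rs = by_target[t]
        return (min(r.query_start for r in rs), max(r.query_end for r in rs))

    spans = {t: span(t) for t in (target_a, target_b)}
    upstream = min((target_a, target_b), key=lambda t: spans[t][1])
    downstream = target_b if upstream == target_a else target_a
    gap_start = spans[upstream][1]  # max query_end of the upstream cluster
    gap_end = spans[downstream][0]  # min query_start of the downstream cluster
    gap_len = gap_end - gap_start
    if gap_len < -interleave_tolerance * chrom_len:
        raise ValueError(
            f"alignment clusters to {target_a}/{target_b} interleave by "
            f"{-gap_len} bp (> {interleave_tolerance:.0%} of {chrom_len} bp)"
        )
    if gap_len < 0:
        warnings.warn(
            f"{query_chrom}: clusters overlap by {-gap_len} bp; "
            "taking the midpoint of the overlap"
        )
    return FusionCall(
        query_chrom=query_chrom,
        fusion_point=(gap_start + gap_end) // 2,
        upstream_target=upstream,
        upstream_span=spans[upstream],
        downstream_target=downstream,
        downstream_span=spans[downstream],
        gap_len=gap_len,
    )


def split_chromosome(
    chrom_len: int, fusion_point: int, chrom: str = "chr1"
) -> ChromosomeSplit:
    """Split a chromosome at the fusion point into ``<chrom>_a`` (upstream)
    and ``<chrom>_b`` (downstream) segments."""
    if not (0 < fusion_point < chrom_len):
        raise ValueError(
            f"fusion point {fusion_point} outside (0, {chrom_len})"
        )
    return ChromosomeSplit(
        chrom=chrom,
        chrom_len=chrom_len,
        fusion_point=fusion_point,
        segment_a=Segment(f"{chrom}_a", 0, fusion_point),
        segment_b=Segment(f"{chrom}_b", fusion_point, chrom_len),
    )


def lift_coordinate(pos: int, split: ChromosomeSplit) -> tuple[str, int]:
    """Map a 0-based position on the fused chromosome onto its segment."""
    if not (0 <= pos < split.chrom_len):
        raise ValueError(f"position {pos} outside [0, {split.chrom_len})")
    if pos < split.fusion_point:
        return (split.segment_a.name, pos)
    return (split.segment_b.name, pos - split.fusion_point)


def unlift_coordinate(segment: str, pos: int, split: ChromosomeSplit) -> int:
    """Inverse of :func:`lift_coordinate`."""
    if segment == split.segment_a.name:
        if not (0 <= pos < split.segment_a.length):
            raise ValueError(f"{segment}: position {pos} out of bounds")
        return pos
    if segment == split.segment_b.name:
        if not (0 <= pos < split.segment_b.length):
            raise ValueError(f"{segment}: position {pos} out of bounds")
        return pos + split.fusion_point
    raise ValueError(f"unknown segment {segment!r}")
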