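"""Windowed hysteresis peak calling over standardized selection-scan scores.

Scores are averaged over consecutive non-overlapping windows of a fixed number
of valid variants (100 by default). A peak is seeded wherever the absolute
window mean rises to the seed threshold (1.5) and extended in both directions
over consecutive windows while the absolute mean stays at or above the edge
threshold (0.5); seeding high and extending low keeps one broad sweep signal
from fragmenting into many small calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .haplotype import StandardizedScore
from .variants import GeneModel, GenomicInterval, merge_intervals

__all__ = [
    "WindowMean",
    "Peak",
    "PeakConfig",
    "window_means",
    "call_peaks",
    "merge_peak_regions",
    "genes_in_peaks",
]


@dataclass(frozen=True)
class WindowMean:
    chrom: str
    window_index: int
    first_site_index: int
    last_site_index: int
    first_pos: int
    last_pos: int
    mean_z: float
    n_sites: int


@dataclass
class Peak:
    """A called selection-sweep interval (1-based inclusive bp)."""

    chrom: str
    start_pos: int
    end_pos: int
    first_window: int
    last_window: int
    seed_window: int
    max_abs_mean: float
    metric: str = ""
    population: str = ""

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start_pos, self.end_pos)


@dataclass
class PeakConfig:
    window_size: int = 100  # valid variants per window
    seed_threshold: float = 1.5
    edge_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (self.seed_threshold > self.edge_threshold > 0):
            raise ValueError("need seed_threshold > edge_threshold > 0")


def window_means(
    scores: Sequence[StandardizedScore],
    config: PeakConfig | None = None,
    chrom: str = "1",
) -> list[WindowMean]:
    """Average standardized scores over consecutive windows of exactly
    ``window_size`` valid sites; the trailing partial window is dropped.

    ``scores`` must belong to a single chromosome and be sorted by position;
    invalid scores are ignored. Windows never span a chromosome boundary:
    callers run this per chromosome.
    """
    config = config or PeakConfig()
    valid = [s for s in scores if s.valid]
    out = []
    w = config.window_size
    for wi in range(len(valid) // w):
        chunk = valid[wi * w : (wi + 1) * w]
        out.append(
            WindowMean(
                chrom=chrom,
                window_index=wi,
                first_site_index=chunk[0].site_index,
                last_site_index=chunk[-1].site_index,
                first_pos=chunk[0].pos,
                last_pos=chunk[-1].pos,
                mean_z=sum(s.z for s in chunk) / w,
                n_sites=w,
            )
        )
    return out


def call_peaks(
    windows: Sequence[WindowMean],
    config: PeakConfig | None = None,
    metric: str = "",
    population: str = "",
) -> list[Peak]:
    """Hysteresis peak calling on window means.

    Any window with ``|mean_z| >= seed_threshold`` seeds a peak, which is
    extended left and right over consecutive windows while
    ``|mean_z| >= edge_threshold``. Spans arising from different seeds that
    overlap or abut (consecutive window indices) are merged; each peak keeps
    its largest absolute window mean and the seed achieving it.
    """
    config = config or PeakConfig()
    by_chrom: dict[str, list[WindowMean]] = {}
    for wm in windows:
        by_chrom.setdefault(wm.chrom, []).append(wm)
    peaks: list[Peak] = []
    for chrom, wms in by_chrom.items():
        wms = sorted(wms, key=lambda w: w.window_index)
        absm = [abs(w.mean_z) for w in wms]
        spans: list[tuple[int, int, int]] = []  # (lo, hi, seed) in list indices
        for i, a in enumerate(absm):
            if a >= config.seed_threshold:
                lo = i
                while lo > 0 and absm[lo - 1] >= config.edge_threshold and (
                    wms[lo].window_index - wms[lo - 1].window_index == 1
                ):
                    lo -= 1
                hi = i
                while hi < len(wms) - 1 and absm[hi + 1] >= config.edge_threshold and (
                    wms[hi + 1].window_index - wms[hi].window_index == 1
                ):
                    hi += 1
                spans.append((lo, hi, i))
        # merge overlapping/adjacent spans from different seeds
        merged: list[list[int]] = []
        for lo, hi, seed in sorted(spans):
            if merged and lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
                merged[-1][2].append(seed)
            else:
                merged.append([lo, hi, [seed]])
        for lo, hi, seeds in merged:
            best = max(seeds, key=lambda s: absm[s])
            peaks.append(
                Peak(
                    chrom=chrom,
                    start_pos=wms[lo].first_pos,
                    end_pos=wms[hi].last_pos,
                    first_window=wms[lo].window_index,
                    last_window=wms[hi].window_index,
                    seed_window=wms[best].window_index,
                    max_abs_mean=absm[best],
                    metric=metric,
                    population=population,
                )
            )
    return sorted(peaks, key=lambda p: (p.chrom, p.start_pos))


def merge_peak_regions(peaks: Iterable[Peak]) -> list[GenomicInterval]:
    """Union of peak intervals (across metrics/populations): sorted, disjoint."""
    return merge_intervals(p.interval for p in peaks)


def genes_in_peaks(
    peaks: Sequence[Peak], genes: Sequence[GeneModel]
) -> tuple[dict[int, list[GeneModel]], dict[str, int]]:
    """Genes overlapping each peak by >= 1 bp (1-based inclusive semantics).

    Returns (peak index -> overlapping genes, gene_id -> number of peaks hit).
    """
    per_peak: dict[int, list[GeneModel]] = {}
    gene_hits: dict[str, int] = {}
    for i, p in enumerate(peaks):
        hits = [
            g
            for g in genes
            if g.chrom == p.chrom and g.start <= p.end_pos and p.start_pos <= g.end
        ]
        per_peak[i] = hits
        for g in hits:
            gene_hits[g.gene_id] = gene_hits.get(g.gene_id, 0) + 1
    return per_peak, gene_hits
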