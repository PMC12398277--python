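"""Model/Results interface to the haplotype selection scan.

`SelectionScan` wraps a phased haplotype panel and a metric (iHS or nSL);
`fit()` scores every eligible site, standardizes within derived-allele-
frequency bins, and returns a `SelectionScanResults` carrying the score table,
per-bin diagnostics, peak calling and a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .haplotype import (
    HaplotypeMatrix,
    ScanConfig,
    SiteScore,
    StandardizedScore,
    ihs_unstandardized,
    nsl_unstandardized,
    standardize,
)
from .peaks import Peak, PeakConfig, call_peaks, window_means
from .variants import read_vcf, split_multiallelic

__all__ = ["SelectionScan", "SelectionScanResults"]


class SelectionScan:
    """A haplotype-based selection scan over one phased panel.

    Parameters
    ----------
    haplotypes
        Binary phased haplotype-by-site matrix.
    metric
        "ihs" (physical-distance integrated haplotype homozygosity) or
        "nsl" (segregating-sites haplotype lengths).
    config
        Scan parameters; defaults follow common tool conventions
        (EHH cutoff 0.05, 50 DAF bins, MAF floor 0.05).
    """

    def __init__(
        self,
        haplotypes: HaplotypeMatrix,
        metric: str = "ihs",
        config: ScanConfig | None = None,
        population: str = "",
    ) -> None:
        if metric not in ("ihs", "nsl"):
            raise ValueError("metric must be 'ihs' or 'nsl'")
        self.haplotypes = haplotypes
        self.metric = metric
        self.config = config or ScanConfig()
        self.population = population

    @classmethod
    def from_vcf(
        cls,
        path: str,
        metric: str = "ihs",
        config: ScanConfig | None = None,
        population: str = "",
    ) -> "SelectionScan":
        """Build a scan from a phased VCF (multiallelic records are split;
        sites with missing alleles are dropped)."""
        raw, samples = read_vcf(path)
        records = [r for rec in raw for r in split_multiallelic(rec)]
        matrix = HaplotypeMatrix.from_records(records, samples)
        return cls(matrix, metric=metric, config=config, population=population)

    def fit(self) -> "SelectionScanResults":
        score_fn = ihs_unstandardized if self.metric == "ihs" else nsl_unstandardized
        scores = [
            score_fn(self.haplotypes, i, self.config)
            for i in range(self.haplotypes.n_site)
        ]
        std = standardize(
            scores,
            n_daf_bins=self.config.n_daf_bins,
            min_bin_count=self.config.min_bin_count,
        )
        return SelectionScanResults(model=self, scores=std)


@dataclass
class SelectionScanResults:
    """Fitted selection scan: standardized per-site scores plus diagnostics."""

    model: SelectionScan
    scores: list[StandardizedScore]

    @property
    def frame(self) -> pd.DataFrame:
        """Score table: chrom, pos, daf, raw, z, valid, bin."""
        m = self.model.haplotypes
        return pd.DataFrame(
            {
                "chrom": m.chrom,
                "pos": [s.pos for s in self.scores],
                "daf": [s.daf for s in self.scores],
                "raw": [s.raw for s in self.scores],
                "z": [s.z for s in self.scores],
                "valid": [s.valid for s in self.scores],
                "bin": [s.bin_index for s in self.scores],
            }
        )

    @property
    def n_valid(self) -> int:
        return sum(s.valid for s in self.scores)

    def bin_diagnostics(self) -> pd.DataFrame:
        """Per-DAF-bin count, mean and sd of standardized scores."""
        df = self.frame
        df = df[df["valid"]]
        g = df.groupby("bin")["z"]
        return pd.DataFrame(
            {"n": g.size(), "mean_z": g.mean(), "sd_z": g.std(ddof=0)}
        )

    def window_means(self, peak_config: PeakConfig | None = None):
        return window_means(
            self.scores, peak_config, chrom=self.model.haplotypes.chrom
        )

    def call_peaks(self, peak_config: PeakConfig | None = None) -> list[Peak]:
        """Windowed hysteresis peak calling on the standardized scores."""
        return call_peaks(
            self.window_means(peak_config),
            peak_config,
            metric=self.model.metric,
            population=self.model.population,
        )

    def to_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self, peak_config: PeakConfig | None = None) -> str:
        m = self.model.haplotypes
        df = self.frame
        valid = df[df["valid"]]
        peaks = self.call_peaks(peak_config)
        lines = [
            f"Selection scan ({self.model.metric.upper()})",
            "=" * 40,
            f"haplotypes:        {m.n_hap}",
            f"sites:             {m.n_site}",
            f"scored sites:      {len(valid)}",
            f"DAF bins (final):  {valid['bin'].nunique()}",
            f"mean |z|:          {valid['z'].abs().mean():.3f}" if len(valid) else "",
            f"max |z|:           {valid['z'].abs().max():.3f}" if len(valid) else "",
            f"peaks called:      {len(peaks)}",
        ]
        for p in peaks:
            lines.append(
                f"  peak {p.chrom}:{p.start_pos}-{p.end_pos} "
                f"(windows {p.first_window}-{p.last_window}, "
                f"max |mean z| {p.max_abs_mean:.2f})"
            )
        return "\n".join(l for l in lines if l)
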