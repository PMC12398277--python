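"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a stylized stand-in for the corresponding real data source
and is bit-reproducible given its seed:

* phased haplotype panels as founder mosaics — each sample haplotype copies a
  founder, switching founders with a per-site recombination probability and
  flipping alleles with a per-site mutation probability. This produces
  linkage disequilibrium without a coalescent simulation.
* a hard selective sweep implanted into a panel — a chosen fraction of
  haplotypes share founder 0's alleles (plus noise) across a window around
  the core site, creating the long shared derived haplotype that iHS/nSL
  scans detect.
* toy multi-assembly pangenome VCFs with known per-assembly presence
  patterns and insertion/deletion lengths.
* kinship cohorts with family clusters and per-sample coverage.
* PAF records of a fused chromosome aligned to two target chromosomes, with
  a known fusion point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .haplotype import HaplotypeMatrix
from .variants import PafRecord, VariantRecord

__all__ = [
    "PanelConfig",
    "SweepConfig",
    "ToyPangenomeConfig",
    "KinCohortConfig",
    "KinCohort",
    "generate_neutral_panel",
    "implant_sweep",
    "generate_toy_pangenome",
    "panel_to_vcf_records",
    "generate_kin_cohort",
    "generate_paf_fusion_case",
]

BASES = np.array(list("ACGT"))


@dataclass
class PanelConfig:
    """Founder-mosaic haplotype panel parameters.

    n_founders=8 distinct ancestral haplotypes; recomb_prob=0.01 per-site
    founder-switch probability; mut_prob=0.002 per-site allele flip;
    mean_spacing=1000 bp mean gap between adjacent sites.
    """

    n_haplotypes: int = 100
    n_sites: int = 2000
    n_founders: int = 8
    recomb_prob: float = 0.01
    mut_prob: float = 0.002
    mean_spacing: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.recomb_prob, self.mut_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.n_haplotypes < 4:
            raise ValueError("need at least 4 haplotypes")


@dataclass
class SweepConfig:
    """Hard-sweep implant: carriers share founder 0's haplotype over
    [core - halfwidth, core + halfwidth] with per-site flip probability
    template_noise; the core column is set to 1 for carriers only."""

    core_index: int
    target_daf: float = 0.8
    halfwidth_sites: int = 150
    template_noise: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.target_daf < 1):
            raise ValueError("target_daf must lie in (0, 1)")


@dataclass
class ToyPangenomeConfig:
    n_assemblies: int = 6
    n_variants: int = 200
    singleton_weight: float = 0.6
    sv_fraction: float = 0.3
    max_ins_len: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_assemblies < 2:
            raise ValueError("need at least 2 assemblies")


@dataclass
class KinCohortConfig:
    n_clusters: int = 5
    cluster_size_range: tuple[int, int] = (2, 5)
    within_kinship_range: tuple[float, float] = (0.07, 0.25)
    between_kinship_range: tuple[float, float] = (0.0, 0.05)
    coverage_range: tuple[float, float] = (5.0, 40.0)
    n_isolated: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.within_kinship_range[0] > 0.0625 >= self.between_kinship_range[1]):
            raise ValueError(
                "within-cluster kinship must exceed 0.0625, which must be "
                ">= the between-cluster maximum"
            )


@dataclass
class KinCohort:
    """Pairwise kinship list, per-sample coverage, and the true clusters."""

    pairs: list[tuple[str, str, float]]
    coverage: dict[str, float]
    clusters: dict[str, list[str]]


def generate_neutral_panel(config: PanelConfig) -> HaplotypeMatrix:
    """Neutral founder-mosaic panel; allele 0 is ancestral.

    Founder haplotypes are i.i.d. Bernoulli(0.5) per site. Each sample
    haplotype starts from a uniformly chosen founder and, at each site,
    switches to a different uniform founder with probability recomb_prob and
    flips its allele with probability mut_prob. Positions are cumulative sums
    of geometric gaps (mean mean_spacing, minimum 1 bp).
    """
    rng = np.random.default_rng(config.seed)
    n, m, f = config.n_haplotypes, config.n_sites, config.n_founders
    founders = rng.integers(0, 2, size=(f, m), dtype=np.int8)
    alleles = np.empty((n, m), dtype=np.int8)
    for h in range(n):
        fid = int(rng.integers(f))
        switch = rng.random(m) < config.recomb_prob
        path = np.empty(m, dtype=np.int64)
        for s in range(m):
            if switch[s]:
                # uniform over the other founders: a switch always switches
                fid = int((fid + 1 + rng.integers(f - 1)) % f)
            path[s] = fid
        hap = founders[path, np.arange(m)].copy()
        flips = rng.random(m) < config.mut_prob
        hap[flips] ^= 1
        alleles[h] = hap
    gaps = rng.geometric(1.0 / config.mean_spacing, size=m)
    positions = np.cumsum(gaps)
    return HaplotypeMatrix(
        alleles=alleles, positions=positions, chrom="1", founders=founders
    )


def implant_sweep(panel: HaplotypeMatrix, config: SweepConfig) -> HaplotypeMatrix:
    """Implant a hard sweep; returns a new panel, the input is untouched.

    round(target_daf * n_hap) haplotypes (a seeded shuffle's prefix) become
    carriers: across the swept window their alleles are replaced by founder
    0's (flipped per site with probability template_noise), and the core
    column is set to 1 for carriers and 0 for everyone else.
    """
    lo = config.core_index - config.halfwidth_sites
    hi = config.core_index + config.halfwidth_sites
    if lo < 0 or hi >= panel.n_site:
        raise ValueError(
            f"sweep window [{lo}, {hi}] outside the panel's {panel.n_site} sites"
        )
    rng = np.random.default_rng(config.seed)
    n = panel.n_hap
    order = rng.permutation(n)
    carriers = np.sort(order[: round(config.target_daf * n)])
    template = (
        panel.founders[0] if panel.founders is not None else panel.alleles[0]
    )
    alleles = panel.alleles.copy()
    width = hi - lo + 1
    for h in carriers:
        seg = template[lo : hi + 1].copy()
        flips = rng.random(width) < config.template_noise
        seg[flips] ^= 1
        alleles[h, lo : hi + 1] = seg
    alleles[:, config.core_index] = 0
    alleles[carriers, config.core_index] = 1
    return HaplotypeMatrix(
        alleles=alleles,
        positions=panel.positions.copy(),
        chrom=panel.chrom,
        founders=None if panel.founders is None else panel.founders.copy(),
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def generate_toy_pangenome(
    config: ToyPangenomeConfig,
) -> tuple[list[VariantRecord], list[str], pd.DataFrame]:
    """Toy multi-assembly pangenome VCF records plus their truth table.

    Each variant receives a presence bit pattern over the assemblies: a
    singleton pattern with probability singleton_weight, otherwise uniform
    over all non-empty patterns. Present assemblies are genotyped 1/1 (an
    assembly haplotype either carries the path or does not), absent ones 0/0.
    Allele length differences are log-uniform on [1, max_ins_len], with a
    fraction sv_fraction forced to >= 50 bp (structural variants); insertions
    and deletions are equally likely.

    Returns (records, sample list, truth table with pattern and length_delta).
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_assemblies
    samples = [f"ASM{i + 1}" for i in range(k)]
    records, truth = [], []
    pos = 0
    for v in range(config.n_variants):
        if rng.random() < config.singleton_weight:
            pattern = ["0"] * k
            pattern[int(rng.integers(k))] = "1"
            pattern = "".join(pattern)
        else:
            code = int(rng.integers(1, 2**k))  # uniform over non-empty patterns
            pattern = format(code, f"0{k}b")
        is_sv = rng.random() < config.sv_fraction
        lo, hi = (50, config.max_ins_len) if is_sv else (1, 49)
        length = int(np.floor(np.exp(rng.uniform(np.log(lo), np.log(hi + 1)))))
        length = min(max(length, lo), hi)
        delta = length if rng.random() < 0.5 else -length
        pos += int(rng.integers(200, 2000))
        anchor = str(BASES[rng.integers(0, 4)])
        if delta > 0:
            ref, alt = anchor, anchor + _random_seq(rng, delta)
        else:
            ref, alt = anchor + _random_seq(rng, -delta), anchor
        genotypes = {
            s: ((1, 1) if pattern[i] == "1" else (0, 0))
            for i, s in enumerate(samples)
        }
        records.append(
            VariantRecord(
                chrom="1", pos=pos, ref=ref, alts=(alt,),
                genotypes=genotypes, phased=True,
            )
        )
        truth.append(
            {"chrom": "1", "pos": pos, "pattern": pattern, "length_delta": delta}
        )
    return records, samples, pd.DataFrame(truth)


def panel_to_vcf_records(
    panel: HaplotypeMatrix,
) -> tuple[list[VariantRecord], list[str]]:
    """Export a haplotype panel as phased biallelic SNV records.

    Haplotypes 2i and 2i+1 become sample ``S{i+1}``; the panel must hold an
    even number of haplotypes. Alleles are written as A (ancestral) / G
    (derived) SNVs.
    """
    if panel.n_hap % 2:
        raise ValueError("panel must have an even number of haplotypes")
    samples = [f"S{i + 1}" for i in range(panel.n_hap // 2)]
    records = []
    for s in range(panel.n_site):
        col = panel.alleles[:, s]
        genotypes = {
            smp: (int(col[2 * i]), int(col[2 * i + 1]))
            for i, smp in enumerate(samples)
        }
        records.append(
            VariantRecord(
                chrom=panel.chrom, pos=int(panel.positions[s]),
                ref="A", alts=("G",), genotypes=genotypes, phased=True,
            )
        )
    return records, samples


def generate_kin_cohort(config: KinCohortConfig) -> KinCohort:
    """Kinship cohort with fully related clusters and unrelated singletons.

    Every within-cluster pair draws its kinship uniformly from
    within_kinship_range (> 0.0625); every cross-cluster and singleton pair
    draws from between_kinship_range (<= 0.0625). Coverage is uniform on
    coverage_range. Sample ids encode the true cluster (``C3_S2``).
    """
    rng = np.random.default_rng(config.seed)
    clusters: dict[str, list[str]] = {}
    for c in range(config.n_clusters):
        size = int(rng.integers(config.cluster_size_range[0],
                                config.cluster_size_range[1] + 1))
        clusters[f"C{c + 1}"] = [f"C{c + 1}_S{i + 1}" for i in range(size)]
    singles = [f"U_S{i + 1}" for i in range(config.n_isolated)]
    if singles:
        clusters["U"] = singles  # singletons: no within edges emitted

    samples = [s for members in clusters.values() for s in members]
    coverage = {
        s: float(rng.uniform(*config.coverage_range)) for s in samples
    }
    member_cluster = {
        s: c for c, members in clusters.items() for s in members
    }
    pairs = []
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            same = member_cluster[a] == member_cluster[b] and member_cluster[a] != "U"
            rng_range = (
                config.within_kinship_range if same else config.between_kinship_range
            )
            pairs.append((a, b, float(rng.uniform(*rng_range))))
    return KinCohort(pairs=pairs, coverage=coverage, clusters=clusters)


def generate_paf_fusion_case(
    chr1_len: int,
    block1_end: int,
    block2_start: int,
    query_chrom: str = "chr1",
    targets: tuple[str, str] = ("chr4", "chr9"),
    n_subblocks: int = 1,
    seed: int = 0,
) -> tuple[list[PafRecord], int]:
    """PAF records for a fused chromosome and the true fusion point.

    Query [0, block1_end) aligns to the first target and
    [block2_start, chr1_len) to the second; the truth is
    ``floor((block1_end + block2_start) / 2)``. With ``n_subblocks > 1`` each
    block is cut into contiguous sub-alignments (same truth).
    """
    if not (0 < block1_end <= block2_start < chr1_len):
        raise ValueError("need 0 < block1_end <= block2_start < chr1_len")
    rng = np.random.default_rng(seed)

    def cut(start: int, end: int) -> list[tuple[int, int]]:
        if n_subblocks <= 1 or end - start < 2 * n_subblocks:
            return [(start, end)]
        inner = np.sort(
            rng.choice(np.arange(start + 1, end), size=n_subblocks - 1, replace=False)
        )
        bounds = [start, *inner.tolist(), end]
        return list(zip(bounds[:-1], bounds[1:]))

    records = []
    for target, (qs, qe) in (
        (targets[0], (0, block1_end)),
        (targets[1], (block2_start, chr1_len)),
    ):
        for s, e in cut(qs, qe):
            tlen = max(chr1_len, e)
            records.append(
                PafRecord(
                    query_name=query_chrom, query_len=chr1_len,
                    query_start=s, query_end=e, strand="+",
                    target_name=target, target_len=tlen,
                    target_start=s, target_end=e,
                    n_match=e - s, aln_len=e - s, mapq=60,
                )
            )
    return records, (block1_end + block2_start) // 2
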