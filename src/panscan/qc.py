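"""Variant- and sample-level cohort quality control.

Implements the cohort filters applied ahead of the selection scans:
genotype-quality masking (GQ < 25 set missing), missingness/minor-allele-
frequency variant filters, kinship-based pruning of related samples with
coverage prioritization (KING kinship > 0.0625 marks pairs closer than
third degree), and the transition/transversion ratio as a coarse quality
indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx

from .variants import MISSING, VariantRecord, classify_variant

__all__ = [
    "QCConfig",
    "KinshipGraph",
    "mask_low_gq",
    "filter_variants",
    "prune_related",
    "titv_ratio",
]

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class QCConfig:
    max_missing_frac: float = 0.2
    min_maf: float = 0.05
    min_gq: int = 25
    min_callrate_biallelic: float = 0.75
    kinship_threshold: float = 0.0625

    def __post_init__(self) -> None:
        for name in ("max_missing_frac", "min_maf", "min_callrate_biallelic",
                     "kinship_threshold"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_gq < 0:
            raise ValueError("min_gq must be >= 0")


@dataclass
class KinshipGraph:
    """Samples as nodes (with mean read-depth coverage), pairwise kinship
    coefficients as weighted edges."""

    coverage: dict[str, float]
    edges: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b, phi in self.edges:
            if a == b:
                raise ValueError(f"self kinship edge for {a}")
            if not (-1.0 <= phi <= 0.5):
                raise ValueError(f"kinship {phi} for ({a},{b}) outside [-1, 0.5]")

    @property
    def samples(self) -> list[str]:
        return list(self.coverage)


def mask_low_gq(
    records: Sequence[VariantRecord], min_gq: int = 25
) -> list[VariantRecord]:
    """Set genotypes with GQ strictly below ``min_gq`` to missing.

    Records (or samples) without a GQ value are left untouched.
    """
    out = []
    for rec in records:
        if not rec.gq:
            out.append(rec)
            continue
        genos = dict(rec.genotypes)
        for s, q in rec.gq.items():
            if q < min_gq and s in genos:
                genos[s] = MISSING
        out.append(replace(rec, genotypes=genos, gq=dict(rec.gq),
                           info=dict(rec.info)))
    return out


def _missing_and_maf(rec: VariantRecord) -> tuple[float, float | None]:
    n_samples = len(rec.genotypes)
    if n_samples == 0:
        return 1.0, None
    n_missing = 0
    alt = 0
    called = 0
    for gt in rec.genotypes.values():
        if gt[0] is None or gt[1] is None:
            n_missing += 1
        for a in gt:
            if a is not None:
                called += 1
                alt += a
    if called == 0:
        return 1.0, None
    p = alt / called
    return n_missing / n_samples, min(p, 1.0 - p)


def filter_variants(
    records: Sequence[VariantRecord], config: QCConfig | None = None
) -> list[VariantRecord]:
    """Keep biallelic variants with missing fraction <= max_missing_frac and
    MAF strictly > min_maf (computed over non-missing alleles).

    Variants with every genotype missing are dropped (MAF undefined).
    """
    config = config or QCConfig()
    kept = []
    for rec in records:
        miss, maf = _missing_and_maf(rec)
        if maf is None:
            continue
        if miss <= config.max_missing_frac and maf > config.min_maf:
            kept.append(rec)
    return kept


def prune_related(
    graph: KinshipGraph, threshold: float = 0.0625
) -> tuple[set[str], set[str]]:
    """Prune related samples, prioritizing higher-coverage individuals.

    Edges with kinship strictly above ``threshold`` define clusters of
    relatives (connected components). Within each component a greedy
    maximum-coverage independent set is kept: members are visited by coverage
    descending (ties by sample id ascending) and kept iff no already-kept
    member is a direct relative. Isolated samples are always kept.

    Returns (keep, remove) sets partitioning the samples.
    """
    missing = [s for a, b, _ in graph.edges for s in (a, b)
               if s not in graph.coverage]
    if missing:
        raise ValueError(f"no coverage for sample(s): {sorted(set(missing))}")
    g = nx.Graph()
    g.add_nodes_from(graph.coverage)
    for a, b, phi in graph.edges:
        if phi > threshold:
            g.add_edge(a, b)
    keep: set[str] = set()
    remove: set[str] = set()
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda s: (-graph.coverage[s], s))
        for s in members:
            if any(nbr in keep for nbr in g.adj[s]):
                remove.add(s)
            else:
                keep.add(s)
    return keep, remove


def titv_ratio(records: Iterable[VariantRecord]) -> float:
    """Transition/transversion ratio over the SNV records (others ignored).

    Returns ``inf`` when transitions exist but no transversions, and ``nan``
    when there are no SNVs at all.
    """
    ti = tv = 0
    for rec in records:
        if not rec.is_biallelic or classify_variant(rec).kind != "SNV":
            continue
        if (rec.ref.upper(), rec.alt.upper()) in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return math.inf if ti else math.nan
    return ti / tv
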