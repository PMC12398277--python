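"""Impact-class enrichment of variants inside sweep regions and per-population
alternate-allele-frequency queries.

Enrichment compares, for each functional impact class (HIGH, MODERATE, LOW,
MODIFIER) within each variant class (SNV, indel, SV), the composition of
variants inside the merged sweep regions against the composition outside them,
with a two-sided Fisher exact test. The exact test sums hypergeometric point
probabilities (all tables with the observed margins whose probability does not
exceed the observed table's); tie comparison is done in exact integer
arithmetic, so no floating-point epsilon is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .variants import GenomicInterval, VariantRecord, classify_variant

__all__ = [
    "IMPACT_CLASSES",
    "ContingencyTable",
    "fisher_exact_two_sided",
    "extract_impact",
    "impact_enrichment",
    "population_aaf",
]

#: SnpEff impact classes, most severe first
IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_SEVERITY = {c: i for i, c in enumerate(IMPACT_CLASSES)}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a, b = in-region (class X, not X); c, d = background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_margin(self) -> bool:
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )

    def odds_ratio(self) -> float:
        """ad/bc, with a 0.5 continuity (Haldane) correction when any cell is 0."""
        a, b, c, d = self.a, self.b, self.c, self.d
        if 0 in (a, b, c, d):
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value by point-probability summation.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability is <= the observed table's. Comparisons use
    exact integers (unnormalized hypergeometric weights), so ties are exact.
    A table with a zero margin has a single attainable configuration and
    returns p = 1 by convention.
    """
    if table.has_zero_margin:
        return 1.0
    N = table.n
    K = table.a + table.b  # row-1 margin
    n = table.a + table.c  # col-1 margin
    lo = max(0, n - (N - K))
    hi = min(K, n)
    weights = [math.comb(K, x) * math.comb(N - K, n - x) for x in range(lo, hi + 1)]
    observed = weights[table.a - lo]
    num = sum(w for w in weights if w <= observed)
    return num / sum(weights)


def extract_impact(record: VariantRecord) -> str | None:
    """Most severe impact class annotated on a record.

    Reads either a plain ``IMPACT`` INFO key or SnpEff-style ``ANN`` entries
    (impact is the third pipe-separated token of each comma-separated
    annotation). Returns None when no impact is annotated.
    """
    found: list[str] = []
    imp = record.info.get("IMPACT")
    if imp:
        found.extend(t for t in imp.split(",") if t in _SEVERITY)
    ann = record.info.get("ANN")
    if ann:
        for entry in ann.split(","):
            parts = entry.split("|")
            if len(parts) > 2 and parts[2] in _SEVERITY:
                found.append(parts[2])
    if not found:
        return None
    return min(found, key=lambda c: _SEVERITY[c])


def _region_trees(regions: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in regions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1)
    return trees


def _in_region(trees: Mapping[str, IntervalTree], chrom: str, pos: int) -> bool:
    tree = trees.get(chrom)
    return bool(tree and tree.overlaps(pos))


def _variant_class_group(record: VariantRecord) -> str:
    kind = classify_variant(record).kind
    if kind == "SNV":
        return "SNV"
    return "SV" if kind.startswith("SV") else "INDEL"


def _bh(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, pvals[i] * m / rank)
        adj[i] = prev
    return adj


def impact_enrichment(
    annotated_variants: Sequence[VariantRecord],
    regions: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Enrichment of each impact class within sweep regions, per variant class.

    For every (impact class, variant class group) cell the 2x2 table compares
    in-region variants of that impact against in-region variants of other
    impacts, with out-of-region variants as the background (disjoint table).
    Returns a frame with the table cells, in/out proportions, odds ratio
    (Haldane-corrected when needed), raw two-sided Fisher p and BH-adjusted q.
    Variants lacking an impact annotation are ignored.
    """
    trees = _region_trees(regions)
    rows = []
    strata: dict[str, list[tuple[str, bool]]] = {}
    for rec in annotated_variants:
        impact = extract_impact(rec)
        if impact is None:
            continue
        strata.setdefault(_variant_class_group(rec), []).append(
            (impact, _in_region(trees, rec.chrom, rec.pos))
        )
    for vclass, obs in sorted(strata.items()):
        for impact in IMPACT_CLASSES:
            a = sum(1 for imp, inr in obs if inr and imp == impact)
            b = sum(1 for imp, inr in obs if inr and imp != impact)
            c = sum(1 for imp, inr in obs if not inr and imp == impact)
            d = sum(1 for imp, inr in obs if not inr and imp != impact)
            table = ContingencyTable(a, b, c, d)
            rows.append(
                {
                    "variant_class": vclass,
                    "impact": impact,
                    "in_region_impact": a,
                    "in_region_other": b,
                    "background_impact": c,
                    "background_other": d,
                    "prop_in_region": a / (a + b) if a + b else math.nan,
                    "prop_background": c / (c + d) if c + d else math.nan,
                    "odds_ratio": table.odds_ratio(),
                    "p_value": fisher_exact_two_sided(table),
                    "zero_margin": table.has_zero_margin,
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = _bh(df["p_value"].tolist())
    return df


def population_aaf(
    records: Sequence[VariantRecord],
    population_map: Mapping[str, str],
    regions: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Alternate-allele frequency per population for every in-region variant.

    aAF = alt allele count / non-missing allele count within the population;
    NaN when every genotype in the population is missing. ``population_map``
    maps sample id -> population label and must cover every sample queried.
    """
    trees = _region_trees(regions)
    pops = sorted(set(population_map.values()))
    rows = []
    for rec in records:
        if not _in_region(trees, rec.chrom, rec.pos):
            continue
        row: dict[str, object] = {
            "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": rec.alt,
        }
        for pop in pops:
            alt = called = 0
            for s, gt in rec.genotypes.items():
                if population_map.get(s) != pop:
                    continue
                for a in gt:
                    if a is not None:
                        called += 1
                        alt += a
            row[pop] = alt / called if called else math.nan
        rows.append(row)
    return pd.DataFrame(rows)
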