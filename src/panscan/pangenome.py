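"""Multi-assembly pangenome set accounting.

A pangenome graph VCF carries one pseudo-sample per assembly. The support
vector (SUPP_VEC) is a per-variant bit string, ordered by the sample list,
recording presence ("1") or absence ("0") of the alternative allele in each
assembly. On top of it this module counts structural-variant sharing patterns
(upset sets), accounts for non-reference inserted sequence per assembly group,
and classifies exact-key overlap between two call sets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .variants import SV_LENGTH_THRESHOLD, VariantRecord

__all__ = [
    "LengthAccount",
    "compute_support_vectors",
    "upset_counts",
    "nonreference_lengths",
    "classify_caller_overlap",
]


@dataclass(frozen=True)
class LengthAccount:
    """Inserted-sequence accounting for one group of assemblies (bp).

    total: insertions present in at least one group member.
    exclusive: insertions whose every carrier lies inside the group.
    """

    total_inserted_bp: int
    exclusive_inserted_bp: int

    def __post_init__(self) -> None:
        if self.exclusive_inserted_bp > self.total_inserted_bp:
            raise ValueError("exclusive length exceeds total")


def compute_support_vectors(
    records: Sequence[VariantRecord], samples: Sequence[str]
) -> list[VariantRecord]:
    """Annotate each biallelic record with its SUPP_VEC INFO field.

    Bit i is 1 iff sample i's genotype carries at least one alternative
    allele; a missing genotype contributes 0 (in a graph VCF, missingness
    means the assembly path is absent).
    """
    out = []
    for rec in records:
        if not rec.is_biallelic:
            raise ValueError(
                f"{rec.chrom}:{rec.pos}: split multiallelic records first"
            )
        bits = "".join(
            "1"
            if any(a == 1 for a in rec.genotypes.get(s, (None, None)) if a is not None)
            else "0"
            for s in samples
        )
        info = dict(rec.info)
        info["SUPP_VEC"] = bits
        out.append(replace(rec, info=info,
                           genotypes=dict(rec.genotypes),
                           gq=dict(rec.gq) if rec.gq else None))
    return out


def _suppvec(rec: VariantRecord) -> str:
    try:
        return rec.info["SUPP_VEC"]
    except KeyError:
        raise ValueError(
            f"{rec.chrom}:{rec.pos}: no SUPP_VEC; run compute_support_vectors"
        ) from None


def upset_counts(
    records: Iterable[VariantRecord],
    min_sv_len: int = SV_LENGTH_THRESHOLD,
    top_k: int | None = None,
) -> dict[str, int]:
    """Count presence patterns among structural variants.

    Considers records with ``|length_delta| >= min_sv_len``, keyed by their
    exact SUPP_VEC bit pattern. ``top_k`` truncates the report to the most
    frequent patterns (ties broken by pattern string for determinism).
    """
    counts: Counter[str] = Counter()
    for rec in records:
        if abs(rec.length_delta) >= min_sv_len:
            counts[_suppvec(rec)] += 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        items = items[:top_k]
    return dict(items)


def nonreference_lengths(
    records: Iterable[VariantRecord],
    groups: Mapping[str, Sequence[str]],
    samples: Sequence[str],
) -> dict[str, LengthAccount]:
    """Non-reference inserted sequence per assembly group.

    For insertions (length_delta > 0): a group's total counts every insertion
    present in at least one member; its exclusive length counts insertions
    whose carriers all lie within the group. Each variant is counted once per
    group regardless of how many members carry it.
    """
    index = {s: i for i, s in enumerate(samples)}
    group_idx = {
        g: {index[s] for s in members} for g, members in groups.items()
    }
    total = {g: 0 for g in groups}
    exclusive = {g: 0 for g in groups}
    for rec in records:
        delta = rec.length_delta
        if delta <= 0:
            continue
        bits = _suppvec(rec)
        carriers = {i for i, b in enumerate(bits) if b == "1"}
        if not carriers:
            continue
        for g, idx in group_idx.items():
            if carriers & idx:
                total[g] += delta
                if carriers <= idx:
                    exclusive[g] += delta
    return {
        g: LengthAccount(total_inserted_bp=total[g],
                         exclusive_inserted_bp=exclusive[g])
        for g in groups
    }


def _aaf(rec: VariantRecord) -> float | None:
    alt = called = 0
    for gt in rec.genotypes.values():
        for a in gt:
            if a is not None:
                called += 1
                alt += a
    return alt / called if called else None


def classify_caller_overlap(
    records_a: Sequence[VariantRecord],
    records_b: Sequence[VariantRecord],
) -> tuple[dict[str, int], dict[str, list[float]]]:
    """Exact-key overlap between two normalized call sets.

    Variants are matched on (chrom, pos, ref, alt); each key falls in exactly
    one of {both, only_A, only_B}. Returns the class counts and, per class,
    the list of alternate-allele frequencies (from set A for "both").
    This is a deliberate simplification of haplotype-aware matching: calls
    representing the same change with different alignments will not match.
    """
    a_by_key = {r.key: r for r in records_a}
    b_by_key = {r.key: r for r in records_b}
    counts = {"both": 0, "only_A": 0, "only_B": 0}
    afs: dict[str, list[float]] = {"both": [], "only_A": [], "only_B": []}

    def _record_af(cls: str, rec: VariantRecord) -> None:
        af = _aaf(rec)
        if af is not None:
            afs[cls].append(af)

    for key, rec in a_by_key.items():
        if key in b_by_key:
            counts["both"] += 1
            _record_af("both", rec)
        else:
            counts["only_A"] += 1
            _record_af("only_A", rec)
    for key, rec in b_by_key.items():
        if key not in a_by_key:
            counts["only_B"] += 1
            _record_af("only_B", rec)
    return counts, afs
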