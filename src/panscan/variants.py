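"""Readers/writers for the standard formats the pipeline touches and variant
normalization/classification.

Coordinate conventions follow each format's standard: VCF and internal variant
positions are 1-based; PAF and BED are 0-based half-open. Genomic intervals are
held 1-based inclusive internally and converted on BED output.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam

__all__ = [
    "Genotype",
    "VariantRecord",
    "VariantClass",
    "PafRecord",
    "GeneModel",
    "GenomicInterval",
    "VcfParseError",
    "PafParseError",
    "read_vcf",
    "write_vcf",
    "split_multiallelic",
    "classify_variant",
    "read_paf",
    "read_gff3_genes",
    "merge_intervals",
    "write_bed",
]

#: a diploid genotype: pair of allele indices, ``None`` marking a missing allele
Genotype = tuple[Optional[int], Optional[int]]

MISSING: Genotype = (None, None)

SV_LENGTH_THRESHOLD = 50  # bp; |len(alt) - len(ref)| >= 50 defines an SV


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; names the failing record."""


class PafParseError(ValueError):
    """Raised when a PAF line cannot be parsed; names the failing line."""


@dataclass
class VariantRecord:
    """One VCF record.

    ``alts`` may hold several alternative alleles for a raw multiallelic
    record; most of the pipeline operates on biallelic records obtained via
    :func:`split_multiallelic`. Genotypes are an ordered map from sample id to
    a pair of allele indices (``None`` = missing allele).
    """

    chrom: str
    pos: int  # 1-based bp
    ref: str
    alts: tuple[str, ...]
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    gq: Optional[dict[str, int]] = None
    info: dict[str, str] = field(default_factory=dict)
    phased: bool = False
    vid: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("empty REF allele")
        if isinstance(self.alts, str):
            self.alts = (self.alts,)
        else:
            self.alts = tuple(self.alts)
        if not self.alts:
            raise ValueError("record has no ALT allele")
        for a in self.alts:
            if not a:
                raise ValueError("empty ALT allele")
            if a.startswith("<"):
                raise ValueError(
                    f"symbolic ALT allele {a!r} not supported; explicit "
                    "sequence alleles are required"
                )

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def alt(self) -> str:
        if not self.is_biallelic:
            raise ValueError("record is multiallelic; split it first")
        return self.alts[0]

    @property
    def length_delta(self) -> int:
        """len(alt) - len(ref) in bp (biallelic records only)."""
        return len(self.alt) - len(self.ref)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantClass:
    """SNV / small indel / structural insertion or deletion."""

    kind: str  # one of SNV, INDEL, SV_INS, SV_DEL
    length_delta: int

    KINDS = ("SNV", "INDEL", "SV_INS", "SV_DEL")

    @property
    def is_sv(self) -> bool:
        return self.kind in ("SV_INS", "SV_DEL")


@dataclass(frozen=True)
class PafRecord:
    """One PAF alignment record (12 mandatory columns; tags ignored)."""

    query_name: str
    query_len: int
    query_start: int  # 0-based half-open
    query_end: int
    strand: str
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    n_match: int = 0
    aln_len: int = 0
    mapq: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        for side, start, end, length in (
            ("query", self.query_start, self.query_end, self.query_len),
            ("target", self.target_start, self.target_end, self.target_len),
        ):
            if not (0 <= start < end <= length):
                raise ValueError(
                    f"{side} interval [{start}, {end}) violates "
                    f"0 <= start < end <= {length}"
                )


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based inclusive interval; converted to 0-based half-open on BED output."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF (plain or gzipped) into :class:`VariantRecord` objects.

    Returns records in file order plus the sample-id list. Multiallelic
    records are preserved as-is; use :func:`split_multiallelic` to obtain
    biallelic records.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: malformed VCF header: {exc}") from exc
    samples = list(vf.header.samples)
    records: list[VariantRecord] = []
    it = iter(vf)
    while True:
        try:
            rec = next(it)
        except StopIteration:
            break
        except (ValueError, OSError) as exc:
            raise VcfParseError(
                f"{path}: cannot parse record {len(records) + 1}: {exc}"
            ) from exc
        if rec.alts is None:
            continue  # no ALT: nothing to represent
        genotypes: dict[str, Genotype] = {}
        gq: dict[str, int] = {}
        phased = True
        for s in samples:
            call = rec.samples[s]
            gt = call.get("GT", MISSING)
            if gt is None or len(gt) == 0:
                gt = MISSING
            elif len(gt) == 1:
                gt = (gt[0], gt[0])
            genotypes[s] = (gt[0], gt[1])
            if not call.phased:
                phased = False
            q = call.get("GQ")
            if q is not None:
                gq[s] = int(q)
        info = {}
        for k, v in rec.info.items():
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            info[k] = str(v) if v is not True else "1"
        records.append(
            VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alts=tuple(rec.alts),
                genotypes=genotypes,
                gq=gq or None,
                info=info,
                phased=phased and bool(samples),
                vid=rec.id or ".",
            )
        )
    return records, samples


def _format_gt(gt: Genotype, phased: bool) -> str:
    sep = "|" if phased else "/"
    return sep.join("." if a is None else str(a) for a in gt)


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
) -> None:
    """Write records as minimal VCF v4.2 text (gzipped if path ends in .gz).

    Declares every INFO key present in the records (SUPP_VEC and other keys as
    Type=String) plus GT and, when any record carries genotype qualities, GQ.
    """
    info_keys: list[str] = []
    for r in records:
        for k in r.info:
            if k not in info_keys:
                info_keys.append(k)
    any_gq = any(r.gq for r in records)
    contigs: list[str] = []
    for r in records:
        if r.chrom not in contigs:
            contigs.append(r.chrom)

    lines = ["##fileformat=VCFv4.2"]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    for k in info_keys:
        lines.append(
            f'##INFO=<ID={k},Number=1,Type=String,Description="{k}">'
        )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if any_gq:
        lines.append(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">'
        )
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        header += "\tFORMAT\t" + "\t".join(samples)
    lines.append(header)

    for r in records:
        info_str = (
            ";".join(f"{k}={v}" for k, v in r.info.items()) if r.info else "."
        )
        cols = [
            r.chrom,
            str(r.pos),
            r.vid,
            r.ref,
            ",".join(r.alts),
            ".",
            ".",
            info_str,
        ]
        if samples:
            fmt = "GT:GQ" if any_gq else "GT"
            cols.append(fmt)
            for s in samples:
                gt = _format_gt(r.genotypes.get(s, MISSING), r.phased)
                if any_gq:
                    q = (r.gq or {}).get(s)
                    gt += ":" + ("." if q is None else str(q))
                cols.append(gt)
        lines.append("\t".join(cols))

    path = Path(path)
    text = "\n".join(lines) + "\n"
    if path.suffix == ".gz":
        with pysam.BGZFile(str(path), "w") as fh:  # bgzf, htslib-seekable
            fh.write(text.encode())
    else:
        path.write_text(text)


def _trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    # drop shared trailing bases, then shared leading bases (advancing pos)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def split_multiallelic(record: VariantRecord) -> list[VariantRecord]:
    """Split a k-allelic record into k biallelic records.

    For the record representing alt allele k, sample alleles equal to k are
    recoded to 1, reference alleles stay 0, and alleles belonging to a
    different alt become missing. Shared leading/trailing bases are trimmed.
    Biallelic input is returned unchanged (after the ref==alt sanity check).
    """
    for a in record.alts:
        if a == record.ref:
            raise ValueError(
                f"{record.chrom}:{record.pos}: ALT allele identical to REF"
            )
    if record.is_biallelic:
        return [record]
    out = []
    for k, alt in enumerate(record.alts, start=1):
        genos: dict[str, Genotype] = {}
        for s, gt in record.genotypes.items():
            genos[s] = tuple(
                None if (a is None or (a != 0 and a != k)) else (1 if a == k else 0)
                for a in gt
            )  # type: ignore[assignment]
        pos, ref, a = _trim_alleles(record.pos, record.ref, alt)
        out.append(
            replace(
                record,
                pos=pos,
                ref=ref,
                alts=(a,),
                genotypes=genos,
                gq=dict(record.gq) if record.gq else None,
                info=dict(record.info),
            )
        )
    return out


def classify_variant(record: VariantRecord) -> VariantClass:
    """Classify a biallelic record as SNV, INDEL or SV (>= 50 bp length change)."""
    delta = record.length_delta
    if len(record.ref) == 1 and len(record.alt) == 1:
        return VariantClass("SNV", 0)
    if delta >= SV_LENGTH_THRESHOLD:
        return VariantClass("SV_INS", delta)
    if delta <= -SV_LENGTH_THRESHOLD:
        return VariantClass("SV_DEL", delta)
    return VariantClass("INDEL", delta)


def read_paf(path: str | Path) -> list[PafRecord]:
    """Parse a PAF file (minimap2 dialect); optional tag columns are ignored."""
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise PafParseError(
                    f"{path}: line {lineno}: expected >= 12 columns, got {len(cols)}"
                )
            try:
                rec = PafRecord(
                    query_name=cols[0],
                    query_len=int(cols[1]),
                    query_start=int(cols[2]),
                    query_end=int(cols[3]),
                    strand=cols[4],
                    target_name=cols[5],
                    target_len=int(cols[6]),
                    target_start=int(cols[7]),
                    target_end=int(cols[8]),
                    n_match=int(cols[9]),
                    aln_len=int(cols[10]),
                    mapq=int(cols[11]),
                )
            except ValueError as exc:
                raise PafParseError(f"{path}: line {lineno}: {exc}") from exc
            records.append(rec)
    return records


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Extract gene models from a GFF3 file.

    Rows of type ``gene`` contribute one :class:`GeneModel` each, identified by
    their ``ID`` (or, failing that, ``gene``/``Name``) attribute; rows lacking
    any identifier are skipped with a warning. All other feature types are
    ignored.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = None
        for key in ("ID", "gene", "Name"):
            if key in feat.attributes:
                gene_id = feat.attributes[key][0]
                break
        if gene_id is None:
            warnings.warn(
                f"{path}: gene at {feat.seqid}:{feat.start}-{feat.end} has no "
                "ID/gene attribute; skipped"
            )
            continue
        genes.append(
            GeneModel(gene_id=gene_id, chrom=feat.seqid, start=feat.start, end=feat.end)
        )
    return genes


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted by (chrom, start), overlapping or book-ended
    (adjacent) intervals merged."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + 1:
            last = merged[-1]
            merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
        else:
            merged.append(iv)
    return merged


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3 (0-based half-open), merged and sorted."""
    with open(path, "wt") as fh:
        for iv in merge_intervals(intervals):
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ into 1-based inclusive intervals."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            out.append(GenomicInterval(cols[0], int(cols[1]) + 1, int(cols[2])))
    return out
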