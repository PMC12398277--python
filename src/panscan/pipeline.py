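"""End-to-end orchestration of the selection-scan pipeline.

Stages: (optional) simulation of a phased sweep cohort, genotype-quality
masking and variant filtering, the haplotype scan (iHS and/or nSL),
window/hysteresis peak calling, merged selection regions, gene overlap and
(when impact annotations are present) impact-class enrichment. All randomness
flows from one global seed through named per-stage substreams, and every
intermediate artifact is plain TSV/BED/VCF.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .enrichment import impact_enrichment
from .haplotype import HaplotypeMatrix, ScanConfig
from .peaks import PeakConfig, genes_in_peaks, merge_peak_regions
from .qc import QCConfig, filter_variants, mask_low_gq
from .scan import SelectionScan
from .simulate import (
    PanelConfig,
    SweepConfig,
    generate_neutral_panel,
    implant_sweep,
    panel_to_vcf_records,
)
from .variants import (
    read_gff3_genes,
    read_vcf,
    split_multiallelic,
    write_bed,
    write_vcf,
)

__all__ = ["PipelineConfig", "run_selection_pipeline"]


def _substream(seed: int, name: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class SimulationSection:
    panel: PanelConfig = field(default_factory=PanelConfig)
    sweep: Optional[SweepConfig] = None


@dataclass
class PipelineConfig:
    out_dir: str = "panscan_out"
    seed: int = 0
    vcf: Optional[str] = None  # phased input VCF; exclusive with simulate
    simulate: Optional[SimulationSection] = None
    genes_gff3: Optional[str] = None
    population: str = ""
    metrics: tuple[str, ...] = ("ihs",)
    qc: QCConfig = field(default_factory=QCConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("out_dir", "seed", "vcf", "genes_gff3", "population"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "metrics" in raw:
            cfg.metrics = tuple(raw["metrics"])
        if "qc" in raw:
            cfg.qc = QCConfig(**raw["qc"])
        if "scan" in raw:
            cfg.scan = ScanConfig(**raw["scan"])
        if "peaks" in raw:
            cfg.peaks = PeakConfig(**raw["peaks"])
        if "simulate" in raw:
            sim = raw["simulate"] or {}
            section = SimulationSection()
            if "panel" in sim:
                section.panel = PanelConfig(**sim["panel"])
            if "sweep" in sim:
                section.sweep = SweepConfig(**sim["sweep"])
            cfg.simulate = section
        return cfg


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        return asdict(o) if hasattr(o, "__dataclass_fields__") else str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_selection_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> QC -> scan -> peaks -> regions (-> genes, enrichment).

    Returns a run log (also written as run_log.json) recording the config
    hash, seed, and per-stage record counts; record counts are conserved
    (records out of each filter = records in - records removed).
    """
    if config.vcf is None and config.simulate is None:
        raise ValueError("config must provide an input VCF or a simulate section")
    if config.vcf is not None and config.simulate is not None:
        raise ValueError("provide either an input VCF or a simulate section, not both")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    # --- input stage -----------------------------------------------------
    if config.simulate is not None:
        panel_cfg = config.simulate.panel
        if panel_cfg.seed == 0 and config.seed:
            panel_cfg.seed = _substream(config.seed, "panel")
        panel = generate_neutral_panel(panel_cfg)
        if config.simulate.sweep is not None:
            sweep_cfg = config.simulate.sweep
            if sweep_cfg.seed == 0 and config.seed:
                sweep_cfg.seed = _substream(config.seed, "sweep")
            panel = implant_sweep(panel, sweep_cfg)
        records, samples = panel_to_vcf_records(panel)
        vcf_path = out / "simulated.vcf"
        write_vcf(records, samples, vcf_path)
        log["stages"]["simulate"] = {
            "n_haplotypes": panel.n_hap, "n_sites": panel.n_site,
        }
    else:
        records, samples = read_vcf(config.vcf)
        records = [r for rec in records for r in split_multiallelic(rec)]
    n_in = len(records)

    # --- QC stage --------------------------------------------------------
    records = mask_low_gq(records, config.qc.min_gq)
    kept = filter_variants(records, config.qc)
    log["stages"]["qc"] = {
        "records_in": n_in,
        "records_removed": n_in - len(kept),
        "records_out": len(kept),
    }
    assert log["stages"]["qc"]["records_out"] == n_in - (
        log["stages"]["qc"]["records_removed"]
    )

    # --- scan stage ------------------------------------------------------
    matrix = HaplotypeMatrix.from_records(kept, samples)
    all_peaks = []
    for metric in config.metrics:
        results = SelectionScan(
            matrix, metric=metric, config=config.scan,
            population=config.population,
        ).fit()
        scores_path = out / f"scores_{metric}.tsv"
        results.to_tsv(scores_path)
        peaks = results.call_peaks(config.peaks)
        all_peaks.extend(peaks)
        log["stages"][f"scan_{metric}"] = {
            "sites": matrix.n_site,
            "valid_scores": results.n_valid,
            "peaks": len(peaks),
        }

    # --- regions stage ---------------------------------------------------
    regions = merge_peak_regions(all_peaks)
    write_bed(regions, out / "peaks.bed")
    log["stages"]["regions"] = {"merged_regions": len(regions)}

    if config.genes_gff3:
        genes = read_gff3_genes(config.genes_gff3)
        _, gene_hits = genes_in_peaks(all_peaks, genes)
        with open(out / "genes.tsv", "w") as fh:
            fh.write("gene_id\tn_peaks\n")
            for gid, n in sorted(gene_hits.items()):
                fh.write(f"{gid}\t{n}\n")
        log["stages"]["genes"] = {"genes_in_peaks": len(gene_hits)}

    annotated = [r for r in kept if "IMPACT" in r.info or "ANN" in r.info]
    if annotated and regions:
        enr = impact_enrichment(annotated, regions)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        log["stages"]["enrichment"] = {"tests": len(enr)}

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return log
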