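"""Pipeline orchestration: config, the annotate run, and report rendering.

A run reads the reference FASTA + GFF3, loads mutant and parent variant
sets (VCF or delimited table), subtracts parent from mutant, classifies
every differential variant, and writes: an annotated VCF (INFO field with
gene/category/notation), a per-gene TSV report in summary-table layout
(chromosome, gene, symbol, description, CDS length, '; '-joined
variations sorted by CDS offset), and a machine-readable summary JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .consequences import (
    DEFAULT_INACTIVATING,
    INACTIVATING_WITH_INFRAME,
    AnnotationResult,
    SubstitutionMatrix,
    annotate_variants,
)
from .reference_io import Genome, read_fasta, read_gff3
from .variants import (
    StrainVariantSet,
    differential_variants,
    read_variant_table,
    read_vcf,
)

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1

POLICIES = {
    "default": DEFAULT_INACTIVATING,
    "include-inframe": INACTIVATING_WITH_INFRAME,
}


class PipelineError(ValueError):
    """Invalid pipeline configuration or stage failure."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for one annotate run."""

    fasta: Path
    gff: Path
    mutant: Path
    parent: Path
    outdir: Path
    blosum_threshold: int = 0
    inactivating_policy: str = "default"
    table_format: Mapping[str, str] | None = None  # column mapping for TSVs
    keep_filtered: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fasta", "gff", "mutant", "parent"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise PipelineError(f"missing input file for {name}: {p}")
        self.outdir = Path(self.outdir)
        if self.inactivating_policy not in POLICIES:
            raise PipelineError(
                f"unknown inactivating policy {self.inactivating_policy!r}; "
                f"choose from {sorted(POLICIES)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _load_variants(
    path: Path, genome: Genome, strain: str, cfg: PipelineConfig
) -> StrainVariantSet:
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_vcf(
            path, genome, strain=strain, keep_filtered=cfg.keep_filtered,
            reference="+".join(genome.sequences),
        )
    # bare tables default to keeping every row (no FILTER column semantics)
    return read_variant_table(
        path, genome, strain=strain, columns=cfg.table_format,
        reference="+".join(genome.sequences),
    )


def run_annotate(cfg: PipelineConfig) -> dict:
    """Execute the full annotate stage; returns the summary dict.

    Artifacts under ``cfg.outdir``: differential.vcf (annotated),
    gene_report.tsv, summary.json, manifest.json.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    logger.info("strainvar %s annotate: inputs fasta=%s(%s) gff=%s(%s)",
                __version__, cfg.fasta, _checksum(cfg.fasta),
                cfg.gff, _checksum(cfg.gff))
    logger.info("thresholds: blosum>=%d conservative, policy=%s",
                cfg.blosum_threshold, cfg.inactivating_policy)

    genome = read_fasta(cfg.fasta)
    genes = read_gff3(cfg.gff, genome)
    mutant = _load_variants(cfg.mutant, genome, "mutant", cfg)
    parent = _load_variants(cfg.parent, genome, "parent", cfg)
    diff = differential_variants(mutant, parent)
    logger.info("%d mutant, %d parent, %d differential variants",
                len(mutant), len(parent), len(diff))

    matrix = SubstitutionMatrix(conservative_threshold=cfg.blosum_threshold)
    result = annotate_variants(
        diff.variants, genes, genome, matrix=matrix,
        policy=POLICIES[cfg.inactivating_policy],
    )

    _write_annotated_vcf(result, genome, cfg.outdir / "differential.vcf")
    rows = result.gene_rows(genes, genome)
    pd.DataFrame(
        rows,
        columns=["Chromosome", "GeneID", "Symbol", "Description",
                 "CDS length", "Amino acid variation"],
    ).to_csv(cfg.outdir / "gene_report.tsv", sep="\t", index=False)

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "strainvar_version": __version__,
        "inputs": {
            "fasta": str(cfg.fasta),
            "gff": str(cfg.gff),
            "mutant": str(cfg.mutant),
            "parent": str(cfg.parent),
        },
        "checksums": {
            name: _checksum(getattr(cfg, name))
            for name in ("fasta", "gff", "mutant", "parent")
        },
        "thresholds": {
            "blosum_threshold": cfg.blosum_threshold,
            "inactivating_policy": cfg.inactivating_policy,
        },
        "n_mutant": len(mutant),
        "n_parent": len(parent),
        "n_differential": len(diff),
        **result.summary.as_dict(),
    }
    with open(cfg.outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(cfg.outdir / "manifest.json", "w") as fh:
        json.dump(
            {
                "artifacts": ["differential.vcf", "gene_report.tsv", "summary.json"],
                "config": {k: str(v) for k, v in vars(cfg).items()},
            },
            fh,
            indent=2,
        )
    return summary


def _write_annotated_vcf(result: AnnotationResult, genome: Genome, path: Path) -> None:
    by_variant: dict = {}
    for c in result.consequences:
        by_variant.setdefault(c.variant, []).append(c)
    for lv in result.intergenic:
        by_variant.setdefault(lv.variant, [])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=strainvar-annotate\n")
        fh.write(
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
            'gene|category|notation">\n'
        )
        for chrom, seq in genome.sequences.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(by_variant):
            cons = by_variant[v]
            if cons:
                info = "CSQ=" + ",".join(
                    f"{c.gene_id}|{c.category.value}|{c.notation.replace(' ', '_')}"
                    for c in cons
                )
            else:
                info = "CSQ=intergenic||"
            fh.write(f"{v.chromosome}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")


def load_summary(path: str | Path) -> dict:
    """Load and schema-check a summary JSON."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("schema_version") != SUMMARY_SCHEMA_VERSION:
        raise PipelineError(
            f"summary schema version {data.get('schema_version')!r} != "
            f"{SUMMARY_SCHEMA_VERSION}"
        )
    required = {"counts", "n_variants", "n_genes_affected", "n_inactivating"}
    missing = required - set(data)
    if missing:
        raise PipelineError(f"summary missing fields: {sorted(missing)}")
    return data


def render_report(summary: dict, gene_report_tsv: str | Path | None = None) -> str:
    """Deterministic human-readable rendering of a summary (plus the
    per-gene table when available), suitable for printing."""
    lines = [
        "strainvar annotate summary",
        "==========================",
        f"differential variants : {summary.get('n_differential', summary['n_variants'])}",
        f"variant-gene pairs    : {summary['n_variants']}",
        f"genes affected        : {summary['n_genes_affected']}",
        f"intergenic records    : {summary.get('n_intergenic', 0)}",
        f"CDS-inactivating      : {summary['n_inactivating']}",
        "",
        "category counts:",
    ]
    for cat in sorted(summary["counts"]):
        lines.append(f"  {cat:<26s} {summary['counts'][cat]}")
    if gene_report_tsv is not None and Path(gene_report_tsv).exists():
        df = pd.read_csv(gene_report_tsv, sep="\t")
        lines += ["", "per-gene variations:"]
        for _, r in df.iterrows():
            lines.append(
                f"  {r['Chromosome']:<6s} {r['Symbol']:<10s} "
                f"{r['CDS length']:>5d}  {r['Amino acid variation']}"
            )
    return "\n".join(lines) + "\n"
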