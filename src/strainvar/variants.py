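"""Per-strain variant sets: reading, normalization, strain comparison.

Variant identity is the normalized (chromosome, pos, ref, alt) 4-tuple;
genotype and zygosity are ignored because strain call sets are treated as
flat haploid lists. Indels are kept in anchored (VCF-style) representation
and left-aligned so that different encodings of the same event compare
equal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .reference_io import Genome

logger = logging.getLogger(__name__)

_ALLELE_BASES = frozenset("ACGTN")


class VariantError(ValueError):
    """Inconsistent or malformed variant input."""


@dataclass(frozen=True, order=True)
class Variant:
    """Normalized chrom/pos/ref/alt record, 1-based position."""

    chromosome: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantError(f"position must be 1-based, got {self.pos}")
        if not self.ref or not self.alt:
            raise VariantError("alleles must be non-empty (anchored indels)")
        if self.ref == self.alt:
            raise VariantError(f"ref == alt ({self.ref}) at {self.chromosome}:{self.pos}")
        for allele in (self.ref, self.alt):
            bad = set(allele.upper()) - _ALLELE_BASES
            if bad:
                raise VariantError(f"invalid allele characters {sorted(bad)}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_mnv(self) -> bool:
        return len(self.ref) == len(self.alt) > 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def net_length_change(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def ref_span(self) -> tuple[int, int]:
        """Genomic interval covered by the REF allele (1-based inclusive)."""
        return self.pos, self.pos + len(self.ref) - 1

    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.pos, self.ref, self.alt)


@dataclass
class StrainVariantSet:
    """A named strain's set of normalized variants."""

    strain: str
    variants: set[Variant] = field(default_factory=set)
    reference: str | None = None  # genome id used for normalization

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(sorted(self.variants))

    def add(self, v: Variant) -> None:
        self.variants.add(v)


def _check_ref(v: Variant, genome: Genome, source: str) -> None:
    start, end = v.ref_span
    observed = genome.slice(v.chromosome, start, end)
    if observed != v.ref:
        raise VariantError(
            f"{source}: REF mismatch at {v.chromosome}:{v.pos} "
            f"(record says {v.ref!r}, reference has {observed!r})"
        )


def normalize_variant(v: Variant, genome: Genome) -> Variant:
    """Canonical form: shared prefix/suffix trimmed, indels left-aligned.

    Idempotent; identity on already-normal variants. The algorithm is the
    standard left-alignment loop: trim equal terminal bases, then, while
    the trailing bases of both alleles agree, rotate in the reference base
    preceding the locus.
    """
    chrom, pos, ref, alt = v.chromosome, v.pos, v.ref.upper(), v.alt.upper()
    _check_ref(Variant(chrom, pos, ref, alt), genome, "normalize")

    # trim shared suffix, keeping at least one base per allele
    while min(len(ref), len(alt)) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix
    while min(len(ref), len(alt)) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    # left-shift anchored indels through repeats
    while len(ref) != len(alt) and ref[-1] == alt[-1] and pos > 1:
        prev = genome.slice(chrom, pos - 1, pos - 1)
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
        while min(len(ref), len(alt)) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
    return Variant(chrom, pos, ref, alt)


def read_vcf(
    path: str | Path,
    genome: Genome,
    strain: str | None = None,
    keep_filtered: bool = False,
    reference: str | None = None,
) -> StrainVariantSet:
    """Read a VCF 4.x (sites-only or single-sample) into a normalized set.

    Multi-allelic records are split one Variant per ALT; records failing
    FILTER are excluded unless ``keep_filtered``. REF alleles are checked
    against the genome; mismatches raise listing the offending records.
    """
    name = strain or Path(path).stem
    out = StrainVariantSet(strain=name, reference=reference)
    mismatches: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # pysam warns on missing index
        vcf = pysam.VariantFile(str(path))
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            filters = list(rec.filter.keys())
            if filters and filters != ["PASS"] and not keep_filtered:
                continue
            for alt in rec.alts or ():
                if alt is None or set(alt.upper()) - _ALLELE_BASES:
                    logger.warning("skipping symbolic ALT %r at %s:%s",
                                   alt, rec.chrom, rec.pos)
                    continue
                v = Variant(rec.chrom, rec.pos, rec.ref.upper(), alt.upper())
                try:
                    _check_ref(v, genome, str(path))
                except VariantError as exc:
                    mismatches.append(str(exc))
                    continue
                out.add(normalize_variant(v, genome))
    if mismatches:
        raise VariantError(
            f"{len(mismatches)} REF mismatch(es) vs reference:\n" + "\n".join(mismatches)
        )
    return out


DEFAULT_TABLE_COLUMNS: Mapping[str, str] = {
    "chromosome": "chromosome",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
}


def read_variant_table(
    path: str | Path,
    genome: Genome,
    strain: str | None = None,
    columns: Mapping[str, str] | None = None,
    sep: str = "\t",
    one_based: bool = True,
    reference: str | None = None,
) -> StrainVariantSet:
    """Read a delimited per-strain variant table (supplementary-dataset
    dialect) into a normalized set; same contract as :func:`read_vcf`.

    ``columns`` maps the canonical field names (chromosome/pos/ref/alt) to
    the table's column headers. The table's exact layout is config-driven
    because published supplementary lists vary.
    """
    colmap = dict(DEFAULT_TABLE_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise VariantError(
            f"{path}: cannot map required fields; missing columns {missing} "
            f"(available: {list(df.columns)})"
        )
    name = strain or Path(path).stem
    out = StrainVariantSet(strain=name, reference=reference)
    n_dup = 0
    for _, row in df.iterrows():
        pos = int(row[colmap["pos"]])
        if not one_based:
            pos += 1
        v = Variant(
            str(row[colmap["chromosome"]]),
            pos,
            str(row[colmap["ref"]]).upper(),
            str(row[colmap["alt"]]).upper(),
        )
        _check_ref(v, genome, str(path))
        v = normalize_variant(v, genome)
        if v in out.variants:
            n_dup += 1
        out.add(v)
    if n_dup:
        logger.warning("%s: %d duplicate row(s) collapsed", path, n_dup)
    return out


def differential_variants(
    mutant: StrainVariantSet, parent: StrainVariantSet
) -> StrainVariantSet:
    """Variants private to the mutant: exact set difference mutant - parent
    on (chrom, pos, ref, alt) keys. Both sets must have been normalized
    against the same reference."""
    if (
        mutant.reference is not None
        and parent.reference is not None
        and mutant.reference != parent.reference
    ):
        raise VariantError(
            f"variant sets normalized against different references: "
            f"{mutant.reference!r} vs {parent.reference!r}"
        )
    return StrainVariantSet(
        strain=f"{mutant.strain}_minus_{parent.strain}",
        variants=mutant.variants - parent.variants,
        reference=mutant.reference,
    )


def write_vcf(
    variants: Iterable[Variant],
    genome: Genome,
    path: str | Path,
    source: str = "strainvar",
) -> None:
    """Write a minimal sites-only VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for chrom, seq in genome.sequences.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants):
            fh.write(f"{v.chromosome}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\n")
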