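"""Reference genome and gene-model IO.

Parses FASTA reference sequences and GFF3 gene annotations into an
in-memory genome model, and provides strand-aware CDS extraction and
translation with the standard nuclear genetic code.

Coordinate convention: 1-based inclusive throughout (GFF3 and VCF share
it), so no off-by-one translation happens at module seams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class ReferenceError(ValueError):
    """Malformed reference sequence or annotation."""


@dataclass
class Genome:
    """Reference sequences keyed by chromosome id (uppercase A/C/G/T/N)."""

    sequences: dict[str, str]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Return bases start..end, 1-based inclusive."""
        if start < 1 or end > self.length(chrom):
            raise ReferenceError(
                f"slice {chrom}:{start}-{end} outside chromosome bounds "
                f"(1..{self.length(chrom)})"
            )
        return self.sequences[chrom][start - 1 : end]


@dataclass
class GeneModel:
    """A stranded set of CDS intervals on one chromosome.

    ``cds_segments`` are 1-based inclusive (start, end) pairs stored in
    genomic order regardless of strand; splicing into transcript order is
    done at extraction time.
    """

    gene_id: str
    symbol: str
    chromosome: str
    strand: str  # "+" or "-"
    cds_segments: list[tuple[int, int]]
    description: str = ""
    codon_ready: bool = True  # False when CDS length % 3 != 0

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ReferenceError(f"{self.gene_id}: strand must be '+' or '-'")
        segs = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ReferenceError(f"{self.gene_id}: overlapping CDS segments")
        for s, e in segs:
            if s < 1 or e < s:
                raise ReferenceError(f"{self.gene_id}: bad segment {s}..{e}")
        self.cds_segments = segs

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    def genomic_positions(self) -> list[int]:
        """All CDS genomic positions in transcript (5'->3' mRNA) order."""
        pos: list[int] = []
        for s, e in self.cds_segments:
            pos.extend(range(s, e + 1))
        if self.strand == "-":
            pos.reverse()
        return pos

    def contains(self, genomic_pos: int) -> bool:
        return any(s <= genomic_pos <= e for s, e in self.cds_segments)

    def cds_offset_of(self, genomic_pos: int) -> int | None:
        """1-based offset of a genomic position within the spliced,
        strand-corrected CDS; None if the position is not in the CDS."""
        if not self.contains(genomic_pos):
            return None
        before = 0
        for s, e in self.cds_segments:
            if genomic_pos > e:
                before += e - s + 1
            elif genomic_pos >= s:
                before += genomic_pos - s
                break
        if self.strand == "+":
            return before + 1
        return self.cds_length - before

    def genomic_pos_of(self, cds_offset: int) -> int:
        """Inverse of :meth:`cds_offset_of` (1-based both sides)."""
        if not 1 <= cds_offset <= self.cds_length:
            raise ReferenceError(
                f"{self.gene_id}: CDS offset {cds_offset} out of 1..{self.cds_length}"
            )
        k = cds_offset if self.strand == "+" else self.cds_length - cds_offset + 1
        for s, e in self.cds_segments:
            n = e - s + 1
            if k <= n:
                return s + k - 1
            k -= n
        raise AssertionError("unreachable")


@dataclass
class CodingSequence:
    """Spliced, strand-corrected CDS nucleotides for one gene."""

    gene_id: str
    nucleotides: str
    length_codons: int = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.nucleotides)
        if n % 3 != 0:
            raise ReferenceError(
                f"{self.gene_id}: CDS length {n} not divisible by 3"
            )
        self.length_codons = n // 3
        if not self.nucleotides.startswith("ATG"):
            logger.warning("%s: CDS does not start with ATG", self.gene_id)
        if self.nucleotides[-3:] not in {"TAA", "TAG", "TGA"}:
            logger.warning("%s: CDS does not end with a stop codon", self.gene_id)

    def codon(self, codon_index: int) -> str:
        """1-based codon lookup."""
        if not 1 <= codon_index <= self.length_codons:
            raise ReferenceError(
                f"{self.gene_id}: codon {codon_index} out of 1..{self.length_codons}"
            )
        return self.nucleotides[3 * (codon_index - 1) : 3 * codon_index]


def read_fasta(path: str | Path) -> Genome:
    """Read a multi-record FASTA into a :class:`Genome`.

    Sequences are uppercased; only A/C/G/T/N are accepted (RNA with U is
    rejected). Duplicate ids, empty sequences and empty headers raise
    :class:`ReferenceError` naming the record.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ReferenceError(f"{path}: record with empty header")
        if rec.id in sequences:
            raise ReferenceError(f"{path}: duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ReferenceError(f"{path}: record {rec.id!r} has empty sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ReferenceError(
                f"{path}: record {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        sequences[rec.id] = seq
    if not sequences:
        raise ReferenceError(f"{path}: no FASTA records found")
    return Genome(sequences)


def read_gff3(
    path: str | Path,
    genome: Genome,
    feature_types: Sequence[str] = ("gene", "mRNA", "CDS"),
) -> list[GeneModel]:
    """Read GFF3 gene models, grouping CDS segments per gene.

    CDS features are attached to genes via their ``Parent`` chain
    (CDS -> mRNA -> gene, or CDS -> gene directly for CDS-only files when
    ``feature_types`` omits mRNA). Genes whose total CDS length is not
    divisible by 3 are kept for variant location but flagged
    ``codon_ready=False`` and excluded from codon-level classification.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    # map feature id -> ultimate gene id by walking Parent links
    def gene_of(feature: gffutils.Feature) -> gffutils.Feature | None:
        cur = feature
        seen = set()
        while True:
            parents = list(db.parents(cur, level=1))
            if not parents:
                return cur if cur.featuretype == "gene" else None
            cur = parents[0]
            if cur.id in seen:
                return None
            seen.add(cur.id)

    grouped: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        if "Parent" not in cds.attributes and cds.featuretype == "CDS":
            if "ID" not in cds.attributes:
                logger.warning("CDS at %s:%s-%s lacks Parent, skipped",
                               cds.seqid, cds.start, cds.end)
                continue
        anchor = gene_of(cds)
        if anchor is None:
            # CDS-only files: group by the CDS's own Parent/ID string
            pid = cds.attributes.get("Parent", cds.attributes.get("ID", [None]))[0]
            if pid is None:
                logger.warning("CDS at %s:%s-%s has no Parent linkage, skipped",
                               cds.seqid, cds.start, cds.end)
                continue
            gid, symbol, desc = pid, pid, ""
        else:
            gid = anchor.id
            symbol = anchor.attributes.get("Name", [gid])[0]
            desc = anchor.attributes.get("description", [""])[0]
        if cds.seqid not in genome:
            raise ReferenceError(
                f"{path}: CDS of {gid} on unknown chromosome {cds.seqid!r}"
            )
        if cds.start < 1 or cds.end > genome.length(cds.seqid):
            raise ReferenceError(
                f"{path}: CDS of {gid} at {cds.seqid}:{cds.start}-{cds.end} "
                "outside chromosome bounds"
            )
        entry = grouped.setdefault(
            gid,
            {"symbol": symbol, "chrom": cds.seqid, "strand": cds.strand,
             "desc": desc, "segments": []},
        )
        entry["segments"].append((cds.start, cds.end))

    models: list[GeneModel] = []
    for gid, entry in grouped.items():
        gene = GeneModel(
            gene_id=gid,
            symbol=entry["symbol"],
            chromosome=entry["chrom"],
            strand=entry["strand"] if entry["strand"] in {"+", "-"} else "+",
            cds_segments=entry["segments"],
            description=entry["desc"],
        )
        if gene.cds_length % 3 != 0:
            gene.codon_ready = False
            logger.warning(
                "%s: CDS length %d not divisible by 3; excluded from "
                "codon-level classification", gid, gene.cds_length,
            )
        models.append(gene)
    models.sort(key=lambda g: (g.chromosome, g.span))
    return models


def extract_cds(gene: GeneModel, genome: Genome) -> CodingSequence:
    """Spliced, strand-corrected CDS nucleotides.

    Minus-strand genes are concatenated in reverse genomic order and
    reverse-complemented. An N inside the CDS warns but the sequence is
    returned.
    """
    parts = [genome.slice(gene.chromosome, s, e) for s, e in gene.cds_segments]
    nt = "".join(parts)
    if gene.strand == "-":
        nt = str(Seq(nt).reverse_complement())
    if "N" in nt:
        logger.warning("%s: CDS contains N", gene.gene_id)
    return CodingSequence(gene_id=gene.gene_id, nucleotides=nt)


def translate_cds(cds: CodingSequence | str) -> str:
    """Translate with the standard nuclear code; stops rendered '*'.

    Translation does not stop early: internal stops appear as '*' in the
    output (and are the caller's business to report). Codons containing N
    translate to 'X' unless unambiguous.
    """
    nt = cds if isinstance(cds, str) else cds.nucleotides
    if len(nt) % 3 != 0:
        raise ReferenceError("nucleotide length not divisible by 3")
    return str(Seq(nt).translate(table=1))


def translate_codon(codon: str) -> str:
    """Single-codon translation; '*' for stop, 'X' for N-ambiguity."""
    return translate_cds(codon)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/CDS features with ID/Parent attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = g.span
            fh.write(
                f"{g.chromosome}\tstrainvar\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.symbol};description={g.description}\n"
            )
            mrna = f"{g.gene_id}_mRNA"
            fh.write(
                f"{g.chromosome}\tstrainvar\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds_segments, 1):
                phase = 0  # phase tracking unused downstream; 0 placeholder
                fh.write(
                    f"{g.chromosome}\tstrainvar\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={g.gene_id}_CDS{i};Parent={mrna}\n"
                )
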