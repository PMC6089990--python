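"""Codon-level consequence classification of CDS variants.

Each differential variant is located in gene space and classified by its
effect on the spliced, strand-corrected coding sequence:

* substitutions: synonymous, missense (split into conservative /
  non-conservative by BLOSUM62 score), nonsense (sense -> stop), sense
  (stop-loss, stop -> sense), start_loss (codon 1 ATG destroyed);
* indels: frameshift (net length change not divisible by 3) or in-frame
  insertion/deletion, with nucleotide-level notation — insertion
  "+SEQ p/p+1" between CDS offsets p and p+1, deletion "-SEQ p" at CDS
  offset p (sequence and offsets strand-corrected);
* indels spanning a CDS boundary are flagged ``complex``.

"Sense mutation" here means stop-loss: the reading frame's stop codon is
converted to a sense codon, extending translation. A substitution inside
a stop codon that yields another stop is synonymous.

CDS-inactivating status is a policy over categories; the default policy
is {nonsense, frameshift, start_loss, sense}, with in-frame indels
optionally included.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .reference_io import CodingSequence, GeneModel, Genome, extract_cds, translate_codon
from .variants import Variant

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _comp(base: str) -> str:
    return base.translate(_COMPLEMENT)


class Category(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE_CONSERVATIVE = "missense_conservative"
    MISSENSE_NONCONSERVATIVE = "missense_nonconservative"
    NONSENSE = "nonsense"
    SENSE = "sense"  # stop-loss
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    START_LOSS = "start_loss"
    COMPLEX = "complex"


#: categories counted as CDS-inactivating by default
DEFAULT_INACTIVATING: frozenset[Category] = frozenset(
    {Category.NONSENSE, Category.FRAMESHIFT, Category.START_LOSS, Category.SENSE}
)

#: alternative policy also counting whole-codon insertions/deletions
INACTIVATING_WITH_INFRAME: frozenset[Category] = DEFAULT_INACTIVATING | {
    Category.INFRAME_INDEL
}


class ClassificationError(ValueError):
    """Contract violation in consequence classification."""


@dataclass
class SubstitutionMatrix:
    """Amino-acid substitution scores with a conservativeness threshold.

    An exchange is conservative iff score(ref, alt) >= threshold; the
    default matrix is BLOSUM62 with threshold 0, the standard reading of
    conservative vs non-conservative replacements.
    """

    name: str = "BLOSUM62"
    conservative_threshold: int = 0

    def __post_init__(self) -> None:
        self._scores = substitution_matrices.load(self.name)

    def score(self, a: str, b: str) -> float:
        return self._scores[a, b]

    def is_conservative(self, ref_aa: str, alt_aa: str) -> bool:
        return self.score(ref_aa, alt_aa) >= self.conservative_threshold


@dataclass(frozen=True)
class LocatedVariant:
    """A variant placed in gene space: inside a CDS or intergenic."""

    variant: Variant
    region: str  # "CDS" or "intergenic"
    gene_id: str | None = None
    cds_offset: int | None = None  # 1-based, strand-corrected spliced CDS

    def __post_init__(self) -> None:
        in_cds = self.region == "CDS"
        if in_cds != (self.gene_id is not None and self.cds_offset is not None):
            raise ClassificationError(
                "region=CDS requires gene_id and cds_offset (and conversely)"
            )


@dataclass(frozen=True)
class Consequence:
    """One classified variant-gene effect with its notation string."""

    gene_id: str
    variant: Variant
    category: Category
    codon_index: int
    ref_aa: str | None
    alt_aa: str | None
    notation: str
    inactivating: bool
    cds_offset: int = 0

    def __post_init__(self) -> None:
        if not self.notation:
            raise ClassificationError("notation must be non-empty")


def locate_variant(v: Variant, genes: Sequence[GeneModel]) -> list[LocatedVariant]:
    """One record per gene whose CDS overlaps the variant's REF span; a
    single intergenic record when none does. Overlapping genes each get a
    record (per-gene reporting)."""
    hits: list[LocatedVariant] = []
    start, end = v.ref_span
    for g in genes:
        if g.chromosome != v.chromosome:
            continue
        overlapping = [p for p in range(start, end + 1) if g.contains(p)]
        if not overlapping:
            continue
        # anchor offset: first REF-span position inside the CDS, in
        # transcript order (smallest strand-corrected offset)
        offset = min(g.cds_offset_of(p) for p in overlapping)  # type: ignore[arg-type]
        hits.append(LocatedVariant(v, "CDS", g.gene_id, offset))
    if not hits:
        return [LocatedVariant(v, "intergenic")]
    return hits


def classify_substitution(
    lv: LocatedVariant,
    gene: GeneModel,
    cds: CodingSequence,
    matrix: SubstitutionMatrix,
) -> Consequence:
    """Classify a single-nucleotide substitution inside a CDS.

    The affected codon is rebuilt with the alternate base (complemented
    for minus-strand genes) and both codons translated; notation is
    "<refAA><codon_index><altAA>" with "*" for stop.
    """
    v = lv.variant
    if not v.is_snv:
        raise ClassificationError(f"classify_substitution needs an SNV, got {v}")
    offset = gene.cds_offset_of(v.pos)
    if offset is None:
        raise ClassificationError(f"{v} not inside CDS of {gene.gene_id}")
    codon_index = (offset - 1) // 3 + 1
    within = (offset - 1) % 3
    codon = cds.codon(codon_index)
    alt_base = v.alt if gene.strand == "+" else _comp(v.alt)
    mutated = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = translate_codon(codon)
    alt_aa = translate_codon(mutated)

    if ref_aa == alt_aa:
        category = Category.SYNONYMOUS  # includes stop->stop
    elif ref_aa == "*":
        category = Category.SENSE  # stop-loss / read-through
    elif alt_aa == "*":
        category = Category.NONSENSE
    elif codon_index == 1 and codon == "ATG":
        category = Category.START_LOSS
    elif matrix.is_conservative(ref_aa, alt_aa):
        category = Category.MISSENSE_CONSERVATIVE
    else:
        category = Category.MISSENSE_NONCONSERVATIVE

    return Consequence(
        gene_id=gene.gene_id,
        variant=v,
        category=category,
        codon_index=codon_index,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        notation=f"{ref_aa}{codon_index}{alt_aa}",
        inactivating=False,  # assigned by policy later
        cds_offset=offset,
    )


def canonical_indel_notation(ref_cds: str, alt_cds: str) -> tuple[str, int]:
    """Canonical nucleotide-level indel notation from the reference and
    mutated CDS strings.

    Within a repeat, an indel has several equivalent placements along the
    transcript; the 5'-most one is chosen (maximal common suffix), which
    makes the notation independent of strand and of the genomic
    normalization direction. Returns (notation, first_affected_offset).
    """
    net = len(alt_cds) - len(ref_cds)
    if net == 0:
        raise ClassificationError("not an indel")
    b = 0
    while (
        b < min(len(ref_cds), len(alt_cds))
        and ref_cds[len(ref_cds) - 1 - b] == alt_cds[len(alt_cds) - 1 - b]
    ):
        b += 1
    if net > 0:
        a = len(ref_cds) - b  # kept 5' prefix length
        seq = alt_cds[a : a + net]
        return f"+{seq} {a}/{a + 1}", a + 1
    a = len(alt_cds) - b
    seq = ref_cds[a : a - net]
    return f"-{seq} {a + 1}", a + 1


def _contiguous_offsets(gene: GeneModel, positions: list[int]) -> list[int] | None:
    """Strand-corrected CDS offsets of genomic positions if all lie in the
    CDS and form one consecutive run (no intron crossing); else None."""
    offsets = []
    for p in positions:
        o = gene.cds_offset_of(p)
        if o is None:
            return None
    offsets = sorted(gene.cds_offset_of(p) for p in positions)  # type: ignore[misc]
    if offsets[-1] - offsets[0] + 1 != len(offsets):
        return None
    return offsets


def classify_indel(
    lv: LocatedVariant, gene: GeneModel, cds: CodingSequence
) -> Consequence:
    """Classify an anchored insertion or deletion inside a CDS.

    Net length change mod 3 decides frameshift vs in-frame. Notation is
    nucleotide-level with strand-corrected sequence and offsets:
    insertion "+SEQ p/p+1", deletion "-SEQ p". Events that cross a CDS
    boundary (into an intron or past either CDS end) are ``complex``.
    """
    v = lv.variant
    if not v.is_indel:
        raise ClassificationError(f"classify_indel needs an indel, got {v}")
    net = v.net_length_change
    category = Category.FRAMESHIFT if net % 3 != 0 else Category.INFRAME_INDEL

    complex_reason: str | None = None
    notation = ""
    first_offset = lv.cds_offset or 1

    nt = cds.nucleotides
    if len(v.ref) > 1 and len(v.alt) > 1:
        # unequal-length block substitution that normalization could not
        # reduce to an anchored event
        complex_reason = "block substitution with length change"
    elif net > 0:
        inserted = v.alt[1:]
        left, right = v.pos, v.pos + 1
        lo, ro = gene.cds_offset_of(left), gene.cds_offset_of(right)
        if lo is None or ro is None or abs(ro - lo) != 1:
            complex_reason = "insertion at a CDS boundary"
        else:
            p = min(lo, ro)  # transcript 5' flank offset
            seq_t = inserted if gene.strand == "+" else _revcomp(inserted)
            alt_nt = nt[:p] + seq_t + nt[p:]
            notation, first_offset = canonical_indel_notation(nt, alt_nt)
    else:
        deleted = v.ref[1:]
        positions = list(range(v.pos + 1, v.pos + 1 + len(deleted)))
        offsets = _contiguous_offsets(gene, positions)
        if offsets is None:
            complex_reason = "deletion spans a CDS boundary"
        else:
            p = offsets[0]
            alt_nt = nt[: p - 1] + nt[p - 1 + len(deleted) :]
            notation, first_offset = canonical_indel_notation(nt, alt_nt)

    if complex_reason is not None:
        category = Category.COMPLEX
        notation = f"complex({complex_reason}) at CDS~{first_offset}"
        logger.warning("%s in %s flagged complex: %s", v, gene.gene_id, complex_reason)

    codon_index = (first_offset - 1) // 3 + 1
    return Consequence(
        gene_id=gene.gene_id,
        variant=v,
        category=category,
        codon_index=min(codon_index, cds.length_codons),
        ref_aa=None,
        alt_aa=None,
        notation=notation,
        inactivating=False,
        cds_offset=first_offset,
    )


def is_cds_inactivating(
    c: Consequence, policy: frozenset[Category] = DEFAULT_INACTIVATING
) -> bool:
    """True iff the consequence category is in the inactivating policy set."""
    return c.category in policy


def decompose_mnv(v: Variant) -> list[Variant]:
    """Split an equal-length multi-nucleotide substitution into per-base
    SNVs at the positions that actually differ."""
    if not v.is_mnv:
        return [v]
    return [
        Variant(v.chromosome, v.pos + i, r, a)
        for i, (r, a) in enumerate(zip(v.ref, v.alt))
        if r != a
    ]


@dataclass
class ConsequenceSummary:
    """Per-category tallies over variant-gene pairs."""

    counts: dict[str, int]
    n_variants: int            # variant-gene pairs classified
    n_distinct_variants: int   # distinct variant keys
    n_genes_affected: int
    n_inactivating: int
    n_intergenic: int = 0
    codon_collisions: int = 0  # decomposed MNV bases hitting one codon

    def as_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "n_variants": self.n_variants,
            "n_distinct_variants": self.n_distinct_variants,
            "n_genes_affected": self.n_genes_affected,
            "n_inactivating": self.n_inactivating,
            "n_intergenic": self.n_intergenic,
            "codon_collisions": self.codon_collisions,
        }


def summarize(
    consequences: Iterable[Consequence], n_intergenic: int = 0
) -> ConsequenceSummary:
    """Tally classified consequences. Categories are exhaustive and
    mutually exclusive per gene-hit, so counts sum to the number of
    variant-gene pairs."""
    consequences = list(consequences)
    counts = Counter(c.category.value for c in consequences)
    collisions = 0
    by_gene_codon = Counter((c.gene_id, c.codon_index) for c in consequences)
    collisions = sum(n - 1 for n in by_gene_codon.values() if n > 1)
    return ConsequenceSummary(
        counts=dict(counts),
        n_variants=len(consequences),
        n_distinct_variants=len({c.variant.key() for c in consequences}),
        n_genes_affected=len({c.gene_id for c in consequences}),
        n_inactivating=sum(1 for c in consequences if c.inactivating),
        n_intergenic=n_intergenic,
        codon_collisions=collisions,
    )


def format_gene_report(
    gene: GeneModel, consequences: Sequence[Consequence], cds: CodingSequence
) -> dict:
    """One report row per gene: multiple variants joined with '; ' in CDS
    order, alongside the gene's chromosome, symbol and CDS length in
    codons (stop codon included)."""
    if not consequences:
        raise ClassificationError(f"{gene.gene_id}: empty consequence list")
    ordered = sorted(consequences, key=lambda c: c.cds_offset)
    return {
        "Chromosome": gene.chromosome,
        "GeneID": gene.gene_id,
        "Symbol": gene.symbol,
        "Description": gene.description,
        "CDS length": cds.length_codons,
        "Amino acid variation": "; ".join(c.notation for c in ordered),
    }


@dataclass
class AnnotationResult:
    """Everything the consequence stage produces for one variant set."""

    consequences: list[Consequence]
    intergenic: list[LocatedVariant]
    skipped_genes: list[str]
    summary: ConsequenceSummary = field(init=False)

    def __post_init__(self) -> None:
        self.summary = summarize(self.consequences, n_intergenic=len(self.intergenic))

    def gene_rows(
        self, genes: Sequence[GeneModel], genome: Genome
    ) -> list[dict]:
        """Report rows sorted by chromosome then coordinate."""
        by_gene: dict[str, list[Consequence]] = defaultdict(list)
        for c in self.consequences:
            by_gene[c.gene_id].append(c)
        gene_index = {g.gene_id: g for g in genes}
        rows = []
        for gid, cons in by_gene.items():
            g = gene_index[gid]
            rows.append(format_gene_report(g, cons, extract_cds(g, genome)))
        order = {g.gene_id: (g.chromosome, g.span) for g in genes}
        rows.sort(key=lambda r: order[r["GeneID"]])
        return rows


def annotate_variants(
    variants: Iterable[Variant],
    genes: Sequence[GeneModel],
    genome: Genome,
    matrix: SubstitutionMatrix | None = None,
    policy: frozenset[Category] = DEFAULT_INACTIVATING,
) -> AnnotationResult:
    """Locate and classify every variant against every overlapping gene.

    Multi-nucleotide substitutions are decomposed into per-base SNVs
    first, each classified independently. Genes flagged not codon-ready
    are skipped for classification (their hits are dropped with a
    warning). Classification is deterministic and order-independent.
    """
    matrix = matrix or SubstitutionMatrix()
    cds_cache: dict[str, CodingSequence] = {}
    gene_index = {g.gene_id: g for g in genes}
    consequences: list[Consequence] = []
    intergenic: list[LocatedVariant] = []
    skipped: set[str] = set()

    for v in sorted(set(variants)):
        for piece in decompose_mnv(v):
            for lv in locate_variant(piece, genes):
                if lv.region == "intergenic":
                    # only count truly gene-free pieces once per piece
                    intergenic.append(lv)
                    continue
                gene = gene_index[lv.gene_id]  # type: ignore[index]
                if not gene.codon_ready:
                    skipped.add(gene.gene_id)
                    continue
                if gene.gene_id not in cds_cache:
                    cds_cache[gene.gene_id] = extract_cds(gene, genome)
                cds = cds_cache[gene.gene_id]
                if piece.is_snv:
                    c = classify_substitution(lv, gene, cds, matrix)
                else:
                    c = classify_indel(lv, gene, cds)
                c = Consequence(
                    gene_id=c.gene_id,
                    variant=c.variant,
                    category=c.category,
                    codon_index=c.codon_index,
                    ref_aa=c.ref_aa,
                    alt_aa=c.alt_aa,
                    notation=c.notation,
                    inactivating=is_cds_inactivating(c, policy),
                    cds_offset=c.cds_offset,
                )
                consequences.append(c)
    if skipped:
        logger.warning(
            "skipped classification in %d non-codon-ready gene(s): %s",
            len(skipped), ", ".join(sorted(skipped)),
        )
    return AnnotationResult(
        consequences=consequences,
        intergenic=intergenic,
        skipped_genes=sorted(skipped),
    )
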