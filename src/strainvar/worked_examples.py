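"""Toy genes engineered to reproduce canonical report notations.

Builds a small deterministic genome whose genes carry the codon content
needed so that specific planted variants render the classic notation
forms a comparative-genomics report uses: an early stop gain "Q5*", a
stop gain "E94*", an in-frame 3-nt insertion "+TTG 1211/1212", a 1-nt
frameshifting deletion "-G 3233", and two substitutions in one gene
joined as "V373G; K376*". Both strands are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference_io import GeneModel, Genome
from .simulate import _SENSE_CODONS, _revcomp
from .variants import Variant, normalize_variant

_COMP = str.maketrans("ACGTN", "TGCAN")


def _toy_cds(rng: np.random.Generator, n_codons: int, overrides: dict[int, str]) -> str:
    codons = ["ATG"]
    codons += list(rng.choice(_SENSE_CODONS, size=n_codons - 2))
    codons.append("TAA")
    for idx, codon in overrides.items():
        codons[idx - 1] = codon
    return "".join(codons)


def plant_substitution(
    gene: GeneModel, genome: Genome, cds_offset: int, alt_transcript_base: str
) -> Variant:
    """Genomic SNV changing the transcript base at a spliced CDS offset."""
    pos = gene.genomic_pos_of(cds_offset)
    ref = genome.sequences[gene.chromosome][pos - 1]
    alt = (
        alt_transcript_base
        if gene.strand == "+"
        else alt_transcript_base.translate(_COMP)
    )
    return normalize_variant(Variant(gene.chromosome, pos, ref, alt), genome)


def plant_insertion(
    gene: GeneModel, genome: Genome, five_prime_offset: int, seq_t: str
) -> Variant:
    """Anchored genomic insertion between CDS offsets q and q+1
    (transcript orientation sequence ``seq_t``)."""
    q = five_prime_offset
    if gene.strand == "+":
        anchor = gene.genomic_pos_of(q)
        inserted = seq_t
    else:
        anchor = gene.genomic_pos_of(q + 1)
        inserted = _revcomp(seq_t)
    ref = genome.sequences[gene.chromosome][anchor - 1]
    return normalize_variant(
        Variant(gene.chromosome, anchor, ref, ref + inserted), genome
    )


def plant_deletion(
    gene: GeneModel, genome: Genome, first_offset: int, length: int
) -> Variant:
    """Anchored genomic deletion of CDS offsets first..first+length-1."""
    if gene.strand == "+":
        anchor = gene.genomic_pos_of(first_offset) - 1
    else:
        anchor = gene.genomic_pos_of(first_offset + length - 1) - 1
    seq = genome.sequences[gene.chromosome]
    ref = seq[anchor - 1 : anchor + length]
    return normalize_variant(
        Variant(gene.chromosome, anchor, ref, ref[0]), genome
    )


@dataclass
class WorkedBundle:
    genome: Genome
    genes: list[GeneModel]
    variants: list[Variant]
    expected_cells: dict[str, str]  # symbol -> "Amino acid variation" cell


def build_worked_bundle(seed: int = 7) -> WorkedBundle:
    """Five toy genes, each set up for one canonical notation.

    ================  =======  ======  ===========================
    toy gene          codons   strand  expected variation cell
    ================  =======  ======  ===========================
    MRPL44-like         148      -     Q5*
    CDC40-like          456      +     E94*
    CYC8-like           967      +     +TTG 1211/1212 (in-frame)
    TBS1-like          1095      +     -G 3233 (frameshift)
    GEP3-like           557      -     V373G; K376*
    ================  =======  ======  ===========================
    """
    rng = np.random.default_rng(seed)
    layout = [
        # symbol, codons, strand, codon overrides
        ("MRPL44", 148, "-", {5: "CAA"}),
        ("CDC40", 456, "+", {94: "GAA"}),
        # codon 404 spans CDS offsets 1210-1212; offset-1211 base must not
        # be G so the +TTG insertion cannot left-shift
        ("CYC8", 967, "+", {404: "CAT"}),
        # codon 1078 spans offsets 3232-3234; base 3233 is the deleted G,
        # base 3232 differs from G so the deletion is already left-aligned
        ("TBS1", 1095, "+", {1078: "AGT"}),
        ("GEP3", 557, "-", {373: "GTT", 376: "AAA"}),
    ]
    gap = 97
    cursor = 0
    parts: list[str] = []
    genes: list[GeneModel] = []
    filler = "".join(rng.choice(list("ACGT"), size=gap))
    for symbol, n_codons, strand, overrides in layout:
        parts.append("".join(rng.choice(list("ACGT"), size=gap)))
        cursor += gap
        cds = _toy_cds(rng, n_codons, overrides)
        genomic = cds if strand == "+" else _revcomp(cds)
        start = cursor + 1
        end = cursor + len(genomic)
        parts.append(genomic)
        cursor = end
        genes.append(
            GeneModel(
                gene_id=f"toy_{symbol}",
                symbol=symbol,
                chromosome="chrT",
                strand=strand,
                cds_segments=[(start, end)],
                description=f"{symbol}-like toy gene",
            )
        )
    parts.append(filler)
    genome = Genome({"chrT": "".join(parts)})
    by_symbol = {g.symbol: g for g in genes}

    variants = [
        # CAA (Q) codon 5 -> TAA: transcript C->T at CDS offset 13
        plant_substitution(by_symbol["MRPL44"], genome, 13, "T"),
        # GAA (E) codon 94 -> TAA: transcript G->T at offset 280
        plant_substitution(by_symbol["CDC40"], genome, 280, "T"),
        plant_insertion(by_symbol["CYC8"], genome, 1211, "TTG"),
        plant_deletion(by_symbol["TBS1"], genome, 3233, 1),
        # GTT (V373) -> GGT (G): transcript T->G at offset 1118
        plant_substitution(by_symbol["GEP3"], genome, 1118, "G"),
        # AAA (K376) -> TAA: transcript A->T at offset 1126
        plant_substitution(by_symbol["GEP3"], genome, 1126, "T"),
    ]
    expected = {
        "MRPL44": "Q5*",
        "CDC40": "E94*",
        "CYC8": "+TTG 1211/1212",
        "TBS1": "-G 3233",
        "GEP3": "V373G; K376*",
    }
    return WorkedBundle(genome, genes, variants, expected)
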