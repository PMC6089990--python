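"""Synthetic genomes, mutagenized strain pairs and expression matrices.

The generator emulates the structure of a mutate-and-screen comparison:
a small multi-chromosome genome with stranded (occasionally two-segment)
genes, a parent and a mutant strain sharing background variants, a
mutant-private load of NTG-like substitutions plus small indels with
ground-truth consequence labels, and replicate treated/control expression
matrices with planted fold changes. Every draw is seeded and bit-stable.

Truth labels are derived by full-ORF re-application and re-translation of
each planted variant (not by the incremental classifier), so recovery
comparisons are a genuine dual-route check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .consequences import Category, SubstitutionMatrix, canonical_indel_notation
from .expression import ExpressionMatrix
from .reference_io import (
    GeneModel,
    Genome,
    extract_cds,
    translate_cds,
    write_fasta,
    write_gff3,
)
from .variants import StrainVariantSet, Variant, normalize_variant, write_vcf

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOPS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_SENSE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOPS
]

TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}


class SimulationError(ValueError):
    """Infeasible or invalid simulation configuration."""


@dataclass
class MutationSpectrum:
    """Joint probabilities over the 12 ordered (ref -> alt) substitution
    types, plus the indel share of planted events.

    ``joint`` sums to 1 over substitution types; conditional rows
    P(alt | ref) are exposed via :meth:`row`. ``indel_rate`` is the
    fraction of planted events drawn as small indels, with net length
    drawn from ``indel_lengths``.
    """

    joint: dict[tuple[str, str], float]
    indel_rate: float = 0.15
    indel_lengths: dict[int, float] = field(
        default_factory=lambda: {1: 0.3, -1: 0.3, 3: 0.2, -3: 0.2}
    )

    def __post_init__(self) -> None:
        total = sum(self.joint.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"substitution probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.joint.values()):
            raise SimulationError("probabilities must be >= 0")
        if any(r == a for r, a in self.joint):
            raise SimulationError("ref == alt type in spectrum")
        if not 0 <= self.indel_rate <= 1:
            raise SimulationError("indel_rate must be in [0, 1]")

    def ref_weight(self, ref: str) -> float:
        return sum(p for (r, _), p in self.joint.items() if r == ref)

    def row(self, ref: str) -> dict[str, float]:
        """P(alt | ref): sums to 1 over the three alt != ref bases."""
        w = self.ref_weight(ref)
        if w == 0:
            return {a: 1 / 3 for a in BASES if a != ref}
        return {a: p / w for (r, a), p in self.joint.items() if r == ref}

    def draw_substitution(self, rng: np.random.Generator) -> tuple[str, str]:
        types = sorted(self.joint)
        probs = np.array([self.joint[t] for t in types])
        idx = rng.choice(len(types), p=probs / probs.sum())
        return types[idx]

    def draw_indel_length(self, rng: np.random.Generator) -> int:
        lengths = sorted(self.indel_lengths)
        probs = np.array([self.indel_lengths[k] for k in lengths], dtype=float)
        return int(lengths[rng.choice(len(lengths), p=probs / probs.sum())])

    @property
    def transition_mass(self) -> float:
        return sum(p for (r, a), p in self.joint.items() if TRANSITIONS[r] == a)

    @classmethod
    def ntg(cls, gc_at_mass: float = 0.8, **kwargs) -> "MutationSpectrum":
        """NTG-like alkylation spectrum: ``gc_at_mass`` of the substitution
        probability on G:C -> A:T transitions (G->A and C->T), the rest
        uniform over the other 10 types. The default 0.8 reflects NTG's
        strong O6-methylguanine signature; the true spectrum of any one
        screen is unknown, so it is configurable."""
        joint = {}
        other = [
            (r, a) for r in BASES for a in BASES
            if r != a and (r, a) not in {("G", "A"), ("C", "T")}
        ]
        joint[("G", "A")] = gc_at_mass / 2
        joint[("C", "T")] = gc_at_mass / 2
        for t in other:
            joint[t] = (1 - gc_at_mass) / len(other)
        return cls(joint=joint, **kwargs)

    @classmethod
    def transitions_only(cls, **kwargs) -> "MutationSpectrum":
        joint = {(r, TRANSITIONS[r]): 0.25 for r in BASES}
        return cls(joint=joint, **kwargs)

    @classmethod
    def uniform(cls, **kwargs) -> "MutationSpectrum":
        joint = {(r, a): 1 / 12 for r in BASES for a in BASES if r != a}
        return cls(joint=joint, **kwargs)


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic strain pair."""

    seed: int
    n_chromosomes: int = 2
    n_genes: int = 20
    gene_length_codons: tuple[int, int] = (80, 400)
    strand_probability: float = 0.5  # probability a gene is minus-strand
    intron_probability: float = 0.25  # chance a gene has two CDS segments
    intergenic_gap: tuple[int, int] = (60, 240)
    n_background_variants: int = 40
    n_private_variants: int = 60
    private_intergenic_fraction: float = 0.15
    category_coverage: bool = True
    include_start_loss: bool = False
    chromosome_length: int | None = None  # None: sized to content

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "n_genes", "n_background_variants", "n_private_variants"
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.n_chromosomes == 0 or self.n_genes == 0:
            raise SimulationError("need at least one chromosome and one gene")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted mutant-private variant."""

    variant: Variant
    gene_id: str | None  # None = intergenic
    category: str        # Category value or "intergenic"
    notation: str


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + stop; no internal stops, no Ns."""
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    stop = STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def simulate_genome(cfg: SimulationConfig) -> tuple[Genome, list[GeneModel]]:
    """Build a packed synthetic genome with valid stranded gene models.

    Genes are laid out left to right with random intergenic gaps; roughly
    ``intron_probability`` of them are split into two CDS segments by a
    short non-coding spacer. Every CDS starts ATG, ends with a stop and
    has length divisible by 3 by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    genes_per_chrom = np.array_split(np.arange(cfg.n_genes), cfg.n_chromosomes)
    sequences: dict[str, str] = {}
    models: list[GeneModel] = []

    for ci, idxs in enumerate(genes_per_chrom):
        chrom = f"chr{ci + 1}"
        parts: list[str] = []
        cursor = 0  # 0-based length so far

        def gap() -> None:
            nonlocal cursor
            n = int(rng.integers(*cfg.intergenic_gap))
            parts.append("".join(rng.choice(list(BASES), size=n)))
            cursor += n

        gap()
        for gi in idxs:
            n_codons = int(rng.integers(*cfg.gene_length_codons))
            cds = _random_cds(rng, n_codons)
            strand = "-" if rng.random() < cfg.strand_probability else "+"
            genomic_cds = cds if strand == "+" else _revcomp(cds)
            if rng.random() < cfg.intron_probability and len(cds) > 60:
                cut = int(rng.integers(30, len(cds) - 30))
                cut = 3 * (cut // 3) or 3  # cut anywhere; segments need not be codon-aligned
                intron = "".join(rng.choice(list(BASES), size=int(rng.integers(40, 90))))
                seg1 = genomic_cds[:cut]
                seg2 = genomic_cds[cut:]
                start1 = cursor + 1
                end1 = cursor + len(seg1)
                start2 = end1 + len(intron) + 1
                end2 = start2 + len(seg2) - 1
                parts.extend([seg1, intron, seg2])
                cursor = end2
                segments = [(start1, end1), (start2, end2)]
            else:
                start = cursor + 1
                end = cursor + len(genomic_cds)
                parts.append(genomic_cds)
                cursor = end
                segments = [(start, end)]
            gid = f"G{gi + 1:04d}"
            models.append(
                GeneModel(
                    gene_id=gid,
                    symbol=f"SYN{gi + 1}",
                    chromosome=chrom,
                    strand=strand,
                    cds_segments=segments,
                    description=f"synthetic gene {gi + 1}",
                )
            )
            gap()
        seq = "".join(parts)
        if cfg.chromosome_length is not None:
            if len(seq) > cfg.chromosome_length:
                raise SimulationError(
                    f"{chrom}: genes need {len(seq)} bp but chromosome_length "
                    f"is {cfg.chromosome_length}"
                )
            pad = cfg.chromosome_length - len(seq)
            seq += "".join(rng.choice(list(BASES), size=pad))
        sequences[chrom] = seq

    genome = Genome(sequences)
    for g in models:  # construction sanity
        cds = extract_cds(g, genome)
        prot = translate_cds(cds)
        assert prot.endswith("*") and "*" not in prot[:-1]
    return genome, models


# ---------------------------------------------------------------------------
# full-ORF truth oracle (independent of the incremental classifier)
# ---------------------------------------------------------------------------

def _transcript_positions(gene: GeneModel) -> list[int]:
    return gene.genomic_positions()


def apply_variant_to_cds(
    v: Variant, gene: GeneModel, genome: Genome
) -> tuple[str, str, int] | None:
    """Apply an anchored variant to the spliced CDS by brute-force rebuild.

    Returns (ref_cds, alt_cds, first_affected_offset_1based), or None when
    the event is not cleanly contained in the CDS (boundary-spanning).
    Works position-list-wise, independently of the classifier's offset
    arithmetic.
    """
    positions = _transcript_positions(gene)
    index_of = {p: i for i, p in enumerate(positions)}
    # strand-correct base by base
    bases = [genome.sequences[gene.chromosome][p - 1] for p in positions]
    if gene.strand == "-":
        bases = [b.translate(_COMPLEMENT) for b in bases]
    ref_cds = "".join(bases)

    if v.is_snv or v.is_mnv:
        out = list(bases)
        first = None
        for i, (r, a) in enumerate(zip(v.ref, v.alt)):
            p = v.pos + i
            if r == a:
                continue
            if p not in index_of:
                return None
            j = index_of[p]
            out[j] = a if gene.strand == "+" else a.translate(_COMPLEMENT)
            first = j if first is None else min(first, j)
        if first is None:
            return None
        return ref_cds, "".join(out), first + 1

    if v.net_length_change > 0:  # insertion between pos and pos+1
        inserted = v.alt[1:]
        left, right = v.pos, v.pos + 1
        if left not in index_of or right not in index_of:
            return None
        il, ir = index_of[left], index_of[right]
        if abs(il - ir) != 1:
            return None  # insertion point falls in an intron gap
        j = min(il, ir)  # transcript index of the 5' flank
        ins_t = inserted if gene.strand == "+" else _revcomp(inserted)
        alt_cds = ref_cds[: j + 1] + ins_t + ref_cds[j + 1 :]
        return ref_cds, alt_cds, j + 2
    # deletion of ref[1:]
    deleted_positions = list(range(v.pos + 1, v.pos + len(v.ref)))
    if any(p not in index_of for p in deleted_positions):
        return None
    idxs = sorted(index_of[p] for p in deleted_positions)
    if idxs[-1] - idxs[0] + 1 != len(idxs):
        return None
    alt_cds = ref_cds[: idxs[0]] + ref_cds[idxs[-1] + 1 :]
    return ref_cds, alt_cds, idxs[0] + 1


def truth_label(
    v: Variant,
    gene: GeneModel,
    genome: Genome,
    matrix: SubstitutionMatrix | None = None,
) -> tuple[str, str] | None:
    """(category, notation) by full re-translation of the mutated ORF.

    Substitutions: translate both full CDSs and diff the proteins. Indels:
    category from net length change, notation from the brute-force CDS
    rebuild. Returns None for boundary-spanning (complex) events.
    """
    matrix = matrix or SubstitutionMatrix()
    applied = apply_variant_to_cds(v, gene, genome)
    if applied is None:
        return None
    ref_cds, alt_cds, first = applied

    if len(ref_cds) == len(alt_cds):
        prot_ref = translate_cds(ref_cds)
        prot_alt = translate_cds(alt_cds)
        if prot_ref == prot_alt:
            ci = (first - 1) // 3 + 1
            aa = prot_ref[ci - 1]
            return Category.SYNONYMOUS.value, f"{aa}{ci}{aa}"
        diffs = [i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
        i = diffs[0]
        ref_aa, alt_aa = prot_ref[i], prot_alt[i]
        ci = i + 1
        notation = f"{ref_aa}{ci}{alt_aa}"
        if ref_aa == "*":
            return Category.SENSE.value, notation
        if alt_aa == "*":
            return Category.NONSENSE.value, notation
        if ci == 1 and ref_cds[:3] == "ATG":
            return Category.START_LOSS.value, notation
        if matrix.is_conservative(ref_aa, alt_aa):
            return Category.MISSENSE_CONSERVATIVE.value, notation
        return Category.MISSENSE_NONCONSERVATIVE.value, notation

    net = len(alt_cds) - len(ref_cds)
    notation, _ = canonical_indel_notation(ref_cds, alt_cds)
    cat = Category.INFRAME_INDEL if net % 3 == 0 else Category.FRAMESHIFT
    return cat.value, notation


# ---------------------------------------------------------------------------
# mutagenesis
# ---------------------------------------------------------------------------

def _blocked(positions: set[int], pos: int, margin: int = 6) -> bool:
    return any(pos + d in positions for d in range(-margin, margin + 1))


def _plant_substitution_at(
    genome: Genome,
    gene: GeneModel,
    cds_offset: int,
    alt_genomic: str,
) -> Variant:
    pos = gene.genomic_pos_of(cds_offset)
    ref = genome.sequences[gene.chromosome][pos - 1]
    return Variant(gene.chromosome, pos, ref, alt_genomic)


def _search_codon_substitution(
    genome: Genome,
    genes: Sequence[GeneModel],
    want: Category,
    rng: np.random.Generator,
    used_by_chrom: dict[str, set[int]],
    matrix: SubstitutionMatrix,
    avoid_start: bool = True,
) -> tuple[Variant, GeneModel] | None:
    """Find a single-base substitution producing the wanted category by
    scanning codons in random order and testing all 9 single-base edits."""
    order = rng.permutation(len(genes))
    for gi in order:
        gene = genes[gi]
        cds = extract_cds(gene, genome)
        codon_indices = list(rng.permutation(cds.length_codons))
        for ci0 in codon_indices:
            ci = int(ci0) + 1
            if avoid_start and ci == 1:
                continue
            codon = cds.codon(ci)
            for within in range(3):
                for alt_t in BASES:
                    if alt_t == codon[within]:
                        continue
                    mutated = codon[:within] + alt_t + codon[within + 1 :]
                    from .reference_io import translate_codon

                    raa = translate_codon(codon)
                    aaa = translate_codon(mutated)
                    if raa == aaa:
                        cat = Category.SYNONYMOUS
                    elif raa == "*":
                        cat = Category.SENSE
                    elif aaa == "*":
                        cat = Category.NONSENSE
                    elif ci == 1 and codon == "ATG":
                        cat = Category.START_LOSS
                    elif matrix.is_conservative(raa, aaa):
                        cat = Category.MISSENSE_CONSERVATIVE
                    else:
                        cat = Category.MISSENSE_NONCONSERVATIVE
                    if cat is not want:
                        continue
                    offset = 3 * (ci - 1) + within + 1
                    pos = gene.genomic_pos_of(offset)
                    if _blocked(used_by_chrom[gene.chromosome], pos):
                        continue
                    alt_g = alt_t if gene.strand == "+" else alt_t.translate(_COMPLEMENT)
                    return (
                        _plant_substitution_at(genome, gene, offset, alt_g),
                        gene,
                    )
    return None


def _plant_indel(
    genome: Genome,
    gene: GeneModel,
    rng: np.random.Generator,
    net: int,
    used_pos: set[int],
) -> Variant | None:
    """Plant an anchored indel strictly inside one CDS segment, redrawing
    until the event is already in normal form (no homopolymer shift), so
    the constructed truth notation survives normalization."""
    chrom_seq = genome.sequences[gene.chromosome]
    for _ in range(60):
        seg_i = int(rng.integers(0, len(gene.cds_segments)))
        s, e = gene.cds_segments[seg_i]
        if net < 0:
            if e - s + 1 < -net + 8:
                continue
            anchor = int(rng.integers(s + 2, e + net - 1))
            ref = chrom_seq[anchor - 1 : anchor - net]
            v = Variant(gene.chromosome, anchor, ref, ref[0])
        else:
            if e - s + 1 < 10:
                continue
            anchor = int(rng.integers(s + 2, e - 2))
            ins = "".join(rng.choice(list(BASES), size=net))
            ref = chrom_seq[anchor - 1]
            v = Variant(gene.chromosome, anchor, ref, ref + ins)
        if any(_blocked(used_pos, p) for p in range(v.ref_span[0], v.ref_span[1] + 1)):
            continue
        if normalize_variant(v, genome) != v:
            continue  # would left-shift; placement ambiguous, redraw
        return v
    return None


def simulate_mutagenesis(
    genome: Genome,
    genes: Sequence[GeneModel],
    spectrum: MutationSpectrum,
    cfg: SimulationConfig,
) -> tuple[StrainVariantSet, StrainVariantSet, list[TruthRecord]]:
    """Draw a parent/mutant strain pair with ground-truth labels.

    Parent and mutant share ``n_background_variants`` substitutions; the
    mutant additionally carries ``n_private_variants`` events drawn from
    the spectrum (CDS substitutions, small indels, and a configurable
    intergenic fraction). With ``category_coverage`` the private load is
    guaranteed to contain at least one nonsense, stop-loss, synonymous,
    missense (both kinds), frameshift and in-frame indel. Variants
    colliding within a codon-scale window are redrawn (logged).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    matrix = SubstitutionMatrix()
    used: set[tuple[str, int]] = set()
    used_by_chrom: dict[str, set[int]] = {c: set() for c in genome.sequences}

    cds_positions: dict[str, list[tuple[GeneModel, int]]] = {c: [] for c in genome.sequences}
    covered: dict[str, set[int]] = {c: set() for c in genome.sequences}
    for g in genes:
        for p in g.genomic_positions():
            cds_positions[g.chromosome].append((g, p))
            covered[g.chromosome].add(p)

    def register(v: Variant) -> None:
        for p in range(v.ref_span[0], v.ref_span[1] + 1):
            used_by_chrom[v.chromosome].add(p)
        used.add((v.chromosome, v.pos))

    def spot_free(v: Variant) -> bool:
        return not any(
            _blocked(used_by_chrom[v.chromosome], p)
            for p in range(v.ref_span[0], v.ref_span[1] + 1)
        )

    def random_substitution(intergenic: bool) -> tuple[Variant, GeneModel | None]:
        for _ in range(500):
            ref_b, alt_b = spectrum.draw_substitution(rng)
            chrom = list(genome.sequences)[int(rng.integers(0, len(genome.sequences)))]
            seq = genome.sequences[chrom]
            pos = int(rng.integers(1, len(seq) + 1))
            if seq[pos - 1] != ref_b:
                continue
            in_cds = pos in covered[chrom]
            if intergenic == in_cds:
                continue
            v = Variant(chrom, pos, ref_b, alt_b)
            if not spot_free(v):
                continue
            gene = None
            if in_cds:
                gene = next(g for g, p in cds_positions[chrom] if p == pos)
                # avoid the start codon so labels stay unambiguous
                off = gene.cds_offset_of(pos)
                if off is not None and off <= 3 and not cfg.include_start_loss:
                    continue
            return v, gene
        raise SimulationError("could not place a substitution; genome too crowded")

    # background variants: anywhere, shared by both strains
    background: set[Variant] = set()
    while len(background) < cfg.n_background_variants:
        v, _ = random_substitution(intergenic=bool(rng.random() < 0.5))
        background.add(v)
        register(v)

    truth: list[TruthRecord] = []
    private: set[Variant] = set()

    def add_private(v: Variant, gene: GeneModel | None) -> bool:
        vn = normalize_variant(v, genome)
        if vn in private or vn in background:
            return False
        if gene is None:
            truth.append(TruthRecord(vn, None, "intergenic", "."))
        else:
            lab = truth_label(vn, gene, genome, matrix)
            if lab is None:
                return False
            truth.append(TruthRecord(vn, gene.gene_id, lab[0], lab[1]))
        private.add(vn)
        register(vn)
        return True

    coding_genes = [g for g in genes if g.codon_ready]

    if cfg.category_coverage:
        wanted = [
            Category.NONSENSE,
            Category.SENSE,
            Category.SYNONYMOUS,
            Category.MISSENSE_CONSERVATIVE,
            Category.MISSENSE_NONCONSERVATIVE,
        ]
        if cfg.include_start_loss:
            wanted.append(Category.START_LOSS)
        for cat in wanted:
            found = _search_codon_substitution(
                genome, coding_genes, cat, rng, used_by_chrom, matrix,
                avoid_start=cat is not Category.START_LOSS,
            )
            if found is None:
                raise SimulationError(f"coverage: no placement for {cat.value}")
            v, gene = found
            if not add_private(v, gene):
                raise SimulationError(f"coverage: collision planting {cat.value}")
        for net in (-1, 1, -3, 3):  # one frameshift and one in-frame each way
            gene = coding_genes[int(rng.integers(0, len(coding_genes)))]
            v = _plant_indel(genome, gene, rng, net, used_by_chrom[gene.chromosome])
            if v is None or not add_private(v, gene):
                # try other genes before giving up
                ok = False
                for g2 in coding_genes:
                    v = _plant_indel(genome, g2, rng, net, used_by_chrom[g2.chromosome])
                    if v is not None and add_private(v, g2):
                        ok = True
                        break
                if not ok:
                    raise SimulationError(f"coverage: no placement for indel net {net}")

    attempts = 0
    while len(private) < cfg.n_private_variants:
        attempts += 1
        if attempts > 50 * max(cfg.n_private_variants, 1):
            raise SimulationError("could not place requested private variants")
        if rng.random() < cfg.private_intergenic_fraction:
            v, gene = random_substitution(intergenic=True)
            add_private(v, gene)
        elif rng.random() < spectrum.indel_rate:
            gene = coding_genes[int(rng.integers(0, len(coding_genes)))]
            net = spectrum.draw_indel_length(rng)
            v = _plant_indel(genome, gene, rng, net, used_by_chrom[gene.chromosome])
            if v is not None:
                if not add_private(v, gene):
                    logger.debug("collision planting indel, redrawn")
        else:
            v, gene = random_substitution(intergenic=False)
            add_private(v, gene)

    parent = StrainVariantSet("parent", set(background), reference="synthetic")
    mutant = StrainVariantSet(
        "mutant", set(background) | private, reference="synthetic"
    )
    return parent, mutant, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    n_probes: int = 1000,
    n_planted_up: int = 50,
    n_planted_down: int = 30,
    effect: float = 2.0,
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Replicate treated/control matrix with planted log2 fold changes.

    ``effect`` is the planted |log2 fold change| (2.0 = fourfold);
    baseline log2 intensities are probe-specific, noise is i.i.d. normal
    per replicate. Returns the matrix and a truth map probe -> label in
    {"up", "down", "null"}.
    """
    if effect <= 0:
        raise SimulationError("effect must be > 0")
    if n_planted_up + n_planted_down > n_probes:
        raise SimulationError("more planted probes than probes")
    rng = np.random.default_rng(seed)
    probes = [f"P{i + 1:05d}" for i in range(n_probes)]
    labels = (
        ["up"] * n_planted_up
        + ["down"] * n_planted_down
        + ["null"] * (n_probes - n_planted_up - n_planted_down)
    )
    order = rng.permutation(n_probes)
    truth = {probes[i]: labels[j] for i, j in zip(range(n_probes), order)}

    base = rng.uniform(6.0, 12.0, size=n_probes)
    shift = np.array(
        [
            effect if truth[p] == "up" else -effect if truth[p] == "down" else 0.0
            for p in probes
        ]
    )
    cols = {}
    for r in range(n_replicates):
        cols[f"control_{r + 1}"] = base + rng.normal(0, noise_sd, n_probes)
    for r in range(n_replicates):
        cols[f"treated_{r + 1}"] = base + shift + rng.normal(0, noise_sd, n_probes)
    df = pd.DataFrame({k: np.power(2.0, v) for k, v in cols.items()}, index=probes)
    conditions = {
        c: ("treated" if c.startswith("treated") else "control") for c in df.columns
    }
    return ExpressionMatrix(values=df, conditions=conditions), truth


# ---------------------------------------------------------------------------
# recovery report
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Per-category confusion between planted truth and classifier calls."""

    confusion: dict[tuple[str, str], int]  # (truth_category, called_category) -> n
    precision: dict[str, float]
    recall: dict[str, float]
    mismatches: list[tuple[Variant, str, str]]  # variant, truth, called
    notation_agreement: float
    n_compared: int


def recovery_report(truth: Sequence[TruthRecord], result) -> RecoveryReport:
    """Compare planted truth against an :class:`AnnotationResult`.

    Truth and calls are joined on (variant key, gene); an unmatched CDS
    truth key is an error. Intergenic truths must appear among the
    result's intergenic records.
    """
    calls = {(c.variant.key(), c.gene_id): c for c in result.consequences}
    intergenic_keys = {lv.variant.key() for lv in result.intergenic}
    confusion: dict[tuple[str, str], int] = {}
    mismatches = []
    notation_hits = 0
    n_notation = 0
    for t in truth:
        if t.gene_id is None:
            called = "intergenic" if t.variant.key() in intergenic_keys else "missing"
            confusion[("intergenic", called)] = confusion.get(("intergenic", called), 0) + 1
            if called != "intergenic":
                mismatches.append((t.variant, "intergenic", called))
            continue
        key = (t.variant.key(), t.gene_id)
        if key not in calls:
            raise SimulationError(
                f"truth variant {t.variant} in {t.gene_id} has no classifier call"
            )
        c = calls[key]
        confusion[(t.category, c.category.value)] = (
            confusion.get((t.category, c.category.value), 0) + 1
        )
        if c.category.value != t.category:
            mismatches.append((t.variant, t.category, c.category.value))
        n_notation += 1
        if c.notation == t.notation:
            notation_hits += 1

    cats = {t for t, _ in confusion} | {c for _, c in confusion}
    precision = {}
    recall = {}
    for cat in sorted(cats):
        tp = confusion.get((cat, cat), 0)
        fn = sum(n for (t, c), n in confusion.items() if t == cat and c != cat)
        fp = sum(n for (t, c), n in confusion.items() if c == cat and t != cat)
        recall[cat] = tp / (tp + fn) if tp + fn else float("nan")
        precision[cat] = tp / (tp + fp) if tp + fp else float("nan")
    return RecoveryReport(
        confusion=confusion,
        precision=precision,
        recall=recall,
        mismatches=mismatches,
        notation_agreement=notation_hits / n_notation if n_notation else float("nan"),
        n_compared=len(truth),
    )


# ---------------------------------------------------------------------------
# strand-mirror transform and file output
# ---------------------------------------------------------------------------

def mirror_bundle(
    genome: Genome,
    genes: Sequence[GeneModel],
    variants: Sequence[Variant],
) -> tuple[Genome, list[GeneModel], list[Variant]]:
    """Reverse-complement every chromosome, flip strands and remap
    coordinates. Consequence calls must be invariant under this transform.
    Mirrored variants are re-normalized (mirroring moves the indel anchor
    to the other side)."""
    lengths = {c: len(s) for c, s in genome.sequences.items()}
    mirrored_genome = Genome({c: _revcomp(s) for c, s in genome.sequences.items()})
    mirrored_genes = []
    for g in genes:
        L = lengths[g.chromosome]
        segs = sorted((L - e + 1, L - s + 1) for s, e in g.cds_segments)
        mirrored_genes.append(
            GeneModel(
                gene_id=g.gene_id,
                symbol=g.symbol,
                chromosome=g.chromosome,
                strand="-" if g.strand == "+" else "+",
                cds_segments=segs,
                description=g.description,
                codon_ready=g.codon_ready,
            )
        )
    mirrored_variants = []
    for v in variants:
        L = lengths[v.chromosome]
        start, end = v.ref_span
        new_pos = L - end + 1
        mv = Variant(v.chromosome, new_pos, _revcomp(v.ref), _revcomp(v.alt))
        mirrored_variants.append(normalize_variant(mv, mirrored_genome))
    return mirrored_genome, mirrored_genes, mirrored_variants


def write_truth_tsv(truth: Sequence[TruthRecord], path: str | Path) -> None:
    rows = [
        {
            "chromosome": t.variant.chromosome,
            "pos": t.variant.pos,
            "ref": t.variant.ref,
            "alt": t.variant.alt,
            "gene_id": t.gene_id or ".",
            "category": t.category,
            "notation": t.notation,
        }
        for t in truth
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_bundle(
    outdir: str | Path,
    genome: Genome,
    genes: Sequence[GeneModel],
    parent: StrainVariantSet,
    mutant: StrainVariantSet,
    truth: Sequence[TruthRecord],
) -> dict[str, Path]:
    """Write FASTA, GFF3, per-strain VCFs and the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "gff": outdir / "genes.gff3",
        "parent_vcf": outdir / "parent.vcf",
        "mutant_vcf": outdir / "mutant.vcf",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(genome, paths["fasta"])
    write_gff3(genes, paths["gff"])
    write_vcf(parent.variants, genome, paths["parent_vcf"], source="strainvar-simulate")
    write_vcf(mutant.variants, genome, paths["mutant_vcf"], source="strainvar-simulate")
    write_truth_tsv(truth, paths["truth"])
    return paths
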