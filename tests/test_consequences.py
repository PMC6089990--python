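"""Consequence classification: categories, notation, policies, oracles."""

import random

import pytest

from strainvar.consequences import (
    DEFAULT_INACTIVATING,
    INACTIVATING_WITH_INFRAME,
    Category,
    ClassificationError,
    Consequence,
    SubstitutionMatrix,
    annotate_variants,
    classify_substitution,
    decompose_mnv,
    format_gene_report,
    is_cds_inactivating,
    locate_variant,
    summarize,
)
from strainvar.reference_io import GeneModel, Genome, extract_cds
from strainvar.simulate import mirror_bundle, truth_label
from strainvar.variants import Variant, differential_variants
from strainvar.worked_examples import build_worked_bundle, plant_substitution


@pytest.fixture(scope="module")
def worked_result(worked_bundle):
    return annotate_variants(
        worked_bundle.variants, worked_bundle.genes, worked_bundle.genome
    )


class TestWorkedNotations:
    """The five canonical report cells must be reproduced exactly."""

    def test_gene_cells_exact(self, worked_bundle, worked_result):
        rows = worked_result.gene_rows(worked_bundle.genes, worked_bundle.genome)
        cells = {r["Symbol"]: r["Amino acid variation"] for r in rows}
        assert cells == worked_bundle.expected_cells

    @pytest.mark.parametrize(
        "symbol,category",
        [
            ("MRPL44", Category.NONSENSE),        # Q5*: early stop gain
            ("CDC40", Category.NONSENSE),         # E94*
            ("CYC8", Category.INFRAME_INDEL),     # +TTG: 3 nt, in frame
            ("TBS1", Category.FRAMESHIFT),        # -G: 1 nt, shifts frame
        ],
    )
    def test_categories(self, worked_result, symbol, category):
        cats = {
            c.category for c in worked_result.consequences
            if c.gene_id == f"toy_{symbol}"
        }
        assert category in cats

    def test_two_variant_gene_joined_in_cds_order(self, worked_result):
        gep3 = [c for c in worked_result.consequences if c.gene_id == "toy_GEP3"]
        assert sorted(c.notation for c in gep3) == ["K376*", "V373G"]
        cats = {c.notation: c.category for c in gep3}
        assert cats["V373G"] is Category.MISSENSE_NONCONSERVATIVE
        assert cats["K376*"] is Category.NONSENSE

    def test_blosum62_scores_drive_conservativeness(self):
        m = SubstitutionMatrix()
        assert m.score("V", "G") == -3 and not m.is_conservative("V", "G")
        assert m.score("D", "E") == 2 and m.is_conservative("D", "E")


def _single_gene(seq: str, strand: str = "+") -> tuple[Genome, GeneModel]:
    genome = Genome({"c": seq})
    gene = GeneModel("g", "G", "c", strand, [(1, len(seq))])
    return genome, gene


class TestSubstitutionRules:
    def test_synonymous(self):
        genome, gene = _single_gene("ATGCTGTAA")
        (lv,) = locate_variant(Variant("c", 6, "G", "A"), [gene])  # CTG->CTA
        c = classify_substitution(lv, gene, extract_cds(gene, genome), SubstitutionMatrix())
        assert c.category is Category.SYNONYMOUS and c.notation == "L2L"

    def test_stop_loss_is_sense(self):
        genome, gene = _single_gene("ATGCTGTAA")
        (lv,) = locate_variant(Variant("c", 7, "T", "C"), [gene])  # TAA->CAA
        c = classify_substitution(lv, gene, extract_cds(gene, genome), SubstitutionMatrix())
        assert c.category is Category.SENSE and c.notation == "*3Q"

    def test_stop_to_stop_is_synonymous(self):
        genome, gene = _single_gene("ATGCTGTAA")
        (lv,) = locate_variant(Variant("c", 9, "A", "G"), [gene])  # TAA->TAG
        c = classify_substitution(lv, gene, extract_cds(gene, genome), SubstitutionMatrix())
        assert c.category is Category.SYNONYMOUS

    def test_start_loss(self):
        genome, gene = _single_gene("ATGCTGTAA")
        (lv,) = locate_variant(Variant("c", 1, "A", "C"), [gene])  # ATG->CTG
        c = classify_substitution(lv, gene, extract_cds(gene, genome), SubstitutionMatrix())
        assert c.category is Category.START_LOSS and c.notation == "M1L"

    def test_indel_input_is_contract_violation(self):
        genome, gene = _single_gene("ATGCTGTAA")
        (lv,) = locate_variant(Variant("c", 4, "C", "CT"), [gene])
        with pytest.raises(ClassificationError):
            classify_substitution(lv, gene, extract_cds(gene, genome), SubstitutionMatrix())


class TestLocate:
    def test_intergenic(self):
        genome = Genome({"c": "ATGCTGTAA" + "T" * 20})
        gene = GeneModel("g", "G", "c", "+", [(1, 9)])
        (lv,) = locate_variant(Variant("c", 15, "T", "A"), [gene])
        assert lv.region == "intergenic" and lv.gene_id is None

    def test_overlapping_genes_get_one_record_each(self):
        genome = Genome({"c": "ATGATGGCTGCTTAATAA"})
        g1 = GeneModel("g1", "A", "c", "+", [(1, 15)])
        g2 = GeneModel("g2", "B", "c", "+", [(4, 18)])
        hits = locate_variant(Variant("c", 8, "C", "T"), [g1, g2])
        assert {h.gene_id for h in hits} == {"g1", "g2"}

    def test_minus_strand_offset_matches_position_list_oracle(self, sim_bundle):
        genes = [g for g in sim_bundle["genes"] if g.strand == "-"]
        gene = genes[0]
        positions = gene.genomic_positions()  # transcript order
        for k in (0, 1, len(positions) // 2, len(positions) - 1):
            p = positions[k]
            assert gene.cds_offset_of(p) == k + 1
            assert gene.genomic_pos_of(k + 1) == p


class TestMnv:
    def test_decomposed_per_base(self):
        v = Variant("c", 10, "ACG", "TCA")
        parts = decompose_mnv(v)
        assert parts == [Variant("c", 10, "A", "T"), Variant("c", 12, "G", "A")]

    def test_mnv_classified_as_snvs(self):
        genome, gene = _single_gene("ATGCTGGGGTAA")
        res = annotate_variants([Variant("c", 4, "CTG", "TTA")], [gene], genome)
        # C4T and G6A both inside codon 2: reported as two consequences
        assert len(res.consequences) == 2
        assert res.summary.codon_collisions == 1


class TestPolicy:
    @pytest.mark.parametrize(
        "category,expected",
        [
            (Category.NONSENSE, True),
            (Category.FRAMESHIFT, True),
            (Category.SENSE, True),
            (Category.START_LOSS, True),
            (Category.MISSENSE_CONSERVATIVE, False),
            (Category.SYNONYMOUS, False),
            (Category.INFRAME_INDEL, False),
        ],
    )
    def test_default_policy(self, category, expected):
        c = Consequence("g", Variant("c", 1, "A", "T"), category, 1, "A", "T", "x", False)
        assert is_cds_inactivating(c) is expected

    def test_inframe_included_under_switch(self):
        c = Consequence(
            "g", Variant("c", 1, "A", "AT"), Category.INFRAME_INDEL, 1, None, None,
            "+T 1/2", False,
        )
        assert not is_cds_inactivating(c, DEFAULT_INACTIVATING)
        assert is_cds_inactivating(c, INACTIVATING_WITH_INFRAME)


class TestSummary:
    def test_arithmetic(self, worked_result):
        s = worked_result.summary
        assert sum(s.counts.values()) == s.n_variants == len(worked_result.consequences)
        assert s.n_genes_affected == 5
        assert s.n_inactivating == 4  # 3 stop gains + 1 frameshift

    def test_empty_input_all_zero(self):
        s = summarize([])
        assert s.counts == {} and s.n_variants == 0 and s.n_inactivating == 0

    def test_empty_gene_report_is_contract_violation(self, worked_bundle):
        with pytest.raises(ClassificationError):
            format_gene_report(worked_bundle.genes[0], [], None)


class TestOracleEquivalence:
    """The incremental classifier must agree with full-ORF re-translation."""

    def test_planted_variants_agree_with_full_retranslation(
        self, sim_bundle, sim_annotation
    ):
        _, result = sim_annotation
        calls = {(c.variant.key(), c.gene_id): c for c in result.consequences}
        genes = {g.gene_id: g for g in sim_bundle["genes"]}
        n_checked = 0
        for t in sim_bundle["truth"]:
            if t.gene_id is None:
                continue
            oracle = truth_label(t.variant, genes[t.gene_id], sim_bundle["genome"])
            assert oracle is not None
            c = calls[(t.variant.key(), t.gene_id)]
            assert (c.category.value, c.notation) == oracle
            n_checked += 1
        assert n_checked >= 50

    def test_strand_mirror_leaves_calls_invariant(self, sim_bundle, sim_annotation):
        diff, result = sim_annotation
        mg, mgenes, mvars = mirror_bundle(
            sim_bundle["genome"], sim_bundle["genes"], sorted(diff.variants)
        )
        mirrored = annotate_variants(mvars, mgenes, mg)
        a = sorted((c.gene_id, c.category.value, c.notation) for c in result.consequences)
        b = sorted((c.gene_id, c.category.value, c.notation) for c in mirrored.consequences)
        assert a == b

    def test_order_independence(self, sim_bundle, sim_annotation):
        diff, result = sim_annotation
        shuffled = sorted(diff.variants)
        random.Random(5).shuffle(shuffled)
        again = annotate_variants(shuffled, sim_bundle["genes"], sim_bundle["genome"])
        assert sorted(
            (c.variant.key(), c.gene_id, c.notation) for c in again.consequences
        ) == sorted(
            (c.variant.key(), c.gene_id, c.notation) for c in result.consequences
        )

    def test_missense_split_sums_to_total_missense(self, sim_annotation):
        _, result = sim_annotation
        s = result.summary.counts
        cons = s.get("missense_conservative", 0)
        noncons = s.get("missense_nonconservative", 0)
        total = sum(
            1 for c in result.consequences
            if c.category in (Category.MISSENSE_CONSERVATIVE,
                              Category.MISSENSE_NONCONSERVATIVE)
        )
        assert cons + noncons == total > 0


def test_blosum_threshold_moves_the_split(worked_bundle):
    """Raising the conservativeness threshold can only shrink the
    conservative class; at threshold > max score everything is
    non-conservative."""
    genes, genome = worked_bundle.genes, worked_bundle.genome
    v = [x for x in worked_bundle.variants]
    strict = annotate_variants(
        v, genes, genome, matrix=SubstitutionMatrix(conservative_threshold=12)
    )
    assert all(
        c.category is not Category.MISSENSE_CONSERVATIVE for c in strict.consequences
    )
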