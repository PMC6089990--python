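"""Variant reading, normalization and strain set comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainvar.reference_io import Genome
from strainvar.variants import (
    StrainVariantSet,
    Variant,
    VariantError,
    differential_variants,
    normalize_variant,
    read_variant_table,
    read_vcf,
    write_vcf,
)


class TestVariantInvariants:
    def test_ref_equals_alt_rejected(self):
        with pytest.raises(VariantError):
            Variant("c", 5, "A", "A")

    def test_zero_position_rejected(self):
        with pytest.raises(VariantError):
            Variant("c", 0, "A", "T")

    def test_empty_allele_rejected(self):
        with pytest.raises(VariantError):
            Variant("c", 5, "", "T")


class TestNormalize:
    def test_shared_prefix_trimmed(self):
        genome = Genome({"c": "G" * 99 + "CAT" + "G" * 40})
        v = normalize_variant(Variant("c", 100, "CA", "CT"), genome)
        assert v == Variant("c", 101, "A", "T")

    def test_homopolymer_insertion_left_aligned(self):
        #          123456789
        genome = Genome({"c": "GTAAAACGT"})
        # inserting A after any of the As is the same event; leftmost is
        # anchored at the T before the run
        for anchor in (3, 4, 5, 6):
            ref = genome.sequences["c"][anchor - 1]
            v = normalize_variant(Variant("c", anchor, ref, ref + "A"), genome)
            assert v == Variant("c", 2, "T", "TA")

    def test_idempotent(self):
        genome = Genome({"c": "GTAAAACGT"})
        v = normalize_variant(Variant("c", 4, "A", "AA"), genome)
        assert normalize_variant(v, genome) == v

    def test_ref_mismatch_rejected(self):
        genome = Genome({"c": "ACGT"})
        with pytest.raises(VariantError, match="REF mismatch"):
            normalize_variant(Variant("c", 2, "A", "T"), genome)


def _apply(seq: str, v: Variant) -> str:
    """Apply an anchored variant to a sequence string (oracle helper)."""
    s, e = v.ref_span
    assert seq[s - 1 : e] == v.ref
    return seq[: s - 1] + v.alt + seq[e:]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 100_000), net=st.sampled_from([-3, -2, -1, 1, 2, 3]))
def test_normalization_is_canonical_by_brute_force(seed, net):
    """All anchored representations of the same indel (enumerated by
    checking sequence-level equivalence) normalize to one variant, and
    that variant is the leftmost representation."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=30))
    genome = Genome({"c": seq})
    pos = int(rng.integers(5, 20))
    if net > 0:
        ins = "".join(rng.choice(list("ACGT"), size=net))
        v0 = Variant("c", pos, seq[pos - 1], seq[pos - 1] + ins)
    else:
        if pos - net > len(seq):
            return
        v0 = Variant("c", pos, seq[pos - 1 : pos - net], seq[pos - 1])
    mutated = _apply(seq, v0)

    # brute-force: every anchored variant of the same net length whose
    # application yields the same mutated sequence
    equivalents = []
    for p in range(1, len(seq) + 1):
        ref_len = 1 if net > 0 else 1 - net
        if p + ref_len - 1 > len(seq):
            continue
        ref = seq[p - 1 : p + ref_len - 1]
        if net > 0:
            for alt_tail in itertools.product("ACGT", repeat=net):
                cand = Variant("c", p, ref, ref + "".join(alt_tail)) \
                    if ref + "".join(alt_tail) != ref else None
                if cand and _apply(seq, cand) == mutated:
                    equivalents.append(cand)
        else:
            cand = Variant("c", p, ref, ref[0])
            if _apply(seq, cand) == mutated:
                equivalents.append(cand)
    assert equivalents, "enumeration must find at least the original"
    normals = {normalize_variant(v, genome) for v in equivalents}
    assert len(normals) == 1
    norm = normals.pop()
    assert norm.pos == min(v.pos for v in equivalents)


class TestReadVcf:
    def _write(self, tmp_path, records):
        p = tmp_path / "x.vcf"
        header = (
            "##fileformat=VCFv4.2\n"
            '##FILTER=<ID=q10,Description="low qual">\n'
            "##contig=<ID=chrI,length=100>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        p.write_text(header + "".join(records))
        return p

    @pytest.fixture
    def genome(self):
        return Genome({"chrI": "AG" * 50})

    def test_basic_record(self, tmp_path, genome):
        p = self._write(tmp_path, ["chrI\t9\t.\tA\tT\t.\tPASS\t.\n"])
        s = read_vcf(p, genome)
        assert s.variants == {Variant("chrI", 9, "A", "T")}

    def test_multiallelic_split(self, tmp_path, genome):
        p = self._write(tmp_path, ["chrI\t9\t.\tA\tT,C\t.\tPASS\t.\n"])
        s = read_vcf(p, genome)
        assert s.variants == {Variant("chrI", 9, "A", "T"), Variant("chrI", 9, "A", "C")}

    def test_non_pass_excluded_by_default(self, tmp_path, genome):
        p = self._write(
            tmp_path,
            ["chrI\t9\t.\tA\tT\t.\tq10\t.\n", "chrI\t11\t.\tA\tC\t.\tPASS\t.\n"],
        )
        assert read_vcf(p, genome).variants == {Variant("chrI", 11, "A", "C")}
        assert len(read_vcf(p, genome, keep_filtered=True)) == 2

    def test_ref_mismatch_lists_record(self, tmp_path, genome):
        p = self._write(tmp_path, ["chrI\t10\t.\tC\tT\t.\tPASS\t.\n"])
        with pytest.raises(VariantError, match="chrI:10"):
            read_vcf(p, genome)


class TestReadVariantTable:
    @pytest.fixture
    def genome(self):
        return Genome({"chrI": "AG" * 50})

    def test_three_row_toy(self, tmp_path, genome):
        p = tmp_path / "t.tsv"
        p.write_text(
            "chromosome\tpos\tref\talt\n"
            "chrI\t9\tA\tT\nchrI\t11\tA\tC\nchrI\t13\tA\tG\n"
        )
        assert len(read_variant_table(p, genome)) == 3

    def test_duplicate_row_deduplicated(self, tmp_path, genome):
        p = tmp_path / "t.tsv"
        p.write_text("chromosome\tpos\tref\talt\nchrI\t9\tA\tT\nchrI\t9\tA\tT\n")
        assert len(read_variant_table(p, genome)) == 1

    def test_zero_position_rejected(self, tmp_path, genome):
        p = tmp_path / "t.tsv"
        p.write_text("chromosome\tpos\tref\talt\nchrI\t0\tG\tT\n")
        with pytest.raises(VariantError):
            read_variant_table(p, genome)

    def test_missing_columns_named(self, tmp_path, genome):
        p = tmp_path / "t.tsv"
        p.write_text("chrom\tposition\tref\talt\nchrI\t9\tA\tT\n")
        with pytest.raises(VariantError, match="missing columns"):
            read_variant_table(p, genome)

    def test_custom_column_mapping(self, tmp_path, genome):
        p = tmp_path / "t.tsv"
        p.write_text("Chr\tPosition\tRef\tVar\nchrI\t9\tA\tT\n")
        s = read_variant_table(
            p, genome,
            columns={"chromosome": "Chr", "pos": "Position", "ref": "Ref", "alt": "Var"},
        )
        assert s.variants == {Variant("chrI", 9, "A", "T")}


def test_vcf_and_table_encodings_agree(tmp_path, sim_bundle):
    """The same variant set round-tripped through VCF and through the
    delimited-table dialect yields equal normalized sets."""
    genome, mutant = sim_bundle["genome"], sim_bundle["mutant"]
    vcf = tmp_path / "m.vcf"
    write_vcf(mutant.variants, genome, vcf)
    tsv = tmp_path / "m.tsv"
    with open(tsv, "w") as fh:
        fh.write("chromosome\tpos\tref\talt\n")
        for v in sorted(mutant.variants):
            fh.write(f"{v.chromosome}\t{v.pos}\t{v.ref}\t{v.alt}\n")
    from_vcf = read_vcf(vcf, genome)
    from_tsv = read_variant_table(tsv, genome)
    assert from_vcf.variants == from_tsv.variants == mutant.variants


class TestDifferential:
    def test_identical_sets_give_empty(self):
        a = StrainVariantSet("m", {Variant("c", 1, "A", "T")})
        b = StrainVariantSet("p", {Variant("c", 1, "A", "T")})
        assert len(differential_variants(a, b)) == 0

    def test_simple_difference(self):
        v1, v2 = Variant("c", 1, "A", "T"), Variant("c", 5, "G", "C")
        d = differential_variants(
            StrainVariantSet("m", {v1, v2}), StrainVariantSet("p", {v2})
        )
        assert d.variants == {v1}

    def test_parent_private_variants_ignored(self):
        v1, v2, v3 = (Variant("c", i, "A", "T") for i in (1, 3, 5))
        d1 = differential_variants(
            StrainVariantSet("m", {v1}), StrainVariantSet("p", {v2})
        )
        d2 = differential_variants(
            StrainVariantSet("m", {v1}), StrainVariantSet("p", {v2, v3})
        )
        assert d1.variants == d2.variants == {v1}

    def test_difference_union_intersection_reconstructs_mutant(self, sim_bundle):
        mutant, parent = sim_bundle["mutant"], sim_bundle["parent"]
        diff = differential_variants(mutant, parent)
        assert diff.variants | (mutant.variants & parent.variants) == mutant.variants

    def test_mismatched_references_rejected(self):
        a = StrainVariantSet("m", {Variant("c", 1, "A", "T")}, reference="r1")
        b = StrainVariantSet("p", set(), reference="r2")
        with pytest.raises(VariantError, match="different references"):
            differential_variants(a, b)
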