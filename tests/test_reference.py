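"""Reference model: labels, coordinates, codon arithmetic, coding effects."""

import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from mtpop.errors import (
    MissingSequenceError,
    PositionRangeError,
    ProfileConflictError,
    VariantParseError,
)
from mtpop.reference import (
    DELETION,
    INSERTION,
    SUBSTITUTION,
    GeneFeature,
    MitoReference,
    Variant,
    annotate_effect,
    apply_profile,
    codon_position,
    format_variant,
    locate_all_features,
    locate_feature,
    parse_variant_label,
    position_from_codon,
    rcrs,
)

# Published protein positions for the twelve coding substitutions of the
# bundled cohort panel, keyed by nucleotide position.
PANEL_PROTEIN_POSITIONS = {
    3909: ("ND1", 201),
    4769: ("ND2", 100),
    5465: ("ND2", 332),
    6261: ("COI", 120),
    6719: ("COI", 272),
    6782: ("COI", 293),
    6905: ("COI", 334),
    7028: ("COI", 375),
    8860: ("ATP6", 112),
    8865: ("ATP6", 113),
    9123: ("ATP6", 199),
    9145: ("ATP6", 207),
}


class TestParseVariantLabel:
    @pytest.mark.parametrize(
        "label, kind, position, ref_allele, alt",
        [
            ("m.1806T>C", SUBSTITUTION, 1806, "T", "C"),
            ("3909T", SUBSTITUTION, 3909, "C", "T"),
            ("m.16295C insA", INSERTION, 16295, "", "A"),
            ("16295insA", INSERTION, 16295, "", "A"),
            ("8281-8289d", DELETION, 8281, "N" * 9, ""),
        ],
    )
    def test_dialects(self, ref, label, kind, position, ref_allele, alt):
        v = parse_variant_label(label, ref)
        assert (v.kind, v.position, v.ref, v.alt) == (kind, position, ref_allele, alt)

    def test_back_mutation_assertion(self, ref):
        v = parse_variant_label("4769!", ref)
        assert v.back_mutation and v.alt == "A" and v.position == 4769

    @pytest.mark.parametrize(
        "label",
        ["", "m.0A>G", "m.1806T>T", "xyz", "m.99999A>G", "1806-1805d", "4769A"],
    )
    def test_malformed_labels_rejected(self, ref, label):
        with pytest.raises(VariantParseError):
            parse_variant_label(label, ref)

    def test_round_trip_is_canonical(self, ref):
        for label in ["m.1806T>C", "3909T", "4769!", "m.16295C insA", "8281-8289d"]:
            v = parse_variant_label(label, ref)
            canonical = format_variant(v)
            assert parse_variant_label(canonical, ref) == v
            assert format_variant(parse_variant_label(canonical, ref)) == canonical


class TestLocateFeature:
    @pytest.mark.parametrize(
        "position, name",
        [(9255, "COIII"), (1185, "12SrRNA"), (16295, "HVRI"), (3909, "ND1"),
         (15014, "CYTB"), (73, "HVRII"), (16569, "control")],
    )
    def test_known_positions(self, ref, position, name):
        assert locate_feature(ref, position).name == name

    def test_intergenic(self, ref):
        assert locate_feature(ref, 8281) is None  # COII/ATP8 spacer

    def test_overlapping_genes_report_both_with_primary_first(self, ref):
        hits = locate_all_features(ref, 8550)  # ATP8/ATP6 overlap
        assert [g.name for g in hits] == ["ATP6", "ATP8"]
        hits = lambda p: [g.name for g in locate_all_features(ref, p)]
        assert hits(10763) == ["ND4", "ND4L"]

    def test_out_of_range(self, ref):
        with pytest.raises(PositionRangeError):
            locate_feature(ref, 0)
        with pytest.raises(PositionRangeError):
            locate_feature(ref, 16570)


class TestCodonPosition:
    @pytest.mark.parametrize(
        "gene, position, expected",
        [("COIII", 9255, (17, 0)), ("CYTB", 15014, (90, 0)), ("ND1", 3909, (201, 2)),
         ("ND1", 3307, (1, 0))],
    )
    def test_examples(self, ref, gene, position, expected):
        assert codon_position(ref, ref.gene(gene), position) == expected

    def test_panel_protein_positions(self, ref):
        """All twelve published codon indices come out of the bundled gene starts."""
        for nt_pos, (gene, prot_pos) in PANEL_PROTEIN_POSITIONS.items():
            got, _ = codon_position(ref, ref.gene(gene), nt_pos)
            assert got == prot_pos, f"{gene} {nt_pos}: {got} != {prot_pos}"

    def test_outside_gene_rejected(self, ref):
        with pytest.raises(PositionRangeError):
            codon_position(ref, ref.gene("COIII"), 100)

    @given(st.integers(min_value=9207, max_value=9990))
    def test_bijection_on_heavy_strand(self, position):
        ref = rcrs()
        gene = ref.gene("COIII")
        prot, off = codon_position(ref, gene, position)
        assert position_from_codon(ref, gene, prot, off) == position

    def test_light_strand_counts_from_gene_end(self, ref):
        gene = ref.gene("ND6")
        assert codon_position(ref, gene, gene.end) == (1, 0)
        assert codon_position(ref, gene, gene.end - 3) == (2, 0)
        assert position_from_codon(ref, gene, 2, 1) == gene.end - 4


class TestAnnotateEffect:
    def test_requires_sequence(self, ref):
        with pytest.raises(MissingSequenceError):
            annotate_effect(ref, Variant(9255, SUBSTITUTION, "C", "T"))

    def test_direct_codon_change(self):
        # gene 4..12 codes CCT-TTT-AAA; C>T at offset 0 of codon 1: Pro->Ser
        seq = "AAACCTTTTAAAGGG"
        mref = MitoReference(
            id="toy", length=15, sequence=seq,
            genes=(GeneFeature("g1", 4, 12, "heavy", "protein"),),
        )
        eff = annotate_effect(mref, Variant(4, SUBSTITUTION, "C", "T"))
        assert eff.effect == "nonsynonymous"
        assert eff.aa_change == "Pro1Ser"
        # third-position wobble: CCT->CCC still proline
        eff = annotate_effect(mref, Variant(6, SUBSTITUTION, "T", "C"))
        assert eff.effect == "synonymous" and eff.aa_change is None

    def test_non_coding_positions_not_applicable(self, synth_ref):
        rrna = synth_ref.gene("rrna-1")
        v = Variant(rrna.start, SUBSTITUTION, synth_ref.sequence[rrna.start - 1], "A")
        if v.ref == "A":
            v = Variant(rrna.start, SUBSTITUTION, v.ref, "G")
        assert annotate_effect(synth_ref, v).effect == "not_applicable"

    def test_indels_flagged_with_length_change(self, synth_ref):
        eff = annotate_effect(synth_ref, Variant(5, DELETION, "NNN", ""))
        assert eff.effect == "not_applicable" and "length change -3" in eff.note

    def test_random_substitutions_match_whole_gene_translation(self, synth_ref, rng):
        """Effects agree with a brute-force before/after gene translation."""
        gene = synth_ref.gene("orf-1")
        gene_seq = synth_ref.sequence[gene.start - 1 : gene.end]
        for _ in range(50):
            pos = int(rng.integers(gene.start, gene.end + 1))
            current = synth_ref.sequence[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != current])
            eff = annotate_effect(synth_ref, Variant(pos, SUBSTITUTION, current, str(alt)))
            mutated = (
                gene_seq[: pos - gene.start] + str(alt) + gene_seq[pos - gene.start + 1 :]
            )
            aa_before = str(Seq(gene_seq).translate(table=2))
            aa_after = str(Seq(mutated).translate(table=2))
            expected = "synonymous" if aa_before == aa_after else "nonsynonymous"
            assert eff.effect == expected

    def test_light_strand_effect_uses_reverse_complement_frame(self):
        # light-strand gene over 4..12; coding sequence = revcomp(seq[3:12])
        seq = "AAACCTTTTAAAGGG"
        mref = MitoReference(
            id="toy", length=15, sequence=seq,
            genes=(GeneFeature("lg", 4, 12, "light", "protein"),),
        )
        for pos in range(4, 13):
            current = seq[pos - 1]
            alt = "A" if current != "A" else "G"
            eff = annotate_effect(mref, Variant(pos, SUBSTITUTION, current, alt))
            before = str(Seq(seq[3:12]).reverse_complement().translate(table=2))
            mut = seq[: pos - 1] + alt + seq[pos:]
            after = str(Seq(mut[3:12]).reverse_complement().translate(table=2))
            expected = "synonymous" if before == after else "nonsynonymous"
            assert eff.effect == expected, pos


class TestApplyProfile:
    def test_empty_profile_is_identity(self, synth_ref):
        assert apply_profile(synth_ref, []) == synth_ref.sequence

    def test_single_substitution_changes_one_site(self, synth_ref):
        pos = 100
        current = synth_ref.sequence[pos - 1]
        alt = "A" if current != "A" else "C"
        out = apply_profile(synth_ref, [Variant(pos, SUBSTITUTION, current, alt)])
        diffs = [i for i, (a, b) in enumerate(zip(out, synth_ref.sequence)) if a != b]
        assert diffs == [pos - 1] and out[pos - 1] == alt

    def test_nine_bp_deletion_shortens_genome(self):
        from mtpop.simulate import random_reference

        big = random_reference(length=16569, seed=7)
        deleted = big.sequence[8280:8289]
        out = apply_profile(big, [Variant(8281, DELETION, deleted, "")])
        assert len(out) == big.length - 9

    def test_colliding_variants_rejected(self, synth_ref):
        a = Variant(50, SUBSTITUTION, synth_ref.sequence[49], "A" if synth_ref.sequence[49] != "A" else "C")
        b = Variant(48, DELETION, synth_ref.sequence[47:52], "")
        with pytest.raises(ProfileConflictError):
            apply_profile(synth_ref, [a, b])


def test_gene_map_spans_are_codon_clean(ref):
    for g in ref.genes:
        if g.kind == "protein" and not g.incomplete_stop:
            assert g.span(ref.length) % 3 == 0


def test_gene_table_override_round_trip(tmp_path, ref):
    path = tmp_path / "genes.tsv"
    path.write_text(
        "name\tstart\tend\tstrand\tkind\n"
        "COIII\t9207\t9990\theavy\tprotein\n"
        "HVRI\t16024\t16383\theavy\tcontrol\n"
    )
    from mtpop.reference import load_gene_table

    genes = load_gene_table(path)
    assert [g.name for g in genes] == ["COIII", "HVRI"]
    assert genes[0].incomplete_stop  # 784 bp span is not codon-clean

    zb = tmp_path / "genes0.tsv"
    zb.write_text("COIII\t9206\t9990\theavy\tprotein\n")
    assert load_gene_table(zb, zero_based=True)[0].start == 9207
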