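"""Codon projection, consequence calling and HGVSp labelling."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_random_transcript, make_snp
from oracle_utils import cds_positions, oracle_snp_consequence, revcomp

from equivar.consequence import (
    ReferenceMismatchError,
    annotate_variant,
    call_consequence,
    project_to_cds,
    splice_region_flag,
)
from equivar.io_formats import TranscriptModel, VariantRecord
from equivar.synthetic_data import (
    FixtureSpec,
    TranscriptLayout,
    VariantSpec,
    design_reference,
)


def simple_transcript(strand="+", exons=((11, 22), (40, 51)), chrom="ctg"):
    return TranscriptModel(
        transcript_id="tx1", gene_symbol="G", chrom=chrom, strand=strand,
        cds_exons=exons,
    )


class TestProjectToCds:
    def test_first_base_plus_strand(self):
        tx = simple_transcript("+")
        v = VariantRecord(chrom="ctg", pos=11, ref_allele="A", alt_allele="G")
        assert project_to_cds(v, tx) == 0

    def test_last_base_of_leftmost_interval_minus_strand(self):
        tx = simple_transcript("-")
        # leftmost interval's lowest position is the final CDS base in
        # translation order on the minus strand
        v = VariantRecord(chrom="ctg", pos=11, ref_allele="A", alt_allele="G")
        assert project_to_cds(v, tx) == tx.cds_length - 1

    def test_intronic_position_is_none(self):
        tx = simple_transcript("+")
        v = VariantRecord(chrom="ctg", pos=30, ref_allele="A", alt_allele="G")
        assert project_to_cds(v, tx) is None

    def test_agrees_with_position_list_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            tx, seq = make_random_transcript(rng)
            positions = cds_positions(tx)
            for offset in (0, len(positions) // 2, len(positions) - 1):
                pos = positions[offset]
                v = make_snp(rng, seq, pos)
                assert project_to_cds(v, tx) == offset


class TestCallConsequence:
    def test_engineered_missense_with_hgvsp(self):
        """A designed A→V swap at codon 96 comes back labelled A96V."""
        spec = FixtureSpec(
            variants=(
                VariantSpec(gene="FAAH", ref="G", alt="A", ref_aa="A",
                            alt_aa="V", aa_position=96,
                            layout=TranscriptLayout(strand="-")),
            ),
            seed=3,
        )
        bundle = design_reference(spec)
        genome = _genome_from_fasta(bundle.fasta)
        (placement,) = bundle.placements
        v = VariantRecord(chrom=placement.chrom, pos=placement.pos,
                          ref_allele=placement.ref, alt_allele=placement.alt)
        (tx,) = bundle.transcripts
        result = call_consequence(v, tx, genome)
        assert result.classification == "non_synonymous_coding"
        assert result.hgvsp == "A96V"

    def test_synonymous_wobble(self):
        # GGA -> GGG at the third codon position is silent
        seq = "TT" + "GGA" + "TTTT"
        tx = TranscriptModel(transcript_id="t", gene_symbol="g", chrom="c",
                             strand="+", cds_exons=((3, 5),))
        v = VariantRecord(chrom="c", pos=5, ref_allele="A", alt_allele="G")
        result = call_consequence(v, tx, {"c": seq})
        assert result.classification == "synonymous_coding"
        assert result.ref_aa == result.alt_aa == "G"

    def test_reference_mismatch_names_position(self):
        seq = "TTGGATTTT"
        tx = TranscriptModel(transcript_id="t", gene_symbol="g", chrom="c",
                             strand="+", cds_exons=((3, 5),))
        v = VariantRecord(chrom="c", pos=5, ref_allele="C", alt_allele="G")
        with pytest.raises(ReferenceMismatchError, match="c:5"):
            call_consequence(v, tx, {"c": seq})

    def test_insertion_peptide_translated(self):
        # codon-multiple insertion right after the anchor position
        seq = "TT" + "ATGGGATTT" + "TT"
        tx = TranscriptModel(transcript_id="t", gene_symbol="g", chrom="c",
                             strand="+", cds_exons=((3, 11),))
        v = VariantRecord(chrom="c", pos=6, ref_allele="G",
                          alt_allele="GGCTGCT")
        result = call_consequence(v, tx, {"c": seq})
        assert result.classification == "codon_insertion"
        assert result.alt_aa == "AA"
        assert result.hgvsp.startswith("G2")

    def test_frame_breaking_insertion_has_no_peptide(self):
        seq = "TT" + "ATGGGATTT" + "TT"
        tx = TranscriptModel(transcript_id="t", gene_symbol="g", chrom="c",
                             strand="+", cds_exons=((3, 11),))
        v = VariantRecord(chrom="c", pos=6, ref_allele="G", alt_allele="GGC")
        result = call_consequence(v, tx, {"c": seq})
        assert result.classification == "codon_insertion"
        assert result.alt_aa is None


@pytest.mark.filterwarnings("ignore:internal stop codon")
class TestOracleEquivalence:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_fixtures_match_brute_force(self, strand):
        """On random multi-exon fixtures of both strands, fast codon
        arithmetic agrees with mutate-splice-translate on every field."""
        rng = np.random.default_rng(11 if strand == "+" else 13)
        checked = 0
        while checked < 120:
            tx, seq = make_random_transcript(rng)
            if tx.strand != strand:
                continue
            positions = cds_positions(tx)
            for _ in range(4):
                pos = int(rng.choice(positions))
                v = make_snp(rng, seq, pos)
                got = call_consequence(v, tx, {"ctg": seq})
                want = oracle_snp_consequence(v, tx, seq)
                assert (got.classification, got.aa_position,
                        got.ref_aa, got.alt_aa) == want
                checked += 1

    def test_mutated_protein_differs_only_at_reported_position(self):
        from oracle_utils import splice_translate

        rng = np.random.default_rng(17)
        for _ in range(40):
            tx, seq = make_random_transcript(rng)
            positions = cds_positions(tx)
            pos = int(rng.choice(positions))
            v = make_snp(rng, seq, pos)
            got = call_consequence(v, tx, {"ctg": seq})
            mutated = seq[: pos - 1] + v.alt_allele + seq[pos:]
            p_ref = splice_translate(seq, tx)
            p_alt = splice_translate(mutated, tx)
            diffs = [i + 1 for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b]
            if got.classification == "synonymous_coding":
                assert diffs == []
            else:
                assert diffs == [got.aa_position]


@pytest.mark.filterwarnings("ignore:internal stop codon")
class TestStrandSymmetry:
    def test_mirrored_genome_gives_identical_consequences(self):
        """Reverse-complementing the contig, flipping the strand and
        mirroring all coordinates leaves every call invariant."""
        rng = np.random.default_rng(23)
        for _ in range(40):
            tx, seq = make_random_transcript(rng)
            positions = cds_positions(tx)
            pos = int(rng.choice(positions))
            v = make_snp(rng, seq, pos)
            got = call_consequence(v, tx, {"ctg": seq})

            length = len(seq)
            mirrored_seq = revcomp(seq)
            mirrored_exons = tuple(
                sorted((length - e + 1, length - s + 1) for s, e in tx.cds_exons)
            )
            mirrored_tx = TranscriptModel(
                transcript_id=tx.transcript_id, gene_symbol=tx.gene_symbol,
                chrom="ctg", strand="-" if tx.strand == "+" else "+",
                cds_exons=mirrored_exons,
            )
            comp = dict(zip("ACGT", "TGCA"))
            mirrored_v = VariantRecord(
                chrom="ctg", pos=length - pos + 1,
                ref_allele=comp[v.ref_allele], alt_allele=comp[v.alt_allele],
            )
            mirrored = call_consequence(mirrored_v, mirrored_tx,
                                        {"ctg": mirrored_seq})
            assert (got.classification, got.aa_position, got.ref_aa,
                    got.alt_aa, got.hgvsp) == (
                mirrored.classification, mirrored.aa_position,
                mirrored.ref_aa, mirrored.alt_aa, mirrored.hgvsp)


class TestSpliceRegion:
    def test_near_internal_junction(self):
        tx = simple_transcript("+", exons=((11, 40), (60, 101)))
        near_end = VariantRecord(chrom="ctg", pos=39, ref_allele="A",
                                 alt_allele="G")
        mid = VariantRecord(chrom="ctg", pos=25, ref_allele="A", alt_allele="G")
        assert splice_region_flag(near_end, tx)
        assert not splice_region_flag(mid, tx)

    def test_outer_edges_do_not_count(self):
        tx = simple_transcript("+", exons=((11, 40), (60, 101)))
        first_base = VariantRecord(chrom="ctg", pos=11, ref_allele="A",
                                   alt_allele="G")
        last_base = VariantRecord(chrom="ctg", pos=101, ref_allele="A",
                                  alt_allele="G")
        assert not splice_region_flag(first_base, tx)
        assert not splice_region_flag(last_base, tx)

    def test_window_configurable(self):
        tx = simple_transcript("+", exons=((11, 40), (60, 101)))
        v = VariantRecord(chrom="ctg", pos=36, ref_allele="A", alt_allele="G")
        assert not splice_region_flag(v, tx, window=3)
        assert splice_region_flag(v, tx, window=5)

    def test_designed_splice_variant_is_flagged(self):
        """A missense swap placed 2 exonic bases from a junction carries the
        splice-region tag on top of its coding classification."""
        spec = FixtureSpec(
            variants=(
                VariantSpec(gene="GABRA6", ref="T", alt="C", ref_aa="H",
                            alt_aa="R", aa_position=363,
                            layout=TranscriptLayout(
                                strand="-", splice_break_near_variant=True)),
            ),
            seed=5,
        )
        bundle = design_reference(spec)
        genome = _genome_from_fasta(bundle.fasta)
        (placement,) = bundle.placements
        v = VariantRecord(chrom=placement.chrom, pos=placement.pos,
                          ref_allele=placement.ref, alt_allele=placement.alt)
        results = annotate_variant(v, bundle.transcripts, genome)
        (result,) = results
        assert result.hgvsp == "H363R"
        assert result.classification == "non_synonymous_coding"
        assert result.splice_region


class TestAnnotateVariant:
    def test_two_splice_forms_offset_by_39_codons(self):
        spec = FixtureSpec(
            variants=(
                VariantSpec(gene="CDH13", ref="C", alt="T", ref_aa="R",
                            alt_aa="W", aa_position=173,
                            layout=TranscriptLayout(
                                strand="+", second_codon_shift=-39)),
            ),
            seed=9,
        )
        bundle = design_reference(spec)
        genome = _genome_from_fasta(bundle.fasta)
        (placement,) = bundle.placements
        v = VariantRecord(chrom=placement.chrom, pos=placement.pos,
                          ref_allele=placement.ref, alt_allele=placement.alt)
        results = annotate_variant(v, bundle.transcripts, genome)
        assert [r.hgvsp for r in results] == ["R173W", "R134W"]
        assert results[0].aa_position - results[1].aa_position == 39

    def test_no_overlap_gives_empty_list(self):
        tx = simple_transcript("+")
        v = VariantRecord(chrom="other", pos=11, ref_allele="A", alt_allele="G")
        assert annotate_variant(v, [tx], {"ctg": "A" * 200}) == []


def _genome_from_fasta(fasta_text: str) -> dict[str, str]:
    genome: dict[str, str] = {}
    name = None
    for line in fasta_text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            genome[name] = ""
        elif name:
            genome[name] += line.strip()
    return genome
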