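"""Brute-force oracles used by the tests.

Deliberately independent of the library's coordinate arithmetic: the
consequence oracle mutates the whole chromosome string, splices exons by
slicing, translates both proteins in full and diffs them; CDS offsets are
found by materialising the list of genomic positions in translation order
and searching it.
"""

from __future__ import annotations

from Bio.Seq import Seq

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def cds_positions(transcript) -> list[int]:
    """Genomic positions (1-based) of every CDS base, in translation order."""
    positions: list[int] = []
    for start, end in transcript.cds_exons:
        positions.extend(range(start, end + 1))
    if transcript.strand == "-":
        positions.reverse()
    return positions


def splice_translate(genome_seq: str, transcript) -> str:
    parts = "".join(
        genome_seq[start - 1 : end] for start, end in transcript.cds_exons
    )
    if transcript.strand == "-":
        parts = revcomp(parts)
    return str(Seq(parts).translate(table=1))


def oracle_snp_consequence(variant, transcript, genome_seq: str):
    """(classification, aa_position, ref_aa, alt_aa) by mutate-splice-translate."""
    positions = cds_positions(transcript)
    if variant.pos not in positions:
        return ("non_coding", None, None, None)
    offset = positions.index(variant.pos)
    codon_index = offset // 3
    mutated = (
        genome_seq[: variant.pos - 1]
        + variant.alt_allele
        + genome_seq[variant.pos :]
    )
    protein_ref = splice_translate(genome_seq, transcript)
    protein_alt = splice_translate(mutated, transcript)
    ref_aa = protein_ref[codon_index]
    alt_aa = protein_alt[codon_index]
    diffs = [
        i for i, (a, b) in enumerate(zip(protein_ref, protein_alt)) if a != b
    ]
    if not diffs:
        return ("synonymous_coding", codon_index + 1, ref_aa, alt_aa)
    assert diffs == [codon_index], "SNP must change exactly its own codon"
    return ("non_synonymous_coding", codon_index + 1, ref_aa, alt_aa)
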