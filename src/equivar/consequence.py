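"""Codon-level consequence calling and HGVS protein nomenclature.

Variants are projected onto the spliced coding sequence of each overlapping
transcript, the affected codon is re-translated under the standard genetic
code, and the effect is classified as synonymous, non-synonymous (missense),
codon insertion, or non-coding.  Substitutions are labelled in the compact
one-letter HGVSp style (``A96V`` = Ala at codon 96 → Val).

Exonic variants close to an exon–intron boundary additionally carry a
splice-region flag; annotators disagree on the exact window, so it is
configurable (default: the 3 exonic bases adjacent to an intron).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

from Bio.Seq import Seq

from .io_formats import TranscriptModel, VariantRecord, normalize_chrom

__all__ = [
    "Classification",
    "CodingConsequence",
    "ReferenceMismatchError",
    "annotate_variant",
    "call_consequence",
    "project_to_cds",
    "spliced_cds",
    "splice_region_flag",
    "SPLICE_REGION_WINDOW",
]

Classification = Literal[
    "synonymous_coding", "non_synonymous_coding", "codon_insertion", "non_coding"
]

#: exonic bases adjacent to an intron that count as splice region
SPLICE_REGION_WINDOW = 3

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ReferenceMismatchError(ValueError):
    """VCF REF allele disagrees with the reference genome sequence."""


@dataclass(frozen=True)
class CodingConsequence:
    """Effect of one variant on one transcript.

    ``aa_position`` is the 1-based codon index in the protein (``None`` for
    non-coding calls); for insertions ``alt_aa`` holds the inserted peptide
    (``None`` when its length is not a multiple of 3).
    """

    transcript_id: str
    classification: Classification
    aa_position: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    hgvsp: str = ""
    splice_region: bool = False
    stop_involved: bool = False


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def project_to_cds(variant: VariantRecord, transcript: TranscriptModel) -> int | None:
    """0-based offset of the variant position in the spliced CDS, or ``None``.

    The offset counts in translation order: on the minus strand exon
    intervals are walked right-to-left and positions within an exon
    high-to-low.
    """
    if normalize_chrom(variant.chrom) != normalize_chrom(transcript.chrom):
        return None
    pos = variant.pos
    offset = 0
    if transcript.strand == "+":
        for start, end in transcript.cds_exons:
            if start <= pos <= end:
                return offset + (pos - start)
            offset += end - start + 1
    else:
        for start, end in reversed(transcript.cds_exons):
            if start <= pos <= end:
                return offset + (end - pos)
            offset += end - start + 1
    return None


def _cds_offset_to_genomic(transcript: TranscriptModel, offset: int) -> int:
    """Inverse of :func:`project_to_cds` (1-based genomic position)."""
    remaining = offset
    exons = transcript.cds_exons if transcript.strand == "+" else tuple(
        reversed(transcript.cds_exons)
    )
    for start, end in exons:
        length = end - start + 1
        if remaining < length:
            return start + remaining if transcript.strand == "+" else end - remaining
        remaining -= length
    raise IndexError(f"CDS offset {offset} beyond CDS of {transcript.transcript_id}")


def spliced_cds(transcript: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Transcript-strand spliced CDS sequence."""
    seq = _chrom_seq(genome, transcript.chrom)
    parts = [seq[start - 1 : end] for start, end in transcript.cds_exons]
    joined = "".join(parts)
    return joined if transcript.strand == "+" else _revcomp(joined)


def _chrom_seq(genome: Mapping[str, str], chrom: str) -> str:
    want = normalize_chrom(chrom)
    for name, seq in genome.items():
        if normalize_chrom(name) == want:
            return seq
    raise KeyError(f"chromosome {chrom!r} not present in the reference")


def _translate(codons: str) -> str:
    return str(Seq(codons).translate(table=1))


def splice_region_flag(variant: VariantRecord, transcript: TranscriptModel,
                       window: int = SPLICE_REGION_WINDOW) -> bool:
    """True iff the variant sits within *window* exonic bases of an intron.

    Only boundaries that abut an intron count: the outer edges of the first
    and last CDS exon never trigger the flag.
    """
    pos = variant.pos
    exons = transcript.cds_exons
    for i, (start, end) in enumerate(exons):
        if start <= pos <= end:
            if i > 0 and pos - start < window:
                return True
            if i < len(exons) - 1 and end - pos < window:
                return True
            return False
    return False


def call_consequence(variant: VariantRecord, transcript: TranscriptModel,
                     genome: Mapping[str, str],
                     splice_window: int = SPLICE_REGION_WINDOW) -> CodingConsequence:
    """Classify one variant against one transcript.

    The reference genome base(s) at the variant position must equal the
    VCF REF allele (compared on the plus strand, as both are stored);
    a mismatch raises :class:`ReferenceMismatchError` rather than silently
    re-referencing the record.
    """
    seq = _chrom_seq(genome, variant.chrom)
    genome_ref = seq[variant.pos - 1 : variant.pos - 1 + len(variant.ref_allele)]
    if genome_ref != variant.ref_allele:
        raise ReferenceMismatchError(
            f"VCF REF {variant.ref_allele!r} does not match reference "
            f"{genome_ref!r} at {variant.chrom}:{variant.pos}"
        )

    offset = project_to_cds(variant, transcript)
    if offset is None:
        return CodingConsequence(
            transcript_id=transcript.transcript_id, classification="non_coding"
        )

    cds = spliced_cds(transcript, genome)
    protein = _translate(cds)
    if "*" in protein[:-1]:
        warnings.warn(
            f"internal stop codon in reference CDS of {transcript.transcript_id}",
            stacklevel=2,
        )

    splice = splice_region_flag(variant, transcript, splice_window)
    minus = transcript.strand == "-"
    codon_index = offset // 3
    aa_position = codon_index + 1

    if variant.is_insertion:
        inserted = variant.alt_allele[len(variant.ref_allele):]
        anchor = protein[codon_index] if codon_index < len(protein) else "?"
        peptide: str | None = None
        if len(inserted) % 3 == 0:
            peptide = _translate(_revcomp(inserted) if minus else inserted)
        hgvsp = f"{anchor}{aa_position}{peptide if peptide is not None else '?'}"
        return CodingConsequence(
            transcript_id=transcript.transcript_id,
            classification="codon_insertion",
            aa_position=aa_position,
            ref_aa=anchor,
            alt_aa=peptide,
            hgvsp=hgvsp,
            splice_region=splice,
        )

    within = offset % 3
    ref_codon = cds[codon_index * 3 : codon_index * 3 + 3]
    alt_base = _revcomp(variant.alt_allele) if minus else variant.alt_allele
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = _translate(ref_codon)
    alt_aa = _translate(alt_codon)
    classification: Classification = (
        "synonymous_coding" if ref_aa == alt_aa else "non_synonymous_coding"
    )
    return CodingConsequence(
        transcript_id=transcript.transcript_id,
        classification=classification,
        aa_position=aa_position,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        hgvsp=f"{ref_aa}{aa_position}{alt_aa}",
        splice_region=splice,
        stop_involved="*" in (ref_aa + alt_aa),
    )


def annotate_variant(variant: VariantRecord, transcripts: Sequence[TranscriptModel],
                     genome: Mapping[str, str],
                     splice_window: int = SPLICE_REGION_WINDOW) -> list[CodingConsequence]:
    """One consequence per overlapping transcript, ordered by transcript id.

    A transcript overlaps when the variant position falls within its CDS
    genomic span (intronic positions inside the span yield ``non_coding``
    consequences; transcripts elsewhere contribute nothing).
    """
    out: list[CodingConsequence] = []
    for transcript in sorted(transcripts, key=lambda t: t.transcript_id):
        if normalize_chrom(transcript.chrom) != normalize_chrom(variant.chrom):
            continue
        lo, hi = transcript.span
        if not (lo <= variant.pos <= hi):
            continue
        out.append(call_consequence(variant, transcript, genome, splice_window))
    return out
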