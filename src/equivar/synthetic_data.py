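"""Generators for every input the pipeline needs, without downloads.

Two kinds of fixtures live here:

* the **packaged in-study tables** — 55 curated variants with alleles and
  cohort frequencies, their protein-level consequences, and an 18-gene
  trait/function map — loadable as DataFrames via :func:`paper_fixture`;
* **inverse-designed genomic fixtures** — given a wish-list of amino-acid
  substitutions, :func:`design_reference` emits a small synthetic reference
  FASTA and GFF3 transcript models such that running the consequence module
  on them reproduces each desired HGVSp label, and :func:`generate_cohort`
  emits a diploid VCF whose recomputed allele frequencies hit exact targets
  (``count`` alternate alleles over ``2 × n_individuals`` chromosomes).

The emulated cohort is 101 diploid individuals, matching the population the
packaged frequencies were measured in.  Real genomic coordinates are kept as
metadata only; fixture positions live on small per-variant synthetic
contigs, so no genome download is ever needed.  Codon choice during inverse
design is the lexicographically smallest feasible ``(ref_codon, alt_codon)``
pair, reproducible without a seed; everything stochastic (intron/flank fill,
allele placement) is driven by the spec's seed.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._rounding import round_half_up
from .candidates import AnnotatedVariant, parse_hgvsp
from .consequence import CodingConsequence, _cds_offset_to_genomic
from .frequency import UNAVAILABLE, AlleleFrequencyRecord, from_precomputed
from .io_formats import GeneTraitMap, TranscriptModel, read_trait_map

__all__ = [
    "FixtureSpec",
    "FixtureTables",
    "InfeasibleSubstitutionError",
    "PlacedVariant",
    "ReferenceBundle",
    "TranscriptLayout",
    "VariantSpec",
    "design_reference",
    "find_codon_pair",
    "fixture_annotated_variants",
    "generate_cohort",
    "paper_fixture",
    "table2_cohort_spec",
    "table3_reference_spec",
    "write_fixture_dir",
    "INSERTION_SEQUENCE",
    "INSERTION_SEQUENCE_RAW",
    "COHORT_SIZE",
]

#: diploid cohort size the packaged frequencies were measured in
COHORT_SIZE = 101

#: the curated chrX insertion allele; the raw form keeps the line-break
#: hyphen found in the source table, the clean form strips it
INSERTION_SEQUENCE_RAW = (
    "CATCTTTCCCGTTCTTGGGCTCCTCCCAAGTGTCGGTACTAGGGTCCGCCCCGCCATCAGTGCCAACTCCCC-"
    "CTGGAGTTCGGTACAAGG"
)
INSERTION_SEQUENCE = INSERTION_SEQUENCE_RAW.replace("-", "")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = np.array(list("ACGT"))

#: codon → amino acid under the standard genetic code
_CODON_TABLE: dict[str, str] = {
    a + b + c: str(Seq(a + b + c).translate(table=1))
    for a in "TCAG" for b in "TCAG" for c in "TCAG"
}
_CODONS_OF: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.items():
    _CODONS_OF.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_OF:
    _CODONS_OF[_aa].sort()

#: neutral filler codon for positions the spec does not constrain (Gly)
_FILL_CODON = "GGC"


class InfeasibleSubstitutionError(ValueError):
    """No single-nucleotide codon path realizes the requested substitutions."""

    def __init__(self, entries: list[str]):
        self.entries = entries
        super().__init__(
            "infeasible substitution spec entries:\n  " + "\n  ".join(entries)
        )


FixtureTables = namedtuple("FixtureTables", ["variants", "impacts", "trait_map"])


def _data_frame(name: str) -> pd.DataFrame:
    ref = resources.files("equivar.data") / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def paper_fixture() -> FixtureTables:
    """The packaged in-study tables: variant frequencies, protein
    consequences, and the gene trait/function map."""
    variants = _data_frame("variant_frequencies.tsv")
    impacts = _data_frame("protein_consequences.tsv")
    ref = resources.files("equivar.data") / "gene_annotations.tsv"
    with resources.as_file(ref) as path:
        trait_map = read_trait_map(path)
    return FixtureTables(variants=variants, impacts=impacts, trait_map=trait_map)


def fixture_annotated_variants() -> tuple[
    list[AnnotatedVariant], dict, GeneTraitMap
]:
    """Packaged tables as pipeline-shaped inputs.

    Returns annotated variants (one per curated variant, with one
    consequence per recorded transcript label), a frequency mapping keyed by
    ``(chrom, pos, alt)``, and the trait map.  Impact columns of the
    packaged table are *not* propagated: scores are always recomputed.
    """
    tables = paper_fixture()
    merged = tables.variants.merge(
        tables.impacts, on=["gene", "chrom", "pos"], validate="one_to_one"
    )
    annotated: list[AnnotatedVariant] = []
    freqs: dict = {}
    for row in merged.itertuples(index=False):
        labels = str(row.hgvsp).split(";")
        is_insertion = row.annotation == "codon insertion"
        splice = "splice site region" in row.annotation
        consequences = []
        for i, label in enumerate(labels):
            if is_insertion:
                anchor, aa_pos, peptide = parse_hgvsp(label)
                consequences.append(
                    CodingConsequence(
                        transcript_id=f"{row.gene}_{row.pos}_t{i + 1}",
                        classification="codon_insertion",
                        aa_position=aa_pos,
                        ref_aa=anchor,
                        alt_aa=peptide,
                        hgvsp=label,
                        splice_region=splice,
                    )
                )
            else:
                ref_aa, aa_pos, alt_aa = parse_hgvsp(label)
                consequences.append(
                    CodingConsequence(
                        transcript_id=f"{row.gene}_{row.pos}_t{i + 1}",
                        classification="non_synonymous_coding",
                        aa_position=aa_pos,
                        ref_aa=ref_aa,
                        alt_aa=alt_aa,
                        hgvsp=label,
                        splice_region=splice,
                    )
                )
        av = AnnotatedVariant(
            gene_symbol=str(row.gene),
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref_allele=str(row.ref_allele),
            alt_allele=str(row.alt_allele),
            consequences=tuple(consequences),
        )
        annotated.append(av)
        if pd.isna(row.ref_freq) or pd.isna(row.alt_freq):
            freqs[av.key] = UNAVAILABLE
        else:
            freqs[av.key] = from_precomputed(
                float(row.ref_freq), float(row.alt_freq),
                n_alleles=2 * COHORT_SIZE,
            )
    return annotated, freqs, tables.trait_map


# --------------------------------------------------------------------------
# inverse design
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptLayout:
    """Shape of the synthetic transcript(s) carrying one designed variant.

    ``cds_breaks`` are CDS offsets (0 < offset < CDS length) where introns
    are inserted; ``second_codon_shift`` adds a second splice form whose
    codon numbering differs by that many codons (positive: its CDS extends
    upstream; negative: it starts downstream); ``splice_break_near_variant``
    places an exon junction 2 exonic bases past the variant so the call
    carries the splice-region tag.
    """

    strand: str = "+"
    n_codons: int | None = None
    cds_breaks: tuple[int, ...] = ()
    intron_length: int = 40
    second_codon_shift: int | None = None
    splice_break_near_variant: bool = False


@dataclass(frozen=True)
class VariantSpec:
    """One wished-for variant: alleles, cohort count, optional missense goal."""

    gene: str
    ref: str
    alt: str
    target_alt_allele_count: int = 0
    chrom: str | None = None
    pos: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    aa_position: int | None = None
    layout: TranscriptLayout | None = None
    source_chrom: str | None = None
    source_pos: int | None = None


@dataclass(frozen=True)
class FixtureSpec:
    variants: tuple[VariantSpec, ...]
    n_individuals: int = COHORT_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        limit = 2 * self.n_individuals
        for v in self.variants:
            if not (0 <= v.target_alt_allele_count <= limit):
                raise ValueError(
                    f"target alt-allele count {v.target_alt_allele_count} for "
                    f"{v.gene} outside [0, {limit}]"
                )


@dataclass(frozen=True)
class PlacedVariant:
    """A designed variant landed on its synthetic contig."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    target_alt_allele_count: int
    contig_length: int
    expected_hgvsp: tuple[str, ...]
    source_chrom: str | None = None
    source_pos: int | None = None


@dataclass(frozen=True)
class ReferenceBundle:
    fasta: str
    gff3: str
    placements: tuple[PlacedVariant, ...]
    transcripts: tuple[TranscriptModel, ...]


def _comp(base: str) -> str:
    return base.translate(_COMPLEMENT)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def find_codon_pair(ref_aa: str, alt_aa: str, ref_base: str, alt_base: str
                    ) -> tuple[str, str, int] | None:
    """Smallest codon pair realizing ref_aa→alt_aa by one base change.

    The changed base must read *ref_base*→*alt_base* on the transcript
    strand.  Returns ``(ref_codon, alt_codon, position_in_codon)`` or
    ``None`` when no single-nucleotide path exists.
    """
    for ref_codon in _CODONS_OF.get(ref_aa, ()):
        for alt_codon in _CODONS_OF.get(alt_aa, ()):
            diffs = [i for i in range(3) if ref_codon[i] != alt_codon[i]]
            if len(diffs) != 1:
                continue
            i = diffs[0]
            if ref_codon[i] == ref_base and alt_codon[i] == alt_base:
                return ref_codon, alt_codon, i
    return None


def _segment_lengths(total: int, breaks: Sequence[int]) -> list[int]:
    edges = [0, *sorted(set(breaks)), total]
    return [edges[i + 1] - edges[i] for i in range(len(edges) - 1)]


def _design_one(
    spec_variant: VariantSpec, contig: str, rng: np.random.Generator
) -> tuple[str, list[str], PlacedVariant, list[TranscriptModel]]:
    """Design one contig; returns (sequence, gff3 lines, placement, models)."""
    v = spec_variant
    layout = v.layout or TranscriptLayout()
    if v.ref_aa == v.alt_aa:
        raise InfeasibleSubstitutionError(
            [f"{v.gene}: desired reference and alternate residues are both "
             f"{v.ref_aa!r}"]
        )
    strand = layout.strand
    ref_t = v.ref if strand == "+" else _comp(v.ref)
    alt_t = v.alt if strand == "+" else _comp(v.alt)
    pair = find_codon_pair(v.ref_aa, v.alt_aa, ref_t, alt_t)
    if pair is None:
        raise InfeasibleSubstitutionError(
            [f"{v.gene}: no single-base codon path {v.ref_aa}->{v.alt_aa} "
             f"with transcript-strand alleles {ref_t}->{alt_t} on strand {strand}"]
        )
    ref_codon, alt_codon, within = pair

    aa_pos = v.aa_position
    n_codons = layout.n_codons or aa_pos + 2
    if n_codons < aa_pos:
        raise ValueError(f"{v.gene}: transcript of {n_codons} codons cannot "
                         f"hold codon {aa_pos}")
    codons = [_FILL_CODON] * n_codons
    codons[aa_pos - 1] = ref_codon
    cds_seq = "".join(codons)
    cds_len = len(cds_seq)
    variant_offset = (aa_pos - 1) * 3 + within

    breaks = list(layout.cds_breaks)
    if layout.splice_break_near_variant:
        breaks.append(variant_offset + 2)
    breaks = sorted({b for b in breaks if 0 < b < cds_len})
    seg_lens = _segment_lengths(cds_len, breaks)

    shift = layout.second_codon_shift or 0
    ext_len = 3 * shift if shift > 0 else 0
    trim_len = -3 * shift if shift < 0 else 0
    if trim_len and (trim_len >= seg_lens[0] or trim_len > variant_offset):
        raise ValueError(
            f"{v.gene}: codon shift {shift} incompatible with the first exon "
            f"or the variant position"
        )

    flank = 60
    intron = layout.intron_length
    total_exonic = cds_len
    total_intronic = intron * len(breaks)
    contig_len = flank + ext_len + total_exonic + total_intronic + flank

    seq = rng.choice(_BASES, size=contig_len)

    # translation-order CDS segments
    segments: list[str] = []
    cursor = 0
    for length in seg_lens:
        segments.append(cds_seq[cursor:cursor + length])
        cursor += length

    # genomic placement: upstream margin (flank + optional extension room)
    # sits on the left for '+', on the right for '-'
    exon_intervals: list[tuple[int, int]] = []  # 1-based inclusive, ascending
    if strand == "+":
        cur = flank + ext_len  # 0-based
        for segment in segments:
            start0, end0 = cur, cur + len(segment)
            seq[start0:end0] = list(segment)
            exon_intervals.append((start0 + 1, end0))
            cur = end0 + intron
    else:
        cur = flank  # genomic left; genomic order is reversed translation order
        for segment in reversed(segments):
            start0, end0 = cur, cur + len(segment)
            seq[start0:end0] = list(_revcomp(segment))
            exon_intervals.append((start0 + 1, end0))
            cur = end0 + intron

    tx1 = TranscriptModel(
        transcript_id=f"{contig}_t1", gene_symbol=v.gene, chrom=contig,
        strand=strand, cds_exons=tuple(exon_intervals),
    )
    transcripts = [tx1]

    if shift > 0:
        ext_seq = _FILL_CODON * shift
        if strand == "+":
            first = exon_intervals[0]
            new_first = (first[0] - ext_len, first[1])
            seq[new_first[0] - 1:first[0] - 1] = list(ext_seq)
            exons2 = (new_first, *exon_intervals[1:])
        else:
            last = exon_intervals[-1]
            new_last = (last[0], last[1] + ext_len)
            seq[last[1]:new_last[1]] = list(_revcomp(ext_seq))
            exons2 = (*exon_intervals[:-1], new_last)
        transcripts.append(replace(tx1, transcript_id=f"{contig}_t2",
                                   cds_exons=exons2))
    elif shift < 0:
        if strand == "+":
            first = exon_intervals[0]
            exons2 = ((first[0] + trim_len, first[1]), *exon_intervals[1:])
        else:
            last = exon_intervals[-1]
            exons2 = (*exon_intervals[:-1], (last[0], last[1] - trim_len))
        transcripts.append(replace(tx1, transcript_id=f"{contig}_t2",
                                   cds_exons=exons2))

    pos = _cds_offset_to_genomic(tx1, variant_offset)
    genome_base = seq[pos - 1]
    assert genome_base == v.ref, (
        f"design bug: genome base {genome_base!r} != ref allele {v.ref!r}"
    )

    expected = [f"{v.ref_aa}{aa_pos}{v.alt_aa}"]
    if shift:
        expected.append(f"{v.ref_aa}{aa_pos + shift}{v.alt_aa}")

    gff_lines: list[str] = []
    gene_id = f"gene:{contig}"
    lo = min(t.span[0] for t in transcripts)
    hi = max(t.span[1] for t in transcripts)
    gff_lines.append(
        f"{contig}\tequivar\tgene\t{lo}\t{hi}\t.\t{strand}\t.\t"
        f"ID={gene_id};Name={v.gene}"
    )
    for tx in transcripts:
        t_lo, t_hi = tx.span
        gff_lines.append(
            f"{contig}\tequivar\tmRNA\t{t_lo}\t{t_hi}\t.\t{strand}\t.\t"
            f"ID={tx.transcript_id};Parent={gene_id};gene={v.gene}"
        )
        for k, (s, e) in enumerate(tx.cds_exons):
            gff_lines.append(
                f"{contig}\tequivar\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
                f"ID=cds:{tx.transcript_id}.{k + 1};Parent={tx.transcript_id};"
                f"gene={v.gene}"
            )

    placement = PlacedVariant(
        gene=v.gene, chrom=contig, pos=pos, ref=v.ref, alt=v.alt,
        target_alt_allele_count=v.target_alt_allele_count,
        contig_length=contig_len,
        expected_hgvsp=tuple(expected),
        source_chrom=v.source_chrom or v.chrom,
        source_pos=v.source_pos or v.pos,
    )
    return "".join(seq), gff_lines, placement, transcripts


def design_reference(spec: FixtureSpec) -> ReferenceBundle:
    """Inverse-design a reference FASTA and GFF3 realizing a fixture spec.

    Every variant lands on its own small contig; infeasible substitutions
    (amino-acid pairs with no one-base codon path under the given alleles
    and strand) are collected and reported together rather than silently
    altered.
    """
    rng = np.random.default_rng(spec.seed)
    fasta_parts: list[str] = []
    gff_parts: list[str] = ["##gff-version 3"]
    placements: list[PlacedVariant] = []
    transcripts: list[TranscriptModel] = []
    problems: list[str] = []
    for index, v in enumerate(spec.variants):
        if v.ref_aa is None or v.alt_aa is None or v.aa_position is None:
            raise ValueError(
                f"variant {index} ({v.gene}) lacks a missense goal; "
                f"design_reference needs ref_aa/alt_aa/aa_position"
            )
        label = v.source_pos or v.pos or index
        contig = f"syn_{v.gene}_{label}"
        try:
            seq, gff_lines, placement, txs = _design_one(v, contig, rng)
        except InfeasibleSubstitutionError as exc:
            problems.extend(exc.entries)
            continue
        wrapped = "\n".join(seq[i:i + 80] for i in range(0, len(seq), 80))
        fasta_parts.append(f">{contig}\n{wrapped}")
        gff_parts.extend(gff_lines)
        placements.append(placement)
        transcripts.extend(txs)
    if problems:
        raise InfeasibleSubstitutionError(problems)
    return ReferenceBundle(
        fasta="\n".join(fasta_parts) + "\n",
        gff3="\n".join(gff_parts) + "\n",
        placements=tuple(placements),
        transcripts=tuple(transcripts),
    )


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def generate_cohort(spec: FixtureSpec,
                    placements: Sequence[PlacedVariant] | None = None) -> str:
    """Emit deterministic VCF text for a diploid cohort.

    Each variant receives exactly its target number of alternate alleles,
    assigned to random chromosomes of random individuals, so recomputed
    frequencies hit their targets exactly.  Identical spec + seed give
    byte-identical output.
    """
    n = spec.n_individuals
    slots = 2 * n
    rng = np.random.default_rng(spec.seed)

    if placements is not None:
        sites = [
            (p.chrom, p.pos, p.ref, p.alt, p.target_alt_allele_count,
             p.contig_length)
            for p in placements
        ]
    else:
        sites = []
        for v in spec.variants:
            if v.chrom is None or v.pos is None:
                raise ValueError(
                    f"variant in gene {v.gene} has no chrom/pos; design a "
                    f"reference first or specify coordinates"
                )
            sites.append((v.chrom, v.pos, v.ref, v.alt,
                          v.target_alt_allele_count, None))

    contig_len: dict[str, int] = {}
    for chrom, pos, _, _, _, length in sites:
        need = length if length is not None else pos + 1000
        contig_len[chrom] = max(contig_len.get(chrom, 0), need)

    lines = ["##fileformat=VCFv4.2", "##source=equivar-synthetic"]
    for chrom in contig_len:
        lines.append(f"##contig=<ID={chrom},length={contig_len[chrom]}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = [f"ind{i + 1:03d}" for i in range(n)]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))

    for chrom, pos, ref, alt, count, _ in sorted(
        sites, key=lambda s: (s[0], s[1])
    ):
        if not (0 <= count <= slots):
            raise ValueError(
                f"alt-allele count {count} at {chrom}:{pos} infeasible for "
                f"{n} diploid individuals"
            )
        carrier = np.zeros(slots, dtype=int)
        chosen = rng.choice(slots, size=count, replace=False)
        carrier[chosen] = 1
        gts = [f"{carrier[2 * i]}/{carrier[2 * i + 1]}" for i in range(n)]
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# specs derived from the packaged tables
# --------------------------------------------------------------------------

def _target_count(alt_freq: float, n_individuals: int = COHORT_SIZE) -> int:
    return int(round_half_up(alt_freq * 2 * n_individuals, 0))


def table2_cohort_spec(seed: int = 0,
                       n_individuals: int = COHORT_SIZE) -> FixtureSpec:
    """Cohort spec matching the packaged frequency table.

    Alternate-allele counts are the unique integers whose frequency over
    ``2 × n_individuals`` chromosomes rounds (half-up, 3 decimals) to each
    printed value; sites with withheld frequencies are excluded.
    """
    tables = paper_fixture()
    variants = []
    for row in tables.variants.itertuples(index=False):
        if pd.isna(row.alt_freq):
            continue
        variants.append(
            VariantSpec(
                gene=str(row.gene), chrom=str(row.chrom), pos=int(row.pos),
                ref=str(row.ref_allele), alt=str(row.alt_allele),
                target_alt_allele_count=_target_count(
                    float(row.alt_freq), n_individuals
                ),
            )
        )
    return FixtureSpec(variants=tuple(variants), n_individuals=n_individuals,
                       seed=seed)


def table3_reference_spec(seed: int = 0,
                          n_individuals: int = COHORT_SIZE) -> FixtureSpec:
    """Inverse-design spec for the 54 curated substitutions.

    Strand is chosen per variant as the first of ``+``/``-`` under which the
    genomic alleles admit a single-base codon path; dual splice-form rows
    get a second transcript with the recorded codon shift, and splice-region
    rows get an exon junction adjacent to the variant.  The curated
    insertion is packaged as data only and excluded from design.
    """
    tables = paper_fixture()
    merged = tables.variants.merge(
        tables.impacts, on=["gene", "chrom", "pos"], validate="one_to_one"
    )
    variants: list[VariantSpec] = []
    problems: list[str] = []
    for row in merged.itertuples(index=False):
        if row.annotation == "codon insertion":
            continue
        labels = [parse_hgvsp(lab) for lab in str(row.hgvsp).split(";")]
        ref_aa, aa_pos, alt_aa = labels[0]
        shift = labels[1][1] - aa_pos if len(labels) > 1 else None
        strand = None
        for candidate in ("+", "-"):
            ref_t = row.ref_allele if candidate == "+" else _comp(row.ref_allele)
            alt_t = row.alt_allele if candidate == "+" else _comp(row.alt_allele)
            if find_codon_pair(ref_aa, alt_aa, ref_t, alt_t):
                strand = candidate
                break
        if strand is None:
            problems.append(
                f"{row.gene} {row.chrom}:{row.pos} {ref_aa}->{alt_aa} with "
                f"alleles {row.ref_allele}->{row.alt_allele}: no strand works"
            )
            continue
        layout = TranscriptLayout(
            strand=strand,
            second_codon_shift=shift,
            splice_break_near_variant="splice site region" in row.annotation,
        )
        count = 0 if pd.isna(row.alt_freq) else _target_count(
            float(row.alt_freq), n_individuals
        )
        variants.append(
            VariantSpec(
                gene=str(row.gene), ref=str(row.ref_allele),
                alt=str(row.alt_allele), target_alt_allele_count=count,
                ref_aa=ref_aa, alt_aa=alt_aa, aa_position=aa_pos,
                layout=layout,
                source_chrom=str(row.chrom), source_pos=int(row.pos),
            )
        )
    if problems:
        raise InfeasibleSubstitutionError(problems)
    return FixtureSpec(variants=tuple(variants), n_individuals=n_individuals,
                       seed=seed)


def write_fixture_dir(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a complete synthetic input set (VCF, FASTA, GFF3, trait TSV).

    The set realizes the packaged substitution table on synthetic contigs
    with cohort genotypes matching the packaged frequencies.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = table3_reference_spec(seed=seed)
    bundle = design_reference(spec)
    vcf_text = generate_cohort(spec, bundle.placements)
    paths = {
        "fasta": outdir / "reference.fasta",
        "gff3": outdir / "transcripts.gff3",
        "vcf": outdir / "cohort.vcf",
        "traits": outdir / "gene_traits.tsv",
    }
    paths["fasta"].write_text(bundle.fasta)
    paths["gff3"].write_text(bundle.gff3)
    paths["vcf"].write_text(vcf_text)
    ref = resources.files("equivar.data") / "gene_annotations.tsv"
    with resources.as_file(ref) as p:
        paths["traits"].write_text(Path(p).read_text())
    return paths
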