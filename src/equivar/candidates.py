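"""End-to-end candidate-gene join and summary counts.

This module keeps variants whose consequence on at least one transcript is
non-synonymous (or a codon insertion) in a gene present in the user's
trait map, attaches impact scores, allele frequencies, PTM transitions and
functional categories, and emits report rows plus summary counts.  A variant
is counted once even when it has consequences on several transcripts.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import frequency as freqmod
from .consequence import CodingConsequence, annotate_variant
from .io_formats import (
    GeneTraitMap,
    TranscriptModel,
    VariantRecord,
    normalize_chrom,
)
from .properties import AminoAcidTable, ImpactScore, classify_impact

__all__ = [
    "AnnotatedVariant",
    "CandidateRow",
    "SummaryCounts",
    "annotate_cohort",
    "build_report",
    "cohort_frequencies",
    "impact_scores",
    "parse_hgvsp",
    "report_frame",
    "reproduce_fixture",
    "select_candidates",
    "summarize",
]

_HGVSP_RE = re.compile(r"^([A-Z\*])(\d+)([A-Z\*]+)$")

_CLASS_DISPLAY = {
    "non_synonymous_coding": "non-synonymous coding",
    "synonymous_coding": "synonymous coding",
    "codon_insertion": "codon insertion",
    "non_coding": "non-coding",
}

_CANDIDATE_CLASSES = frozenset({"non_synonymous_coding", "codon_insertion"})

Key = tuple[str, int, str]


def parse_hgvsp(label: str) -> tuple[str, int, str]:
    """Split a compact one-letter HGVSp label into (ref_aa, position, alt_aa)."""
    match = _HGVSP_RE.match(label)
    if not match:
        raise ValueError(f"cannot parse HGVSp label {label!r}")
    return match.group(1), int(match.group(2)), match.group(3)


@dataclass(frozen=True)
class AnnotatedVariant:
    """One cohort variant with its per-transcript consequences."""

    gene_symbol: str | None
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    consequences: tuple[CodingConsequence, ...] = ()

    @property
    def key(self) -> Key:
        return (normalize_chrom(self.chrom), self.pos, self.alt_allele)

    @property
    def is_insertion(self) -> bool:
        return len(self.alt_allele) > len(self.ref_allele)

    @property
    def candidate_consequences(self) -> tuple[CodingConsequence, ...]:
        return tuple(
            c for c in self.consequences if c.classification in _CANDIDATE_CLASSES
        )


@dataclass(frozen=True)
class CandidateRow:
    gene_symbol: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_freq: float | None
    alt_freq: float | None
    stratum: str
    hgvsp_labels: tuple[str, ...]
    annotation: str
    mw_difference: float | None
    hydropathy_difference: float | None
    high_mw: bool | None
    high_hydropathy: bool | None
    ptm_lost: frozenset[str]
    ptm_gained: frozenset[str]
    traits: frozenset[str]
    function_category: str


@dataclass(frozen=True)
class SummaryCounts:
    n_variants: int
    n_genes: int
    n_snps: int
    n_insertions: int
    n_high_mw: int
    n_high_hydropathy: int
    n_rare: int
    n_common: int
    per_gene_variant_counts: Mapping[str, int]


def annotate_cohort(variants: Sequence[VariantRecord],
                    transcripts: Sequence[TranscriptModel],
                    genome: Mapping[str, str],
                    splice_window: int = 3) -> list[AnnotatedVariant]:
    """Run consequence calling over a cohort and attach gene symbols."""
    gene_of = {t.transcript_id: t.gene_symbol for t in transcripts}
    annotated: list[AnnotatedVariant] = []
    for variant in variants:
        consequences = annotate_variant(variant, transcripts, genome, splice_window)
        gene = None
        for c in consequences:
            gene = gene_of.get(c.transcript_id)
            if gene:
                break
        annotated.append(
            AnnotatedVariant(
                gene_symbol=gene,
                chrom=variant.chrom,
                pos=variant.pos,
                ref_allele=variant.ref_allele,
                alt_allele=variant.alt_allele,
                consequences=tuple(consequences),
            )
        )
    return annotated


def select_candidates(annotated: Iterable[AnnotatedVariant],
                      trait_map: GeneTraitMap) -> list[AnnotatedVariant]:
    """Keep variants with ≥1 candidate-class consequence in a mapped gene."""
    return [
        av for av in annotated
        if av.gene_symbol is not None
        and av.gene_symbol in trait_map
        and av.candidate_consequences
    ]


def impact_scores(selected: Iterable[AnnotatedVariant],
                  table: AminoAcidTable | None = None,
                  scale: str | None = None,
                  mw_threshold: float = 40.00,
                  hydropathy_threshold: float = 1.00) -> dict[Key, ImpactScore | None]:
    """Score the substitution of each selected variant.

    Codon insertions and stop-involving substitutions carry no residue pair
    to score and map to ``None``.
    """
    scores: dict[Key, ImpactScore | None] = {}
    for av in selected:
        score: ImpactScore | None = None
        for c in av.candidate_consequences:
            if (c.classification == "non_synonymous_coding"
                    and not c.stop_involved and c.ref_aa and c.alt_aa):
                score = classify_impact(
                    c.ref_aa, c.alt_aa, table, scale,
                    mw_threshold, hydropathy_threshold,
                )
                break
        scores[av.key] = score
    return scores


def cohort_frequencies(
    variants: Sequence[VariantRecord],
    suppressed_chroms: frozenset[str] | set[str] = freqmod.SUPPRESSED_CHROMS,
) -> dict[Key, freqmod.AlleleFrequencyRecord]:
    return {v.key: freqmod.variant_frequencies(v, suppressed_chroms) for v in variants}


def _annotation_string(av: AnnotatedVariant) -> str:
    classes = []
    for c in av.candidate_consequences:
        display = _CLASS_DISPLAY[c.classification]
        if display not in classes:
            classes.append(display)
    joined = "; ".join(classes)
    if any(c.splice_region for c in av.candidate_consequences):
        joined = "splice site region; " + joined
    return joined


def _chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    name = normalize_chrom(chrom)
    if name.isdigit():
        return (0, int(name), "")
    return (1, 0, name)


def build_report(selected: Sequence[AnnotatedVariant],
                 scores: Mapping[Key, ImpactScore | None],
                 freqs: Mapping[Key, freqmod.AlleleFrequencyRecord],
                 trait_map: GeneTraitMap) -> list[CandidateRow]:
    """Join consequences, scores and frequencies into report rows.

    Inputs must be keyed consistently by ``(chrom, pos, alt)``; a variant
    missing from *scores* or *freqs* is an error naming the orphan record.
    Rows are sorted by (chromosome, position), numeric chromosomes first.
    """
    rows: list[CandidateRow] = []
    for av in selected:
        if av.key not in scores:
            raise KeyError(f"no impact score for variant {av.chrom}:{av.pos} "
                           f"alt={av.alt_allele}")
        if av.key not in freqs:
            raise KeyError(f"no frequency record for variant {av.chrom}:{av.pos} "
                           f"alt={av.alt_allele}")
        score = scores[av.key]
        freq = freqs[av.key]
        annotation = _annotation_string(av)
        labels = tuple(c.hgvsp for c in av.candidate_consequences if c.hgvsp)
        ann = trait_map[av.gene_symbol]
        rows.append(
            CandidateRow(
                gene_symbol=av.gene_symbol,
                chrom=av.chrom,
                pos=av.pos,
                ref_allele=av.ref_allele,
                alt_allele=av.alt_allele,
                ref_freq=freq.ref_freq,
                alt_freq=freq.alt_freq,
                stratum=freqmod.stratify(freq),
                hgvsp_labels=labels,
                annotation=annotation,
                mw_difference=score.mw_difference if score else None,
                hydropathy_difference=score.hydropathy_difference if score else None,
                high_mw=score.high_mw if score else None,
                high_hydropathy=score.high_hydropathy if score else None,
                ptm_lost=score.ptm_lost if score else frozenset(),
                ptm_gained=score.ptm_gained if score else frozenset(),
                traits=ann.traits,
                function_category=ann.function_category,
            )
        )
    rows.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.pos))
    return rows


def summarize(report: Sequence[CandidateRow]) -> SummaryCounts:
    per_gene = Counter(r.gene_symbol for r in report)
    n_insertions = sum(
        1 for r in report if len(r.alt_allele) > len(r.ref_allele)
    )
    return SummaryCounts(
        n_variants=len(report),
        n_genes=len(per_gene),
        n_snps=len(report) - n_insertions,
        n_insertions=n_insertions,
        n_high_mw=sum(1 for r in report if r.high_mw),
        n_high_hydropathy=sum(1 for r in report if r.high_hydropathy),
        n_rare=sum(1 for r in report if r.stratum == "rare"),
        n_common=sum(1 for r in report if r.stratum == "common"),
        per_gene_variant_counts=dict(per_gene),
    )


def report_frame(rows: Sequence[CandidateRow]) -> pd.DataFrame:
    """Flatten report rows into a DataFrame (sets joined with ';')."""
    return pd.DataFrame(
        {
            "gene": r.gene_symbol,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref_allele": r.ref_allele,
            "alt_allele": r.alt_allele,
            "ref_freq": r.ref_freq,
            "alt_freq": r.alt_freq,
            "stratum": r.stratum,
            "hgvsp": ";".join(r.hgvsp_labels),
            "annotation": r.annotation,
            "mw_difference": r.mw_difference,
            "hydropathy_difference": r.hydropathy_difference,
            "high_mw": r.high_mw,
            "high_hydropathy": r.high_hydropathy,
            "ptm_lost": ";".join(sorted(r.ptm_lost)),
            "ptm_gained": ";".join(sorted(r.ptm_gained)),
            "traits": ";".join(sorted(r.traits)),
            "function_category": r.function_category,
        }
        for r in rows
    )


def reproduce_fixture(scale: str = "paper",
                      mw_threshold: float = 40.00,
                      hydropathy_threshold: float = 1.00
                      ) -> tuple[list[CandidateRow], SummaryCounts]:
    """Run the full join on the packaged in-study variant tables.

    Scores are recomputed from the residue property tables (never read from
    the packaged impact columns), frequencies come from the packaged cohort
    frequencies with sex-chromosome suppression, and the result is the
    candidate report plus its summary counts.
    """
    from .synthetic_data import fixture_annotated_variants

    annotated, freqs, trait_map = fixture_annotated_variants()
    selected = select_candidates(annotated, trait_map)
    scores = impact_scores(
        selected, scale=scale,
        mw_threshold=mw_threshold, hydropathy_threshold=hydropathy_threshold,
    )
    rows = build_report(selected, scores, freqs, trait_map)
    return rows, summarize(rows)
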