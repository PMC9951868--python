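"""Readers and writers for the standard formats the pipeline touches.

No science lives here.  Internal coordinates are 0-based half-open; every
I/O boundary (VCF, GFF3) is 1-based inclusive, and the conversion happens
only in this module and in the coordinate helpers it exports.

Chromosome names are matched exactly after stripping an optional ``chr``
prefix on both sides, since upstream sources mix ``chr11:...`` with plain
``11``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

__all__ = [
    "BIG_FIVE_TRAITS",
    "FormatError",
    "GeneAnnotation",
    "GeneTraitMap",
    "TranscriptModel",
    "VariantRecord",
    "normalize_chrom",
    "read_fasta",
    "read_gff3",
    "read_trait_map",
    "read_vcf",
    "write_report",
    "write_trait_map",
    "REPORT_COLUMNS",
]

BIG_FIVE_TRAITS = frozenset(
    {"Agreeableness", "Conscientiousness", "Extraversion", "Neuroticism", "Openness"}
)

_ALLELE_RE = re.compile(r"^[ACGT]+$")

Genotype = tuple[int | None, int | None]


class FormatError(ValueError):
    """Malformed input file (bad record, bad header, bad value)."""


def normalize_chrom(name: str) -> str:
    """Strip an optional ``chr`` prefix for exact-match comparison."""
    return name[3:] if name.lower().startswith("chr") else name


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic cohort variant (SNP or simple insertion).

    ``genotypes`` holds diploid calls as allele-index pairs, ``(None, None)``
    for missing; ``precomputed_freq`` is ``(ref_freq, alt_freq)`` when the
    source provides frequencies instead of genotypes.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    genotypes: tuple[Genotype, ...] | None = None
    precomputed_freq: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref_allele, self.alt_allele):
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"allele must be non-empty A/C/G/T, got {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def is_insertion(self) -> bool:
        return len(self.alt_allele) > len(self.ref_allele)

    @property
    def key(self) -> tuple[str, int, str]:
        return (normalize_chrom(self.chrom), self.pos, self.alt_allele)


@dataclass(frozen=True)
class TranscriptModel:
    """Strand-aware CDS exon structure of one transcript.

    ``cds_exons`` are 1-based inclusive genomic intervals, sorted ascending
    regardless of strand; translation order on the minus strand is the
    reverse of storage order.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = 0
        for start, end in self.cds_exons:
            if start < 1 or end < start:
                raise ValueError(f"bad CDS interval ({start}, {end})")
            if start <= prev_end:
                raise ValueError("CDS intervals must be sorted and non-overlapping")
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.cds_exons[0][0], self.cds_exons[-1][1])


@dataclass(frozen=True)
class GeneAnnotation:
    traits: frozenset[str]
    function_category: str


@dataclass(frozen=True)
class GeneTraitMap:
    """Gene symbol → Big Five trait set and biological-function label."""

    genes: Mapping[str, GeneAnnotation]

    def __post_init__(self) -> None:
        for gene, ann in self.genes.items():
            if not ann.traits:
                raise ValueError(f"gene {gene} has an empty trait set")
            bad = ann.traits - BIG_FIVE_TRAITS
            if bad:
                raise FormatError(
                    f"unknown trait(s) {sorted(bad)} for gene {gene}; "
                    f"allowed: {sorted(BIG_FIVE_TRAITS)}"
                )

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __getitem__(self, gene: str) -> GeneAnnotation:
        return self.genes[gene]

    def __len__(self) -> int:
        return len(self.genes)


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read biallelic variants from a VCF 4.x text file.

    FORMAT/GT fields become per-individual genotype tuples; when the file has
    no samples, an INFO/AF value is honored as ``precomputed_freq``.
    Multi-allelic rows are rejected (split them upstream).
    """
    records: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    with vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(
                    f"multi-allelic or ALT-less record at "
                    f"{rec.chrom}:{rec.pos}; split multi-allelic rows first"
                )
            genotypes: tuple[Genotype, ...] | None = None
            freq: tuple[float, float] | None = None
            if sample_names:
                calls = []
                for name in sample_names:
                    gt = rec.samples[name].get("GT")
                    if gt is None:
                        gt = (None, None)
                    if len(gt) != 2:
                        raise FormatError(
                            f"non-diploid genotype {gt} at {rec.chrom}:{rec.pos}"
                        )
                    calls.append((gt[0], gt[1]))
                genotypes = tuple(calls)
            elif "AF" in rec.info:
                af = rec.info["AF"]
                alt_freq = float(af[0] if isinstance(af, tuple) else af)
                freq = (round(1.0 - alt_freq, 10), alt_freq)
            try:
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref.upper(),
                        alt_allele=rec.alts[0].upper(),
                        genotypes=genotypes,
                        precomputed_freq=freq,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"bad record at {rec.chrom}:{rec.pos}: {exc}") from exc
    return records


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into ``{name: uppercase sequence}``."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate FASTA record name: {rec.id}")
        sequences[rec.id] = str(rec.seq).upper()
    return sequences


def read_gff3(path: str | Path) -> list[TranscriptModel]:
    """Group GFF3 CDS features into per-transcript models.

    CDS features must carry a ``Parent`` (transcript id) attribute and a
    ``gene`` attribute on the CDS or its parent feature.  Transcripts whose
    total CDS length is not a multiple of 3 are skipped with a warning;
    mixed strands within one transcript are an error.
    """
    import warnings

    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent")
        if not parents:
            raise FormatError(
                f"CDS feature at {cds.seqid}:{cds.start}-{cds.end} has no Parent"
            )
        gene = cds.attributes.get("gene", [None])[0]
        if gene is None:
            for parent in db.parents(cds):
                gene = parent.attributes.get("gene", [None])[0]
                if gene:
                    break
        for parent_id in parents:
            entry = grouped.setdefault(
                parent_id,
                {"chrom": cds.seqid, "strand": cds.strand,
                 "gene": gene or parent_id, "exons": []},
            )
            if cds.strand != entry["strand"]:
                raise FormatError(f"mixed strands within transcript {parent_id}")
            if cds.seqid != entry["chrom"]:
                raise FormatError(f"multiple chromosomes within transcript {parent_id}")
            entry["exons"].append((cds.start, cds.end))

    models: list[TranscriptModel] = []
    for tx_id in sorted(grouped):
        entry = grouped[tx_id]
        exons = tuple(sorted(entry["exons"]))
        length = sum(e - s + 1 for s, e in exons)
        if length % 3 != 0:
            warnings.warn(
                f"transcript {tx_id}: CDS length {length} not divisible by 3; skipped",
                stacklevel=2,
            )
            continue
        models.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_symbol=entry["gene"],
                chrom=entry["chrom"],
                strand=entry["strand"],
                cds_exons=exons,
            )
        )
    return models


def read_trait_map(path: str | Path) -> GeneTraitMap:
    """Read a gene→trait/function TSV (columns gene, function_category, traits).

    ``traits`` is a ``;``-separated subset of the Big Five trait names.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "function_category", "traits"}
    if not required.issubset(frame.columns):
        raise FormatError(
            f"trait map must have columns {sorted(required)}, got {list(frame.columns)}"
        )
    genes: dict[str, GeneAnnotation] = {}
    for row in frame.itertuples(index=False):
        traits = frozenset(t.strip() for t in str(row.traits).split(";") if t.strip())
        genes[str(row.gene)] = GeneAnnotation(
            traits=traits, function_category=str(row.function_category)
        )
    return GeneTraitMap(genes=genes)


def write_trait_map(trait_map: GeneTraitMap, path: str | Path) -> None:
    rows = [
        {
            "gene": gene,
            "function_category": ann.function_category,
            "traits": ";".join(sorted(ann.traits)),
        }
        for gene, ann in trait_map.genes.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


#: candidate-report column order: the frequency-table layout first, then the
#: protein-impact extensions, for diffability against the published tables
REPORT_COLUMNS = [
    "gene", "chrom", "pos", "ref_allele", "alt_allele",
    "ref_freq", "alt_freq", "stratum",
    "hgvsp", "annotation",
    "mw_difference", "hydropathy_difference", "high_mw", "high_hydropathy",
    "ptm_lost", "ptm_gained",
    "traits", "function_category",
]


def write_report(rows: Sequence[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write candidate rows as a TSV with the canonical column order."""
    frame = pd.DataFrame(rows)
    cols = [c for c in REPORT_COLUMNS if c in frame.columns]
    cols += [c for c in frame.columns if c not in cols]
    frame.to_csv(path, sep="\t", index=False, columns=cols)
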