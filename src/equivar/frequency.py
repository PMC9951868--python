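"""Allele-frequency computation, MAF stratification and histogram binning.

Frequencies are computed from diploid genotype calls (missing calls are
excluded from the denominator, never imputed) and rounded half-up to 3
decimals *before* stratification, so strata agree with printed tables rather
than with raw counts.  MAF is ``min(ref_freq, alt_freq)``: the minor allele
may be the reference one when the alternate allele has swept past 0.5.

Sites on suppressed chromosomes (default X and Y, mirroring variant
databases that withhold sex-chromosome frequencies) are marked unavailable;
the policy is a flag, not a hard rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._rounding import round_half_up
from .io_formats import Genotype, VariantRecord, normalize_chrom

__all__ = [
    "AlleleFrequencyRecord",
    "allele_frequencies",
    "bin_frequencies",
    "from_precomputed",
    "stratify",
    "variant_frequencies",
    "SUPPRESSED_CHROMS",
]

#: chromosomes whose frequencies are withheld by default
SUPPRESSED_CHROMS = frozenset({"X", "Y"})

UNAVAILABLE: "AlleleFrequencyRecord"


@dataclass(frozen=True)
class AlleleFrequencyRecord:
    """Reference/alternate allele proportions at one biallelic site."""

    ref_freq: float | None
    alt_freq: float | None
    maf: float | None
    n_alleles: int
    available: bool = True

    def __post_init__(self) -> None:
        if self.available:
            total = self.ref_freq + self.alt_freq
            if not (0.999 <= total <= 1.001):
                raise ValueError(f"ref + alt frequency = {total}, expected ~1")


UNAVAILABLE = AlleleFrequencyRecord(
    ref_freq=None, alt_freq=None, maf=None, n_alleles=0, available=False
)


def allele_frequencies(genotypes: Sequence[Genotype]) -> AlleleFrequencyRecord:
    """Frequencies from diploid calls; missing alleles leave the denominator."""
    n_alt = 0
    n_called = 0
    for a, b in genotypes:
        for allele in (a, b):
            if allele is None:
                continue
            if allele not in (0, 1):
                raise ValueError(f"allele index must be 0 or 1, got {allele}")
            n_called += 1
            n_alt += allele
    if n_called == 0:
        return UNAVAILABLE
    alt = round_half_up(n_alt / n_called, 3)
    ref = round_half_up((n_called - n_alt) / n_called, 3)
    return AlleleFrequencyRecord(
        ref_freq=ref, alt_freq=alt, maf=min(ref, alt), n_alleles=n_called
    )


def from_precomputed(ref_freq: float, alt_freq: float,
                     n_alleles: int = 0) -> AlleleFrequencyRecord:
    """Wrap database-supplied frequencies (rounded half-up to 3 decimals)."""
    ref = round_half_up(ref_freq, 3)
    alt = round_half_up(alt_freq, 3)
    return AlleleFrequencyRecord(
        ref_freq=ref, alt_freq=alt, maf=min(ref, alt), n_alleles=n_alleles
    )


def variant_frequencies(
    variant: VariantRecord,
    suppressed_chroms: frozenset[str] | set[str] = SUPPRESSED_CHROMS,
) -> AlleleFrequencyRecord:
    """Frequency record for one variant, honoring chromosome suppression.

    Genotypes win over precomputed frequencies when both are present.
    """
    if normalize_chrom(variant.chrom) in suppressed_chroms:
        return UNAVAILABLE
    if variant.genotypes is not None:
        return allele_frequencies(variant.genotypes)
    if variant.precomputed_freq is not None:
        return from_precomputed(*variant.precomputed_freq)
    return UNAVAILABLE


def stratify(record: AlleleFrequencyRecord,
             rare_maf: float = 0.05,
             common_range: tuple[float, float] = (0.3, 0.7)) -> str:
    """Assign a frequency stratum: rare, common, other or unavailable.

    ``rare`` means MAF ≤ ``rare_maf``; ``common`` means the alternate-allele
    frequency lies in the closed ``common_range`` interval.  Rare is checked
    first, so a site can never be both.
    """
    if not record.available:
        return "unavailable"
    if record.maf <= rare_maf:
        return "rare"
    lo, hi = common_range
    if lo <= record.alt_freq <= hi:
        return "common"
    return "other"


def bin_frequencies(records: Iterable[AlleleFrequencyRecord],
                    bin_width: float = 0.05) -> dict[float, int]:
    """Histogram of alternate-allele frequencies over half-open bins.

    Keys are left bin edges (``k * bin_width`` rounded to 6 decimals), values
    the count of available records with ``alt_freq`` in ``[edge, edge+width)``.
    Unavailable records are excluded, so the counts sum to the number of
    available records.
    """
    if not (0 < bin_width <= 1):
        raise ValueError(f"bin_width must be in (0, 1], got {bin_width}")
    histogram: dict[float, int] = {}
    for record in records:
        if not record.available:
            continue
        index = math.floor(round(record.alt_freq / bin_width, 9))
        edge = round(index * bin_width, 6)
        histogram[edge] = histogram.get(edge, 0) + 1
    return dict(sorted(histogram.items()))
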