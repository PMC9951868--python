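"""Amino-acid property tables and substitution impact scoring.

A missense variant swaps one residue for another; the physicochemical
footprint of that swap is summarised here by two deltas computed from
per-residue lookup tables:

* **molecular-weight difference** — average mass of the free (un-polymerised)
  alternate amino acid minus that of the reference amino acid, in daltons;
* **hydropathy difference** — alternate minus reference hydrophobicity index
  on a normalized consensus scale.

Substitutions with ``|ΔMW| >= 40.00`` Da or ``|Δhydropathy| >= 1.00`` are
flagged as high-impact.  Gain or loss of residues that host common
posttranslational modifications (phospho-acceptors S/T/Y, the N-glycosylation
acceptor N, and the S-nitrosylation / disulfide-forming C) is reported
alongside.

Two hydropathy scales are shipped.  ``consensus`` is the normalized consensus
hydrophobicity scale; ``paper`` is identical except that glutamine (Q)
carries the value 0.48 (the same as glycine), which is the effective value
required to reproduce the published candidate-gene impact table this package
targets.  ``paper`` is the default so reproductions round-trip exactly;
``consensus`` is recommended for new analyses.  The discrepancy is deliberate
and documented, never merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from ._rounding import round_half_up

__all__ = [
    "AminoAcidTable",
    "ImpactScore",
    "UnknownResidueError",
    "classify_impact",
    "hydropathy_difference",
    "load_amino_acid_table",
    "mass_difference",
    "ptm_transition",
    "CANONICAL_RESIDUES",
    "PTM_CLASSES",
    "MW_THRESHOLD",
    "HYDROPATHY_THRESHOLD",
]

Scale = Literal["consensus", "paper"]

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: default high-impact thresholds, in Da and (dimensionless) hydropathy units
MW_THRESHOLD = 40.00
HYDROPATHY_THRESHOLD = 1.00

#: residue classes capable of the three posttranslational modifications tracked
PTM_CLASSES: dict[str, frozenset[str]] = {
    "phospho": frozenset("STY"),
    "n_glycosylation": frozenset("N"),
    "s_nitrosylation_disulfide": frozenset("C"),
}


class UnknownResidueError(KeyError):
    """Raised for residue codes outside the 20 canonical amino acids."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"unknown or non-canonical residue code: {self.code!r}"


@dataclass(frozen=True)
class AminoAcidEntry:
    three_letter: str
    mass: float
    hydropathy_consensus: float
    hydropathy_paper: float


@dataclass(frozen=True)
class AminoAcidTable:
    """Per-residue average free-amino-acid mass and hydropathy values.

    Parameters
    ----------
    entries
        One :class:`AminoAcidEntry` per canonical one-letter code.
    scale_selector
        Which hydropathy column :meth:`hydropathy` uses by default.
    """

    entries: dict[str, AminoAcidEntry]
    scale_selector: Scale = "paper"

    def __post_init__(self) -> None:
        codes = set(self.entries)
        if codes != CANONICAL_RESIDUES:
            missing = sorted(CANONICAL_RESIDUES - codes)
            extra = sorted(codes - CANONICAL_RESIDUES)
            raise ValueError(
                f"amino-acid table must contain exactly the 20 canonical "
                f"residues (missing {missing}, unexpected {extra})"
            )
        if any(e.mass <= 0 for e in self.entries.values()):
            raise ValueError("amino-acid masses must be positive")
        if self.scale_selector not in ("consensus", "paper"):
            raise ValueError(f"unknown hydropathy scale: {self.scale_selector!r}")

    def _entry(self, code: str) -> AminoAcidEntry:
        try:
            return self.entries[code]
        except KeyError:
            raise UnknownResidueError(code) from None

    def mass(self, code: str) -> float:
        """Average mass (Da) of the free amino acid *code*."""
        return self._entry(code).mass

    def hydropathy(self, code: str, scale: Scale | None = None) -> float:
        """Hydrophobicity index of *code* on the selected scale."""
        entry = self._entry(code)
        scale = scale or self.scale_selector
        if scale == "consensus":
            return entry.hydropathy_consensus
        if scale == "paper":
            return entry.hydropathy_paper
        raise ValueError(f"unknown hydropathy scale: {scale!r}")


def load_amino_acid_table(path: str | Path | None = None,
                          scale: Scale = "paper") -> AminoAcidTable:
    """Load the residue property table (packaged TSV or a user override).

    The TSV must carry the columns ``code``, ``three_letter``, ``mass``,
    ``hydropathy_consensus`` and ``hydropathy_paper``.
    """
    if path is None:
        ref = resources.files("equivar.data") / "amino_acid_properties.tsv"
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p, sep="\t")
    else:
        frame = pd.read_csv(path, sep="\t")
    entries = {
        str(row.code): AminoAcidEntry(
            three_letter=str(row.three_letter),
            mass=float(row.mass),
            hydropathy_consensus=float(row.hydropathy_consensus),
            hydropathy_paper=float(row.hydropathy_paper),
        )
        for row in frame.itertuples(index=False)
    }
    return AminoAcidTable(entries=entries, scale_selector=scale)


_DEFAULT_TABLE: AminoAcidTable | None = None


def default_table() -> AminoAcidTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_amino_acid_table()
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class ImpactScore:
    """Impact summary of a single amino-acid substitution.

    ``mw_difference`` and ``hydropathy_difference`` are alt-minus-ref deltas
    rounded half-up to 2 decimals; the ``high_*`` flags compare the rounded
    absolute deltas against the thresholds the score was built with.
    """

    mw_difference: float
    hydropathy_difference: float
    high_mw: bool
    high_hydropathy: bool
    ptm_lost: frozenset[str] = field(default_factory=frozenset)
    ptm_gained: frozenset[str] = field(default_factory=frozenset)


def mass_difference(ref_aa: str, alt_aa: str,
                    table: AminoAcidTable | None = None) -> float:
    """Return ``mass(alt) - mass(ref)`` in Da, rounded to 2 decimals."""
    table = table or default_table()
    return round_half_up(table.mass(alt_aa) - table.mass(ref_aa), 2)


def hydropathy_difference(ref_aa: str, alt_aa: str,
                          table: AminoAcidTable | None = None,
                          scale: Scale | None = None) -> float:
    """Return ``hydropathy(alt) - hydropathy(ref)``, rounded to 2 decimals."""
    table = table or default_table()
    return round_half_up(
        table.hydropathy(alt_aa, scale) - table.hydropathy(ref_aa, scale), 2
    )


def ptm_transition(ref_aa: str, alt_aa: str) -> tuple[frozenset[str], frozenset[str]]:
    """PTM classes lost and gained by substituting *ref_aa* with *alt_aa*.

    A class is *lost* when the reference residue belongs to it and the
    alternate does not, and *gained* in the converse case; a swap within a
    class (e.g. S→T, both phospho-acceptors) reports neither.
    """
    for code in (ref_aa, alt_aa):
        if code not in CANONICAL_RESIDUES:
            raise UnknownResidueError(code)
    lost = frozenset(
        name for name, members in PTM_CLASSES.items()
        if ref_aa in members and alt_aa not in members
    )
    gained = frozenset(
        name for name, members in PTM_CLASSES.items()
        if alt_aa in members and ref_aa not in members
    )
    return lost, gained


def classify_impact(ref_aa: str, alt_aa: str,
                    table: AminoAcidTable | None = None,
                    scale: Scale | None = None,
                    mw_threshold: float = MW_THRESHOLD,
                    hydropathy_threshold: float = HYDROPATHY_THRESHOLD) -> ImpactScore:
    """Score one substitution: both deltas, threshold flags, PTM transitions."""
    table = table or default_table()
    dmw = mass_difference(ref_aa, alt_aa, table)
    dhyd = hydropathy_difference(ref_aa, alt_aa, table, scale)
    lost, gained = ptm_transition(ref_aa, alt_aa)
    return ImpactScore(
        mw_difference=dmw,
        hydropathy_difference=dhyd,
        high_mw=abs(dmw) >= mw_threshold,
        high_hydropathy=abs(dhyd) >= hydropathy_threshold,
        ptm_lost=lost,
        ptm_gained=gained,
    )
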