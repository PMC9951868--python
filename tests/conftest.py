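from __future__ import annotations

import numpy as np
import pytest

from equivar.io_formats import TranscriptModel, VariantRecord
from equivar.properties import load_amino_acid_table
from equivar.synthetic_data import paper_fixture


@pytest.fixture(scope="session")
def aa_table():
    return load_amino_acid_table()


@pytest.fixture(scope="session")
def tables():
    """The packaged curated variant/impact/trait tables."""
    return paper_fixture()


@pytest.fixture(scope="session")
def substitution_rows(tables):
    """The 54 substitution rows (insertion excluded), parsed once."""
    from equivar.candidates import parse_hgvsp

    rows = []
    for row in tables.impacts.itertuples(index=False):
        if row.annotation == "codon insertion":
            continue
        labels = [parse_hgvsp(lab) for lab in str(row.hgvsp).split(";")]
        rows.append(
            {
                "gene": row.gene,
                "pos": int(row.pos),
                "labels": labels,
                "annotation": row.annotation,
                "mw": float(row.mw_difference),
                "hydro": float(row.hydropathy_difference),
            }
        )
    assert len(rows) == 54
    return rows


def make_random_transcript(rng: np.random.Generator, chrom: str = "ctg"):
    """Random transcript fixture: 1-5 exons, either strand, CDS % 3 == 0."""
    n_exons = int(rng.integers(1, 6))
    exon_lens = [int(rng.integers(2, 30)) for _ in range(n_exons)]
    total = sum(exon_lens)
    exon_lens[-1] += (-total) % 3  # pad to a whole number of codons
    strand = "+" if rng.random() < 0.5 else "-"
    intervals = []
    cursor = int(rng.integers(5, 30))
    for length in exon_lens:
        intervals.append((cursor + 1, cursor + length))
        cursor += length + int(rng.integers(5, 40))
    genome_len = cursor + int(rng.integers(5, 30))
    seq = "".join(rng.choice(list("ACGT"), size=genome_len))
    transcript = TranscriptModel(
        transcript_id="tx_rand",
        gene_symbol="RAND",
        chrom=chrom,
        strand=strand,
        cds_exons=tuple(intervals),
    )
    return transcript, seq


def make_snp(rng: np.random.Generator, seq: str, pos: int,
             chrom: str = "ctg") -> VariantRecord:
    ref = seq[pos - 1]
    alt = rng.choice([b for b in "ACGT" if b != ref])
    return VariantRecord(chrom=chrom, pos=pos, ref_allele=ref, alt_allele=str(alt))
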