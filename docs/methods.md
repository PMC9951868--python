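# Methods

`equivar` nominates candidate genes for a behavioural or physiological
phenotype from a cohort variant call set.  The procedure it implements is
deliberately simple and fully reproducible: filter cohort variants to those
that change an encoded amino acid in a curated gene list, then characterise
each substitution by the physicochemical contrast between the reference and
alternate residues and by the site's allele-frequency profile in the cohort.
It was built around a curated set of 55 variants in 18 equine
personality-candidate genes from a 101-horse Thoroughbred cohort, which
ships with the package as a desk-scale reference dataset.

## Consequence model

A variant is projected onto the spliced coding sequence (CDS) of every
transcript whose CDS genomic span contains it.  CDS exons are stored as
ascending 1-based inclusive genomic intervals; on the minus strand the
translation order is the reverse of storage order and bases are
complemented.  For a SNP at spliced-CDS offset *o*, the affected codon is
`o div 3` (0-based) and the within-codon position `o mod 3`; the reference
and mutated codons are translated under the standard genetic code
(NCBI table 1) and the call is `synonymous_coding` or
`non_synonymous_coding` accordingly, labelled in compact one-letter HGVSp
(`A96V`).  Substitutions to or from a stop translate as `*` and are flagged
(`stop_involved`) so reports can distinguish them; they are classified
non-synonymous.  A variant overlapping several splice forms receives one
consequence per transcript, ordered by transcript id, and downstream
counting treats the variant as a single entity.

Insertions (alt allele longer than ref) are classified `codon_insertion`;
when the inserted length is a multiple of 3 the inserted peptide is
translated on the transcript strand and reported after the anchor residue,
otherwise the peptide is marked unavailable.  The insertion is
right-anchored at the VCF position and no re-normalisation is attempted.
Deletions, MNVs, frameshift peptide prediction and UTR consequences are out
of scope.

A VCF REF allele that disagrees with the reference genome raises an error;
records are never silently re-referenced.  An in-frame internal stop in the
reference CDS produces a warning but the call is still emitted.

**Splice-region tag.** Public annotation sources tag exonic variants near
exon–intron boundaries, but the window is convention-dependent.  We flag a
variant when it lies within `splice_window` exonic bases (default 3) of an
exon edge that abuts an intron; the outer edges of the first and last CDS
exon never count.  The default matches common annotator practice and
reproduces the two splice-tagged rows of the packaged dataset; it is
configurable precisely because the upstream convention is unstated.

## Substitution impact score

For a substitution ref→alt the package reports

* `ΔMW = mass(alt) − mass(ref)` in daltons, using the average masses of the
  free (un-polymerised) amino acids at 2 decimals (Gly 75.07 … Trp 204.23).
  Free masses — not residue masses — are what reproduces the packaged
  impact table (e.g. A→D = 133.10 − 89.09 = +44.01 Da), and a fixture test
  pins this.
* `Δhydropathy = h(alt) − h(ref)` on a normalized consensus hydrophobicity
  scale (Ala 0.62, Arg −2.53, …, Val 1.08).

Both deltas are computed from the 2-decimal table values and rounded
half-up to 2 decimals, so equality tests against the packaged table are
exact, and the high-impact flags (`|ΔMW| ≥ 40.00` Da, `|Δhydropathy| ≥
1.00`; thresholds configurable) compare the rounded values.

**Two hydropathy scales.** Back-calculation from the packaged impact table
matches the normalized consensus scale for 19 of 20 residues; every row
involving glutamine, however, requires an effective value of Q = 0.48
(identical to glycine) rather than the consensus −0.85.  Whether that value
is a transcription slip in the source or deliberate cannot be decided from
the data, so the package ships both columns: `paper` (Q = 0.48, default,
reproduces the packaged table bit-exactly) and `consensus` (recommended for
new analyses).  The only qualitative difference on the packaged data is the
E→Q row (+1.22 under `paper`, −0.11 under `consensus`), which moves the
high-hydropathy count from 15 to 14; a dedicated test documents this.

**PTM transitions.** Three residue classes capable of common
posttranslational modifications are tracked: phospho-acceptors {S, T, Y},
the N-glycosylation acceptor {N}, and {C} for S-nitrosylation / disulfide
bonding.  A substitution reports the classes lost by the reference residue
and gained by the alternate; swaps within a class (S→T) report neither.
Ambiguous or non-standard residue codes (U, O, X, B, Z) are rejected with
an error, never scored.

## Allele frequencies and strata

Frequencies come from diploid genotype calls: `alt_freq = n_alt / (2 ×
n_called)` with missing calls (`./.`) excluded from the denominator, never
imputed.  Values are rounded half-up to 3 decimals *before* stratification
so strata agree with printed tables (10/202 = 0.0495 → 0.050).  MAF is
`min(ref_freq, alt_freq)`, because the minor allele can be the reference
one (the packaged dataset contains adjacent sites at alt frequency 0.668).

Strata: `rare` iff MAF ≤ 0.05; else `common` iff alt frequency lies in the
closed interval [0.3, 0.7] (the interval applies to the alternate-allele
frequency, not MAF, exactly as the curated dataset defines it); else
`other`.  Sites on suppressed chromosomes (default {X, Y}, mirroring
databases that withhold sex-chromosome frequencies) are `unavailable`; the
suppression is a policy flag and can be disabled when user genotypes are
trusted.  Histogram binning uses half-open bins `[k·w, (k+1)·w)` over
available records only, so counts always sum to the number of available
sites.

## Candidate join

A variant survives selection when at least one of its consequences is
`non_synonymous_coding` or `codon_insertion` on a gene present in the
user-supplied trait map.  Report rows join HGVSp labels (one per splice
form, transcript order), the impact score, the frequency stratum, PTM
transitions and the gene's trait/function metadata, sorted by (chromosome,
position) with numeric chromosomes first.  Codon insertions and
stop-involving substitutions carry no residue pair and are reported
unscored.  Trait and function labels are pure metadata pass-through; the
packaged trait map reconstructs only the gene–trait pairs its source states
explicitly and defaults the remaining genes to Neuroticism (the dominant
trait there), so per-trait tallies computed from it reflect that partial
reconstruction, not a published matrix.

## Synthetic data

The generator produces every input the pipeline reads, at the scale of the
study it emulates:

* **Cohort** — 101 diploid individuals by default.  Each site receives an
  exact target count of alternate alleles, placed uniformly at random
  (seeded) among the 202 chromosomes; recomputed frequencies therefore hit
  their targets exactly, which is what the round-trip tests assert.  Counts
  for the packaged frequency table are the unique integers whose frequency
  rounds to each printed 3-decimal value (e.g. 135/202 → 0.668).
* **Inverse-designed reference** — for each desired substitution
  (ref_aa, position, alt_aa, VCF alleles, strand), a codon pair differing
  at exactly one base with the required base change on the transcript
  strand is searched; the lexicographically smallest feasible pair is used,
  so design needs no seed.  Pairs with no single-nucleotide path are
  reported as infeasible, never silently altered.  Each variant lands on
  its own small contig (~250–900 bp: 60 bp flanks, glycine-codon filler,
  40 bp introns); real genomic coordinates are kept only as metadata.
  Optional layout features add a second splice form shifted by a chosen
  codon count (reproducing dual HGVSp labels) or an exon junction 2 bases
  past the variant (reproducing the splice-region tag).
* VCF/FASTA/GFF3 are emitted as deterministic plain text: identical spec
  and seed give byte-identical files.

What the generator does **not** emulate: linkage disequilibrium, pedigree
or breed structure, sequencing error, genotype uncertainty, multi-allelic
sites, and realistic gene architecture (filler codons are homopolymeric
glycine).  Passing tests therefore demonstrate correctness of the
annotation arithmetic and the frequency accounting, not robustness to real
sequencing artefacts.

## Verification strategy and problem sizes

The consequence caller is checked against an independent brute-force
oracle — mutate the whole contig, splice, translate both proteins, diff —
on ≥100 random multi-exon fixtures per strand, plus a mirror-symmetry
property (reverse-complement the contig, flip strand, mirror coordinates:
every call must be invariant).  The impact tables are checked row-by-row
against the packaged 54-substitution table, the frequency logic against
the packaged 48-site table and against freshly generated cohorts, and the
end-to-end join against the packaged totals (55 variants, 18 genes, 8
high-ΔMW, 15 high-Δhydropathy, 18 rare, 8 common).  All of this runs in a
few seconds; no scaled-down surrogate is needed.

## Known limitations

* The splice-region rule is a package convention (see above); other
  annotators may tag different rows.
* HGVSp output is the compact one-letter form used by the packaged tables,
  not the full three-letter `p.(…)` recommendation.
* Insertion handling is minimal by design; the packaged chrX insertion is
  carried as annotated data and never scored, matching its source.
* The `paper` hydropathy scale exists only to reproduce its source table;
  analyses of new cohorts should use `consensus`.
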