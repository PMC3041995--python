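# Methods

## Scope and model of the data

`haplopipe` operates on the data model of a targeted Sanger
re-sequencing survey. A single genomic region has one reference
sequence. The region is re-sequenced in *n* individuals as one or more
**contigs** — each contig being the set of aligned reads from all
individuals obtained with one sequencing primer (or a forward/reverse
pair) — with a minimum individual coverage of two reads per contig.
PolyPhred-class software reports, per contig, the polymorphic positions
and each read's genotype call at those positions. Downstream,
population-genetics software needs (a) a rectangular genotype matrix,
(b) PHASE/fastPHASE input for haplotype inference, and (c) full-length
per-haplotype sequences. The pipeline performs only coordinate and
format transformations plus consistency checking; it never calls
genotypes and never infers phase.

## Coordinates and conventions

All reference coordinates are 1-based, fully closed, on the forward
strand. A contig-local position *p* maps to the reference as
`ref_pos = p + reference_offset`; offsets are explicit inputs in each
report header (the historical workflow carried them implicitly in the
assembly). Contigs are assumed co-directional with the reference;
reverse-strand contigs and indels are out of scope. Sites are strictly
biallelic: two contigs disagreeing on an alt allele at the same
reference position is an error, not a third allele, and must be
resolved upstream. Diploid genotypes are unordered; the canonical
serialization order is alphabetical. A read's call is whole or missing
(`?/?`) — half-calls are rejected at parse time.

## Input dialect

No normative grammar exists for PolyPhred report files, and real ones
vary by program version. The package therefore defines an explicit,
section-based dialect (`BEGIN_CONTIG … END_CONTIG` with
`BEGIN_POLYMORPHISM`/`BEGIN_GENOTYPE` blocks, whitespace-delimited
fields, `#` comments), one contig per file, and keeps the parser
tolerant of unrecognised lines outside sections (they are counted, not
fatal). That single parser is the adapter point for version-specific
dialects. Score filtering (`min_score`) defaults to 0 — quality control
is assumed to have happened before the pipeline — and exists as a
convenience only.

SDAT is likewise pinned down here: a TSV whose header is `ID` followed
by 1-based reference positions, one row per individual, diploid cells
`X/Y` in alphabetical order, haploid cells a single base, missing `?/?`
or `?`. Ploidy is inferred from token shape on read. The format stores
positions but not allele pairs; when a run starts from SDAT, the
ref/alt pair per column is reconstructed against the reference (ref
allele = reference base; alt = the single other observed allele; more
than two observed alleles, or two observed alleles neither of which
matches the reference base, is a reference-mismatch error).

## Cross-read consistency

Reads are grouped by individual via a single-capture-group rule on the
read name; the default captures the maximal prefix before the first
`_` or `.`. For each (individual, site) cell, all covering non-missing
read calls are compared as unordered genotypes. Unanimity gives the
cell; disagreement — dominated in practice by heterozygote miscalls —
is recorded in the inconsistency report and resolved by policy:

- `strict`: abort, listing every conflict (for workflows that demand
  chromatogram re-inspection before proceeding);
- `missing` (default): set the cell fully missing — conservative, the
  irreproducible call is dropped but the individual is kept;
- `best_score`: keep the genotype of the highest-scoring read; a score
  tie between disagreeing reads falls back to missing.

Resolution never touches cells without conflicts, and the matrix is
invariant to the order in which reads arrive. Haploid mode requires
every read call homozygous; any heterozygous call is an error naming
the offending reads, since a haploid heterozygote can only be an
artifact.

## PHASE boundary

PHASE input is the classic layout: individual count, locus count, a
`P` line of positions, an `S`-per-locus type line, then per individual
an id line and two unphased allele rows (alphabetical; missing `?`).
fastPHASE accepts the identical file, so fastPHASE support is input
identity; its output is not parsed. From PHASE output only the
`BEGIN BESTPAIRS1` section is consumed — the point-estimate haplotype
pair is all reconstruction needs; posteriors and recombination
estimates are ignored. Individual headers are keyed on `#` (id = text
after `#`) because the surrounding tokens vary across PHASE versions;
`(A)` marks phase-uncertain and `[A]` imputed alleles, which are
unwrapped and flagged per (individual, position). Parsed haplotypes
are validated against the genotype matrix: same individual set, same
vector length, and the unordered pair at each site must reproduce the
non-missing matrix genotype.

## Reconstruction

Each haplotype is spliced into the reference: every position outside
the segregating-site list is the reference base; each site position
carries the haplotype's allele, which must belong to the site's
declared pair. Records span the full reference length by default —
the safe choice when the extent of actually-sequenced subregions is
unknown — with an optional BED mask (0-based half-open, converted to
the internal 1-based closed convention) that replaces un-sequenced
spans with `N` for exon-only designs. Missing alleles that survive to
reconstruction (possible on the haploid path, which has no imputation
step) render as `N`. Names are `<sample>_hap1`/`_hap2` (diploid) or
`<sample>` (haploid); FASTA is written with 60-column wrapping.

## Routing and verification

The route table is explicit: diploid `polyphred→sdat`,
`polyphred→phase_in`, `sdat→phase_in`, `phase_out→fasta`; haploid
additionally `polyphred→fasta` and `sdat→fasta`. Diploid
`polyphred→fasta` is refused with a message naming the manual PHASE
step — the pipeline will not pretend to phase. Before any step runs,
every input file is classified by structural signature (section
keywords, header shape; never the file extension) and rejected on
mismatch, so a mis-supplied file can never be half-processed. Runs
contain no randomness and embed no timestamps or absolute paths in
outputs, making reruns byte-identical.

## Synthetic data generator

The fixtures module simulates the study the pipeline is designed for:
a uniform-random reference; non-overlapping contig blocks with
non-trivial offsets; sites sampled without replacement inside each
contig span with alt ≠ ref; haplotype alleles drawn independently per
chromosome with alt-allele probability equal to the minor allele
frequency; reads that copy their individual's true genotype.
Defaults: 5000 bp reference, 20 individuals, diploid, 3 contigs × 5
sites, 2 reads per individual per contig (the recommended minimum
coverage), MAF 0.2 — a deliberately small survey of the size the tool
chain targets; MAF 0.2 keeps most sites visibly polymorphic in a
20-individual sample without being unrealistically common.

Planted errors operate at the (individual, site) cell level, with
conflict and missing sets disjoint by construction. A conflict flips
exactly one read's genotype deterministically (heterozygote → ref
homozygote, the common real miscall; homozygote → heterozygote), so
the cell's reads provably disagree and the expected inconsistency
report equals the planted set. A missing cell blanks every read of
that individual there, so the consolidated cell is provably missing.
The simulated PHASE output serialises the true haplotype pairs (with
optional wrapping of every allele to exercise flag stripping), standing
in for the external PHASE run.

Haplotypes are drawn site-independently — there is no linkage
disequilibrium, no coalescent genealogy, no sequencing-error model at
the trace level, and sites are ascertained perfectly. Passing tests
therefore demonstrate that the *transformations* are exact (round
trips, coordinate arithmetic, conflict recovery, conservation of
monomorphic sites), not that any inference performs well on real data;
the package performs no inference. Test and acceptance runs use scaled
study sizes (600 bp / 8 individuals for multi-seed sweeps; the full
default design for the master round trip), sizes chosen as
representative smallest-interesting cases.

## Numerical and degenerate-input choices

- Individuals are sorted lexicographically; merge results are
  independent of report order; ties in `best_score` go to missing.
- An empty genotype section is valid (an amplicon monomorphic in this
  batch); an empty site list passes reference verification vacuously.
- Identical duplicate read calls from overlapping contigs deduplicate
  silently; discordant duplicates are an error.
- `detect_format` returns `unknown` as a value, never an error.
- The generator validates its parameters (ploidy ∈ {1,2}, coverage ≥ 2,
  MAF ∈ (0, 0.5], rates ∈ [0,1), sites fitting inside contig blocks).

## Known limitations

Reverse-strand contigs, indels, multiallelic sites, genotype
likelihoods, pedigree checks, IUPAC-ambiguity consensus output and
Haploview export are out of scope. The PolyPhred dialect is normative
for this package rather than byte-compatible with any specific
historical PolyPhred version; adapting a real report means writing a
small translator to the documented dialect. fastPHASE output is not
parsed. The observational miscall rates reported for real chromatogram
data are properties of wet-lab datasets and are not reproducible from
synthetic data; nothing in this package estimates them.
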