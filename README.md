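# haplopipe

A bridge pipeline for Sanger re-sequencing population genetics studies.

Targeted re-sequencing surveys call genotypes with the
Phred-Phrap-Consed-PolyPhred tool chain and analyse the resulting
sequences with population-genetics software such as DNAsp. Between
those two endpoints sits a set of small, error-prone data-handling
tasks: aligning per-amplicon contigs onto one shared reference,
cross-checking the genotype calls of the ≥2 reads covering each
individual, tabulating genotypes, preparing input for the PHASE /
fastPHASE haplotype-inference programs, and turning PHASE's
segregating-sites-only answer back into full-length sequences.
`haplopipe` automates exactly those tasks.

What it does:

1. **Consolidation** — parses per-contig PolyPhred-style polymorphism
   and genotype reports and maps every contig-local position *p* to the
   shared reference via `ref_pos = p + offset` (1-based, closed,
   forward strand), merging all contigs into one call set and checking
   every declared reference allele against the reference FASTA.
2. **Genotype matrix** — groups reads by individual (the sample id is a
   configurable capture rule on the read name), flags every
   (individual, site) where reads disagree — the heterozygote-miscall
   failure mode — and resolves conflicts by policy (`strict`,
   `missing`, `best_score`). The matrix is written as **SDAT**: a TSV
   with individuals as rows and segregating sites as columns.
3. **PHASE bridge** — writes PHASE/fastPHASE input (two unphased allele
   rows per diploid individual) and parses the `BESTPAIRS1` section of
   PHASE output back into per-individual haplotype pairs, stripping and
   flagging `( )` phase-uncertain and `[ ]` imputed alleles.
4. **Reconstruction** — splices each haplotype's alleles into the
   reference to produce full-length sequences (monomorphic sites
   included) and writes DNAsp-ready FASTA (`<sample>_hap1/_hap2`, or
   `<sample>` for haploid data, where genotypes are haplotypes and no
   phasing is needed).

Running PHASE itself (and DNAsp) stays external and manual: the diploid
route deliberately stops at the PHASE input/output boundary. Every
input file is verified by structural signature before any processing,
and every run writes an audit log plus a machine-readable inconsistency
report. Runs are fully deterministic.

## Worked example

Generate a synthetic study (5 kb reference, 20 diploid individuals,
3 amplicon contigs × 5 sites, 2 reads per individual per contig) and
run the first pipeline half:

```sh
haplopipe fixtures generate --seed 1 --out demo/data
haplopipe run --from polyphred --to sdat \
    --reference demo/data/reference.fasta --out demo/half1 \
    demo/data/ctg0*.polyphred
```

```
[merge_reports] 3 contig(s) -> 15 sites, 600 read genotypes
[verify_reference] 15 site(s) consistent with refseq
[build_matrix] 20 individuals, 0 inconsistency(ies), policy=missing
[write_sdat] matrix.sdat
```

The 3 × 5 contig sites merge into 15 reference-coordinate columns; 600
read genotypes (20 individuals × 2 reads × 15 sites) collapse into 300
matrix cells with zero cross-read conflicts (none were planted).
`matrix.sdat` starts:

```
ID      357     369     402     514     1054    2212    ...
IND001  G/G     C/C     G/G     C/C     G/G     A/G     ...
IND002  G/G     C/T     G/G     A/A     C/G     A/A     ...
```

After the (here simulated) external PHASE run, the second half rebuilds
the full-length sequences:

```sh
haplopipe run --from phase_out --to fasta \
    --reference demo/data/reference.fasta --matrix demo/half1/matrix.sdat \
    --out demo/half2 demo/data/phase_output.txt
```

```
[parse_phase_output] 20 individuals, 15 loci, 0 flagged allele position(s)
[reconstruct_sequences] 40 full-length sequence(s)
[write_fasta] haplotypes.fasta
```

`haplotypes.fasta` holds 40 records (two 5000 bp haplotypes per
individual) that differ from the reference only at the 15 segregating
sites — ready for DNAsp-class analysis. On this synthetic study the
output is byte-identical to the generator's ground-truth FASTA.

A diploid `--from polyphred --to fasta` request is refused with an
explanation: haplotypes must first be inferred by running PHASE on the
emitted `phase_input.txt`. Haploid studies (`--ploidy 1`) route
straight through to FASTA.

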