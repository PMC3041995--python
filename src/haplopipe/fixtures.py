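"""Synthetic ground-truth datasets for round-trip testing.

The generator emulates a targeted Sanger re-sequencing study: one
reference region, several non-overlapping primer contigs with known
reference offsets, n individuals each covered by at least two reads per
contig (forward/reverse), biallelic sites with a configurable minor
allele frequency, and planted read-level genotype conflicts and missing
calls.  Haplotypes are drawn site-independently (no linkage
disequilibrium): the pipeline under test performs coordinate and format
transformations, never phase inference, so population-genetic realism
adds nothing to coverage.

Conflicts are planted as read-level genotype flips — the heterozygote
miscall failure mode that motivates cross-read consistency checking.
A planted-missing cell blanks every read of that individual at that
site, so the consolidated matrix cell is missing.  The two planted sets
are disjoint by construction.

Everything is driven by one integer seed; identical parameters and seed
produce byte-identical emitted files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import InvalidParams
from .matrix import write_sdat
from .model import (
    MISSING,
    ContigReport,
    GenotypeMatrix,
    ReadGenotypeRecord,
    ReferenceSequence,
    SiteRecord,
)
from .polyphred import write_polyphred_report
from .reconstruct import ReconstructedRecord, write_fasta

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureParams:
    """Study-design parameters of a simulated re-sequencing dataset.

    Defaults model a small diploid survey: a 5 kb region, 20
    individuals, 3 amplicons of 5 sites each, and the recommended
    minimum individual coverage of two reads per contig.
    """

    seed: int = 0
    ref_length: int = 5000
    n_individuals: int = 20
    ploidy: int = 2
    n_contigs: int = 3
    sites_per_contig: int = 5
    reads_per_individual_per_contig: int = 2
    minor_allele_freq: float = 0.2
    missing_rate: float = 0.0
    conflict_rate: float = 0.0
    reference_id: str = "refseq"

    def validate(self) -> None:
        if self.ploidy not in (1, 2):
            raise InvalidParams(f"ploidy must be 1 or 2: {self.ploidy}")
        if self.n_individuals < 1 or self.n_contigs < 1 or self.sites_per_contig < 1:
            raise InvalidParams("need >=1 individual, contig and site per contig")
        if self.reads_per_individual_per_contig < 2:
            raise InvalidParams("minimum individual coverage is 2 reads per contig")
        if not 0 < self.minor_allele_freq <= 0.5:
            raise InvalidParams(f"minor_allele_freq must be in (0, 0.5]: {self.minor_allele_freq}")
        for name in ("missing_rate", "conflict_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise InvalidParams(f"{name} must be in [0, 1): {v}")
        if self.n_contigs * self.sites_per_contig > self.ref_length:
            raise InvalidParams("total sites exceed reference length")
        if self.ref_length // self.n_contigs < self.sites_per_contig + 2:
            raise InvalidParams("contig blocks too short for the requested sites")


@dataclass
class FixtureBundle:
    """Ground truth plus every emitted file for one simulated dataset."""

    params: FixtureParams
    reference: ReferenceSequence
    site_positions: list[int]  # reference coordinates, increasing
    site_alleles: list[tuple[str, str]]  # (ref, alt) per position
    truth_hap_alleles: dict[str, tuple[list[str], ...]]  # site alleles per chromosome
    truth_haplotypes: dict[str, tuple[str, ...]]  # full-length sequences
    truth_matrix: GenotypeMatrix
    reports: list[ContigReport]
    planted_conflicts: set[tuple[str, int]]
    planted_missing: set[tuple[str, int]]
    emitted_files: dict[str, str] = field(default_factory=dict)

    @property
    def individuals(self) -> list[str]:
        return self.truth_matrix.individuals

    def truth_records(self) -> list[ReconstructedRecord]:
        records = []
        for ind in self.individuals:
            seqs = self.truth_haplotypes[ind]
            for k, seq in enumerate(seqs, start=1):
                name = f"{ind}_hap{k}" if len(seqs) == 2 else ind
                records.append(ReconstructedRecord(name, seq))
        return records

    def manifest(self) -> str:
        """JSON truth manifest consumed by the test suite."""
        return json.dumps(
            {
                "params": asdict(self.params),
                "individuals": self.individuals,
                "site_positions": self.site_positions,
                "site_alleles": [list(p) for p in self.site_alleles],
                "planted_conflicts": sorted(map(list, self.planted_conflicts)),
                "planted_missing": sorted(map(list, self.planted_missing)),
                "n_genotype_records": sum(len(r.genotypes) for r in self.reports),
            },
            indent=1,
        )


def simulate_dataset(params: FixtureParams) -> FixtureBundle:
    """Draw a complete synthetic dataset from one seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    reference = ReferenceSequence(
        id=params.reference_id,
        bases="".join(rng.choice(_BASES, size=params.ref_length)),
    )

    # contig spans: one per equal block, random start within the block's
    # first quarter so offsets are non-trivial, span to the block end
    block = params.ref_length // params.n_contigs
    contigs = []  # (name, offset, length)
    site_positions: list[int] = []
    site_of_contig: dict[str, list[int]] = {}
    for c in range(params.n_contigs):
        block_start = c * block + 1
        block_end = (c + 1) * block
        margin = max(1, (block - params.sites_per_contig) // 4)
        start = block_start + int(rng.integers(0, margin))
        name = f"ctg{c + 1:02d}"
        length = block_end - start + 1
        contigs.append((name, start - 1, length))
        span = np.arange(start, block_end + 1)
        chosen = np.sort(rng.choice(span, size=params.sites_per_contig, replace=False))
        site_of_contig[name] = [int(p) for p in chosen]
        site_positions.extend(site_of_contig[name])
    site_positions.sort()

    site_alleles: list[tuple[str, str]] = []
    allele_of_pos: dict[int, tuple[str, str]] = {}
    for pos in site_positions:
        ref_base = reference.base_at(pos)
        others = [b for b in "ACGT" if b != ref_base]
        alt = others[int(rng.integers(0, 3))]
        site_alleles.append((ref_base, alt))
        allele_of_pos[pos] = (ref_base, alt)

    individuals = [f"IND{i + 1:03d}" for i in range(params.n_individuals)]
    L = len(site_positions)

    # haplotype alleles: alt with probability = minor allele frequency,
    # independently per chromosome and site
    truth_hap_alleles: dict[str, tuple[list[str], ...]] = {}
    truth_haplotypes: dict[str, tuple[str, ...]] = {}
    for ind in individuals:
        vectors = []
        seqs = []
        for _ in range(params.ploidy):
            draws = rng.random(L) < params.minor_allele_freq
            alleles = [
                allele_of_pos[pos][1] if hit else allele_of_pos[pos][0]
                for pos, hit in zip(site_positions, draws)
            ]
            vectors.append(alleles)
            seq = list(reference.bases)
            for pos, a in zip(site_positions, alleles):
                seq[pos - 1] = a
            seqs.append("".join(seq))
        truth_hap_alleles[ind] = tuple(vectors)
        truth_haplotypes[ind] = tuple(seqs)

    # unphased projection at the planted sites
    truth_calls = [
        [
            tuple(sorted(v[j] for v in truth_hap_alleles[ind]))
            for j in range(L)
        ]
        for ind in individuals
    ]
    truth_matrix = GenotypeMatrix(
        reference_id=params.reference_id,
        ploidy=params.ploidy,
        positions=list(site_positions),
        site_alleles=list(site_alleles),
        individuals=list(individuals),
        calls=truth_calls,
    )
    truth_matrix.validate()

    # plant errors at the (individual, site) cell level, disjoint sets
    conflict_mask = rng.random((params.n_individuals, L)) < params.conflict_rate
    missing_mask = (rng.random((params.n_individuals, L)) < params.missing_rate) & ~conflict_mask
    planted_conflicts: set[tuple[str, int]] = set()
    planted_missing: set[tuple[str, int]] = set()
    flip_read = rng.integers(
        0, params.reads_per_individual_per_contig, size=(params.n_individuals, L)
    )

    pos_index = {p: j for j, p in enumerate(site_positions)}
    reports: list[ContigReport] = []
    for name, offset, _length in contigs:
        sites = [
            SiteRecord(pos - offset, *allele_of_pos[pos], 99) for pos in site_of_contig[name]
        ]
        genotypes: list[ReadGenotypeRecord] = []
        for i, ind in enumerate(individuals):
            for r in range(params.reads_per_individual_per_contig):
                read_name = f"{ind}_{name}R{r + 1}.ab1"
                score = int(rng.integers(30, 99))
                for pos in site_of_contig[name]:
                    j = pos_index[pos]
                    true_cell = truth_calls[i][j]
                    if params.ploidy == 1:
                        a1 = a2 = true_cell[0]
                    else:
                        a1, a2 = true_cell
                    if missing_mask[i, j]:
                        planted_missing.add((ind, pos))
                        a1 = a2 = MISSING
                    elif conflict_mask[i, j] and r == flip_read[i, j]:
                        planted_conflicts.add((ind, pos))
                        a1, a2 = _flip_genotype((a1, a2), allele_of_pos[pos], params.ploidy)
                    genotypes.append(
                        ReadGenotypeRecord(pos - offset, read_name, a1, a2, score)
                    )
        report = ContigReport(
            contig_name=name,
            reference_id=params.reference_id,
            reference_offset=offset,
            sites=sites,
            genotypes=genotypes,
        )
        report.validate()
        reports.append(report)

    bundle = FixtureBundle(
        params=params,
        reference=reference,
        site_positions=site_positions,
        site_alleles=site_alleles,
        truth_hap_alleles=truth_hap_alleles,
        truth_haplotypes=truth_haplotypes,
        truth_matrix=truth_matrix,
        reports=reports,
        planted_conflicts=planted_conflicts,
        planted_missing=planted_missing,
    )
    bundle.emitted_files = _emit_files(bundle)
    return bundle


def _flip_genotype(
    cell: tuple[str, str], pair: tuple[str, str], ploidy: int
) -> tuple[str, str]:
    """Replace a genotype with a different one over the same allele pair.

    Deterministic: heterozygote miscalls collapse to ref-homozygous (the
    commonest real failure), homozygotes flip to the heterozygote (or the
    other homozygote in haploid mode).
    """
    ref, alt = pair
    if ploidy == 1:
        other = alt if cell[0] == ref else ref
        return other, other
    het = tuple(sorted((ref, alt)))
    if tuple(sorted(cell)) == het:
        return ref, ref
    return het


def _emit_files(bundle: FixtureBundle) -> dict[str, str]:
    files = {
        "reference.fasta": write_fasta(
            [ReconstructedRecord(bundle.reference.id, bundle.reference.bases)]
        ),
        "truth.sdat": write_sdat(bundle.truth_matrix),
        "truth.fasta": write_fasta(bundle.truth_records()),
    }
    for report in bundle.reports:
        files[f"{report.contig_name}.polyphred"] = write_polyphred_report(report)
    if bundle.params.ploidy == 2:
        files["phase_output.txt"] = emit_phase_output(bundle)
    return files


def emit_phase_output(bundle: FixtureBundle, wrap_all: bool = False) -> str:
    """Serialise the truth haplotypes as a PHASE best-pairs section.

    Stands in for the manual PHASE run between the two pipeline halves.
    With *wrap_all* every allele is parenthesised (phase-uncertain) to
    exercise wrapper stripping in the parser.
    """
    if bundle.params.ploidy != 2:
        raise InvalidParams("PHASE output is only defined for diploid data")
    lines = [
        "Summary of best reconstruction (simulated)",
        "",
        "BEGIN BESTPAIRS1",
    ]
    for ind in bundle.individuals:
        h1, h2 = bundle.truth_hap_alleles[ind]
        lines.append(f"0 #{ind}")
        for vec in (h1, h2):
            toks = [f"({a})" if wrap_all else a for a in vec]
            lines.append(" ".join(toks))
    lines.append("END BESTPAIRS1")
    return "\n".join(lines) + "\n"


def write_bundle(bundle: FixtureBundle, out_dir) -> list[str]:
    """Write every emitted file under *out_dir*; returns the file names."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, text in sorted(bundle.emitted_files.items()):
        (out / name).write_text(text)
    (out / "manifest.json").write_text(bundle.manifest())
    return sorted(bundle.emitted_files) + ["manifest.json"]
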