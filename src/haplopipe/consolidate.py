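"""Reference-coordinate mapping and merging of contig reports.

Each amplicon/primer contig is aligned to one shared reference for the
whole genomic region; a contig-local 1-based position ``p`` maps to
reference position ``p + reference_offset``.  Merging the mapped contigs
yields a single consolidated call set whose site coordinates are
unambiguous across the region, which is what makes downstream genotype
matrices and haplotype splicing well defined.
"""

from __future__ import annotations

from typing import Iterable, TextIO

from Bio import SeqIO

from .errors import (
    AlleleConflict,
    DuplicateReadCall,
    MalformedFasta,
    OutOfRange,
    ReferenceIdMismatch,
    ReferenceMismatch,
)
from .model import (
    ConsolidatedCallSet,
    ContigReport,
    GenotypeMatrix,
    MappedGenotype,
    MappedSite,
    ReferenceSequence,
)


def read_reference_fasta(handle: TextIO | str) -> ReferenceSequence:
    """Load a single-record reference FASTA."""
    records = list(SeqIO.parse(handle, "fasta"))
    if len(records) != 1:
        raise MalformedFasta(
            f"reference FASTA must contain exactly one record, found {len(records)}"
        )
    rec = records[0]
    return ReferenceSequence(id=rec.id, bases=str(rec.seq).upper())


def map_to_reference(
    report: ContigReport, reference: ReferenceSequence | None = None
) -> tuple[list[MappedSite], list[MappedGenotype]]:
    """Lift one contig's sites and genotypes to reference coordinates.

    Output is sorted by ref_pos.  If a reference is supplied, positions
    beyond its length raise :class:`OutOfRange`.
    """
    off = report.reference_offset
    sites = [
        MappedSite(
            ref_pos=s.contig_pos + off,
            ref_allele=s.ref_allele,
            alt_allele=s.alt_allele,
            source_contigs={report.contig_name},
        )
        for s in report.sites
    ]
    genotypes = [
        MappedGenotype(g.contig_pos + off, g.read_name, g.allele1, g.allele2, g.score)
        for g in report.genotypes
    ]
    if reference is not None:
        too_far = [s.ref_pos for s in sites if s.ref_pos > len(reference)]
        if too_far:
            raise OutOfRange(
                f"contig {report.contig_name}: mapped positions {too_far} exceed "
                f"reference {reference.id} length {len(reference)}"
            )
    sites.sort(key=lambda s: s.ref_pos)
    genotypes.sort(key=lambda g: (g.ref_pos, g.read_name))
    return sites, genotypes


def merge_reports(
    reports: Iterable[ContigReport], reference: ReferenceSequence | None = None
) -> ConsolidatedCallSet:
    """Merge mapped contig reports into one consolidated call set.

    Sites at the same reference position fuse when their allele pairs
    agree (source contigs union); disagreement is an
    :class:`AlleleConflict` listing every conflicting position, because
    the pipeline targets biallelic loci.  Identical duplicate read calls
    from overlapping contigs deduplicate silently; discordant duplicates
    raise :class:`DuplicateReadCall`.  The merge is order-independent.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("merge_reports needs at least one report")
    ref_ids = {r.reference_id for r in reports}
    if len(ref_ids) > 1:
        raise ReferenceIdMismatch(f"reports declare different references: {sorted(ref_ids)}")
    if reference is not None and reference.id not in ref_ids:
        raise ReferenceIdMismatch(
            f"reports declare reference {sorted(ref_ids)[0]!r} but FASTA is {reference.id!r}"
        )

    site_by_pos: dict[int, MappedSite] = {}
    conflicts: list[tuple[int, str]] = []
    call_by_key: dict[tuple[int, str], MappedGenotype] = {}

    for report in sorted(reports, key=lambda r: r.contig_name):
        sites, genotypes = map_to_reference(report, reference)
        for s in sites:
            existing = site_by_pos.get(s.ref_pos)
            if existing is None:
                site_by_pos[s.ref_pos] = s
            elif (existing.ref_allele, existing.alt_allele) == (s.ref_allele, s.alt_allele):
                existing.source_contigs |= s.source_contigs
            else:
                conflicts.append(
                    (
                        s.ref_pos,
                        f"{sorted(existing.source_contigs)} says "
                        f"{existing.ref_allele}>{existing.alt_allele}, "
                        f"{sorted(s.source_contigs)} says {s.ref_allele}>{s.alt_allele}",
                    )
                )
        for g in genotypes:
            key = (g.ref_pos, g.read_name)
            prev = call_by_key.get(key)
            if prev is None:
                call_by_key[key] = g
            elif prev.sorted_alleles != g.sorted_alleles:
                raise DuplicateReadCall(
                    f"read {g.read_name} at ref_pos {g.ref_pos} called "
                    f"{prev.allele1}/{prev.allele2} in one contig and "
                    f"{g.allele1}/{g.allele2} in another"
                )
            # identical duplicate: keep the first silently

    if conflicts:
        raise AlleleConflict(sorted(conflicts))

    return ConsolidatedCallSet(
        reference_id=sorted(ref_ids)[0],
        sites=[site_by_pos[p] for p in sorted(site_by_pos)],
        read_genotypes=sorted(call_by_key.values(), key=lambda g: (g.ref_pos, g.read_name)),
    )


def conflict_report_text(exc: AlleleConflict) -> str:
    """Machine-parsable conflict report: tab-separated ref_pos, kind, details."""
    lines = [f"{pos}\tallele_conflict\t{detail}" for pos, detail in exc.conflicts]
    return "\n".join(lines) + "\n"


def verify_reference_consistency(
    call_set: ConsolidatedCallSet, reference: ReferenceSequence
) -> None:
    """Check every site's ref_allele against the reference base (1-based).

    A mismatch signals a wrong offset or wrong reference file; all
    mismatching sites are listed in the raised :class:`ReferenceMismatch`.
    An empty site list passes vacuously.
    """
    if call_set.reference_id != reference.id:
        raise ReferenceIdMismatch(
            f"call set is against {call_set.reference_id!r}, reference is {reference.id!r}"
        )
    mismatches = []
    for site in call_set.sites:
        if site.ref_pos > len(reference):
            mismatches.append((site.ref_pos, site.ref_allele, "<beyond reference end>"))
        elif reference.base_at(site.ref_pos) != site.ref_allele:
            mismatches.append((site.ref_pos, site.ref_allele, reference.base_at(site.ref_pos)))
    if mismatches:
        raise ReferenceMismatch(mismatches)


def infer_site_alleles(matrix: GenotypeMatrix, reference: ReferenceSequence) -> GenotypeMatrix:
    """Fill in ref/alt allele pairs for a matrix read from SDAT.

    SDAT stores positions only, so the allele pair is recovered from the
    reference (ref allele = reference base at the position) plus the
    alleles observed in the matrix column.  More than two observed
    alleles, or two observed alleles neither of which is the reference
    base, contradict the biallelic model and raise
    :class:`ReferenceMismatch`.  Returns the same matrix, mutated.
    """
    if matrix.reference_id and matrix.reference_id != reference.id:
        raise ReferenceIdMismatch(
            f"matrix is against {matrix.reference_id!r}, reference is {reference.id!r}"
        )
    mismatches = []
    site_alleles: list[tuple[str, str]] = []
    for j, pos in enumerate(matrix.positions):
        if pos > len(reference):
            raise OutOfRange(f"position {pos} exceeds reference length {len(reference)}")
        ref_base = reference.base_at(pos)
        observed = {
            a for row in matrix.calls for a in row[j] if a != "?"
        }
        alts = observed - {ref_base}
        if len(alts) > 1:
            mismatches.append((pos, "/".join(sorted(observed)), ref_base))
            site_alleles.append((ref_base, sorted(alts)[0]))
        elif alts:
            site_alleles.append((ref_base, next(iter(alts))))
        else:
            # column monomorphic reference (or fully missing): degenerate
            # biallelic pair with a placeholder alt
            site_alleles.append((ref_base, next(iter(set("ACGT") - {ref_base}))))
    if mismatches:
        raise ReferenceMismatch(mismatches)
    matrix.site_alleles = site_alleles
    matrix.reference_id = matrix.reference_id or reference.id
    return matrix
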