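"""Exception hierarchy for the pipeline.

Every error corresponds to a distinct failure class a user can act on:
malformed inputs, coordinate/reference disagreements, genotype conflicts,
or an impossible routing request.  Errors carry enough context (line
numbers, positions, read names) to locate the offending record.
"""

from __future__ import annotations


class HaplopipeError(Exception):
    """Base class for all pipeline errors."""


class MalformedReport(HaplopipeError):
    """A PolyPhred-style contig report violates the dialect grammar."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class MalformedSdat(HaplopipeError):
    """An SDAT genotype matrix file is structurally invalid."""


class MalformedFasta(HaplopipeError):
    """A FASTA file could not be parsed."""


class DuplicateName(HaplopipeError):
    """Two FASTA records share a name on write."""


class OutOfRange(HaplopipeError):
    """A mapped position falls outside the declared reference."""


class ReferenceIdMismatch(HaplopipeError):
    """Contig reports declare different reference identifiers."""


class AlleleConflict(HaplopipeError):
    """Overlapping contigs disagree on a site's allele pair."""

    def __init__(self, conflicts):
        # conflicts: list of (ref_pos, detail) tuples
        self.conflicts = list(conflicts)
        lines = ", ".join(f"pos {p}: {d}" for p, d in self.conflicts)
        super().__init__(f"allele conflict at {len(self.conflicts)} site(s): {lines}")


class DuplicateReadCall(HaplopipeError):
    """The same (position, read) arrives twice with different alleles."""


class ReferenceMismatch(HaplopipeError):
    """Declared site alleles contradict the reference sequence."""

    def __init__(self, mismatches):
        # mismatches: list of (ref_pos, expected, found)
        self.mismatches = list(mismatches)
        lines = ", ".join(
            f"pos {p}: site says {e}, reference has {f}" for p, e, f in self.mismatches
        )
        super().__init__(f"reference mismatch at {len(self.mismatches)} site(s): {lines}")


class UnmatchedReadName(HaplopipeError):
    """The sample-id rule failed to match a read name."""


class InconsistentGenotypes(HaplopipeError):
    """Reads of the same individual disagree (strict policy)."""

    def __init__(self, entries):
        self.entries = list(entries)
        super().__init__(
            f"{len(self.entries)} genotype inconsistencies (policy=strict): "
            + "; ".join(f"{e.sample_id}@{e.ref_pos}" for e in self.entries)
        )


class HeterozygousInHaploid(HaplopipeError):
    """A heterozygous call appeared in haploid-mode data."""

    def __init__(self, offenders):
        # offenders: list of (read_name, ref_pos, allele1, allele2)
        self.offenders = list(offenders)
        lines = ", ".join(f"{r}@{p}={a1}/{a2}" for r, p, a1, a2 in self.offenders)
        super().__init__(f"heterozygous call(s) in haploid data: {lines}")


class EmptyMatrix(HaplopipeError):
    """The genotype matrix has no individuals or no sites."""


class HaploidUnsupported(HaplopipeError):
    """Haploid data needs no phasing; PHASE input is undefined for it."""


class MissingSection(HaplopipeError):
    """Expected section (e.g. BESTPAIRS1) absent from a PHASE output file."""


class IndividualMismatch(HaplopipeError):
    """PHASE output individuals differ from the genotype matrix."""


class LengthMismatch(HaplopipeError):
    """A haplotype row has the wrong number of loci."""


class AlleleMismatch(HaplopipeError):
    """A parsed haplotype pair contradicts the unphased matrix genotype."""


class AlleleOutsideSiteSet(HaplopipeError):
    """A haplotype allele is not one of the site's two declared alleles."""


class NoRoute(HaplopipeError):
    """No automated path exists between the requested start and end points."""


class FormatMismatch(HaplopipeError):
    """An input file's detected format differs from the plan's expectation."""


class InvalidParams(HaplopipeError):
    """Fixture simulation parameters are inconsistent."""
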