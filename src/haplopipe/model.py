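"""Core in-memory containers shared across the pipeline.

Coordinate convention throughout: 1-based, fully closed, forward strand
of the reference.  A contig-local position ``p`` maps to reference
position ``p + reference_offset``.  Diploid genotypes are unphased
unordered pairs; the canonical serialization order is alphabetical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NUCLEOTIDES = frozenset("ACGT")
MISSING = "?"
ALLELE_ALPHABET = NUCLEOTIDES | {MISSING}


@dataclass(frozen=True)
class SiteRecord:
    """One polymorphic site on a contig consensus."""

    contig_pos: int
    ref_allele: str
    alt_allele: str
    score: int

    def __post_init__(self):
        if self.contig_pos < 1:
            raise ValueError(f"contig_pos must be >= 1, got {self.contig_pos}")
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise ValueError(
                f"alleles must be in {{A,C,G,T}}: {self.ref_allele}/{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.contig_pos}")
        if not 0 <= self.score <= 99:
            raise ValueError(f"score out of range 0-99: {self.score}")


@dataclass(frozen=True)
class ReadGenotypeRecord:
    """One read's genotype call at one contig position.

    A call is whole or missing: if either allele is '?', both must be.
    """

    contig_pos: int
    read_name: str
    allele1: str
    allele2: str
    score: int

    def __post_init__(self):
        if self.contig_pos < 1:
            raise ValueError(f"contig_pos must be >= 1, got {self.contig_pos}")
        if not self.read_name:
            raise ValueError("read_name must be non-empty")
        if self.allele1 not in ALLELE_ALPHABET or self.allele2 not in ALLELE_ALPHABET:
            raise ValueError(f"illegal allele token: {self.allele1}/{self.allele2}")
        if (self.allele1 == MISSING) != (self.allele2 == MISSING):
            raise ValueError(
                f"half-missing call {self.allele1}/{self.allele2} for {self.read_name}"
            )
        if not 0 <= self.score <= 99:
            raise ValueError(f"score out of range 0-99: {self.score}")

    @property
    def is_missing(self) -> bool:
        return self.allele1 == MISSING

    @property
    def sorted_alleles(self) -> tuple[str, str]:
        """Canonical (alphabetical) order; genotypes are unphased."""
        return tuple(sorted((self.allele1, self.allele2)))


@dataclass
class ContigReport:
    """One contig's polymorphic sites and per-read genotype calls."""

    contig_name: str
    reference_id: str
    reference_offset: int
    sites: list[SiteRecord] = field(default_factory=list)
    genotypes: list[ReadGenotypeRecord] = field(default_factory=list)

    def validate(self) -> None:
        if self.reference_offset < 0:
            raise ValueError(f"reference_offset must be >= 0: {self.reference_offset}")
        positions = [s.contig_pos for s in self.sites]
        if positions != sorted(set(positions)) or len(positions) != len(set(positions)):
            raise ValueError("sites must be strictly increasing by contig_pos")
        by_pos = {s.contig_pos: s for s in self.sites}
        seen: set[tuple[int, str]] = set()
        for g in self.genotypes:
            if g.contig_pos not in by_pos:
                raise ValueError(
                    f"genotype at {g.contig_pos} ({g.read_name}) has no matching site"
                )
            key = (g.contig_pos, g.read_name)
            if key in seen:
                raise ValueError(f"duplicate (pos, read) pair {key}")
            seen.add(key)
            site = by_pos[g.contig_pos]
            allowed = {site.ref_allele, site.alt_allele, MISSING}
            if g.allele1 not in allowed or g.allele2 not in allowed:
                raise ValueError(
                    f"genotype {g.allele1}/{g.allele2} at {g.contig_pos} outside "
                    f"site alleles {site.ref_allele}/{site.alt_allele}"
                )


@dataclass(frozen=True)
class ReferenceSequence:
    """The shared reference for the whole re-sequenced region."""

    id: str
    bases: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("reference id must be non-empty")
        if not self.bases:
            raise ValueError("reference must have length >= 1")
        bad = set(self.bases) - set("ACGTN")
        if bad:
            raise ValueError(f"reference contains illegal characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)

    def base_at(self, ref_pos: int) -> str:
        """1-based lookup."""
        return self.bases[ref_pos - 1]


@dataclass
class MappedSite:
    """A polymorphic site in reference coordinates."""

    ref_pos: int
    ref_allele: str
    alt_allele: str
    source_contigs: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class MappedGenotype:
    """A read genotype lifted to reference coordinates."""

    ref_pos: int
    read_name: str
    allele1: str
    allele2: str
    score: int

    @property
    def is_missing(self) -> bool:
        return self.allele1 == MISSING

    @property
    def sorted_alleles(self) -> tuple[str, str]:
        return tuple(sorted((self.allele1, self.allele2)))


@dataclass
class ConsolidatedCallSet:
    """Merged, reference-coordinate sites and read genotypes across contigs."""

    reference_id: str
    sites: list[MappedSite] = field(default_factory=list)
    read_genotypes: list[MappedGenotype] = field(default_factory=list)

    def site_positions(self) -> list[int]:
        return [s.ref_pos for s in self.sites]


@dataclass
class GenotypeMatrix:
    """Individuals x segregating sites, consolidated per-individual calls.

    ``calls[i][j]`` is the genotype of ``individuals[i]`` at ``positions[j]``:
    an alphabetical allele pair for diploid data, a single-allele tuple for
    haploid.  Missing is fully missing: ('?','?') or ('?',).
    ``site_alleles`` may be None for matrices read from SDAT (the format
    stores positions only); use :func:`haplopipe.consolidate.infer_site_alleles`.
    """

    reference_id: str
    ploidy: int
    positions: list[int]
    site_alleles: list[tuple[str, str]] | None
    individuals: list[str]
    calls: list[list[tuple[str, ...]]]

    def validate(self) -> None:
        if self.ploidy not in (1, 2):
            raise ValueError(f"ploidy must be 1 or 2: {self.ploidy}")
        if self.positions != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")
        if self.site_alleles is not None and len(self.site_alleles) != len(self.positions):
            raise ValueError("site_alleles length != positions length")
        if len(self.calls) != len(self.individuals):
            raise ValueError("calls row count != individual count")
        for ind, row in zip(self.individuals, self.calls):
            if len(row) != len(self.positions):
                raise ValueError(f"row for {ind} has wrong width")
            for j, cell in enumerate(row):
                if len(cell) != self.ploidy:
                    raise ValueError(f"cell {ind}@{self.positions[j]} wrong ploidy")
                missing = [a == MISSING for a in cell]
                if any(missing) and not all(missing):
                    raise ValueError(f"half-missing cell {ind}@{self.positions[j]}")
                if self.site_alleles is not None and not any(missing):
                    allowed = set(self.site_alleles[j])
                    if not set(cell) <= allowed:
                        raise ValueError(
                            f"cell {ind}@{self.positions[j]}={cell} outside "
                            f"site alleles {sorted(allowed)}"
                        )

    def cell(self, sample_id: str, ref_pos: int) -> tuple[str, ...]:
        return self.calls[self.individuals.index(sample_id)][self.positions.index(ref_pos)]


@dataclass(frozen=True)
class InconsistencyEntry:
    """One (individual, site) where reads disagreed."""

    sample_id: str
    ref_pos: int
    read_calls: tuple[tuple[str, str, str, int], ...]  # (read, a1, a2, score)
    resolution: str  # "missing" | "best_score:<read>" | "strict"


@dataclass
class InconsistencyReport:
    """All cross-read genotype disagreements found while building a matrix."""

    entries: list[InconsistencyEntry] = field(default_factory=list)

    def conflict_cells(self) -> set[tuple[str, int]]:
        return {(e.sample_id, e.ref_pos) for e in self.entries}

    def to_text(self) -> str:
        lines = ["sample\tref_pos\treads\tresolution"]
        for e in self.entries:
            reads = ",".join(f"{r}={a1}/{a2}(q{s})" for r, a1, a2, s in e.read_calls)
            lines.append(f"{e.sample_id}\t{e.ref_pos}\t{reads}\t{e.resolution}")
        return "\n".join(lines) + "\n"


@dataclass
class HaplotypeSet:
    """Per-individual ordered allele vectors over the segregating sites.

    ``haplotypes[sample_id]`` is a tuple of one (haploid) or two (diploid)
    allele vectors, each of length ``len(positions)``.  ``phase_flags`` maps
    (sample_id, ref_pos) to 'uncertain' or 'imputed' where the PHASE output
    marked the call.
    """

    positions: list[int]
    individuals: list[str]
    haplotypes: dict[str, tuple[list[str], ...]]
    phase_flags: dict[tuple[str, int], str] = field(default_factory=dict)


@dataclass(frozen=True)
class ReconstructedRecord:
    """One full-length haplotype sequence (polymorphic + monomorphic sites)."""

    name: str
    sequence: str
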