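"""PHASE / fastPHASE bridge: input writer and best-pairs output parser.

PHASE infers haplotype phase for diploid genotypes but knows only the
segregating sites; this module writes its input from a genotype matrix
and reads its output back so the surrounding pipeline can splice the
inferred alleles into the full-length reference.

Input layout (identical for fastPHASE)::

    <number of individuals>
    <number of loci L>
    P <pos_1> ... <pos_L>
    SSS...S                 (L locus-type characters, 'S' = SNP)
    #<id>
    <allele row 1>          (L space-separated alleles)
    <allele row 2>

A diploid genotype {X, Y} is written X in row 1, Y in row 2 in
alphabetical order — PHASE treats the two input rows as unphased.
Missing alleles are '?'.

Only the ``BEGIN BESTPAIRS1`` / ``END BESTPAIRS1`` section of PHASE
output is consumed: it carries the point-estimate haplotype pair per
individual, which is all that sequence reconstruction needs.  Alleles
wrapped in ``(...)`` (phase-uncertain) or ``[...]`` (imputed) are
unwrapped and flagged.
"""

from __future__ import annotations

import io
import re
from typing import TextIO

from .errors import (
    AlleleMismatch,
    EmptyMatrix,
    HaploidUnsupported,
    IndividualMismatch,
    LengthMismatch,
    MalformedReport,
    MissingSection,
)
from .model import MISSING, NUCLEOTIDES, GenotypeMatrix, HaplotypeSet


def write_phase_input(matrix: GenotypeMatrix) -> str:
    """Serialise a diploid genotype matrix as PHASE/fastPHASE input."""
    if matrix.ploidy != 2:
        raise HaploidUnsupported(
            "haploid data needs no phasing; route it directly to reconstruction"
        )
    if not matrix.individuals or not matrix.positions:
        raise EmptyMatrix(
            f"matrix is {len(matrix.individuals)} individuals x "
            f"{len(matrix.positions)} sites; PHASE input needs at least 1 of each"
        )
    matrix.validate()
    L = len(matrix.positions)
    lines = [
        str(len(matrix.individuals)),
        str(L),
        "P " + " ".join(str(p) for p in matrix.positions),
        "S" * L,
    ]
    for ind, row in zip(matrix.individuals, matrix.calls):
        lines.append(f"#{ind}")
        sorted_cells = [tuple(sorted(cell)) for cell in row]
        lines.append(" ".join(cell[0] for cell in sorted_cells))
        lines.append(" ".join(cell[1] for cell in sorted_cells))
    return "\n".join(lines) + "\n"


_BEGIN_RE = re.compile(r"^BEGIN BESTPAIRS1\s*$")
_END_RE = re.compile(r"^END BESTPAIRS1\s*$")
# an allele, optionally wrapped: A, (A), [A]
_ALLELE_RE = re.compile(r"^(?:\((?P<paren>[ACGT])\)|\[(?P<brack>[ACGT])\]|(?P<bare>[ACGT?]))$")


def parse_phase_output(stream: TextIO | str, expected: GenotypeMatrix) -> HaplotypeSet:
    """Extract per-individual haplotypes from a PHASE output file.

    The individual set and vector lengths are validated against the
    *expected* genotype matrix, and each parsed unordered pair must
    reproduce the matrix genotype where the matrix is non-missing.
    Individual header lines are keyed on '#' (the id is the text after
    it) to tolerate layout differences between PHASE versions.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = stream.read().splitlines()

    try:
        start = next(i for i, ln in enumerate(lines) if _BEGIN_RE.match(ln.strip()))
    except StopIteration:
        raise MissingSection("no BEGIN BESTPAIRS1 section found") from None
    try:
        end = next(i for i in range(start + 1, len(lines)) if _END_RE.match(lines[i].strip()))
    except StopIteration:
        raise MissingSection("BEGIN BESTPAIRS1 without END BESTPAIRS1") from None

    block = [ln.strip() for ln in lines[start + 1 : end] if ln.strip()]
    L = len(expected.positions)
    haplotypes: dict[str, tuple[list[str], ...]] = {}
    phase_flags: dict[tuple[str, int], str] = {}
    order: list[str] = []

    i = 0
    while i < len(block):
        header = block[i]
        if "#" not in header:
            raise MalformedReport(f"expected an individual header containing '#': {header!r}")
        sample_id = header.split("#", 1)[1].strip()
        if not sample_id:
            raise MalformedReport(f"empty individual id in header {header!r}")
        if sample_id in haplotypes:
            raise IndividualMismatch(f"individual {sample_id!r} appears twice")
        if i + 2 >= len(block):
            raise LengthMismatch(f"truncated haplotype rows for {sample_id!r}")
        pair = []
        for row_line in (block[i + 1], block[i + 2]):
            alleles, flags = _parse_hap_row(row_line, sample_id)
            if len(alleles) != L:
                raise LengthMismatch(
                    f"{sample_id!r}: haplotype row has {len(alleles)} loci, expected {L}"
                )
            pair.append(alleles)
            for j, flag in flags:
                key = (sample_id, expected.positions[j])
                # 'imputed' outranks 'uncertain' if both rows mark a site
                if phase_flags.get(key) != "imputed":
                    phase_flags[key] = flag
        haplotypes[sample_id] = (pair[0], pair[1])
        order.append(sample_id)
        i += 3

    got, want = set(haplotypes), set(expected.individuals)
    if got != want:
        missing, extra = sorted(want - got), sorted(got - want)
        raise IndividualMismatch(
            f"PHASE output individuals differ from matrix: missing {missing}, extra {extra}"
        )

    _check_against_matrix(haplotypes, expected)
    return HaplotypeSet(
        positions=list(expected.positions),
        individuals=[ind for ind in expected.individuals],
        haplotypes=haplotypes,
        phase_flags=phase_flags,
    )


def _parse_hap_row(line: str, sample_id: str) -> tuple[list[str], list[tuple[int, str]]]:
    alleles: list[str] = []
    flags: list[tuple[int, str]] = []
    for j, tok in enumerate(line.split()):
        m = _ALLELE_RE.match(tok)
        if m is None:
            raise MalformedReport(f"{sample_id!r}: unrecognised allele token {tok!r}")
        if m.group("paren"):
            alleles.append(m.group("paren"))
            flags.append((j, "uncertain"))
        elif m.group("brack"):
            alleles.append(m.group("brack"))
            flags.append((j, "imputed"))
        else:
            alleles.append(m.group("bare"))
    return alleles, flags


def _check_against_matrix(
    haplotypes: dict[str, tuple[list[str], ...]], expected: GenotypeMatrix
) -> None:
    for i, ind in enumerate(expected.individuals):
        h1, h2 = haplotypes[ind]
        for j, pos in enumerate(expected.positions):
            cell = expected.calls[i][j]
            if MISSING in cell:
                continue  # PHASE imputes missing genotypes; nothing to compare
            parsed = tuple(sorted((h1[j], h2[j])))
            if MISSING in parsed:
                continue  # PHASE left it missing; reconstruction renders 'N'
            if parsed != tuple(sorted(cell)):
                raise AlleleMismatch(
                    f"{ind} at position {pos}: PHASE pair {parsed} contradicts "
                    f"matrix genotype {tuple(sorted(cell))}"
                )


def haplotypes_valid_alleles(haps: HaplotypeSet) -> bool:
    """True iff every allele in every vector is a concrete nucleotide."""
    return all(
        a in NUCLEOTIDES
        for vectors in haps.haplotypes.values()
        for v in vectors
        for a in v
    )
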