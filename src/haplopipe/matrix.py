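"""Per-individual genotype consolidation and the SDAT matrix format.

Reads from the same individual (forward/reverse reads of an amplicon,
overlapping amplicons) are collapsed into one genotype per individual
per site.  Disagreement between reads — the classic heterozygote-miscall
failure mode of automatic genotype calling — is recorded in an
:class:`~haplopipe.model.InconsistencyReport` and resolved by policy:

``strict``
    abort, listing every conflict;
``missing`` (default)
    set the conflicted cell fully missing — conservative: the
    irreproducible call is discarded but the individual is kept;
``best_score``
    keep the genotype of the highest-scoring read; score ties resolve
    toward missing.

SDAT is a rectangular TSV: header ``ID`` then 1-based reference
positions; one row per individual; diploid cells ``X/Y`` with alleles in
alphabetical order (genotypes are unphased), haploid cells a single
base; missing ``?/?`` or ``?``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import TextIO

from .errors import (
    HeterozygousInHaploid,
    InconsistentGenotypes,
    MalformedSdat,
    UnmatchedReadName,
)
from .model import (
    ALLELE_ALPHABET,
    MISSING,
    ConsolidatedCallSet,
    GenotypeMatrix,
    InconsistencyEntry,
    InconsistencyReport,
)

POLICIES = ("strict", "missing", "best_score")


@dataclass(frozen=True)
class SampleIdRule:
    """A single-capture-group rule extracting the sample id from a read name.

    The default captures the maximal prefix before the first '_' or '.',
    matching the common ``<SAMPLE>_<primer><direction>.<ext>`` naming of
    Sanger trace files.
    """

    pattern: str = r"^([^_.]+)"
    description: str = "prefix before the first '_' or '.'"

    def __post_init__(self):
        compiled = re.compile(self.pattern)
        if compiled.groups != 1:
            raise ValueError(
                f"sample-id pattern must have exactly one capture group: {self.pattern!r}"
            )


DEFAULT_ID_RULE = SampleIdRule()


def extract_sample_id(read_name: str, rule: SampleIdRule = DEFAULT_ID_RULE) -> str:
    """Apply the rule's capture group to a read name."""
    if not read_name:
        raise UnmatchedReadName("empty read name")
    m = re.search(rule.pattern, read_name)
    if m is None or not m.group(1):
        raise UnmatchedReadName(
            f"read name {read_name!r} does not match rule {rule.pattern!r} ({rule.description})"
        )
    return m.group(1)


def build_genotype_matrix(
    call_set: ConsolidatedCallSet,
    ploidy: int = 2,
    rule: SampleIdRule = DEFAULT_ID_RULE,
    policy: str = "missing",
) -> tuple[GenotypeMatrix, InconsistencyReport]:
    """Collapse read-level calls into an individuals x sites matrix.

    Individuals are the sorted distinct sample ids extracted from read
    names; columns are the call set's site positions.  Cells where all
    covering reads agree get that genotype; uncovered cells are missing;
    disagreeing cells become report entries and are resolved per
    *policy*.  Haploid mode requires every read call homozygous and
    stores the single allele.
    """
    if ploidy not in (1, 2):
        raise ValueError(f"ploidy must be 1 or 2: {ploidy}")
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}: {policy!r}")

    if ploidy == 1:
        offenders = [
            (g.read_name, g.ref_pos, g.allele1, g.allele2)
            for g in call_set.read_genotypes
            if not g.is_missing and g.allele1 != g.allele2
        ]
        if offenders:
            raise HeterozygousInHaploid(sorted(offenders))

    positions = call_set.site_positions()
    pos_index = {p: j for j, p in enumerate(positions)}
    site_alleles = [(s.ref_allele, s.alt_allele) for s in call_set.sites]

    # (sample, pos) -> list of covering read calls, deterministic order
    covering: dict[tuple[str, int], list] = {}
    for g in sorted(call_set.read_genotypes, key=lambda g: (g.ref_pos, g.read_name)):
        sample = extract_sample_id(g.read_name, rule)
        covering.setdefault((sample, g.ref_pos), []).append(g)

    individuals = sorted({s for s, _ in covering})
    missing_cell: tuple[str, ...] = (MISSING,) * ploidy
    calls = [[missing_cell for _ in positions] for _ in individuals]
    entries: list[InconsistencyEntry] = []

    for (sample, pos), reads in covering.items():
        i, j = individuals.index(sample), pos_index[pos]
        informative = [g for g in reads if not g.is_missing]
        if not informative:
            continue
        distinct = {g.sorted_alleles for g in informative}
        if len(distinct) == 1:
            calls[i][j] = _as_cell(informative[0].sorted_alleles, ploidy)
            continue
        read_calls = tuple(
            (g.read_name, g.allele1, g.allele2, g.score) for g in informative
        )
        best = max(informative, key=lambda g: g.score)
        top = [g for g in informative if g.score == best.score]
        if policy == "best_score" and len({g.sorted_alleles for g in top}) == 1:
            calls[i][j] = _as_cell(best.sorted_alleles, ploidy)
            resolution = f"best_score:{best.read_name}"
        else:
            # "missing" policy, or a best_score tie between disagreeing reads
            calls[i][j] = missing_cell
            resolution = "missing" if policy != "strict" else "strict"
        entries.append(InconsistencyEntry(sample, pos, read_calls, resolution))

    entries.sort(key=lambda e: (e.sample_id, e.ref_pos))
    report = InconsistencyReport(entries=entries)
    if policy == "strict" and entries:
        raise InconsistentGenotypes(entries)

    matrix = GenotypeMatrix(
        reference_id=call_set.reference_id,
        ploidy=ploidy,
        positions=positions,
        site_alleles=site_alleles,
        individuals=individuals,
        calls=calls,
    )
    matrix.validate()
    return matrix, report


def _as_cell(sorted_pair: tuple[str, str], ploidy: int) -> tuple[str, ...]:
    if ploidy == 2:
        return sorted_pair
    return (sorted_pair[0],)  # haploid: homozygous by precondition


def write_sdat(matrix: GenotypeMatrix) -> str:
    """Serialise a genotype matrix as SDAT text."""
    matrix.validate()
    lines = ["\t".join(["ID"] + [str(p) for p in matrix.positions])]
    for ind, row in zip(matrix.individuals, matrix.calls):
        cells = ["/".join(sorted(cell)) if len(cell) == 2 else cell[0] for cell in row]
        lines.append("\t".join([ind] + cells))
    return "\n".join(lines) + "\n"


def read_sdat(stream: TextIO | str, reference_id: str = "") -> GenotypeMatrix:
    """Parse SDAT text into a genotype matrix.

    Ploidy is inferred from token shape (``X/Y`` vs ``X``); mixing the
    two shapes, ragged rows, non-increasing positions or illegal allele
    tokens raise :class:`MalformedSdat`.  Site allele pairs are not part
    of the format; see :func:`haplopipe.consolidate.infer_site_alleles`.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.rstrip("\n") for ln in stream if ln.strip()]
    if not lines:
        raise MalformedSdat("empty SDAT file")
    header = lines[0].split("\t")
    if header[0] != "ID":
        raise MalformedSdat(f"header must start with 'ID', got {header[0]!r}")
    try:
        positions = [int(tok) for tok in header[1:]]
    except ValueError:
        raise MalformedSdat(f"non-integer position in header: {header[1:]}") from None
    if positions != sorted(set(positions)) or len(positions) != len(set(positions)):
        raise MalformedSdat("header positions must be strictly increasing")

    individuals: list[str] = []
    calls: list[list[tuple[str, ...]]] = []
    ploidy: int | None = None
    for rowno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(positions) + 1:
            raise MalformedSdat(
                f"row {rowno} ({fields[0]!r}) has {len(fields) - 1} genotype tokens, "
                f"expected {len(positions)}"
            )
        ind, tokens = fields[0], fields[1:]
        if ind in individuals:
            raise MalformedSdat(f"duplicate individual {ind!r} at row {rowno}")
        row: list[tuple[str, ...]] = []
        for tok in tokens:
            cell = _parse_cell(tok, rowno)
            if ploidy is None:
                ploidy = len(cell)
            elif len(cell) != ploidy:
                raise MalformedSdat(
                    f"row {rowno}: mixed ploidy token {tok!r} (file is ploidy {ploidy})"
                )
            row.append(cell)
        individuals.append(ind)
        calls.append(row)

    matrix = GenotypeMatrix(
        reference_id=reference_id,
        ploidy=ploidy if ploidy is not None else 2,
        positions=positions,
        site_alleles=None,
        individuals=individuals,
        calls=calls,
    )
    matrix.validate()
    return matrix


def _parse_cell(tok: str, rowno: int) -> tuple[str, ...]:
    if "/" in tok:
        parts = tok.split("/")
        if len(parts) != 2 or any(p not in ALLELE_ALPHABET for p in parts):
            raise MalformedSdat(f"row {rowno}: illegal genotype token {tok!r}")
        a1, a2 = parts
        if (a1 == MISSING) != (a2 == MISSING):
            raise MalformedSdat(f"row {rowno}: half-missing genotype {tok!r}")
        return tuple(sorted((a1, a2)))
    if tok not in ALLELE_ALPHABET:
        raise MalformedSdat(f"row {rowno}: illegal allele token {tok!r}")
    return (tok,)
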