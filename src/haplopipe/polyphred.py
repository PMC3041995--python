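"""Reading and writing the PolyPhred-style per-contig report dialect.

The dialect (one contig per file) is section-based::

    BEGIN_CONTIG <contig_name>
    REFERENCE <reference_id> <offset_integer>
    BEGIN_POLYMORPHISM
    <contig_pos> <ref_allele> <alt_allele> <score>
    END_POLYMORPHISM
    BEGIN_GENOTYPE
    <contig_pos> <read_name> <allele1>/<allele2> <score>
    END_GENOTYPE
    END_CONTIG

Fields are whitespace-delimited, '#' starts a comment, blank lines are
ignored.  Lines outside recognised sections are tolerated and counted,
so the parser doubles as the adapter point for other PolyPhred dialects.

:func:`detect_format` classifies any pipeline file by structural
signature (section keywords, header shape) — never by file extension.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import TextIO

from .errors import MalformedReport
from .model import ALLELE_ALPHABET, NUCLEOTIDES, ContigReport, ReadGenotypeRecord, SiteRecord


@dataclass
class ParseSummary:
    """Bookkeeping from one report parse."""

    n_sites: int = 0
    n_genotypes: int = 0
    n_dropped_low_score: int = 0
    n_ignored_lines: int = 0
    ignored_line_numbers: list[int] = field(default_factory=list)


def _tokens(line: str) -> list[str]:
    """Strip comments and split; empty list for blank/comment-only lines."""
    return line.split("#", 1)[0].split()


def parse_polyphred_report(
    stream: TextIO | str, min_score: int = 0
) -> tuple[ContigReport, ParseSummary]:
    """Parse one contig report.

    Genotype records with score < *min_score* are dropped and counted in
    the returned :class:`ParseSummary`.  Unrecognised lines outside
    sections are ignored but counted; structural violations raise
    :class:`MalformedReport` with the offending line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    summary = ParseSummary()

    contig_name: str | None = None
    reference_id: str | None = None
    reference_offset: int | None = None
    sites: list[SiteRecord] = []
    genotypes: list[ReadGenotypeRecord] = []
    section: str | None = None  # None | "POLYMORPHISM" | "GENOTYPE"
    in_contig = False
    contig_closed = False
    seen_pairs: set[tuple[int, str]] = set()

    for lineno, raw in enumerate(stream, start=1):
        toks = _tokens(raw)
        if not toks:
            continue
        kw = toks[0]
        if kw == "BEGIN_CONTIG":
            if in_contig or contig_closed:
                raise MalformedReport("unexpected BEGIN_CONTIG", lineno)
            if len(toks) != 2:
                raise MalformedReport("BEGIN_CONTIG needs exactly one name", lineno)
            contig_name = toks[1]
            in_contig = True
        elif kw == "END_CONTIG":
            if not in_contig or section is not None:
                raise MalformedReport("unexpected END_CONTIG", lineno)
            in_contig = False
            contig_closed = True
        elif kw == "REFERENCE":
            if not in_contig:
                raise MalformedReport("REFERENCE outside contig", lineno)
            if len(toks) != 3:
                raise MalformedReport("REFERENCE needs id and offset", lineno)
            reference_id = toks[1]
            try:
                reference_offset = int(toks[2])
            except ValueError:
                raise MalformedReport(f"non-integer offset {toks[2]!r}", lineno) from None
            if reference_offset < 0:
                raise MalformedReport(f"negative offset {reference_offset}", lineno)
        elif kw in ("BEGIN_POLYMORPHISM", "BEGIN_GENOTYPE"):
            if not in_contig or section is not None:
                raise MalformedReport(f"unexpected {kw}", lineno)
            section = kw.removeprefix("BEGIN_")
        elif kw in ("END_POLYMORPHISM", "END_GENOTYPE"):
            if section != kw.removeprefix("END_"):
                raise MalformedReport(f"{kw} without matching BEGIN", lineno)
            section = None
        elif section == "POLYMORPHISM":
            sites.append(_parse_site_line(toks, lineno))
        elif section == "GENOTYPE":
            rec = _parse_genotype_line(toks, lineno)
            key = (rec.contig_pos, rec.read_name)
            if key in seen_pairs:
                raise MalformedReport(f"duplicate (pos, read) pair {key}", lineno)
            seen_pairs.add(key)
            if rec.score < min_score:
                summary.n_dropped_low_score += 1
            else:
                genotypes.append(rec)
        else:
            # tolerant: unrecognised line outside any section
            summary.n_ignored_lines += 1
            summary.ignored_line_numbers.append(lineno)

    if in_contig or section is not None:
        raise MalformedReport("unterminated section: missing END_* line")
    if contig_name is None:
        raise MalformedReport("no BEGIN_CONTIG/END_CONTIG block found")
    if reference_id is None or reference_offset is None:
        raise MalformedReport("missing REFERENCE line")

    report = ContigReport(
        contig_name=contig_name,
        reference_id=reference_id,
        reference_offset=reference_offset,
        sites=sorted(sites, key=lambda s: s.contig_pos),
        genotypes=genotypes,
    )
    try:
        report.validate()
    except ValueError as exc:
        raise MalformedReport(str(exc)) from exc
    summary.n_sites = len(report.sites)
    summary.n_genotypes = len(report.genotypes)
    return report, summary


def _parse_site_line(toks: list[str], lineno: int) -> SiteRecord:
    if len(toks) != 4:
        raise MalformedReport(f"polymorphism line needs 4 fields, got {len(toks)}", lineno)
    pos_s, ref, alt, score_s = toks
    try:
        pos = int(pos_s)
        score = int(score_s)
    except ValueError:
        raise MalformedReport(f"non-integer field in {toks}", lineno) from None
    if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
        raise MalformedReport(f"allele outside {{A,C,G,T}}: {ref}/{alt}", lineno)
    try:
        return SiteRecord(pos, ref, alt, score)
    except ValueError as exc:
        raise MalformedReport(str(exc), lineno) from exc


def _parse_genotype_line(toks: list[str], lineno: int) -> ReadGenotypeRecord:
    if len(toks) != 4:
        raise MalformedReport(f"genotype line needs 4 fields, got {len(toks)}", lineno)
    pos_s, read_name, gt, score_s = toks
    try:
        pos = int(pos_s)
        score = int(score_s)
    except ValueError:
        raise MalformedReport(f"non-integer field in {toks}", lineno) from None
    if gt.count("/") != 1:
        raise MalformedReport(f"genotype token must be X/Y: {gt!r}", lineno)
    a1, a2 = gt.split("/")
    if a1 not in ALLELE_ALPHABET or a2 not in ALLELE_ALPHABET:
        raise MalformedReport(f"allele outside alphabet: {gt!r}", lineno)
    try:
        return ReadGenotypeRecord(pos, read_name, a1, a2, score)
    except ValueError as exc:
        raise MalformedReport(str(exc), lineno) from exc


def write_polyphred_report(report: ContigReport) -> str:
    """Serialise a report in the dialect; inverse of the parser."""
    lines = [
        f"BEGIN_CONTIG {report.contig_name}",
        f"REFERENCE {report.reference_id} {report.reference_offset}",
        "BEGIN_POLYMORPHISM",
    ]
    for s in report.sites:
        lines.append(f"{s.contig_pos} {s.ref_allele} {s.alt_allele} {s.score}")
    lines.append("END_POLYMORPHISM")
    lines.append("BEGIN_GENOTYPE")
    for g in report.genotypes:
        lines.append(f"{g.contig_pos} {g.read_name} {g.allele1}/{g.allele2} {g.score}")
    lines.append("END_GENOTYPE")
    lines.append("END_CONTIG")
    return "\n".join(lines) + "\n"


FORMAT_LABELS = ("polyphred_report", "sdat", "phase_input", "phase_output", "fasta", "unknown")


def detect_format(stream: TextIO | str) -> tuple[str, str]:
    """Classify a pipeline file by structural signature.

    Returns ``(label, diagnostics)`` with label one of
    ``{polyphred_report, sdat, phase_input, phase_output, fasta, unknown}``.
    ``unknown`` is a value, not an error.
    """
    if isinstance(stream, str):
        text = stream
    else:
        text = stream.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return "unknown", "empty file"

    first = lines[0].lstrip()
    if first.startswith(">"):
        return "fasta", "first non-blank character is '>'"

    content = [ln for ln in lines if _tokens(ln)]
    if content and _tokens(content[0])[0] == "BEGIN_CONTIG":
        return "polyphred_report", "starts with a BEGIN_CONTIG section header"

    for ln in lines:
        if ln.strip().startswith("BEGIN BESTPAIRS"):
            return "phase_output", "contains a BEGIN BESTPAIRS section"

    if len(lines) >= 3:
        t0, t1 = lines[0].split(), lines[1].split()
        if (
            len(t0) == 1
            and len(t1) == 1
            and t0[0].isdigit()
            and t1[0].isdigit()
            and lines[2].split()[:1] == ["P"]
        ):
            return "phase_input", "two integer count lines followed by a 'P' position line"

    header = lines[0].split("\t")
    if header and header[0] == "ID" and all(c.isdigit() for c in header[1:]) and len(header) >= 1:
        return "sdat", "tab-separated header: 'ID' followed by integer positions"

    return "unknown", "no structural signature matched"
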