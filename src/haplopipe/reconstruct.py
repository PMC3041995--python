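"""Full-length haplotype reconstruction and FASTA output.

PHASE output (and a haploid genotype matrix) carries alleles only at the
segregating sites; population-genetics tools in the DNAsp family need
the entire aligned sequence, monomorphic sites included.  Reconstruction
splices each individual's alleles into the shared reference: every
position outside the site list is the reference base, every segregating
position is the individual's allele.  Missing alleles surviving to this
point render as 'N', as do positions excluded by an optional regions
mask (BED, 0-based half-open) for studies that only sequenced exons.

Record naming: ``<sample>_hap1`` / ``<sample>_hap2`` for diploid data,
bare ``<sample>`` for haploid.
"""

from __future__ import annotations

import io
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlleleOutsideSiteSet,
    DuplicateName,
    HeterozygousInHaploid,
    MalformedFasta,
    OutOfRange,
)
from .model import (
    MISSING,
    GenotypeMatrix,
    HaplotypeSet,
    ReconstructedRecord,
    ReferenceSequence,
)


def _splice(
    reference: ReferenceSequence,
    positions: list[int],
    alleles: list[str],
    mask: list[tuple[int, int]] | None = None,
) -> str:
    seq = list(reference.bases)
    for pos, allele in zip(positions, alleles):
        if not 1 <= pos <= len(reference):
            raise OutOfRange(f"site position {pos} outside reference of length {len(reference)}")
        seq[pos - 1] = "N" if allele == MISSING else allele
    if mask is not None:
        covered = [False] * len(seq)
        for start, end in mask:  # 1-based closed spans
            for p in range(max(1, start), min(len(seq), end) + 1):
                covered[p - 1] = True
        seq = [b if c else "N" for b, c in zip(seq, covered)]
    return "".join(seq)


def _check_site_alleles(
    positions: list[int], alleles: list[str], sites: dict[int, tuple[str, str]], owner: str
) -> None:
    for pos, allele in zip(positions, alleles):
        if allele == MISSING:
            continue
        pair = sites.get(pos)
        if pair is None:
            raise AlleleOutsideSiteSet(f"{owner}: position {pos} is not a declared site")
        if allele not in pair:
            raise AlleleOutsideSiteSet(
                f"{owner} at position {pos}: allele {allele} outside site alleles {pair}"
            )


def reconstruct_sequences(
    haps: HaplotypeSet,
    reference: ReferenceSequence,
    sites: dict[int, tuple[str, str]],
    mask: list[tuple[int, int]] | None = None,
) -> list[ReconstructedRecord]:
    """Splice phased haplotypes into the reference.

    Returns 2n records for n diploid individuals (n for haploid input),
    individuals in input order, hap1 before hap2; every record has the
    reference's length.  *sites* maps ref_pos to the (ref, alt) allele
    pair; alleles outside it raise :class:`AlleleOutsideSiteSet`.
    """
    records: list[ReconstructedRecord] = []
    for ind in haps.individuals:
        vectors = haps.haplotypes[ind]
        for k, vector in enumerate(vectors, start=1):
            name = f"{ind}_hap{k}" if len(vectors) == 2 else ind
            _check_site_alleles(haps.positions, vector, sites, name)
            records.append(
                ReconstructedRecord(name, _splice(reference, haps.positions, vector, mask))
            )
    return records


def reconstruct_haploid(
    matrix: GenotypeMatrix,
    reference: ReferenceSequence,
    sites: dict[int, tuple[str, str]] | None = None,
    mask: list[tuple[int, int]] | None = None,
) -> list[ReconstructedRecord]:
    """Reconstruct one full-length sequence per haploid individual.

    Accepts a ploidy-1 matrix, or a diploid matrix whose every cell is
    homozygous (auto-collapsed); any heterozygous cell raises
    :class:`HeterozygousInHaploid`.  Missing alleles render as 'N'.
    """
    if sites is None:
        if matrix.site_alleles is None:
            raise ValueError(
                "site allele table required (matrix has none; see infer_site_alleles)"
            )
        sites = dict(zip(matrix.positions, matrix.site_alleles))
    offenders = []
    records: list[ReconstructedRecord] = []
    for ind, row in zip(matrix.individuals, matrix.calls):
        alleles = []
        for pos, cell in zip(matrix.positions, row):
            if len(set(cell)) > 1:
                offenders.append((ind, pos, cell[0], cell[1]))
                alleles.append(MISSING)
            else:
                alleles.append(cell[0])
        if not offenders:
            _check_site_alleles(matrix.positions, alleles, sites, ind)
            records.append(
                ReconstructedRecord(ind, _splice(reference, matrix.positions, alleles, mask))
            )
    if offenders:
        raise HeterozygousInHaploid(offenders)
    return records


def write_fasta(records: Iterable[ReconstructedRecord]) -> str:
    """Standard FASTA, 60-character sequence lines, names preserved."""
    records = list(records)
    names = [r.name for r in records]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise DuplicateName(f"duplicate record names: {sorted(dupes)}")
    handle = io.StringIO()
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.name, description="") for r in records),
        handle,
        "fasta",
    )
    return handle.getvalue()


def read_fasta(stream: TextIO | str) -> list[ReconstructedRecord]:
    """Inverse of :func:`write_fasta`."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    try:
        parsed = list(SeqIO.parse(stream, "fasta"))
    except ValueError as exc:
        raise MalformedFasta(str(exc)) from exc
    if not parsed:
        raise MalformedFasta("no FASTA records found")
    return [ReconstructedRecord(rec.id, str(rec.seq).upper()) for rec in parsed]


def read_bed_mask(stream: TextIO | str) -> list[tuple[int, int]]:
    """Read a BED regions mask (0-based half-open) as 1-based closed spans."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    spans: list[tuple[int, int]] = []
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise MalformedFasta(f"BED line {lineno} has fewer than 3 fields")
        try:
            start0, end0 = int(fields[1]), int(fields[2])
        except ValueError:
            raise MalformedFasta(f"BED line {lineno}: non-integer coordinates") from None
        if end0 <= start0:
            raise MalformedFasta(f"BED line {lineno}: empty or inverted interval")
        spans.append((start0 + 1, end0))
    return sorted(spans)
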