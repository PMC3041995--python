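"""Reference-coordinate mapping, contig merging and reference checks."""

import random

import pytest

from haplopipe import (
    ContigReport,
    FixtureParams,
    ReadGenotypeRecord,
    ReferenceSequence,
    SiteRecord,
    map_to_reference,
    merge_reports,
    simulate_dataset,
    verify_reference_consistency,
)
from haplopipe.consolidate import read_reference_fasta
from haplopipe.errors import (
    AlleleConflict,
    DuplicateReadCall,
    OutOfRange,
    ReferenceIdMismatch,
    ReferenceMismatch,
)
from haplopipe.model import ConsolidatedCallSet


def report(name="c1", ref="R", offset=0, sites=(), genotypes=()):
    r = ContigReport(name, ref, offset, list(sites), list(genotypes))
    r.validate()
    return r


def test_zero_offset_is_identity():
    sites, _ = map_to_reference(report(sites=[SiteRecord(17, "A", "G", 99)]))
    assert [s.ref_pos for s in sites] == [17]


def test_offset_shifts_additively():
    r = report(offset=1000, sites=[SiteRecord(5, "A", "G", 99), SiteRecord(50, "C", "T", 99)])
    sites, _ = map_to_reference(r)
    assert [s.ref_pos for s in sites] == [1005, 1050]


def test_mapping_beyond_reference_end_is_out_of_range():
    r = report(offset=10, sites=[SiteRecord(5, "A", "G", 99)])
    with pytest.raises(OutOfRange):
        map_to_reference(r, ReferenceSequence("R", "ACGT"))


def test_singleton_merge_equals_mapped_form():
    r = report(
        offset=3,
        sites=[SiteRecord(2, "A", "G", 99)],
        genotypes=[ReadGenotypeRecord(2, "s1_F", "A", "G", 50)],
    )
    cs = merge_reports([r])
    assert cs.site_positions() == [5]
    assert [(g.ref_pos, g.read_name) for g in cs.read_genotypes] == [(5, "s1_F")]


def test_merge_positions_match_brute_force_recomputation():
    """Oracle: every merged position is contig_pos + offset, recomputed directly."""
    b = simulate_dataset(FixtureParams(seed=5))
    expected = sorted(
        s.contig_pos + r.reference_offset for r in b.reports for s in r.sites
    )
    cs = merge_reports(b.reports, b.reference)
    assert cs.site_positions() == expected == b.site_positions
    assert len(cs.read_genotypes) == sum(len(r.genotypes) for r in b.reports)


def test_merge_is_order_independent():
    b = simulate_dataset(FixtureParams(seed=2))
    reference_result = merge_reports(b.reports, b.reference)
    for i in range(3):
        shuffled = list(b.reports)
        random.Random(i).shuffle(shuffled)
        assert merge_reports(shuffled, b.reference) == reference_result


def test_merge_with_empty_report_is_identity():
    b = simulate_dataset(FixtureParams(seed=2))
    empty = report(name="zzz_empty", ref=b.reference.id, offset=0)
    merged = merge_reports(list(b.reports) + [empty], b.reference)
    assert merged == merge_reports(b.reports, b.reference)


def test_overlapping_contigs_with_discordant_alt_is_allele_conflict():
    r1 = report(name="c1", offset=0, sites=[SiteRecord(10, "A", "G", 99)])
    r2 = report(name="c2", offset=5, sites=[SiteRecord(5, "A", "T", 99)])
    with pytest.raises(AlleleConflict) as exc:
        merge_reports([r1, r2])
    assert [pos for pos, _ in exc.value.conflicts] == [10]


def test_overlapping_contigs_with_matching_site_fuse_sources():
    r1 = report(name="c1", offset=0, sites=[SiteRecord(10, "A", "G", 99)])
    r2 = report(name="c2", offset=5, sites=[SiteRecord(5, "A", "G", 99)])
    cs = merge_reports([r1, r2])
    assert len(cs.sites) == 1
    assert cs.sites[0].source_contigs == {"c1", "c2"}


def test_duplicate_read_calls_dedupe_when_identical_error_when_discordant():
    site1 = [SiteRecord(10, "A", "G", 99)]
    site2 = [SiteRecord(5, "A", "G", 99)]
    same = merge_reports(
        [
            report(name="c1", sites=site1, genotypes=[ReadGenotypeRecord(10, "r1", "A", "G", 50)]),
            report(name="c2", offset=5, sites=site2,
                   genotypes=[ReadGenotypeRecord(5, "r1", "G", "A", 50)]),  # same unordered pair
        ]
    )
    assert len(same.read_genotypes) == 1
    with pytest.raises(DuplicateReadCall, match="r1"):
        merge_reports(
            [
                report(name="c1", sites=site1,
                       genotypes=[ReadGenotypeRecord(10, "r1", "A", "A", 50)]),
                report(name="c2", offset=5, sites=site2,
                       genotypes=[ReadGenotypeRecord(5, "r1", "A", "G", 50)]),
            ]
        )


def test_mixed_reference_ids_are_rejected():
    with pytest.raises(ReferenceIdMismatch):
        merge_reports([report(ref="R1"), report(name="c2", ref="R2")])


class TestVerifyReference:
    def test_fixture_call_set_is_self_consistent(self, bundle):
        cs = merge_reports(bundle.reports, bundle.reference)
        verify_reference_consistency(cs, bundle.reference)  # must not raise

    def test_shifted_offsets_trigger_reference_mismatch(self, bundle):
        shifted = [
            ContigReport(r.contig_name, r.reference_id, r.reference_offset + 1,
                         r.sites, r.genotypes)
            for r in bundle.reports
        ]
        cs = merge_reports(shifted)
        with pytest.raises(ReferenceMismatch) as exc:
            verify_reference_consistency(cs, bundle.reference)
        assert len(exc.value.mismatches) >= 1
        # oracle: recompute the expected mismatch set by direct string lookup
        expected = [
            pos + 1
            for pos, (ref_allele, _) in zip(bundle.site_positions, bundle.site_alleles)
            if bundle.reference.base_at(pos + 1) != ref_allele
        ]
        assert [pos for pos, _, _ in exc.value.mismatches] == expected

    def test_empty_site_list_passes_vacuously(self):
        cs = ConsolidatedCallSet(reference_id="R")
        verify_reference_consistency(cs, ReferenceSequence("R", "ACGT"))


def test_reference_fasta_reader_round_trips(bundle, tmp_path):
    path = tmp_path / "ref.fa"
    path.write_text(bundle.emitted_files["reference.fasta"])
    ref = read_reference_fasta(str(path))
    assert ref == bundle.reference
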