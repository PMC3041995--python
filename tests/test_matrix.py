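"""Per-individual consolidation, conflict policies and SDAT I/O."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplopipe import (
    FixtureParams,
    GenotypeMatrix,
    SampleIdRule,
    build_genotype_matrix,
    extract_sample_id,
    merge_reports,
    read_sdat,
    simulate_dataset,
    write_sdat,
)
from haplopipe.errors import (
    HeterozygousInHaploid,
    InconsistentGenotypes,
    MalformedSdat,
    UnmatchedReadName,
)
from haplopipe.model import ConsolidatedCallSet, MappedGenotype, MappedSite

from conftest import sdat_projection


class TestSampleIdRule:
    @pytest.mark.parametrize(
        "read_name, expected",
        [("IND023_EX2F.ab1", "IND023"), ("s7.fwd", "s7"), ("solo", "solo")],
    )
    def test_default_rule_takes_prefix_before_separator(self, read_name, expected):
        assert extract_sample_id(read_name) == expected

    def test_custom_rule_and_failure(self):
        rule = SampleIdRule(r"^sample-(\d+)", "digits after 'sample-'")
        assert extract_sample_id("sample-42_F", rule) == "42"
        with pytest.raises(UnmatchedReadName, match="oops"):
            extract_sample_id("oops_F", rule)

    def test_rule_requires_one_capture_group(self):
        with pytest.raises(ValueError):
            SampleIdRule(r"^\w+")

    def test_fixture_read_names_resolve_to_assigned_samples(self, bundle):
        for report in bundle.reports:
            for g in report.genotypes:
                assert extract_sample_id(g.read_name) in bundle.individuals


def call_set(reads, site=("A", "G"), pos=10):
    return ConsolidatedCallSet(
        reference_id="R",
        sites=[MappedSite(pos, *site, {"c1"})],
        read_genotypes=[MappedGenotype(pos, *r) for r in reads],
    )


class TestBuildMatrix:
    def test_unanimous_reads_give_the_shared_genotype(self):
        m, rep = build_genotype_matrix(call_set([("s1_F", "A", "G", 40), ("s1_R", "G", "A", 50)]))
        assert m.calls == [[("A", "G")]]
        assert rep.entries == []

    def test_disagreeing_reads_become_missing_and_are_reported(self):
        m, rep = build_genotype_matrix(call_set([("s1_F", "A", "A", 40), ("s1_R", "A", "G", 50)]))
        assert m.calls == [[("?", "?")]]
        assert len(rep.entries) == 1
        entry = rep.entries[0]
        assert (entry.sample_id, entry.ref_pos) == ("s1", 10)
        assert {rc[0] for rc in entry.read_calls} == {"s1_F", "s1_R"}

    def test_strict_policy_aborts_listing_conflicts(self):
        with pytest.raises(InconsistentGenotypes, match="s1@10"):
            build_genotype_matrix(
                call_set([("s1_F", "A", "A", 40), ("s1_R", "A", "G", 50)]), policy="strict"
            )

    def test_best_score_keeps_highest_scoring_read_ties_go_missing(self):
        m, _ = build_genotype_matrix(
            call_set([("s1_F", "A", "A", 40), ("s1_R", "A", "G", 50)]), policy="best_score"
        )
        assert m.calls == [[("A", "G")]]
        tied, _ = build_genotype_matrix(
            call_set([("s1_F", "A", "A", 50), ("s1_R", "A", "G", 50)]), policy="best_score"
        )
        assert tied.calls == [[("?", "?")]]

    def test_uncovered_cells_are_missing(self):
        cs = call_set([("s1_F", "A", "G", 40)])
        cs.sites.append(MappedSite(20, "C", "T", {"c1"}))
        m, _ = build_genotype_matrix(cs)
        assert m.calls == [[("A", "G"), ("?", "?")]]

    def test_all_missing_reads_leave_cell_missing_without_conflict(self):
        m, rep = build_genotype_matrix(call_set([("s1_F", "?", "?", 0), ("s1_R", "?", "?", 0)]))
        assert m.calls == [[("?", "?")]]
        assert rep.entries == []

    def test_haploid_mode_requires_homozygous_reads(self):
        m, _ = build_genotype_matrix(
            call_set([("s1_F", "G", "G", 40), ("s1_R", "G", "G", 50)]), ploidy=1
        )
        assert m.calls == [[("G",)]]
        with pytest.raises(HeterozygousInHaploid, match="s1_R"):
            build_genotype_matrix(
                call_set([("s1_F", "G", "G", 40), ("s1_R", "A", "G", 50)]), ploidy=1
            )

    def test_read_order_does_not_change_the_matrix(self, noisy_bundle):
        cs = merge_reports(noisy_bundle.reports, noisy_bundle.reference)
        m0, rep0 = build_genotype_matrix(cs)
        for i in range(3):
            shuffled = ConsolidatedCallSet(cs.reference_id, cs.sites, list(cs.read_genotypes))
            random.Random(i).shuffle(shuffled.read_genotypes)
            m, rep = build_genotype_matrix(shuffled)
            assert m == m0 and rep == rep0


@pytest.mark.parametrize("seed", [0, 1, 4])
def test_planted_conflicts_are_recovered_exactly(seed):
    """The inconsistency report equals the generator's planted conflict set."""
    b = simulate_dataset(FixtureParams(seed=seed, conflict_rate=0.08, missing_rate=0.05))
    cs = merge_reports(b.reports, b.reference)
    m, rep = build_genotype_matrix(cs)
    assert rep.conflict_cells() == b.planted_conflicts
    # policy=missing: conflicted and planted-missing cells are ?/?, the rest match truth
    for i, ind in enumerate(m.individuals):
        for j, pos in enumerate(m.positions):
            if (ind, pos) in b.planted_conflicts or (ind, pos) in b.planted_missing:
                assert m.calls[i][j] == ("?", "?")
            else:
                assert m.calls[i][j] == b.truth_matrix.calls[i][j]


def test_noise_free_matrix_equals_truth(bundle):
    cs = merge_reports(bundle.reports, bundle.reference)
    m, rep = build_genotype_matrix(cs)
    assert rep.entries == []
    assert m == bundle.truth_matrix


class TestSdat:
    def test_minimal_matrix_serialization(self):
        m = GenotypeMatrix("R", 2, [10], [("A", "G")], ["id"], [[("A", "G")]])
        assert write_sdat(m) == "ID\t10\nid\tA/G\n"

    def test_empty_individual_list_writes_header_only(self):
        m = GenotypeMatrix("R", 2, [10], [("A", "G")], [], [])
        assert write_sdat(m) == "ID\t10\n"

    def test_fixture_matrix_round_trips(self, bundle):
        m = bundle.truth_matrix
        again = read_sdat(write_sdat(m))
        assert sdat_projection(again) == sdat_projection(m)
        assert write_sdat(again) == write_sdat(m)

    def test_haploid_tokens_infer_ploidy_one(self):
        m = read_sdat("ID\t10\t20\ns1\tA\t?\n")
        assert m.ploidy == 1
        assert m.calls == [[("A",), ("?",)]]

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("ID\t10\t20\t30\t40\ns1\tA/A\tA/G\tC/C\n", "row 2"),
            ("ID\t20\t10\ns1\tA/A\tA/G\n", "increasing"),
            ("ID\t10\ns1\tA/Z\n", "illegal"),
            ("ID\t10\t20\ns1\tA/A\tC\n", "mixed ploidy"),
            ("ID\t10\ns1\tA/?\n", "half-missing"),
            ("POS\t10\ns1\tA/A\n", "ID"),
        ],
        ids=["ragged", "unsorted", "bad-allele", "mixed-ploidy", "half-missing", "bad-header"],
    )
    def test_malformed_sdat_is_rejected(self, text, fragment):
        with pytest.raises(MalformedSdat, match=fragment):
            read_sdat(text)


@st.composite
def matrices(draw):
    ploidy = draw(st.sampled_from([1, 2]))
    n_pos = draw(st.integers(1, 5))
    n_ind = draw(st.integers(1, 5))
    positions = sorted(
        draw(st.sets(st.integers(1, 500), min_size=n_pos, max_size=n_pos))
    )
    pairs = [draw(st.sampled_from([("A", "G"), ("C", "T"), ("A", "C")])) for _ in positions]
    individuals = [f"S{i:02d}" for i in range(n_ind)]
    calls = [
        [
            tuple(sorted(draw(st.lists(st.sampled_from(pair), min_size=ploidy, max_size=ploidy))))
            if draw(st.booleans())
            else ("?",) * ploidy
            for pair in pairs
        ]
        for _ in individuals
    ]
    return GenotypeMatrix("R", ploidy, positions, pairs, individuals, calls)


@given(matrices())
@settings(max_examples=40, deadline=None, derandomize=True)
def test_sdat_round_trip_property(m):
    """read_sdat inverts write_sdat for any valid matrix."""
    again = read_sdat(write_sdat(m))
    assert sdat_projection(again) == sdat_projection(m)
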