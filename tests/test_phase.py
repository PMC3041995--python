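"""PHASE input serialization and best-pairs output parsing."""

import pytest

from haplopipe import (
    FixtureParams,
    GenotypeMatrix,
    emit_phase_output,
    parse_phase_output,
    simulate_dataset,
    write_phase_input,
)
from haplopipe.errors import (
    AlleleMismatch,
    EmptyMatrix,
    HaploidUnsupported,
    IndividualMismatch,
    LengthMismatch,
    MissingSection,
)


def diploid_matrix(calls, positions=None, individuals=None):
    individuals = individuals or [f"s{i+1}" for i in range(len(calls))]
    positions = positions or [10 * (j + 1) for j in range(len(calls[0]))]
    pairs = []
    for j in range(len(positions)):
        alleles = sorted({a for row in calls for a in row[j] if a != "?"}) or ["A", "G"]
        while len(alleles) < 2:
            alleles.append(next(b for b in "ACGT" if b not in alleles))
        pairs.append(tuple(alleles[:2]))
    return GenotypeMatrix("R", 2, positions, pairs, individuals, calls)


class TestWritePhaseInput:
    def test_minimal_serialization(self):
        m = diploid_matrix([[("A", "G"), ("T", "T")]], positions=[5, 9], individuals=["id"])
        assert write_phase_input(m) == "1\n2\nP 5 9\nSS\n#id\nA T\nG T\n"

    def test_missing_cell_writes_question_marks_in_both_rows(self):
        m = diploid_matrix([[("?", "?"), ("C", "T")]])
        lines = write_phase_input(m).splitlines()
        assert lines[5] == "? C" and lines[6] == "? T"

    def test_genotype_rows_are_alphabetical_unphased(self):
        m = diploid_matrix([[("G", "A")]])
        lines = write_phase_input(m).splitlines()
        assert (lines[5], lines[6]) == ("A", "G")

    def test_haploid_and_empty_matrices_are_rejected(self):
        hap = GenotypeMatrix("R", 1, [10], [("A", "G")], ["s1"], [[("A",)]])
        with pytest.raises(HaploidUnsupported):
            write_phase_input(hap)
        empty = GenotypeMatrix("R", 2, [], [], ["s1"], [[]])
        with pytest.raises(EmptyMatrix):
            write_phase_input(empty)

    @pytest.mark.parametrize("seed", [0, 1, 9])
    def test_structure_matches_matrix_for_fixture_data(self, seed):
        b = simulate_dataset(FixtureParams(seed=seed, missing_rate=0.05))
        m = b.truth_matrix
        lines = write_phase_input(m).splitlines()
        L = len(m.positions)
        assert lines[0] == str(len(m.individuals))
        assert lines[1] == str(L)
        assert lines[2] == "P " + " ".join(map(str, m.positions))
        assert lines[3] == "S" * L
        body = lines[4:]
        assert len(body) == 3 * len(m.individuals)
        for k, ind in enumerate(m.individuals):
            assert body[3 * k] == f"#{ind}"
            assert len(body[3 * k + 1].split()) == L
            assert len(body[3 * k + 2].split()) == L


class TestParsePhaseOutput:
    def test_fixture_round_trip_recovers_truth_haplotypes(self, bundle):
        m = bundle.truth_matrix
        haps = parse_phase_output(bundle.emitted_files["phase_output.txt"], m)
        assert haps.positions == m.positions
        for ind in bundle.individuals:
            assert haps.haplotypes[ind] == bundle.truth_hap_alleles[ind]
        assert haps.phase_flags == {}

    def test_wrapped_alleles_are_unwrapped_and_flagged(self, bundle):
        m = bundle.truth_matrix
        text = emit_phase_output(bundle, wrap_all=True)
        haps = parse_phase_output(text, m)
        for ind in bundle.individuals:
            assert haps.haplotypes[ind] == bundle.truth_hap_alleles[ind]
        assert set(haps.phase_flags.values()) == {"uncertain"}
        assert len(haps.phase_flags) == len(m.individuals) * len(m.positions)

    def test_bracketed_allele_is_flagged_imputed(self):
        m = diploid_matrix([[("A", "G")]], positions=[7], individuals=["s1"])
        text = "BEGIN BESTPAIRS1\n0 #s1\n[A]\nG\nEND BESTPAIRS1\n"
        haps = parse_phase_output(text, m)
        assert haps.haplotypes["s1"] == (["A"], ["G"])
        assert haps.phase_flags == {("s1", 7): "imputed"}

    def test_sorted_pair_reproduces_matrix_genotype(self, bundle):
        haps = parse_phase_output(bundle.emitted_files["phase_output.txt"], bundle.truth_matrix)
        m = bundle.truth_matrix
        for i, ind in enumerate(m.individuals):
            h1, h2 = haps.haplotypes[ind]
            for j in range(len(m.positions)):
                assert tuple(sorted((h1[j], h2[j]))) == m.calls[i][j]

    def test_missing_section_and_individual_errors(self, bundle):
        m = bundle.truth_matrix
        with pytest.raises(MissingSection):
            parse_phase_output("no best pairs here\n", m)
        text = bundle.emitted_files["phase_output.txt"]
        victim = bundle.individuals[0]
        lines = text.splitlines()
        k = lines.index(f"0 #{victim}")
        pruned = "\n".join(lines[:k] + lines[k + 3 :]) + "\n"
        with pytest.raises(IndividualMismatch, match=victim):
            parse_phase_output(pruned, m)

    def test_wrong_row_length_is_rejected(self):
        m = diploid_matrix([[("A", "G"), ("C", "C")]], individuals=["s1"])
        text = "BEGIN BESTPAIRS1\n#s1\nA\nG\nEND BESTPAIRS1\n"
        with pytest.raises(LengthMismatch):
            parse_phase_output(text, m)

    def test_pair_contradicting_matrix_genotype_is_rejected(self):
        m = diploid_matrix([[("A", "A")]], positions=[7], individuals=["s1"])
        text = "BEGIN BESTPAIRS1\n#s1\nA\nG\nEND BESTPAIRS1\n"
        with pytest.raises(AlleleMismatch, match="position 7"):
            parse_phase_output(text, m)

    def test_empty_best_pairs_section_yields_empty_set(self):
        m = GenotypeMatrix("R", 2, [7], [("A", "G")], [], [])
        haps = parse_phase_output("BEGIN BESTPAIRS1\nEND BESTPAIRS1\n", m)
        assert haps.individuals == [] and haps.haplotypes == {}
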