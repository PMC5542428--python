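"""Haplotype matching, diplotype calling, HAF and haplotype filters."""

import numpy as np
import pandas as pd
import pytest

from popgx import (DiplotypeCall, PopulationMap, UNMATCHED, call_diplotype,
                   filter_extreme_haplotypes, haplotype_frequency,
                   match_allele, population_span, span_histogram,
                   unmatched_rate)
from popgx.haplotypes import ambiguous_mass
from popgx.genotype import MISSING, OTHER, REF, VAR
from popgx.translation import TranslationTable
from popgx.variants import FrequencyTable

from conftest import (oracle_diplotypes, oracle_match, random_fixture,
                      random_state_vector)


def make_calls(gene, pairs, pop="P1", ambiguous_idx=()):
    calls = []
    for i, pair in enumerate(pairs):
        amb = i in ambiguous_idx
        calls.append(DiplotypeCall(
            sample=f"S{i:03d}", gene=gene, allele_matches=tuple(pair),
            ambiguous=amb,
            consistent=(tuple(pair), (pair[1], pair[0])) if amb else ()))
    popmap = PopulationMap({c.sample: pop for c in calls}, {pop: "G"})
    return calls, popmap


class TestMatchAllele:
    def test_all_ref_is_wild_type(self, toy_table):
        assert match_allele([REF, REF], toy_table) == "*1"

    def test_var_pattern_matches_named_haplotype(self, toy_table):
        assert match_allele([VAR, REF], toy_table) == "*2"
        assert match_allele([VAR, VAR], toy_table) == "*3"

    def test_off_table_combination_unmatched(self, toy_table):
        assert match_allele([REF, VAR], toy_table) == UNMATCHED

    def test_other_or_missing_unmatched(self, toy_table):
        assert match_allele([OTHER, REF], toy_table) == UNMATCHED
        assert match_allele([MISSING, VAR], toy_table) == UNMATCHED

    def test_vector_length_mismatch(self, toy_table):
        with pytest.raises(ValueError):
            match_allele([REF], toy_table)

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            table = random_fixture(rng)
            vec = random_state_vector(rng, len(table.variants))
            assert match_allele(vec, table) == oracle_match(vec, table)


@pytest.fixture
def ambiguous_table():
    """Table where an unphased double heterozygote fits two diplotypes:
    cis (*3/*1) and trans (*2/*2b)."""
    frame = pd.DataFrame(
        [["C", "G"], ["T", "G"], ["C", "A"], ["T", "A"]],
        index=pd.Index(["*1", "*2", "*2b", "*3"], name="haplotype"),
        columns=["rs1", "rs2"])
    return TranslationTable(gene="AMB", alleles=frame)


class TestCallDiplotype:
    def test_phased_wild_type_pair(self, toy_table):
        call = call_diplotype([(REF, REF), (REF, REF)], [True, True], toy_table)
        assert call.allele_matches == ("*1", "*1") and not call.ambiguous

    def test_phased_het_pair(self, toy_table):
        call = call_diplotype([(REF, VAR), (REF, REF)], [True, True], toy_table)
        assert set(call.allele_matches) == {"*1", "*2"} and not call.ambiguous

    def test_unphased_ambiguous_two_solutions(self, ambiguous_table):
        call = call_diplotype([(REF, VAR), (REF, VAR)], [False, False],
                              ambiguous_table)
        assert call.ambiguous
        assert set(call.consistent) == {("*1", "*3"), ("*2", "*2b")}

    def test_unphased_unambiguous_agrees_with_phased(self, toy_table):
        phased = call_diplotype([(REF, VAR), (REF, VAR)], [True, True],
                                toy_table)
        unphased = call_diplotype([(REF, VAR), (REF, VAR)], [False, False],
                                  toy_table)
        assert not unphased.ambiguous
        assert sorted(unphased.allele_matches) == sorted(phased.allele_matches)

    def test_no_consistent_phasing_unmatched(self, toy_table):
        # het at rsB only: needs (*1,*?) with VAR at rsB alone -> off table
        call = call_diplotype([(REF, REF), (REF, VAR)], [True, False],
                              toy_table)
        assert call.allele_matches == (UNMATCHED, UNMATCHED)

    def test_strand_order_symmetry(self, toy_table):
        a = call_diplotype([(REF, VAR), (REF, VAR)], [True, True], toy_table)
        b = call_diplotype([(VAR, REF), (VAR, REF)], [True, True], toy_table)
        assert sorted(a.allele_matches) == sorted(b.allele_matches)

    def test_agrees_with_phase_enumeration_oracle(self):
        rng = np.random.default_rng(515)
        for _ in range(150):
            table = random_fixture(rng, max_variants=8, max_haplotypes=12)
            nv = len(table.variants)
            codes = np.stack([random_state_vector(rng, nv),
                              random_state_vector(rng, nv)], axis=1)
            phased = rng.random(nv) > 0.5
            call = call_diplotype(codes, phased, table)
            expected = oracle_diplotypes(codes, phased, table)
            het_unphased = any(codes[i, 0] != codes[i, 1] and not phased[i]
                               for i in range(nv))
            if not het_unphased:
                a = oracle_match(codes[:, 0], table)
                b = oracle_match(codes[:, 1], table)
                assert tuple(call.allele_matches) == (a, b)
            elif not expected:
                assert call.allele_matches == (UNMATCHED, UNMATCHED)
            elif len(expected) == 1:
                assert not call.ambiguous
                assert tuple(sorted(call.allele_matches)) == next(iter(expected))
            else:
                assert call.ambiguous
                assert set(call.consistent) == expected


class TestUnmatchedRate:
    def test_zero_when_everything_matches(self):
        calls, popmap = make_calls("G", [("*1", "*1")] * 10)
        assert (unmatched_rate(calls, popmap) == 0).all().all()

    def test_single_unmatched_strand(self):
        pairs = [("*1", "*1")] * 9 + [("*1", UNMATCHED)]
        calls, popmap = make_calls("G", pairs)
        assert unmatched_rate(calls, popmap).loc["G", "P1"] == pytest.approx(0.05)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(88)
        haps = ["*1", "*2", UNMATCHED]
        pairs = [tuple(rng.choice(haps, 2)) for _ in range(60)]
        calls, popmap = make_calls("G", pairs)
        rate = unmatched_rate(calls, popmap).loc["G", "P1"]
        oracle = sum(p.count(UNMATCHED) for p in pairs) / (2 * len(pairs))
        assert rate == pytest.approx(oracle)


class TestHaplotypeFrequency:
    def test_counting_example(self):
        # 5 samples: strands 6x*1, 3x*2, 1xUNMATCHED
        pairs = [("*1", "*1"), ("*1", "*1"), ("*1", "*2"), ("*1", "*2"),
                 ("*2", UNMATCHED)]
        calls, popmap = make_calls("G", pairs)
        ft = haplotype_frequency(calls, popmap, "population")
        assert ft.values.loc["G:*1", "P1"] == pytest.approx(0.6)
        assert ft.values.loc["G:*2", "P1"] == pytest.approx(0.3)
        unm = unmatched_rate(calls, popmap).loc["G", "P1"]
        assert unm == pytest.approx(0.1)

    def test_conservation_with_ambiguity(self):
        pairs = [("*1", "*1")] * 6 + [("*1", UNMATCHED)] * 2 + \
                [("*1", "*2")] * 2
        calls, popmap = make_calls("G", pairs, ambiguous_idx={8})
        ft = haplotype_frequency(calls, popmap, "population")
        total = (ft.values["P1"].sum()
                 + unmatched_rate(calls, popmap).loc["G", "P1"]
                 + ambiguous_mass(calls, popmap).loc["G", "P1"])
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_zero_frequency_rows_from_tables(self, toy_table):
        calls, popmap = make_calls("TOY", [("*1", "*1")] * 4)
        ft = haplotype_frequency(calls, popmap, "population",
                                 tables={"TOY": toy_table})
        assert ft.values.loc["TOY:*3", "P1"] == 0.0


class TestHaplotypeFilters:
    def _ft(self, rows):
        vals = pd.DataFrame(rows, columns=["P1", "P2"])
        return FrequencyTable(values=vals,
                              denominators=pd.DataFrame(100, index=vals.index,
                                                        columns=vals.columns),
                              level="population")

    def test_extreme_rule(self):
        ft = self._ft([[0.2, 0.0], [0.2, 0.15], [0.0, 0.0]])
        assert filter_extreme_haplotypes(ft) == {0}

    def test_population_span(self):
        ft = self._ft([[0.2, 0.3], [0.0, 0.1], [0.0, 0.0]])
        span = population_span(ft)
        assert list(span) == [2, 1, 0]
        hist = span_histogram(span, n_populations=2)
        assert hist["matched_all"] == pytest.approx(0.5)
        assert hist["matched_one"] == pytest.approx(0.5)
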