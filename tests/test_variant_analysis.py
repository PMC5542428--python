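"""Variant-allele frequencies, functional classes, spread and filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popgx import (FrequencyTable, classify_variant, common_damaging_profile,
                   compute_maf, delta_maf, filter_extreme_variants)
from popgx.genotype import MISSING, OTHER, REF, VAR
from popgx.variants import AMBIGUOUS, BENIGN, DAMAGING, UNKNOWN

from conftest import make_gm


def ft_from(values: dict, denom: int = 100, level="population") -> FrequencyTable:
    vals = pd.DataFrame(values)
    dens = pd.DataFrame(denom, index=vals.index, columns=vals.columns)
    dens = dens.where(vals.notna(), 0)
    return FrequencyTable(values=vals, denominators=dens, level=level)


class TestComputeMaf:
    def test_simple_count(self):
        # 10 samples, one variant, 3 VAR among 20 phased alleles
        calls = np.full((10, 1, 2), REF, dtype=np.int8)
        calls[0, 0, 0] = VAR
        calls[1, 0] = (VAR, VAR)
        gm = make_gm(calls, ["P1"] * 10)
        ft = compute_maf(gm, "population")
        assert ft.values.loc["rs0", "P1"] == pytest.approx(0.15)
        assert ft.denominators.loc["rs0", "P1"] == 20

    def test_all_ref_is_zero(self):
        gm = make_gm(np.full((5, 2, 2), REF, dtype=np.int8), ["P1"] * 5)
        assert (compute_maf(gm, "population").values == 0).all().all()

    def test_missing_excluded_other_counted(self):
        calls = np.array([[(VAR, MISSING)], [(OTHER, REF)]], dtype=np.int8)
        gm = make_gm(calls, ["P1", "P1"])
        ft = compute_maf(gm, "population")
        # denominator: VAR, OTHER, REF = 3 calls; numerator: 1 VAR
        assert ft.denominators.loc["rs0", "P1"] == 3
        assert ft.values.loc["rs0", "P1"] == pytest.approx(1 / 3)

    def test_zero_denominator_flagged_undefined(self):
        calls = np.full((2, 1, 2), MISSING, dtype=np.int8)
        gm = make_gm(calls, ["P1", "P1"])
        ft = compute_maf(gm, "population")
        assert np.isnan(ft.values.loc["rs0", "P1"])
        assert ft.denominators.loc["rs0", "P1"] == 0

    def test_group_pools_allele_counts(self):
        """Group frequency equals a brute-force pooled recount, not a plain
        mean over member populations (sizes differ)."""
        rng = np.random.default_rng(7)
        sizes = {"P1": 11, "P2": 37, "P3": 5}
        groups = {"P1": "G", "P2": "G", "P3": "G"}
        pops = sum(([p] * n for p, n in sizes.items()), [])
        calls = rng.choice([REF, VAR, OTHER, MISSING], size=(len(pops), 4, 2),
                           p=[0.6, 0.25, 0.05, 0.1]).astype(np.int8)
        gm = make_gm(calls, pops, pop_groups=groups)
        ft = compute_maf(gm, "group")
        for v in range(4):
            num = sum(1 for s in range(len(pops)) for k in range(2)
                      if calls[s, v, k] == VAR)
            den = sum(1 for s in range(len(pops)) for k in range(2)
                      if calls[s, v, k] != MISSING)
            assert ft.values.iloc[v, 0] == pytest.approx(num / den)

    def test_global_equals_pooled_recount(self):
        rng = np.random.default_rng(11)
        calls = rng.choice([REF, VAR, MISSING], size=(200, 50, 2),
                           p=[0.7, 0.2, 0.1]).astype(np.int8)
        pops = ["P1"] * 120 + ["P2"] * 80
        gm = make_gm(calls, pops)
        ft = compute_maf(gm, "global")
        num = (calls == VAR).sum(axis=(0, 2))
        den = (calls != MISSING).sum(axis=(0, 2))
        np.testing.assert_allclose(ft.values["ALL"].to_numpy(), num / den)


class TestClassify:
    @pytest.mark.parametrize("sift,polyphen,expected", [
        (0.50, 0.10, BENIGN),
        (0.01, 0.90, DAMAGING),
        (None, 0.90, UNKNOWN),
        (0.50, None, UNKNOWN),
        (0.01, 0.10, AMBIGUOUS),
        (0.90, 0.90, AMBIGUOUS),
        (0.05, 0.2, BENIGN),        # boundary: >= and <=
    ])
    def test_rules(self, sift, polyphen, expected):
        assert classify_variant(sift, polyphen) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_variant(-0.1, 0.5)
        with pytest.raises(ValueError):
            classify_variant(0.5, 1.2)

    @settings(max_examples=300, derandomize=True)
    @given(sift=st.one_of(st.none(), st.floats(0, 1)),
           polyphen=st.one_of(st.none(), st.floats(0, 1)))
    def test_exactly_one_label(self, sift, polyphen):
        label = classify_variant(sift, polyphen)
        assert label in {BENIGN, DAMAGING, UNKNOWN, AMBIGUOUS}
        if sift is None or polyphen is None:
            assert label == UNKNOWN


class TestDeltaMaf:
    def test_max_minus_min(self):
        ft = ft_from({"A": [0.9], "B": [0.1], "C": [0.5], "D": [0.2],
                      "E": [0.4]})
        assert delta_maf(ft).iloc[0] == pytest.approx(0.8)

    def test_constant_is_zero(self):
        ft = ft_from({"A": [0.3], "B": [0.3]})
        assert delta_maf(ft).iloc[0] == 0.0

    def test_single_defined_group_undefined(self):
        ft = ft_from({"A": [0.3], "B": [np.nan]})
        assert np.isnan(delta_maf(ft).iloc[0])

    def test_column_order_invariance_and_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        vals = rng.random((20, 5))
        ft = ft_from({f"g{j}": vals[:, j] for j in range(5)})
        d1 = delta_maf(ft)
        shuffled = ft.values[[f"g{j}" for j in (3, 1, 4, 0, 2)]]
        ft2 = FrequencyTable(values=shuffled,
                             denominators=ft.denominators[shuffled.columns],
                             level="group")
        pd.testing.assert_series_equal(d1, delta_maf(ft2))
        # exhaustive pairwise-difference maximum
        for i in range(20):
            oracle = max(abs(vals[i, a] - vals[i, b])
                         for a in range(5) for b in range(5))
            assert d1.iloc[i] == pytest.approx(oracle)


class TestExtremeFilter:
    def test_rule_application(self):
        ft = ft_from({"P1": [0.3, 0.05, 0.2], "P2": [0.004, 0.05, 0.3],
                      "P3": [0.1, 0.05, 0.2]})
        ft.values.index = ["keep", "mid", "common_everywhere"]
        ft.denominators.index = ft.values.index
        assert filter_extreme_variants(ft) == {"keep"}

    def test_extreme_implies_large_population_spread(self):
        rng = np.random.default_rng(5)
        vals = rng.random((50, 8)) ** 3
        ft = ft_from({f"P{j}": vals[:, j] for j in range(8)})
        selected = filter_extreme_variants(ft, 0.1, 0.005)
        spread = delta_maf(ft)
        assert all(spread[item] >= 0.095 for item in selected)


class TestCommonDamagingProfile:
    def test_single_common_damaging(self):
        ft = ft_from({"P1": [0.5, 0.02], "P2": [0.01, 0.02]})
        ft.values.index = ["rsD", "rsB"]
        ft.denominators.index = ft.values.index
        classes = pd.Series({"rsD": DAMAGING, "rsB": BENIGN})
        out = common_damaging_profile(ft, classes, thr=0.1)
        assert out.loc["P1", DAMAGING] == 1 and out.loc["P2", DAMAGING] == 0
        assert (out[BENIGN] == 0).all()

    def test_unknown_class_never_counted(self):
        ft = ft_from({"P1": [0.9, 0.9]})
        classes = pd.Series({0: UNKNOWN, 1: AMBIGUOUS})
        out = common_damaging_profile(ft, classes)
        assert (out.to_numpy() == 0).all()

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        items = [f"rs{i}" for i in range(30)]
        vals = pd.DataFrame(rng.random((30, 4)),
                            index=items, columns=list("ABCD"))
        ft = FrequencyTable(values=vals,
                            denominators=pd.DataFrame(50, index=vals.index,
                                                      columns=vals.columns),
                            level="population")
        classes = pd.Series(rng.choice([BENIGN, DAMAGING, UNKNOWN, AMBIGUOUS],
                                       size=30), index=items)
        out = common_damaging_profile(ft, classes, thr=0.1)
        for pop in "ABCD":
            for cls in (DAMAGING, BENIGN):
                oracle = sum(1 for it in items
                             if classes[it] == cls and vals.loc[it, pop] >= 0.1)
                assert out.loc[pop, cls] == oracle
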