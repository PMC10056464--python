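"""Descriptive surface: tallies, shares, outcome proportions, correlation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvdose.descriptives import (
    CategoryCountMatrix,
    category_counts,
    group_share_of_totals,
    outcome_proportion,
    pearson_p,
    pearson_r,
    round_half_up,
    share_of_dosing_errors,
    share_of_total_adrs,
    correlation_table,
)
from pvdose.errors import DegenerateInputError
from pvdose.io_counts import (
    Dataset,
    DrugCountProfile,
    OutcomeClass,
    PTCount,
)
from pvdose.taxonomy import DoseErrorCategory

C = DoseErrorCategory
DOACS = ["dabigatran", "rivaroxaban", "apixaban", "edoxaban"]


def test_round_half_up_ties_go_up():
    assert round_half_up(0.125) == 0.13
    assert round_half_up(18.534798) == 18.53
    assert round_half_up(2.435) == 2.44  # repr-based, no float-tie surprise


class TestCategoryCounts:
    # published per-drug per-category dosing-error counts
    EXPECTED = {
        ("rivaroxaban", C.UNDERDOSE): 1703,
        ("apixaban", C.UNDERDOSE): 1637,
        ("dabigatran", C.UNDERDOSE): 43,
        ("edoxaban", C.UNDERDOSE): 136,
        ("rivaroxaban", C.IMPROPER_DOSE): 1569,
        ("edoxaban", C.IMPROPER_DOSE): 225,
        ("apixaban", C.IMPROPER_DOSE): 175,
        ("dabigatran", C.IMPROPER_DOSE): 72,
        ("apixaban", C.OVERDOSE): 482,
        ("rivaroxaban", C.OVERDOSE): 415,
        ("dabigatran", C.OVERDOSE): 312,
        ("edoxaban", C.OVERDOSE): 56,
    }

    def test_reference_counts(self, fixture_matrix):
        for key, expected in self.EXPECTED.items():
            assert fixture_matrix.cell(*key) == expected
        assert fixture_matrix.grand_total() == 6825

    def test_uncategorized_pts_ignored(self, taxonomy):
        ds = Dataset([DrugCountProfile("a", 100, [PTCount("Headache", 50)])])
        m = category_counts(ds, taxonomy)
        assert m.grand_total() == 0

    def test_single_pt_single_cell(self, taxonomy):
        ds = Dataset([DrugCountProfile("a", 100, [PTCount("Overdose", 7)])])
        m = category_counts(ds, taxonomy)
        assert m.cell("a", C.OVERDOSE) == 7
        assert m.drug_total_errors("a") == 7


class TestShares:
    def test_category_shares(self, fixture_matrix):
        shares = share_of_dosing_errors(fixture_matrix, "by_category")
        assert shares[C.UNDERDOSE] == 51.56
        assert shares[C.IMPROPER_DOSE] == 29.90
        assert shares[C.OVERDOSE] == 18.53

    def test_drug_shares(self, fixture_matrix):
        shares = share_of_dosing_errors(fixture_matrix, "by_drug")
        assert shares["rivaroxaban"] == 54.02
        assert shares["apixaban"] == 33.61
        assert shares["dabigatran"] == 6.26
        assert shares["edoxaban"] == 6.11

    def test_uniform_matrix_symmetry(self):
        m = CategoryCountMatrix(
            cells={(d, C.OVERDOSE): 5 for d in "abcd"},
            drug_totals={d: 100 for d in "abcd"},
        )
        assert set(share_of_dosing_errors(m, "by_drug").values()) == {25.00}

    def test_zero_total_raises(self):
        m = CategoryCountMatrix(cells={}, drug_totals={"a": 10})
        with pytest.raises(DegenerateInputError):
            share_of_dosing_errors(m, "by_category")

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(st.integers(min_value=0, max_value=10**6), min_size=12,
                 max_size=12).filter(lambda v: sum(v) > 0)
    )
    def test_unrounded_shares_sum_to_100(self, counts):
        cells = {
            (f"d{i}", cat): counts[3 * i + j]
            for i in range(4)
            for j, cat in enumerate(C)
        }
        m = CategoryCountMatrix(
            cells=cells, drug_totals={f"d{i}": 10**7 for i in range(4)}
        )
        for axis in ("by_category", "by_drug"):
            raw = share_of_dosing_errors(m, axis, ndigits=None)
            assert math.isclose(sum(raw.values()), 100.0, abs_tol=1e-9)
            rounded = share_of_dosing_errors(m, axis)
            assert abs(sum(rounded.values()) - 100.0) <= 0.02


class TestShareOfTotals:
    def test_published_values(self, fixture_matrix):
        assert share_of_total_adrs(fixture_matrix, "apixaban", C.UNDERDOSE) == 2.32
        assert share_of_total_adrs(fixture_matrix, "edoxaban", C.IMPROPER_DOSE) == 2.41

    def test_zero_category_count_is_zero(self, fixture_matrix):
        assert share_of_total_adrs(
            fixture_matrix, "other_anticoagulants", C.OVERDOSE
        ) == 0.00

    def test_doac_share_of_class_reports(self, fixture_ds):
        assert group_share_of_totals(fixture_ds, DOACS) == 62.85


class TestOutcomeProportions:
    @pytest.mark.parametrize(
        "drug,cat,expected",
        [
            ("dabigatran", C.OVERDOSE, 9.94),   # 31/312
            ("edoxaban", C.OVERDOSE, 8.93),     # 5/56
            ("rivaroxaban", C.OVERDOSE, 2.17),  # 9/415
            ("apixaban", C.OVERDOSE, 1.45),     # 7/482
            ("dabigatran", C.IMPROPER_DOSE, 1.39),
            ("edoxaban", C.UNDERDOSE, 2.21),
            ("dabigatran", C.UNDERDOSE, 0.00),
            ("edoxaban", C.IMPROPER_DOSE, 0.00),
        ],
    )
    def test_fatal_proportions(self, fixture_ds, taxonomy, drug, cat, expected):
        assert outcome_proportion(
            fixture_ds, taxonomy, drug, cat, OutcomeClass.FATAL
        ) == expected

    @pytest.mark.parametrize(
        "drug,cat,expected",
        [
            ("edoxaban", C.IMPROPER_DOSE, 38.67),  # 87/225
            ("edoxaban", C.UNDERDOSE, 13.97),      # 19/136
            ("dabigatran", C.IMPROPER_DOSE, 9.72), # 7/72
            ("dabigatran", C.OVERDOSE, 6.09),      # 19/312
        ],
    )
    def test_nr_ns_proportions(self, fixture_ds, taxonomy, drug, cat, expected):
        assert outcome_proportion(
            fixture_ds, taxonomy, drug, cat,
            OutcomeClass.NOT_RECOVERED_NOT_RESOLVED,
        ) == expected

    def test_unknown_outcome_refuses(self, fixture_ds, taxonomy):
        with pytest.raises(DegenerateInputError):
            outcome_proportion(
                fixture_ds, taxonomy, "rivaroxaban", C.UNDERDOSE,
                OutcomeClass.FATAL,
            )

    def test_empty_cell_refuses(self, fixture_ds, taxonomy):
        with pytest.raises(DegenerateInputError):
            outcome_proportion(
                fixture_ds, taxonomy, "other_anticoagulants", C.OVERDOSE,
                OutcomeClass.FATAL,
            )


class TestPearson:
    TOTALS = [57627.0, 131182.0, 70424.0, 9318.0]  # dab, riva, apix, edox

    @pytest.mark.parametrize(
        "counts,expected_r,expected_p",
        [
            ([72, 1569, 175, 225], 0.8193, 0.1807),    # improper dose
            ([312, 415, 482, 56], 0.7801, 0.2199),     # overdose
            ([43, 1703, 1637, 136], 0.7723, 0.2277),   # underdose
        ],
    )
    def test_published_correlations(self, counts, expected_r, expected_p):
        res = pearson_r([float(c) for c in counts], self.TOTALS)
        assert res.r == pytest.approx(expected_r, abs=5e-5)
        assert res.n == 4
        assert pearson_p(res.r, res.n) == pytest.approx(expected_p, abs=5e-5)

    def test_perfect_linearity(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v + 3 for v in x]).r == pytest.approx(1.0)

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_p_domain_error(self):
        with pytest.raises(ValueError):
            pearson_p(1.2, 5)

    def test_p_edge_values(self):
        assert pearson_p(0.0, 10) == 1.0
        assert pearson_p(1.0, 10) == 0.0
        assert pearson_p(-0.6455, 4) == pytest.approx(0.3545, abs=5e-5)

    def test_p_monotone_in_r_and_n(self):
        rs = [0.1, 0.3, 0.5, 0.7, 0.9]
        ps = [pearson_p(r, 6) for r in rs]
        assert ps == sorted(ps, reverse=True)
        ns = [4, 6, 10, 30]
        pn = [pearson_p(0.5, n) for n in ns]
        assert pn == sorted(pn, reverse=True)

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_matches_covariance_definition(self, data):
        """Agreement with a direct covariance/variance oracle to 1e-12."""
        n = data.draw(st.integers(min_value=4, max_value=50))
        ints = st.integers(min_value=-1000, max_value=1000)
        x = data.draw(
            st.lists(ints, min_size=n, max_size=n).filter(
                lambda v: len(set(v)) > 1
            )
        )
        y = data.draw(
            st.lists(ints, min_size=n, max_size=n).filter(
                lambda v: len(set(v)) > 1
            )
        )
        xa, ya = np.asarray(x, float), np.asarray(y, float)
        xc, yc = xa - xa.mean(), ya - ya.mean()
        oracle = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
        assert pearson_r(xa, ya).r == pytest.approx(oracle, abs=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.floats(min_value=0.1, max_value=50),
        st.floats(min_value=-100, max_value=100),
    )
    def test_affine_invariance_and_antisymmetry(self, scale, shift):
        x = [1.0, 4.0, 2.0, 8.0, 5.0]
        y = [3.0, 1.0, 7.0, 2.0, 9.0]
        base = pearson_r(x, y).r
        assert pearson_r([scale * v + shift for v in x], y).r == pytest.approx(
            base, abs=1e-9
        )
        assert pearson_r([-v for v in x], y).r == pytest.approx(-base, abs=1e-12)


class TestCorrelationTable:
    def test_reference_fixture_surface(self, fixture_ds, taxonomy):
        table = correlation_table(fixture_ds, taxonomy)
        assert table["improper_dose"].r == pytest.approx(0.8193, abs=5e-5)
        assert table["overdose"].r == pytest.approx(0.7801, abs=5e-5)
        assert table["underdose"].r == pytest.approx(0.7723, abs=5e-5)
        assert table["improper_dose"].p_two_sided == pytest.approx(0.1807, abs=5e-5)
        # fatal / NR-NS tallies are not fully public, so no correlation
        assert table["fatal"] is None
        assert table["nr_ns"] is None

    def test_complete_outcomes_enable_all_series(self, taxonomy):
        ds = Dataset(
            [
                DrugCountProfile(
                    f"d{i}", 1000 * (i + 1),
                    [PTCount("Overdose", 10 * i + 5, n_fatal=i, n_nr_ns=2 * i)],
                )
                for i in range(4)
            ]
        )
        table = correlation_table(ds, taxonomy)
        assert all(table[k] is not None for k in ("overdose", "fatal", "nr_ns"))
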