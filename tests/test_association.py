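"""Genetic-model contingency association and CT comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pgxprs import association as assoc
from conftest import make_cohort


def _expand(pairs):
    """pairs of (dosage, outcome, count) -> flat arrays."""
    d, y = [], []
    for dose, out, k in pairs:
        d += [dose] * k
        y += [out] * k
    return np.array(d, float), np.array(y)


class TestContingency:
    def test_carrier_table_from_printed_genotype_counts(self):
        # 12 / 2 homozygous-ref / carrier among non-HTPR; 30 / 25 among HTPR
        d, y = _expand([(0, 0, 12), (1, 0, 2), (0, 1, 30), (1, 1, 25)])
        table = assoc.build_contingency(d, y, "carrier")
        assert table.loc["0"].tolist() == [12, 30]
        assert table.loc["1+2"].tolist() == [2, 25]
        pct = assoc.table_percentages(table)
        assert pct.loc["0", "non_case"] == pytest.approx(85.7, abs=0.05)
        assert pct.loc["0", "case"] == pytest.approx(54.5, abs=0.05)

    def test_homozygote_contrast_excludes_heterozygotes(self):
        d, y = _expand([(0, 0, 7), (1, 0, 4), (2, 0, 3),
                        (0, 1, 31), (1, 1, 22), (2, 1, 2)])
        table = assoc.build_contingency(d, y, "homozygote_contrast")
        assert table.to_numpy().sum() == 7 + 3 + 31 + 2  # n_used = 43
        res = assoc.associate_variant(d, y, "v", "homozygote_contrast")
        assert res.n_used == 43

    def test_codominant_three_categories(self):
        d, y = _expand([(0, 0, 5), (1, 0, 5), (2, 0, 5), (0, 1, 5), (1, 1, 5), (2, 1, 5)])
        table = assoc.build_contingency(d, y, "codominant")
        assert list(table.index) == ["0", "1", "2"]

    def test_degenerate_all_reference_flagged(self):
        d, y = _expand([(0, 0, 10), (0, 1, 10)])
        res = assoc.associate_variant(d, y, "v", "carrier")
        assert res.chi2 == 0.0 and res.p == 1.0
        assert res.odds_ratio is None


class TestPearsonChi2:
    def test_proportional_table_null(self):
        chi2, p = assoc.pearson_chi2([[10, 20], [5, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_printed_carrier_table(self):
        chi2, p = assoc.pearson_chi2([[12, 2], [30, 25]])
        assert chi2 == pytest.approx(4.551, abs=1e-3)
        assert p == pytest.approx(0.033, abs=1e-3)

    @given(st.lists(st.integers(1, 50), min_size=4, max_size=4))
    @settings(max_examples=150, deadline=None)
    def test_matches_scipy_without_correction(self, cells):
        table = np.array(cells).reshape(2, 2)
        chi2, p = assoc.pearson_chi2(table)
        chi2_o, p_o, _, _ = stats.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(chi2_o, rel=1e-10)
        assert p == pytest.approx(p_o, rel=1e-10, abs=1e-12)

    def test_invariant_under_row_and_column_permutation(self):
        table = np.array([[12, 2], [30, 25]])
        base = assoc.pearson_chi2(table)[0]
        assert assoc.pearson_chi2(table[::-1])[0] == pytest.approx(base)
        assert assoc.pearson_chi2(table[:, ::-1])[0] == pytest.approx(base)

    def test_codominant_3x2_df2(self):
        table = [[6, 10], [8, 31], [0, 14]]
        chi2, p = assoc.pearson_chi2(table)
        assert p == pytest.approx(stats.chi2.sf(chi2, 2), rel=1e-10)


class TestWoolfOddsRatio:
    def test_symmetric_table_or_one(self):
        o, lo, hi, hald = assoc.odds_ratio_woolf(10, 10, 10, 10)
        assert o == pytest.approx(1.0)
        assert not hald
        assert np.log(hi) == pytest.approx(-np.log(lo))

    def test_haldane_correction_on_single_zero_cell(self):
        o, lo, hi, hald = assoc.odds_ratio_woolf(14, 0, 41, 14)
        assert hald and o is not None and lo < o < hi

    def test_two_zero_cells_undefined(self):
        o, lo, hi, hald = assoc.odds_ratio_woolf(0, 5, 0, 7)
        assert o is None and lo is None and hi is None

    @given(st.lists(st.integers(1, 60), min_size=4, max_size=4))
    @settings(max_examples=150, deadline=None)
    def test_outcome_swap_inverts_or(self, cells):
        a, b, c, d = cells
        o1, *_ = assoc.odds_ratio_woolf(a, b, c, d)
        o2, *_ = assoc.odds_ratio_woolf(b, a, d, c)
        assert o1 * o2 == pytest.approx(1.0, rel=1e-10)


class TestMannWhitney:
    def test_identical_single_values(self):
        _, p = assoc.mann_whitney_ct([5.0], [5.0])
        assert p == 1.0

    def test_complete_separation_small_exact(self):
        u, p = assoc.mann_whitney_ct([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 orderings, two-sided

    def test_agreement_with_enumeration_small_groups(self, rng):
        """Brute force: p = fraction of label assignments with U at least as
        extreme (two-sided) — evaluated for several group sizes <= 6."""
        for n_a, n_b in [(3, 3), (4, 5), (6, 6), (2, 6)]:
            vals = rng.permutation(np.arange(1.0, n_a + n_b + 1))  # untied
            a, b = vals[:n_a], vals[n_a:]
            u_obs, p_obs = assoc.mann_whitney_ct(a, b)
            pooled = np.concatenate([a, b])
            count = total = 0
            for idx in itertools.combinations(range(n_a + n_b), n_a):
                ga = pooled[list(idx)]
                gb = np.delete(pooled, list(idx))
                u = sum((x > gb).sum() + 0.5 * (x == gb).sum() for x in ga)
                dev = abs(u - n_a * n_b / 2)
                count += dev >= abs(u_obs - n_a * n_b / 2) - 1e-9
                total += 1
            assert p_obs == pytest.approx(count / total, abs=1e-9)

    def test_u_statistics_sum_to_product(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(size=22)
        u_a, _ = assoc.mann_whitney_ct(a, b)
        u_b, _ = assoc.mann_whitney_ct(b, a)
        assert u_a + u_b == pytest.approx(15 * 22)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            assoc.mann_whitney_ct([], [1.0])


class TestScan:
    def test_planted_protective_variant_ranks_first(self, rng):
        n = 120
        causal = rng.binomial(2, 0.4, n)
        ct = 115 - 30 * causal + rng.normal(0, 10, n)
        dosages = {"causal": causal}
        for i in range(8):
            dosages[f"null{i}"] = rng.binomial(2, 0.4, n)
        cohort = make_cohort(dosages, ct=ct)
        table, ct_table = assoc.association_scan(cohort)
        variant_rows = table[table["kind"] == "variant"]
        assert variant_rows.iloc[0]["variant_id"] == "causal"
        # CT-by-genotype means fall with dosage for the causal variant
        sub = ct_table[(ct_table["variant_id"] == "causal")
                       & (ct_table["model"] == "codominant")]
        means = sub.set_index("category")["ct_mean"]
        assert means["0"] > means["1"] > means["2"]

    def test_covariate_association_included(self, rng):
        n = 80
        x = rng.binomial(1, 0.5, n)
        y = rng.binomial(1, 0.3 + 0.4 * x)
        cohort = make_cohort({"v": rng.binomial(2, 0.3, n)}, ct=rng.normal(100, 10, n),
                             htpr=y, covariates={"stent": x})
        table, _ = assoc.association_scan(cohort)
        assert (table["kind"] == "covariate").sum() == 1
        row = table[table["kind"] == "covariate"].iloc[0]
        # both orientations are reported and are reciprocal
        assert row["odds_ratio"] * row["odds_ratio_inverse"] == pytest.approx(1.0)

    def test_empty_variant_set(self):
        cohort = make_cohort({"v": [0, 1, 2, 1]}, ct=[90, 95, 100, 105])
        cohort.dosages = cohort.dosages.drop(columns=["v"])
        table, ct_table = assoc.association_scan(cohort)
        assert len(table) == 0 and len(ct_table) == 0

    def test_bh_column_is_supplementary_and_monotone(self, rng):
        cohort = make_cohort(
            {f"v{i}": rng.binomial(2, 0.3, 60) for i in range(5)},
            ct=rng.normal(100, 15, 60))
        table, _ = assoc.association_scan(cohort)
        assert "p_bh_supplementary" in table.columns
        assert (table["p_bh_supplementary"] >= table["p"] - 1e-12).all()
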