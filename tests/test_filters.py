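"""Prioritisation cascade rules, coverage QC, monomorphic exclusion."""

import numpy as np
import pandas as pd
import pytest

from pgxprs import filters
from conftest import (EXPECTED_FILTER_A, EXPECTED_FILTER_B, EXPECTED_FINAL,
                      build_filter_fixture, make_cohort, make_record)


class TestEvidenceFilter:
    def test_tiers_1_to_3_kept_missing_fails(self):
        recs = [make_record(f"v{t}", tier=t) for t in (1, 2, 3)]
        recs.append(make_record("v_none", tier=None))
        kept = filters.filter_evidence(recs)
        assert [r.variant_id for r in kept] == ["v1", "v2", "v3"]
        assert recs[-1].filter_provenance == [("evidence_tier", "fail")]

    def test_empty_input(self):
        assert filters.filter_evidence([]) == []


class TestRareDamagingFilter:
    @pytest.mark.parametrize(
        "maf,csq,n_damaging,ada,expect",
        [
            (0.01, "missense", 3, None, True),   # 3/6 vote at the threshold
            (0.01, "missense", 2, None, False),
            (0.05, "missense", 6, None, False),  # common, however damaging
            (0.001, "splicing", 0, 0.60, True),  # ADA cutoff boundary
            (0.001, "splicing", 0, 0.59, False),
            (0.001, "splicing", 0, None, False),
            (None, "nonsense", 0, None, True),   # novel LoF kept
            (0.001, "frameshift", 0, None, True),
            (0.001, "synonymous", 0, None, False),
            (0.0199999, "missense", 3, None, True),  # just under MAF 2%
            (0.02, "missense", 6, None, False),      # exactly 2% is not rare
        ],
    )
    def test_rule_boundaries(self, maf, csq, n_damaging, ada, expect):
        preds = ("damaging",) * n_damaging + ("benign",) * (6 - n_damaging)
        rec = make_record("v", maf=maf, consequence=csq, predictors=preds, ada=ada)
        assert bool(filters.filter_rare_damaging([rec])) is expect

    def test_missing_predictor_is_not_a_damaging_vote(self):
        rec = make_record("v", maf=0.001, consequence="missense",
                          predictors=("damaging", "damaging", "missing",
                                      "missing", "missing", "missing"))
        assert filters.filter_rare_damaging([rec]) == []


class TestCallQuality:
    @pytest.mark.parametrize(
        "gt,dp,ad,expect,reason",
        [
            ("0/1", 10, (7, 3), True, "ok"),        # balance 0.30
            ("0/1", 10, (8, 2), False, "allele_balance"),  # balance 0.20
            ("0/1", 8, (6, 2), True, "ok"),         # balance exactly 0.25
            ("1/1", 8, (0, 8), True, "ok"),         # balance rule is het-only
            ("0/0", 8, (8, 0), True, "ok"),
            ("0/1", 7, (4, 3), False, "low_depth"),
            ("0/1", 20, None, False, "no_AD"),
            ("./.", 30, (15, 15), False, "missing_genotype"),
        ],
    )
    def test_per_call_rule(self, gt, dp, ad, expect, reason):
        ok, why = filters.call_passes_quality(gt, dp, ad)
        assert ok is expect and why == reason

    def test_failing_calls_become_missing_record_survives_if_any_pass(self):
        rec = make_record("v", calls=[("0/1", 10, (7, 3)), ("0/1", 5, (3, 2))])
        kept = filters.filter_call_quality([rec])
        assert kept and kept[0].calls[1][0] == "./."
        rec2 = make_record("w", calls=[("0/1", 5, (3, 2))])
        assert filters.filter_call_quality([rec2]) == []


class TestCascade:
    def test_hand_tabulated_fixture(self):
        records = build_filter_fixture()
        final, report = filters.apply_cascade(records)
        got_a = set(report.outcomes.index[report.outcomes["filter_a_evidence"]])
        got_b = set(report.outcomes.index[report.outcomes["filter_b_rare_damaging"]])
        assert got_a == EXPECTED_FILTER_A
        assert got_b == EXPECTED_FILTER_B
        assert {r.variant_id for r in final} == EXPECTED_FINAL
        assert report.stage_counts["input"] == 20
        assert report.stage_counts["union_a_b"] == 10
        assert report.stage_counts["call_quality"] == 8

    def test_union_equals_applying_both_tracks_to_input(self):
        records = build_filter_fixture()
        ids_a = {r.variant_id for r in filters.filter_evidence(list(records))}
        ids_b = {r.variant_id for r in filters.filter_rare_damaging(list(records))}
        _, report = filters.apply_cascade(build_filter_fixture())
        union = set(report.outcomes.index[report.outcomes["union_a_b"]])
        assert union == ids_a | ids_b

    def test_stage_counts_monotone_after_union(self):
        _, report = filters.apply_cascade(build_filter_fixture())
        assert report.stage_counts["call_quality"] <= report.stage_counts["union_a_b"]
        assert report.stage_counts["union_a_b"] <= report.stage_counts["input"]


class TestCoverage:
    def _depth_df(self, chrom, positions, depths):
        return pd.DataFrame({"chrom": chrom, "pos": positions, "depth": depths})

    def test_uniform_depth_100(self):
        from pgxprs.io import TargetRegion

        depth = self._depth_df("chr1", range(1, 51), [100] * 50)
        out = filters.coverage_qc(depth, [TargetRegion("chr1", 0, 50, "t")])
        panel = out[out["target"] == "panel"].iloc[0]
        assert [panel[f"frac_{t}x"] for t in (10, 20, 50, 100, 200, 500)] == [
            1.0, 1.0, 1.0, 1.0, 0.0, 0.0]

    def test_half_low_half_high(self):
        from pgxprs.io import TargetRegion

        depth = self._depth_df("chr1", range(1, 101), [5] * 50 + [1000] * 50)
        out = filters.coverage_qc(depth, [TargetRegion("chr1", 0, 100, "t")])
        panel = out[out["target"] == "panel"].iloc[0]
        for t in (10, 20, 50, 100, 200, 500):
            assert panel[f"frac_{t}x"] == 0.5

    def test_mixed_regions_against_per_base_count(self, rng):
        from pgxprs.io import TargetRegion

        regions = [TargetRegion("chr1", 0, 30, "r1"),
                   TargetRegion("chr1", 100, 140, "r2"),
                   TargetRegion("chr2", 10, 25, "r3")]
        rows = []
        for reg in regions:
            for pos in range(reg.start + 1, reg.end + 1):
                rows.append({"chrom": reg.chrom, "pos": pos,
                             "depth": int(rng.integers(0, 600))})
        depth = pd.DataFrame(rows)
        out = filters.coverage_qc(depth, regions).set_index("target")
        for reg in regions:  # brute-force recount
            sub = depth[(depth["chrom"] == reg.chrom)
                        & (depth["pos"] > reg.start) & (depth["pos"] <= reg.end)]
            for t in (10, 20, 50, 100, 200, 500):
                expect = (sub["depth"] >= t).sum() / len(reg)
                assert out.loc[reg.name, f"frac_{t}x"] == pytest.approx(expect)

    def test_target_without_depth_data_warns_zero(self):
        from pgxprs.io import TargetRegion

        depth = self._depth_df("chr1", [1], [50])
        with pytest.warns(UserWarning, match="no depth data"):
            out = filters.coverage_qc(depth, [TargetRegion("chr9", 0, 10, "t")])
        assert out.iloc[0]["frac_10x"] == 0.0


class TestMonomorphic:
    def test_constant_columns_dropped(self):
        cohort = make_cohort({"all0": [0, 0, 0], "poly": [0, 1, 2], "all2": [2, 2, 2]})
        out, dropped = filters.drop_monomorphic(cohort)
        assert set(dropped) == {"all0", "all2"}
        assert out.variant_ids == ["poly"]

    def test_forced_zero_columns_count(self, rng):
        dosages = {f"v{i}": rng.binomial(2, 0.3, 40) for i in range(91)}
        for i in range(6):
            dosages[f"v{i * 15}"] = np.zeros(40, dtype=int)
        cohort = make_cohort(dosages)
        # guard against accidental extra monomorphic draws
        forced = {f"v{i * 15}" for i in range(6)}
        others_poly = all(np.ptp(dosages[v]) > 0 for v in dosages if v not in forced)
        assert others_poly
        _, dropped = filters.drop_monomorphic(cohort)
        assert set(dropped) == forced
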