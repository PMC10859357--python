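"""Agreement counting, group summaries and one-way ANOVA."""

import numpy as np
import pandas as pd
import pytest

from oracles import definitional_anova
from vesselquant.evaluation import (
    VESSEL_CLASS_STRATIFIER,
    PairedAssessments,
    build_paired,
    categorical_agreement,
    one_way_anova,
    read_rater_csv,
    summarize_by_rater_group,
)
from vesselquant.involvement import bin_degree, report_from_degrees


def pairs_from(degree_rater):
    """Rows of (model_degrees, rater_category) -> PairedAssessments."""
    rows = [
        (f"case{i}", "SMA", deg, bin_degree(deg), rater)
        for i, (deg, rater) in enumerate(degree_rater)
    ]
    return PairedAssessments.from_rows(rows)


#: 12 records across 3 rater groups, used for hand-counted assertions.
TWELVE = pairs_from(
    [
        (0.0, "0"), (0.0, "0"), (5.0, "0"), (0.0, "0"),
        (45.0, "0–90"), (80.0, "0–90"), (120.0, "0–90"), (30.0, "0–90"),
        (100.0, "90–180"), (150.0, "90–180"), (170.0, "90–180"), (95.0, "90–180"),
    ]
)


class TestPairedValidation:
    def test_category_consistency_enforced(self):
        rows = [("c", "SMA", 120.0, "0–90", "0–90")]
        with pytest.raises(ValueError, match="inconsistent"):
            PairedAssessments(pd.DataFrame(rows, columns=[
                "case_id", "vessel", "model_degrees", "model_category", "rater_category"]))

    def test_rater_vocabulary_enforced(self):
        rows = [("c", "SMA", 0.0, "0", "none")]
        with pytest.raises(ValueError, match="vocabulary"):
            PairedAssessments.from_rows(rows)


class TestAgreement:
    def test_all_matching(self):
        p = pairs_from([(0.0, "0")] * 10)
        res = categorical_agreement(p)
        assert (res.n_agree, res.n_total, res.fraction) == (10, 10, 1.0)

    def test_three_of_four(self):
        p = pairs_from([(0.0, "0"), (45.0, "0–90"), (100.0, "90–180"), (300.0, "0")])
        assert categorical_agreement(p).fraction == 0.75

    def test_hand_count_on_twelve_record_fixture(self):
        # matches: rows with bin(model) == rater -> 3 + 3 + 4 = 10 of 12
        res = categorical_agreement(TWELVE)
        assert (res.n_agree, res.n_total) == (10, 12)

    def test_stratified_counts(self):
        rows = [(f"c{i}", v, 0.0, "0", "0")
                for i, v in enumerate(["CeTr", "HA", "SMA"] * 2 + ["SMV", "PV"] * 2)]
        res = categorical_agreement(PairedAssessments.from_rows(rows),
                                    VESSEL_CLASS_STRATIFIER)
        assert res.per_stratum["arterial"] == (6, 6)
        assert res.per_stratum["venous"] == (4, 4)
        assert sum(n for _, n in res.per_stratum.values()) == res.n_total

    def test_order_invariance(self):
        recs = TWELVE.records.sample(frac=1.0, random_state=0)
        assert categorical_agreement(PairedAssessments(recs)).fraction == pytest.approx(
            categorical_agreement(TWELVE).fraction
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            categorical_agreement(PairedAssessments.from_rows([]))


class TestGroupSummary:
    def test_zero_group_has_degenerate_iqr(self):
        p = pairs_from([(0.0, "0")] * 5)
        row = summarize_by_rater_group(p).iloc[0]
        assert (row["median"], row["q1"], row["q3"]) == (0.0, 0.0, 0.0)

    def test_median_of_three(self):
        p = pairs_from([(10.0, "0–90"), (20.0, "0–90"), (30.0, "0–90")])
        assert summarize_by_rater_group(p).iloc[0]["median"] == 20.0

    def test_quantiles_match_sorted_order_statistics(self):
        summary = summarize_by_rater_group(TWELVE).set_index("rater_category")
        for cat in ("0", "0–90", "90–180"):
            vals = np.sort(
                TWELVE.records.loc[
                    TWELVE.records["rater_category"] == cat, "model_degrees"
                ].to_numpy()
            )
            # linear interpolation between order statistics, n = 4
            assert summary.loc[cat, "median"] == pytest.approx((vals[1] + vals[2]) / 2)
            assert summary.loc[cat, "q1"] == pytest.approx(vals[0] + 0.75 * (vals[1] - vals[0]))
            assert summary.loc[cat, "q3"] == pytest.approx(vals[2] + 0.25 * (vals[3] - vals[2]))

    def test_absent_groups_noted(self):
        summary = summarize_by_rater_group(TWELVE)
        assert summary.attrs["absent_groups"] == ["180–270", "270–360"]


class TestAnova:
    def test_equal_means_give_zero_F(self):
        res = one_way_anova([[1.0, 3.0], [2.0, 2.0]])
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_matches_definitional_sums_of_squares(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        res = one_way_anova(groups)
        F, p = definitional_anova(groups)
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_matches_oracle_on_random_groups(self):
        rng = np.random.default_rng(3)
        groups = [list(rng.normal(m, 1.0, size=rng.integers(3, 9))) for m in (0, 0.5, 2.0)]
        res = one_way_anova(groups)
        F, p = definitional_anova(groups)
        assert res.F == pytest.approx(F, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])

    def test_degenerate_zero_within_variance(self):
        res = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
        assert res.degenerate
        assert res.p_value == 0.0

    def test_invariances(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0], [0.5, 2.5]]
        base = one_way_anova(groups)
        assert one_way_anova(groups[::-1]).F == pytest.approx(base.F, rel=1e-12)
        shifted = [[x + 7.0 for x in g] for g in groups]
        assert one_way_anova(shifted).F == pytest.approx(base.F, rel=1e-9)


class TestRaterIO:
    def test_round_trip_and_join(self, tmp_path):
        raters = pd.DataFrame(
            {
                "case_id": ["a", "a", "b"],
                "vessel": ["SMA", "PV", "SMA"],
                "rater_category": ["0–90", "0", "90–180"],
            }
        )
        path = tmp_path / "raters.csv"
        raters.to_csv(path, index=False)
        loaded = read_rater_csv(path)
        reports = {
            "a": report_from_degrees({"SMA": 60.0}),
            "b": report_from_degrees({"SMA": 120.0}),
        }
        pairs = build_paired(reports, loaded)
        assert categorical_agreement(pairs).fraction == 1.0

    def test_unknown_vessel_rejected(self, tmp_path):
        path = tmp_path / "raters.csv"
        pd.DataFrame(
            {"case_id": ["a"], "vessel": ["aorta"], "rater_category": ["0"]}
        ).to_csv(path, index=False)
        with pytest.raises(ValueError, match="aorta"):
            read_rater_csv(path)
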