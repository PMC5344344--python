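"""The two missing-data rules: condition status, then visit counts."""

import numpy as np
import pandas as pd
import pytest

from gpprev import impute_all, impute_condition_status, impute_visits, records_to_frame
from gpprev.imputation import ImputationError

from conftest import make_record


class TestConditionStatus:
    def test_chronic_managed_assigns_conditions(self, catalog):
        df = records_to_frame(
            [make_record(1, response="missing",
                         managed=["hypertension", "acute_urti"])]
        )
        out, rep = impute_condition_status(df, catalog)
        assert out.loc[0, "condition_response"] == "has_conditions"
        assert out.loc[0, "conditions"] == {"hypertension"}
        assert rep.n_reassigned_from_encounter == 1

    def test_acute_only_managed_becomes_no_conditions(self, catalog):
        df = records_to_frame(
            [make_record(1, response="missing", managed=["acute_urti"])]
        )
        out, rep = impute_condition_status(df, catalog)
        assert out.loc[0, "condition_response"] == "no_conditions"
        assert out.loc[0, "conditions"] == frozenset()
        assert rep.n_assigned_no_conditions == 1

    def test_non_missing_untouched(self, catalog):
        df = records_to_frame(
            [make_record(1, conditions=["asthma"], managed=["hypertension"])]
        )
        out, rep = impute_condition_status(df, catalog)
        assert out.loc[0, "conditions"] == {"asthma"}
        assert rep.n_missing_condition == 0

    def test_report_split_identity(self, catalog):
        df = records_to_frame(
            [make_record(i, response="missing",
                         managed=["hypertension"] if i % 3 == 0 else ["acute_urti"])
             for i in range(9)]
        )
        _, rep = impute_condition_status(df, catalog)
        assert rep.n_missing_condition == 9
        assert (rep.n_missing_condition
                == rep.n_reassigned_from_encounter + rep.n_assigned_no_conditions)

    def test_idempotent(self, catalog):
        df = records_to_frame(
            [make_record(1, response="missing", managed=["hypertension"]),
             make_record(2, response="missing", managed=["acute_urti"])]
        )
        once, _ = impute_condition_status(df, catalog)
        twice, rep2 = impute_condition_status(once, catalog)
        pd.testing.assert_frame_equal(once, twice)
        assert rep2.n_missing_condition == 0


class TestVisitImputation:
    def donors(self, catalog):
        # two donors in the (male, 40-49, 2 conditions) cell with 4 and 6
        # visits; one (female, 20-29, 0 conditions) donor with 3 visits
        return [
            make_record(1, age=44, visits=4,
                        conditions=["hypertension", "depression"]),
            make_record(2, age=47, visits=6,
                        conditions=["hypertension", "osteoarthritis"]),
            make_record(3, age=25, sex="female", visits=3),
        ]

    def test_cell_mean_assigned(self, catalog):
        recs = self.donors(catalog) + [
            make_record(9, age=42, visits=None,
                        conditions=["asthma", "gord"], response="has_conditions"),
        ]
        df = records_to_frame(recs)
        out, rep = impute_visits(df, catalog)
        assert out.loc[3, "reported_visits"] == pytest.approx(5.0)
        assert bool(out.loc[3, "visits_imputed"])
        assert rep.n_missing_visits == 1
        assert rep.visit_imputation_cells[("40-49", "male", "2")] == pytest.approx(5.0)

    def test_observed_visits_untouched(self, catalog):
        df = records_to_frame(self.donors(catalog))
        out, rep = impute_visits(df, catalog)
        assert out["reported_visits"].tolist() == [4, 6, 3]
        assert rep.n_missing_visits == 0

    def test_empty_cell_falls_back_to_age_sex(self, catalog):
        # recipient has 0 conditions: no (male, 40-49, 0) donors, so the
        # count band collapses to the (male, 40-49) mean of {4, 6} = 5
        recs = self.donors(catalog) + [make_record(9, age=41, visits=None)]
        df = records_to_frame(recs)
        out, rep = impute_visits(df, catalog)
        assert out.loc[3, "reported_visits"] == pytest.approx(5.0)
        assert rep.visit_fallback_levels["p9"] == "age_sex"

    def test_missing_age_falls_back_to_global(self, catalog):
        recs = self.donors(catalog) + [make_record(9, age=None, visits=None)]
        df = records_to_frame(recs)
        out, rep = impute_visits(df, catalog)
        assert out.loc[3, "reported_visits"] == pytest.approx(np.mean([4, 6, 3]))
        assert rep.visit_fallback_levels["p9"] == "global"

    def test_no_donors_is_an_error(self, catalog):
        df = records_to_frame([make_record(1, visits=None)])
        with pytest.raises(ImputationError, match="no records"):
            impute_visits(df, catalog)

    def test_requires_condition_imputation_first(self, catalog):
        df = records_to_frame([make_record(1, response="missing")])
        with pytest.raises(ImputationError, match="condition-status"):
            impute_visits(df, catalog)

    def test_idempotent(self, catalog):
        recs = self.donors(catalog) + [make_record(9, age=41, visits=None)]
        df = records_to_frame(recs)
        once, _ = impute_visits(df, catalog)
        twice, _ = impute_visits(once, catalog)
        pd.testing.assert_frame_equal(once, twice)

    def test_fractional_means_kept(self, catalog):
        recs = [
            make_record(1, age=44, visits=4),
            make_record(2, age=47, visits=7),
            make_record(3, age=42, visits=None),
        ]
        out, _ = impute_visits(records_to_frame(recs), catalog)
        assert out.loc[2, "reported_visits"] == pytest.approx(5.5)


def test_impute_all_defines_every_record(catalog):
    recs = [
        make_record(1, age=44, visits=4, conditions=["hypertension"]),
        make_record(2, age=47, visits=6),
        make_record(3, age=42, visits=None, response="missing",
                    managed=["hypertension"]),
        make_record(4, age=30, sex="female", visits=2, response="missing",
                    managed=["acute_urti"]),
    ]
    out, rep = impute_all(records_to_frame(recs), catalog)
    assert (out["condition_response"] != "missing").all()
    assert out["reported_visits"].notna().all()
    assert (out["reported_visits"] > 0).all()
    assert rep.n_missing_condition == 2 and rep.n_missing_visits == 1
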