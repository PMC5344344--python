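"""Weight algebra: B, C = B/A, E, F = D/E, and the final factors."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpprev import (
    adjusted_mean_visits,
    attendance_weight,
    build_weight_set,
    final_factors,
    national_weight,
    records_to_frame,
    stratum_shares,
)
from gpprev.weighting import WeightingError

from conftest import make_record


class TestAdjustedMeanVisits:
    def test_identity_on_constant_visits(self):
        assert adjusted_mean_visits([4, 4, 4]) == pytest.approx(4.0)

    def test_harmonic_mean_of_two(self):
        # 2 / (1/8 + 1/6) = 48/7
        assert adjusted_mean_visits([8, 6]) == pytest.approx(48 / 7)

    def test_empty_is_error(self):
        with pytest.raises(WeightingError):
            adjusted_mean_visits([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(1, 60), min_size=1, max_size=40))
    def test_inverse_attendance_weighted_mean_equals_b(self, visits):
        a = np.asarray(visits, dtype=float)
        b = adjusted_mean_visits(a)
        w = 1.0 / a
        assert np.average(a, weights=w) == pytest.approx(b)
        assert a.min() <= b <= a.max()


class TestAttendanceWeight:
    def test_new_method_values(self):
        assert attendance_weight(8, 4.54, "new") == pytest.approx(0.5675)
        assert attendance_weight(6, 4.54, "new") == pytest.approx(4.54 / 6)

    def test_old_method_is_unity(self):
        assert np.allclose(attendance_weight(np.array([1, 7, 30]), 4.54, "old"), 1.0)

    def test_a_equal_b_gives_unity(self):
        assert attendance_weight(4.54, 4.54, "new") == pytest.approx(1.0)

    def test_nonpositive_a_is_error(self):
        with pytest.raises(WeightingError):
            attendance_weight(0, 4.54, "new")


class TestStratumShares:
    def test_unit_weight_counting(self):
        e = stratum_shares([1, 1, 1, 1], [0, 0, 0, 1], n_strata=2)
        assert e.tolist() == pytest.approx([0.75, 0.25])

    def test_weighted_shares(self):
        e = stratum_shares([0.5, 0.5, 1.0], [0, 0, 1], n_strata=2)
        assert e.tolist() == pytest.approx([0.5, 0.5])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0.1, 10), st.integers(0, 3)),
            min_size=1,
            max_size=30,
        )
    )
    def test_shares_sum_to_one(self, pairs):
        c = [p[0] for p in pairs]
        ids = [p[1] for p in pairs]
        assert stratum_shares(c, ids, n_strata=4).sum() == pytest.approx(1.0)


class TestNationalWeight:
    def test_ratio(self):
        assert national_weight(0.0310, 0.0203) == pytest.approx(0.0310 / 0.0203)
        assert national_weight(0.0109, 0.0315) == pytest.approx(0.0109 / 0.0315)

    def test_d_equal_e_is_unity(self):
        assert national_weight(0.2, 0.2) == pytest.approx(1.0)

    def test_empty_stratum_with_population_is_error(self):
        with pytest.raises(WeightingError):
            national_weight(np.array([0.5]), np.array([0.0]))


class TestFinalFactors:
    def test_g_scales_numerator_only(self):
        num, den = final_factors(0.5675, 1.527, 0.7485)
        assert den == pytest.approx(0.5675 * 1.527)
        assert num == pytest.approx(den * 0.7485)

    def test_g_of_one_makes_factors_equal(self):
        num, den = final_factors(1.2, 0.8, 1.0)
        assert num == pytest.approx(den)

    def test_invalid_g_rejected(self):
        with pytest.raises(WeightingError):
            final_factors(1.0, 1.0, 1.5)


class TestBuildWeightSet:
    def hand_oracle(self, toy_records, two_strata, method):
        # spreadsheet-style recomputation for the fixed 4-patient sample
        A = toy_records["reported_visits"].to_numpy(dtype=float)
        B = len(A) / np.sum(1 / A)
        C = B / A if method == "new" else np.ones(4)
        strata = [0, 1, 2, 3]  # p1 -> male young, p2 -> male old, ...
        E = {s: C[i] / C.sum() for i, s in enumerate(strata)}
        D = two_strata.population_share().to_numpy()
        F = {s: D[s] / E[s] for s in strata}
        G = two_strata.attender_share().to_numpy()
        num = np.array([C[i] * F[s] * G[s] for i, s in enumerate(strata)])
        den = np.array([C[i] * F[s] for i, s in enumerate(strata)])
        return B, C, num, den

    @pytest.mark.parametrize("method", ["old", "new"])
    def test_matches_hand_computation(self, toy_records, two_strata, method):
        ws = build_weight_set(toy_records, two_strata, method)
        B, C, num, den = self.hand_oracle(toy_records, two_strata, method)
        assert ws.b_constant == pytest.approx(B)
        assert ws.weights["C"].to_numpy() == pytest.approx(C)
        assert ws.weights["numerator_factor"].to_numpy() == pytest.approx(num)
        assert ws.weights["denominator_factor"].to_numpy() == pytest.approx(den)

    def test_post_stratification_exactness(self, toy_records, two_strata):
        # the denominator-weighted age-sex distribution equals D exactly
        for method in ("old", "new"):
            ws = build_weight_set(toy_records, two_strata, method)
            w = ws.weights
            dist = w.groupby("stratum")["denominator_factor"].sum()
            dist = dist / dist.sum()
            D = two_strata.population_share()
            for s, share in dist.items():
                assert share == pytest.approx(D[s], abs=1e-12)

    def test_old_new_equivalent_under_uniform_visits(self, toy_records, two_strata):
        rec = toy_records.copy()
        rec["reported_visits"] = 5.0
        ws_old = build_weight_set(rec, two_strata, "old")
        ws_new = build_weight_set(rec, two_strata, "new")
        pd.testing.assert_frame_equal(ws_old.weights, ws_new.weights)

    def test_factor_ratio_is_stratum_g(self, toy_records, two_strata):
        ws = build_weight_set(toy_records, two_strata, "new")
        w = ws.weights
        g = two_strata.attender_share().to_numpy()[w["stratum"].to_numpy()]
        assert (w["numerator_factor"] / w["denominator_factor"]).to_numpy() == pytest.approx(g)

    def test_b_scale_changes_weights_not_composition(self, toy_records, two_strata):
        ws1 = build_weight_set(toy_records, two_strata, "new")
        ws10 = build_weight_set(
            toy_records, two_strata, "new", b=10 * ws1.b_constant
        )
        r1 = ws1.weights["numerator_factor"] / ws1.weights["denominator_factor"].sum()
        r10 = ws10.weights["numerator_factor"] / ws10.weights["denominator_factor"].sum()
        assert r1.to_numpy() == pytest.approx(r10.to_numpy(), abs=1e-12)

    def test_missing_stratum_records_excluded(self, two_strata):
        recs = records_to_frame(
            [make_record(1, age=30, visits=2, conditions=["hypertension"]),
             make_record(2, age=None, visits=8)]
        )
        ws = build_weight_set(recs, two_strata, "new")
        assert len(ws.weights) == 1

    def test_uncovered_strata_renormalised(self, toy_records, two_strata):
        # drop the older-female patient: her stratum becomes uncovered
        rec = toy_records.iloc[:3].reset_index(drop=True)
        ws = build_weight_set(rec, two_strata, "new")
        assert ws.uncovered_population_share == pytest.approx(0.25)
        assert ws.stratum_table["population_share"].sum() == pytest.approx(1.0)

    def test_unimputed_missing_visits_rejected(self, two_strata):
        recs = records_to_frame([make_record(1, visits=None)])
        with pytest.raises(WeightingError, match="imputation"):
            build_weight_set(recs, two_strata, "new")
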