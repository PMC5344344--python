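"""Record loading/validation, the catalog, and stratum references."""

import numpy as np
import pandas as pd
import pytest

from gpprev import (
    RecordValidationError,
    StratumReference,
    UnknownConditionError,
    load_records,
    load_stratum_reference,
    write_records,
)
from gpprev.strata import StratumError, five_year_bands


def write_csv(tmp_path, text, name="records.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "patient_id,gp_id,age,sex,reported_visits,condition_response,conditions,encounter_managed\n"


class TestLoadRecords:
    def test_valid_rows_round_trip(self, tmp_path, catalog):
        p = write_csv(
            tmp_path,
            HEADER
            + "p1,g1,45,male,6,yes,hypertension;depression,hypertension\n"
            + "p2,g1,30,female,2,no,,acute_urti\n"
            + "p3,g2,81,female,12,yes,osteoarthritis,\n",
        )
        df = load_records(p, catalog)
        assert len(df) == 3
        assert df.loc[0, "conditions"] == {"hypertension", "depression"}
        out = tmp_path / "out.csv"
        write_records(df, out)
        df2 = load_records(out, catalog)
        for col in ["patient_id", "gp_id", "age", "sex", "reported_visits",
                    "condition_response", "conditions", "encounter_managed"]:
            assert df[col].tolist() == df2[col].tolist(), col

    def test_zero_visits_rejected(self, tmp_path, catalog):
        p = write_csv(tmp_path, HEADER + "p1,g1,45,male,0,no,,\n")
        with pytest.raises(RecordValidationError, match="reported_visits 0"):
            load_records(p, catalog)

    def test_blank_condition_fields_become_missing(self, tmp_path, catalog):
        p = write_csv(tmp_path, HEADER + "p1,g1,45,male,3,,,acute_urti\n")
        df = load_records(p, catalog)
        assert df.loc[0, "condition_response"] == "missing"
        assert df.loc[0, "conditions"] == frozenset()

    def test_unknown_code_names_code_and_row(self, tmp_path, catalog):
        p = write_csv(tmp_path, HEADER + "p1,g1,45,male,3,yes,made_up_code,\n")
        with pytest.raises(RecordValidationError, match="made_up_code.*row 2"):
            load_records(p, catalog)

    def test_inconsistent_response_rejected(self, tmp_path, catalog):
        p = write_csv(tmp_path, HEADER + "p1,g1,45,male,3,no,hypertension,\n")
        with pytest.raises(RecordValidationError, match="no_conditions"):
            load_records(p, catalog)

    def test_missing_cells_are_explicit(self, tmp_path, catalog):
        p = write_csv(tmp_path, HEADER + "p1,g1,,,,yes,asthma,\n")
        df = load_records(p, catalog)
        assert np.isnan(df.loc[0, "age"])
        assert df.loc[0, "sex"] is None
        assert np.isnan(df.loc[0, "reported_visits"])


class TestCatalog:
    def test_unknown_lookup_raises(self, catalog):
        with pytest.raises(UnknownConditionError):
            catalog.chapter("nonexistent")

    def test_chronic_subset_filters_acute(self, catalog):
        got = catalog.chronic_subset({"hypertension", "acute_urti"})
        assert got == {"hypertension"}

    def test_invalid_chapter_rejected(self):
        from gpprev.catalog import CatalogEntry, ConditionCatalog

        with pytest.raises(ValueError, match="ICPC-2"):
            ConditionCatalog({"x": CatalogEntry("x", "X", "Q", True)})


REF_HEADER = "sex,age_low,age_high,population_share,attender_share\n"


class TestStratumReference:
    def test_two_strata_valid(self, tmp_path):
        p = write_csv(
            tmp_path,
            REF_HEADER + "male,0,100,0.5,0.8\nfemale,0,100,0.5,0.9\n",
            "ref.csv",
        )
        ref = load_stratum_reference(p)
        assert ref.n_strata == 2

    def test_shares_not_summing_to_one_rejected(self, tmp_path):
        p = write_csv(
            tmp_path,
            REF_HEADER + "male,0,100,0.4,0.8\nfemale,0,100,0.4,0.9\n",
            "ref.csv",
        )
        with pytest.raises(StratumError, match="sum"):
            load_stratum_reference(p)

    def test_tiny_share_error_renormalised(self, tmp_path):
        eps = 4e-7
        p = write_csv(
            tmp_path,
            REF_HEADER + f"male,0,100,{0.5 + eps},0.8\nfemale,0,100,0.5,0.9\n",
            "ref.csv",
        )
        ref = load_stratum_reference(p)
        assert ref.population_share().sum() == pytest.approx(1.0, abs=1e-12)

    def test_gapped_bands_rejected(self, tmp_path):
        p = write_csv(
            tmp_path,
            REF_HEADER
            + "male,0,40,0.25,0.8\nmale,50,100,0.25,0.8\n"
            + "female,0,50,0.25,0.9\nfemale,50,100,0.25,0.9\n",
            "ref.csv",
        )
        with pytest.raises(StratumError, match="partition"):
            load_stratum_reference(p)

    def test_attender_share_out_of_range_rejected(self, tmp_path):
        p = write_csv(
            tmp_path,
            REF_HEADER + "male,0,100,0.5,1.2\nfemale,0,100,0.5,0.9\n",
            "ref.csv",
        )
        with pytest.raises(StratumError, match="attender_share"):
            load_stratum_reference(p)

    def test_reference_values_preserved_exactly(self, tmp_path):
        # e.g. a young male stratum with D=3.10%, G=74.85% and an older
        # female stratum with D=1.09%, G=96.53%
        p = write_csv(
            tmp_path,
            REF_HEADER
            + "male,10,15,0.0310,0.7485\nmale,0,10,0.4690,0.80\nmale,15,100,0.0,0.8\n"
            + "female,80,85,0.0109,0.9653\nfemale,0,80,0.4891,0.90\nfemale,85,100,0.0,0.9\n",
            "ref.csv",
        )
        ref = load_stratum_reference(p)
        t = ref.table
        young_male = t[(t.sex == "male") & (t.age_low == 10)].iloc[0]
        assert young_male.population_share == pytest.approx(0.0310, abs=1e-12)
        assert young_male.attender_share == pytest.approx(0.7485, abs=1e-12)
        old_female = t[(t.sex == "female") & (t.age_low == 80)].iloc[0]
        assert old_female.population_share == pytest.approx(0.0109, abs=1e-12)
        assert old_female.attender_share == pytest.approx(0.9653, abs=1e-12)


class TestStratumAssignment:
    def test_assignment_total_and_unique_on_default_bands(self):
        bands = five_year_bands()
        rows = []
        for sex in ("male", "female"):
            for lo, hi in bands:
                rows.append(
                    {"sex": sex, "age_low": lo, "age_high": hi,
                     "population_share": 1 / (2 * len(bands)),
                     "attender_share": 0.85}
                )
        ref = StratumReference(pd.DataFrame(rows))
        ages = np.arange(0, 120)
        for sex in ("male", "female"):
            ids = ref.assign_many(ages.astype(float), np.array([sex] * len(ages)))
            assert (ids >= 0).all()
            # each age hits exactly one stratum, and boundaries go to the
            # upper band (half-open intervals)
            assert ref.table.loc[ref.assign(10, sex), "age_low"] == 10

    def test_missing_age_or_sex_unassigned(self, two_strata):
        ids = two_strata.assign_many(
            np.array([np.nan, 30.0]), np.array(["male", None], dtype=object)
        )
        assert (ids == -1).all()
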