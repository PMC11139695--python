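"""Schema integrity, cohort I/O, covariate derivation, exclusion cascade."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dietclust import (CovariateRules, apply_exclusion_cascade,
                       bdhq_schema, derive_covariates, load_cohort,
                       save_schema, standard_exclusion_steps)
from dietclust.cohort import CohortValidationError
from dietclust.schema import SchemaError, VariableDef
from dietclust.synth import ROSTER_COUNTS, enrollment_roster


class TestSchema:
    def test_bdhq_counts(self, schema):
        assert len(schema) == 79
        assert schema.category_counts() == {
            "food_item": 58, "dietary_behavior": 12, "cooking_method": 9}

    def test_scale_lengths_are_instrument_scales(self, schema):
        assert {v.n_categories for v in schema} <= {2, 5, 7, 8, 9}

    def test_weights_strictly_monotone_from_one(self, schema):
        for var in schema:
            w = var.weights
            assert w[0] == 1
            assert all(b > a for a, b in zip(w, w[1:]))

    def test_yaml_roundtrip(self, schema, tmp_path):
        path = tmp_path / "schema.yaml"
        save_schema(schema, path)
        from dietclust import load_schema
        loaded = load_schema(path)
        assert loaded.variable_ids == schema.variable_ids
        assert all(loaded[v.id].scale_labels == v.scale_labels
                   for v in schema)

    def test_non_monotone_weights_rejected(self):
        with pytest.raises(SchemaError, match="strictly increasing"):
            VariableDef("x", "food_item", ("a", "b", "c", "d", "e"),
                        {"a": 1, "b": 3, "c": 2, "d": 4, "e": 5})


class TestCohortIO:
    def test_roundtrip_identity(self, cohort_factory, tmp_path, schema):
        cohort = cohort_factory({"coffee": ["1 cup per week",
                                            "4 cups or more per day"]},
                                covariates={"age": [40.0, 50.0]})
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        loaded = load_cohort(path, schema)
        assert len(loaded) == 2
        assert list(loaded.data["coffee"]) == ["1 cup per week",
                                               "4 cups or more per day"]
        assert loaded.data["age"].tolist() == [40.0, 50.0]

    def test_missing_variable_column_named(self, cohort_factory, tmp_path,
                                           schema):
        cohort = cohort_factory({}, n=2)
        df = cohort.data.drop(columns=["coffee"])
        path = tmp_path / "bad.csv"
        df.to_csv(path, index_label="id")
        with pytest.raises(SchemaError, match="coffee"):
            load_cohort(path, schema)

    def test_off_scale_response_names_participant_and_variable(
            self, cohort_factory, tmp_path, schema):
        cohort = cohort_factory({}, n=2)
        df = cohort.data.astype({v.id: object for v in schema})
        df.loc["p1", "grilled_fish"] = "ten times per day"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index_label="id")
        with pytest.raises(CohortValidationError) as err:
            load_cohort(path, schema)
        assert "p1" in str(err.value) and "grilled_fish" in str(err.value)


class TestCovariateDerivation:
    def test_bmi_from_height_weight(self, cohort_factory):
        cohort = cohort_factory({}, covariates={"weight": 70.0,
                                                "height": 1.75}, n=1)
        derived = derive_covariates(cohort)
        assert derived.data["bmi"].iloc[0] == pytest.approx(70 / 1.75**2,
                                                            abs=1e-9)
        assert derived.data["bmi"].iloc[0] == pytest.approx(22.86, abs=0.005)

    @pytest.mark.parametrize(
        "sbp,dbp,history,expected",
        [(142.0, 80.0, False, True),    # SBP at/over 140 alone suffices
         (139.9, 89.9, False, False),
         (120.0, 90.0, False, True),
         (120.0, 80.0, True, True)])
    def test_baseline_hypertension_rule(self, cohort_factory, sbp, dbp,
                                        history, expected):
        cohort = cohort_factory({}, covariates={
            "sbp": sbp, "dbp": dbp,
            "hypertension_history_or_medication": history}, n=1)
        derived = derive_covariates(cohort)
        assert bool(derived.data["baseline_hypertension"].iloc[0]) is expected

    def test_fbg_threshold_is_strict(self, cohort_factory):
        cohort = cohort_factory({}, covariates={
            "fbg": [126.0, 126.1],
            "diabetes_history_or_medication": [False, False]})
        derived = derive_covariates(cohort)
        assert derived.data["diabetes"].tolist() == [False, True]

    def test_dyslipidemia_any_criterion(self, cohort_factory):
        cohort = cohort_factory({}, covariates={
            "ldl": [140.0, 100.0, 100.0, 100.0],
            "hdl": [60.0, 39.9, 60.0, 60.0],
            "triglycerides": [100.0, 100.0, 150.0, 100.0],
            "dyslipidemia_medication": [False, False, False, True]})
        derived = derive_covariates(cohort)
        assert derived.data["dyslipidemia"].tolist() == [True] * 4

    def test_missing_measurement_flagged_not_false(self, cohort_factory):
        cohort = cohort_factory({}, covariates={
            "fbg": [np.nan], "diabetes_history_or_medication": [False]})
        derived = derive_covariates(cohort)
        assert derived.data["diabetes"].isna().iloc[0]

    def test_idempotent(self, cohort_factory):
        cohort = cohort_factory({}, covariates={
            "sbp": [150.0], "dbp": [70.0], "weight": [80.0],
            "height": [1.8]})
        once = derive_covariates(cohort)
        twice = derive_covariates(once)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestExclusionCascade:
    def test_flowchart_counts(self):
        roster = enrollment_roster(seed=0)
        steps = standard_exclusion_steps(roster.schema)
        filtered, cascade = apply_exclusion_cascade(roster, steps)
        assert cascade.n_in == 1253
        assert cascade.n_out == 447
        by_name = {s.name: s.n_removed for s in cascade.steps}
        expected = {k: v for k, v in ROSTER_COUNTS.items() if k != "total"}
        assert by_name == expected
        # consent proportion as printed
        consent_pct = 100 * (1253 - by_name["no_consent"]) / 1253
        assert round(consent_pct, 1) == 92.1

    def test_conservation_and_empty_steps(self, cohort_factory):
        cohort = cohort_factory({}, covariates={"age": [30.0, 40.0]})
        filtered, cascade = apply_exclusion_cascade(cohort, [])
        assert len(filtered) == 2 and cascade.steps == []
        assert cascade.n_in == cascade.n_out + 0

    def test_first_step_attribution(self, cohort_factory):
        cohort = cohort_factory({}, covariates={"age": [30.0, 40.0, 50.0]})
        steps = [
            ("all", "everyone", lambda df: pd.Series(True, index=df.index)),
            ("older", "age>35", lambda df: df["age"] > 35),
        ]
        filtered, cascade = apply_exclusion_cascade(cohort, steps)
        assert cascade.n_out == 0
        assert [s.n_removed for s in cascade.steps] == [3, 0]

    def test_step_order_changes_attribution_not_n_out(self):
        roster = enrollment_roster(seed=1)
        steps = standard_exclusion_steps(roster.schema)
        base_out = apply_exclusion_cascade(roster, steps)[1].n_out
        for perm in itertools.islice(itertools.permutations(steps), 1, 6):
            out = apply_exclusion_cascade(roster, list(perm))[1].n_out
            assert out == base_out

    def test_conservation_invariant(self):
        roster = enrollment_roster(seed=2)
        steps = standard_exclusion_steps(roster.schema)
        _, cascade = apply_exclusion_cascade(roster, steps)
        assert cascade.n_in == cascade.n_out + sum(
            s.n_removed for s in cascade.steps)
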