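"""Peel-off cascade: task construction, imputation, fitting, prediction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator

from adcascade.cascade import (
    LABELS,
    PipelineSpec,
    Scenario,
    SCENARIO_PRESETS,
    FCSImputer,
    feature_importance,
    fit_cascade,
    impute_fcs,
    make_tasks,
    predict_cascade,
    variant_columns,
)
from adcascade.cohort import CohortSpec, generate_cohort, inject_missingness
from adcascade.io import CLINICAL_COLUMNS


class FixedVote(BaseEstimator):
    """Stub classifier that always votes peel (1) or rest (0)."""

    def __init__(self, vote=0):
        self.vote = vote

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p = np.full(len(X), float(self.vote))
        return np.column_stack([1 - p, p])


class ColumnVote(BaseEstimator):
    """Stub that peels subjects whose (z-scored) indicator column is positive."""

    def __init__(self, col=0):
        self.col = col

    def fit(self, X, y):
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        p = (X[:, self.col] > 0).astype(float)
        return np.column_stack([1 - p, p])


class TestScenarioAndTasks:
    def test_peel_order_ad_first(self):
        tasks = make_tasks("AD-LMCI-NC-EMCI")
        assert [t.positive for t in tasks] == ["AD", "LMCI", "NC"]
        assert tasks[0].name == "AD vs. (EMCI + LMCI + NC)"
        assert tasks[2].name == "NC vs. EMCI"

    def test_peel_order_nc_first(self):
        tasks = make_tasks("NC-EMCI-LMCI-AD")
        assert [t.positive for t in tasks] == ["NC", "EMCI", "LMCI"]
        assert tasks[2].others == ("AD",)

    @pytest.mark.parametrize("name", list(SCENARIO_PRESETS))
    def test_every_scenario_yields_three_tasks_last_pairwise(self, name):
        tasks = make_tasks(SCENARIO_PRESETS[name])
        assert len(tasks) == 3
        assert len(tasks[2].others) == 1

    @pytest.mark.parametrize("bad", ["AD-AD-NC-EMCI", "AD-LMCI-NC", "AD-LMCI-NC-MCI"])
    def test_malformed_scenarios_rejected(self, bad):
        with pytest.raises(ValueError):
            Scenario.parse(bad)


class TestVariantColumns:
    def test_clinical_r_excludes_diagnostic_scores(self):
        cols = variant_columns("clinical_r", [])
        assert "mmse" not in cols and "cdr" not in cols
        assert set(cols) == set(CLINICAL_COLUMNS) - {"mmse", "cdr"}

    def test_combined_variants_are_exact_unions(self):
        imaging = ["f1", "f2"]
        assert variant_columns("clinical+imaging", imaging) == \
            variant_columns("clinical", imaging) + imaging
        assert variant_columns("clinical_r+imaging", imaging) == \
            variant_columns("clinical_r", imaging) + imaging

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            variant_columns("imaging_only", ["f1"])

    def test_imaging_variant_requires_columns(self):
        with pytest.raises(ValueError, match="non-empty"):
            variant_columns("imaging", [])


class TestImputeFCS:
    def test_complete_table_returned_unchanged(self, small_cohort):
        tab = small_cohort.clinical_table
        pd.testing.assert_frame_equal(impute_fcs(tab), tab)

    def test_no_missing_cells_remain(self, small_cohort):
        masked = inject_missingness(small_cohort.clinical_table, 0.15, seed=1)
        completed = impute_fcs(masked, m=3, seed=2)
        assert not completed[CLINICAL_COLUMNS].isna().any().any()

    def test_beats_mean_imputation_on_correlated_covariates(self):
        cohort = generate_cohort(CohortSpec(n_per_class=(80, 60, 60, 50), d=4, s=2, seed=8))
        truth = cohort.clinical_table
        masked = inject_missingness(truth, 0.1, seed=3)
        completed = impute_fcs(masked, m=5, seed=4)
        cont = ["age", "education_years", "cdr", "faq", "mmse"]
        holes = masked[cont].isna()
        err_fcs, err_mean = [], []
        for c in cont:
            h = holes[c]
            if not h.any():
                continue
            err_fcs.extend((completed.loc[h, c] - truth.loc[h, c]).tolist())
            err_mean.extend((masked[c].mean() - truth.loc[h, c]).tolist())
        rmse = lambda e: float(np.sqrt(np.mean(np.square(e))))
        assert rmse(err_fcs) < rmse(err_mean)

    def test_seeded_determinism(self, small_cohort):
        masked = inject_missingness(small_cohort.clinical_table, 0.2, seed=5)
        a = impute_fcs(masked, m=3, seed=7)
        b = impute_fcs(masked, m=3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_fully_missing_column_rejected(self, small_cohort):
        masked = small_cohort.clinical_table.copy()
        masked["faq"] = np.nan
        with pytest.raises(ValueError, match="faq"):
            impute_fcs(masked)

    def test_categorical_imputations_are_valid_codes(self, small_cohort):
        masked = inject_missingness(small_cohort.clinical_table, 0.3, seed=6)
        completed = impute_fcs(masked, m=3, seed=8)
        for c in ("sex", "married", "apoe4"):
            assert set(completed[c].unique()) <= {0.0, 1.0}


class TestFitPredictCascade:
    def test_separable_cohort_training_accuracy_one(self, separable_cohort):
        table = separable_cohort.modelling_table([])
        pipe = PipelineSpec(variant="clinical", learner="rf")
        model = fit_cascade(table, pipe, seed=0)
        pred = predict_cascade(model, table)
        assert np.mean(pred == table["label"].to_numpy()) == 1.0

    def test_clinical_r_manifest_excludes_mmse_and_cdr(self, separable_cohort):
        table = separable_cohort.modelling_table([])
        model = fit_cascade(table, PipelineSpec(variant="clinical_r", learner="lr"), seed=0)
        assert "mmse" not in model.columns and "cdr" not in model.columns

    def test_seeded_refit_is_identical(self, small_cohort):
        table = small_cohort.modelling_table(small_cohort.feature_ids[:4])
        pipe = PipelineSpec(variant="clinical+imaging", learner="rf",
                            imaging_columns=small_cohort.feature_ids[:4])
        m1 = fit_cascade(table, pipe, seed=42)
        m2 = fit_cascade(table, pipe, seed=42)
        assert m1.manifest() == m2.manifest()
        assert np.array_equal(predict_cascade(m1, table), predict_cascade(m2, table))

    def test_unsupported_learner_rejected(self, small_cohort):
        table = small_cohort.modelling_table([])
        with pytest.raises(ValueError, match="unsupported learner"):
            fit_cascade(table, PipelineSpec(variant="clinical", learner="mlp"), seed=0)

    def test_missing_class_rejected(self, small_cohort):
        table = small_cohort.modelling_table([])
        with pytest.raises(ValueError, match="missing"):
            fit_cascade(table[table["label"] != "AD"],
                        PipelineSpec(variant="clinical", learner="lr"), seed=0)

    def test_param_grid_tunes_inside_training_data(self, separable_cohort):
        table = separable_cohort.modelling_table([])
        pipe = PipelineSpec(variant="clinical", learner="lr", param_grid={"C": [0.1, 1.0]})
        model = fit_cascade(table, pipe, seed=0)
        pred = predict_cascade(model, table)
        assert np.mean(pred == table["label"].to_numpy()) == 1.0

    def test_manifest_mismatch_rejected_at_predict(self, separable_cohort):
        table = separable_cohort.modelling_table([])
        model = fit_cascade(table, PipelineSpec(variant="clinical", learner="lr"), seed=0)
        with pytest.raises(ValueError, match="manifest"):
            predict_cascade(model, table.drop(columns=["faq"]))


class TestCascadeStubs:
    @staticmethod
    def _indicator_table(order):
        rng = np.random.default_rng(0)
        labels = np.repeat(LABELS, 15)
        tab = pd.DataFrame({"subject_id": [f"s{i}" for i in range(60)], "label": labels})
        for i in range(3):
            tab[f"c{i}"] = (labels == order[i]).astype(float)
        # jitter avoids identical SMOTE neighbours being the only structure
        tab[["c0", "c1", "c2"]] += rng.normal(scale=1e-3, size=(60, 3))
        return tab

    def _pipe(self, learners):
        return PipelineSpec(
            scenario="AD-LMCI-NC-EMCI", variant="imaging",
            imaging_columns=["c0", "c1", "c2"], learner=learners, smote_k=5,
        )

    def test_always_rest_assigns_final_label(self):
        tab = self._indicator_table(("AD", "LMCI", "NC", "EMCI"))
        model = fit_cascade(tab, self._pipe([FixedVote(0)] * 3), seed=0)
        pred = predict_cascade(model, tab)
        assert set(pred) == {"EMCI"}

    def test_always_peel_at_first_task_assigns_first_label(self):
        tab = self._indicator_table(("AD", "LMCI", "NC", "EMCI"))
        model = fit_cascade(tab, self._pipe([FixedVote(1), FixedVote(0), FixedVote(0)]), seed=0)
        pred = predict_cascade(model, tab)
        assert set(pred) == {"AD"}

    def test_truth_encoding_stubs_recover_all_labels(self):
        order = ("AD", "LMCI", "NC", "EMCI")
        tab = self._indicator_table(order)
        model = fit_cascade(tab, self._pipe([ColumnVote(0), ColumnVote(1), ColumnVote(2)]), seed=0)
        pred = predict_cascade(model, tab)
        assert np.array_equal(pred, tab["label"].to_numpy())

    @pytest.mark.parametrize("scenario", list(SCENARIO_PRESETS))
    def test_predictions_partition_subjects(self, scenario, separable_cohort):
        table = separable_cohort.modelling_table([])
        model = fit_cascade(table, PipelineSpec(scenario=scenario, variant="clinical",
                                                learner="nb"), seed=1)
        pred = predict_cascade(model, table)
        assert len(pred) == len(table)
        assert set(pred) <= set(LABELS)


def test_feature_importance_exposed_for_forest(separable_cohort):
    table = separable_cohort.modelling_table([])
    model = fit_cascade(table, PipelineSpec(variant="clinical", learner="rf"), seed=0)
    imp = feature_importance(model)
    assert set(imp["task"]) == {t.name for t in model.tasks}
    # the diagnosis-defining scores must dominate on separable data
    top = imp[imp["task"] == model.tasks[0].name].nlargest(3, "importance")["feature"]
    assert {"cdr", "faq", "mmse"} & set(top)


def test_fcs_imputer_transform_requires_fit(small_cohort):
    imp = FCSImputer(CLINICAL_COLUMNS)
    with pytest.raises(RuntimeError):
        imp.transform(small_cohort.clinical_table)
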