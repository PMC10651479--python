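"""Scaler → PCA → logistic regression pipeline and its robustness analyses."""

import numpy as np
import pandas as pd
import pytest

import tissuedc as t
from tissuedc.exceptions import ParameterError, SchemaError
from conftest import featurize_cohort


def toy_matrix(rng, n=20, p=8, shift=4.0):
    """Two-class Gaussian matrix with a strong mean shift on half the columns."""
    X = rng.normal(0, 1, (n, p))
    labels = ["disease" if i % 2 else "healthy" for i in range(n)]
    for i, lbl in enumerate(labels):
        if lbl == "disease":
            X[i, : p // 2] += shift
    return pd.DataFrame(X, columns=[f"p{j}" for j in range(p)],
                        index=[f"s{i}" for i in range(n)]), labels


class TestFitPipeline:
    def test_separable_cohort_fully_classified(self, rng):
        X, labels = toy_matrix(rng, shift=5.0)
        model = t.fit_pipeline(X, labels, seed=0)
        preds = t.predict_samples(model, X)
        assert all(p.label == l for p, l in zip(preds, labels))

    def test_explained_variance_properties(self, trained_model):
        model, _, _ = trained_model
        evr = model.explained_variance_ratio
        assert evr[0] >= evr[1] >= 0
        assert evr.sum() <= 1 + 1e-12

    def test_loadings_orthonormal(self, trained_model):
        model, _, _ = trained_model
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-9)

    def test_scores_centred_on_training(self, trained_model):
        model, matrix, _ = trained_model
        scores = model.project(matrix.to_numpy(dtype=float))
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-9)

    def test_scaled_training_matrix_in_unit_box(self, trained_model):
        model, matrix, _ = trained_model
        scaled = model.scale(matrix.to_numpy(dtype=float))
        assert scaled.min() >= -1e-12 and scaled.max() <= 1 + 1e-12
        np.testing.assert_allclose(scaled.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(scaled.max(axis=0), 1.0, atol=1e-12)

    def test_row_duplication_keeps_loadings(self, rng):
        X, labels = toy_matrix(rng)
        m1 = t.fit_pipeline(X, labels, seed=0)
        m2 = t.fit_pipeline(pd.concat([X, X]), labels + labels, seed=0)
        np.testing.assert_allclose(m1.loadings, m2.loadings, atol=1e-9)

    def test_constant_column_scaled_to_zero(self, rng):
        X, labels = toy_matrix(rng)
        X["const"] = 3.14
        model = t.fit_pipeline(X, labels, seed=0)
        scaled = model.scale(X.to_numpy(dtype=float))
        assert (scaled[:, -1] == 0).all()
        assert t.feature_importance(model).loc["const"].eq(0).all()

    def test_single_class_rejected(self, rng):
        X, _ = toy_matrix(rng)
        with pytest.raises(ParameterError):
            t.fit_pipeline(X, ["healthy"] * len(X), seed=0)

    def test_json_round_trip(self, trained_model, tmp_path):
        model, matrix, _ = trained_model
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = t.TrainedClassifier.from_json(path)
        p1 = t.predict_samples(model, matrix)
        p2 = t.predict_samples(loaded, matrix)
        assert [p.probability for p in p1] == [p.probability for p in p2]


class TestPredict:
    def test_training_side_consistency(self, trained_model):
        model, matrix, labels = trained_model
        preds = t.predict_samples(model, matrix)
        # the trained decision boundary reproduces the fit-time assignments
        scores = model.project(matrix.to_numpy(dtype=float))
        logits = scores @ model.lr_coef + model.lr_intercept
        for p, logit in zip(preds, logits):
            assert (p.label == "disease") == (logit >= 0)

    def test_identical_sample_identical_prediction(self, trained_model):
        model, matrix, _ = trained_model
        row = matrix.iloc[[0]]
        p1 = t.predict_samples(model, row)[0]
        p2 = t.predict_samples(model, row.copy())[0]
        assert p1.probability == p2.probability

    def test_column_mismatch_rejected(self, trained_model):
        model, matrix, _ = trained_model
        bad = matrix.rename(columns={matrix.columns[0]: "oops"})
        with pytest.raises(SchemaError):
            t.predict_samples(model, bad)

    def test_blind_accuracy_on_generator(self, mouse_cfg):
        """Blind samples from the training distributions classify correctly."""
        correct = total = 0
        for seed in range(30):
            spec = t.CohortSpec(n_pairs=8, events_per_sample=(1000, 2000))
            cohort = t.sample_cohort(spec, seed=seed)
            matrix, labels = featurize_cohort(cohort, mouse_cfg)
            model = t.fit_pipeline(matrix, labels, seed=0)
            blind = t.sample_cohort(
                t.CohortSpec(n_pairs=1, events_per_sample=(1000, 2000)),
                seed=10_000 + seed)
            bm, bl = featurize_cohort(blind, mouse_cfg)
            for p, l in zip(t.predict_samples(model, bm), bl):
                correct += p.label == l
                total += 1
        assert correct / total >= 0.90


class TestFeatureImportance:
    def test_single_signal_dominates_pc1(self, rng):
        n = 24
        X = pd.DataFrame({
            "signal": np.r_[rng.normal(0, 1, n // 2), rng.normal(8, 1, n // 2)],
            **{f"noise{j}": rng.normal(0, 0.05, n) for j in range(5)},
        })
        labels = ["healthy"] * (n // 2) + ["disease"] * (n // 2)
        model = t.fit_pipeline(X, labels, seed=0)
        imp = t.feature_importance(model)
        assert imp["PC1"].idxmax() == "signal"
        assert imp["PC1"].max() == pytest.approx(1.0)

    def test_importances_in_unit_interval(self, trained_model):
        model, _, _ = trained_model
        imp = t.feature_importance(model)
        assert ((imp >= 0) & (imp <= 1)).all().all()


class TestMinCellsCurve:
    def test_full_sample_matches_direct_prediction(self, trained_model,
                                                   paired_cohort, mouse_cfg):
        model, _, _ = trained_model
        rec = paired_cohort[0]
        kept, _ = t.apply_debris_gates(rec.events)
        vec = t.summarize_sample(kept, mouse_cfg, sample_id=rec.sample_id)
        matrix, _ = t.assemble_matrix([vec])
        direct = t.predict_samples(model, matrix)[0]
        curve = t.min_cells_curve({rec.sample_id: kept},
                                  {rec.sample_id: rec.condition},
                                  model, mouse_cfg, n_grid=[len(kept)],
                                  reps=1, seed=0)
        assert curve["accuracy"].iloc[0] == float(direct.label == rec.condition)

    def test_accuracy_saturates_with_cells(self, trained_model, paired_cohort,
                                           mouse_cfg):
        model, _, _ = trained_model
        events, truth = {}, {}
        for rec in paired_cohort[:6]:
            kept, _ = t.apply_debris_gates(rec.events)
            events[rec.sample_id] = kept
            truth[rec.sample_id] = rec.condition
        curve = t.min_cells_curve(events, truth, model, mouse_cfg,
                                  n_grid=[800, 1200], reps=10, seed=0)
        assert curve["accuracy"].iloc[-1] >= 0.95

    def test_reproducible_with_seed(self, trained_model, paired_cohort, mouse_cfg):
        model, _, _ = trained_model
        rec = paired_cohort[0]
        kept, _ = t.apply_debris_gates(rec.events)
        args = ({rec.sample_id: kept}, {rec.sample_id: rec.condition},
                model, mouse_cfg)
        c1 = t.min_cells_curve(*args, n_grid=[300], reps=1, seed=5)
        c2 = t.min_cells_curve(*args, n_grid=[300], reps=1, seed=5)
        assert c1.equals(c2)

    def test_oversized_grid_points_skipped(self, trained_model, paired_cohort,
                                           mouse_cfg):
        model, _, _ = trained_model
        rec = paired_cohort[0]
        kept, _ = t.apply_debris_gates(rec.events)
        curve = t.min_cells_curve({rec.sample_id: kept},
                                  {rec.sample_id: rec.condition},
                                  model, mouse_cfg,
                                  n_grid=[10**7], reps=1, seed=0)
        assert curve.empty


@pytest.fixture(scope="module")
def pools():
    h, _ = t.apply_debris_gates(t.sample_events(t.healthy_colon(), 5000, seed=30))
    d, _ = t.apply_debris_gates(t.sample_events(t.tumour_colon(), 5000, seed=31))
    return h, d


class TestMixtureTitration:
    def test_endpoints_match_pure_predictions(self, trained_model, pools, mouse_cfg):
        model, _, _ = trained_model
        h, d = pools
        n = min(len(h), len(d))
        table = t.mixture_titration(h, d, [0.0, 1.0], model, mouse_cfg,
                                    seed=0, n_pool=n)
        # f=0 is a pure healthy pool, f=1 a pure disease pool
        assert table.loc[table.fraction == 0.0, "label"].iloc[0] == "healthy"
        assert table.loc[table.fraction == 1.0, "label"].iloc[0] == "disease"

    def test_probability_rises_with_tumour_fraction(self, trained_model, pools,
                                                    mouse_cfg):
        model, _, _ = trained_model
        h, d = pools
        probs = []
        for seed in range(15):
            tab = t.mixture_titration(h, d, [0, 0.25, 0.5, 0.75, 1.0],
                                      model, mouse_cfg, seed=seed)
            probs.append(tab["probability"].to_numpy())
        med = np.median(probs, axis=0)
        assert (np.diff(med) >= -1e-9).all()
        assert med[2] >= 0.5  # 50/50 mix reads as tumour

    def test_empty_pool_rejected(self, trained_model, pools, mouse_cfg):
        model, _, _ = trained_model
        h, d = pools
        with pytest.raises(ParameterError):
            t.mixture_titration(h.iloc[:0], d, [0.5], model, mouse_cfg)
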