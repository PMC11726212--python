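import numpy as np
import pytest

from adattn.network import (
    ModelConfig,
    ModelError,
    TrainConfig,
    TrainingError,
    build_matched_baseline,
    build_model,
    count_parameters,
    load_model,
    loss_and_dlogits,
    predict,
    save_model,
    train,
)
from adattn.schema import FeatureSchema, FeatureSpec

from conftest import make_schema, make_table


@pytest.fixture()
def model(tiny_schema):
    return build_model(tiny_schema, ModelConfig(embed_dim=3, hidden=(6, 4), seed=0))


def _rows(schema, n, seed=0):
    return np.random.default_rng(seed).uniform(size=(n, len(schema)))


class TestBuild:
    def test_trunk_input_is_4d_plus_direct(self, schema):
        m = build_model(schema, ModelConfig(embed_dim=8))
        assert m.trunk_in_dim == 4 * 8 + 2 == 34

    def test_same_seed_gives_bit_identical_parameters(self, tiny_schema):
        cfg = ModelConfig(seed=9)
        m1, m2 = build_model(tiny_schema, cfg), build_model(tiny_schema, cfg)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_schema_missing_a_group_is_rejected(self):
        incomplete = make_schema(
            {"G1_blood": ["a"], "G2_biochem": ["b"], "G3_endocrine": ["c"]}
        )
        with pytest.raises(ModelError, match="G4_lifestyle"):
            build_model(incomplete)


class TestForward:
    def test_outputs_in_unit_cube_over_random_rows(self, model, tiny_schema):
        out = model.forward(_rows(tiny_schema, 1000))
        assert out.shape == (1000, 3)
        assert (out >= 0).all() and (out <= 1).all()

    def test_forward_is_a_pure_function(self, model, tiny_schema):
        V = _rows(tiny_schema, 1)
        batch = np.vstack([V, V, V])
        out = model.forward(batch)
        np.testing.assert_array_equal(out[0], out[1])
        np.testing.assert_array_equal(out[1], out[2])

    def test_unnormalized_input_rejected(self, model, tiny_schema):
        V = _rows(tiny_schema, 2)
        V[0, 0] = 1.5
        with pytest.raises(ModelError, match="normalized"):
            model.forward(V)

    def test_within_group_permutation_with_matched_params_is_invariant(
        self, tiny_schema
    ):
        # permute G1's three features in the schema, carry the embedding rows
        # along, permute the input columns identically: outputs must not move
        m = build_model(tiny_schema, ModelConfig(embed_dim=3, hidden=(6, 4), seed=3))
        perm = [2, 0, 1]
        specs = list(tiny_schema.features)
        permuted = tuple([specs[p] for p in perm] + specs[3:])
        m2 = build_model(
            FeatureSchema(permuted), ModelConfig(embed_dim=3, hidden=(6, 4), seed=3)
        )
        for k in m.params:
            m2.params[k] = m.params[k].copy()
        m2.params["G1_blood_w"] = m.params["G1_blood_w"][perm]
        m2.params["G1_blood_b"] = m.params["G1_blood_b"][perm]
        V = _rows(tiny_schema, 5, seed=4)
        V2 = V.copy()
        V2[:, :3] = V[:, perm]
        np.testing.assert_allclose(m2.forward(V2), m.forward(V), atol=1e-12)

    def test_batch_equals_row_by_row(self, model, tiny_schema):
        V = _rows(tiny_schema, 7)
        whole = model.forward(V)
        rows = np.vstack([model.forward(V[i : i + 1]) for i in range(7)])
        np.testing.assert_allclose(whole, rows, atol=1e-12)


class TestParameterCounts:
    def test_single_linear_layer_count(self):
        flat = make_schema({"G2_biochem": ["w", "x", "y", "z"]})
        from adattn.network import BaselineModel

        b = BaselineModel(flat, hidden=(), config=ModelConfig())
        assert count_parameters(b) == 4 * 3 + 3

    def test_widening_trunk_strictly_increases_count(self, tiny_schema):
        narrow = build_model(tiny_schema, ModelConfig(hidden=(8, 4)))
        wide = build_model(tiny_schema, ModelConfig(hidden=(16, 8)))
        assert count_parameters(wide) > count_parameters(narrow)

    @pytest.mark.parametrize(
        "config",
        [
            ModelConfig(),
            ModelConfig(embed_dim=4),
            ModelConfig(hidden=(32, 16)),
            ModelConfig(embed_dim=12, hidden=(48, 24)),
        ],
        ids=["default", "small-embed", "narrow-trunk", "perturbed"],
    )
    def test_baseline_parameter_parity_within_ten_percent(self, schema, config):
        proposed = count_parameters(build_model(schema, config))
        baseline = count_parameters(build_matched_baseline(schema, config))
        assert abs(baseline - proposed) / proposed <= 0.10

    def test_parity_holds_even_for_tiny_schema(self, tiny_schema):
        proposed = count_parameters(build_model(tiny_schema))
        baseline = count_parameters(build_matched_baseline(tiny_schema))
        assert abs(baseline - proposed) / proposed <= 0.10


class TestGradients:
    def test_backprop_matches_finite_differences(self, model, tiny_schema):
        rng = np.random.default_rng(5)
        V = rng.uniform(size=(4, len(tiny_schema)))
        y = rng.uniform(size=(4, 3))

        def loss():
            out, _ = model._forward_cache(V)
            return loss_and_dlogits(out, y, "bce", "sigmoid")[0]

        out, cache = model._forward_cache(V)
        _, dlogits = loss_and_dlogits(out, y, "bce", "sigmoid")
        grads = model._backward(cache, dlogits)
        h = 1e-6
        for key in ("G1_blood_w", "G2_biochem_b", "W0", "c2"):
            g = grads[key]
            flat_idx = [(0,) * g.ndim, tuple(s - 1 for s in g.shape)]
            for idx in flat_idx:
                orig = model.params[key][idx]
                model.params[key][idx] = orig + h
                lp = loss()
                model.params[key][idx] = orig - h
                lm = loss()
                model.params[key][idx] = orig
                assert g[idx] == pytest.approx((lp - lm) / (2 * h), rel=1e-4, abs=1e-8)


class TestTraining:
    def test_constant_targets_converge_to_the_constant(self, tiny_schema):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(120, len(tiny_schema)))
        y = np.full((120, 3), 0.5)
        m = build_model(tiny_schema, ModelConfig(embed_dim=3, hidden=(6, 4), seed=1))
        m, _ = train(
            m, X, y, X[:20], y[:20],
            TrainConfig(max_epochs=150, patience=150, seed=1),
        )
        out = m.forward(X)
        assert np.abs(out - 0.5).max() < 0.05

    def test_same_seed_reproduces_identical_history(self, tiny_schema):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(60, len(tiny_schema)))
        y = rng.uniform(size=(60, 3))
        hists = []
        for _ in range(2):
            m = build_model(tiny_schema, ModelConfig(embed_dim=3, seed=7))
            _, h = train(
                m, X, y, X[:10], y[:10], TrainConfig(max_epochs=20, seed=7)
            )
            hists.append(h)
        assert hists[0]["train_loss"] == hists[1]["train_loss"]
        assert hists[0]["val_loss"] == hists[1]["val_loss"]

    def test_validation_loss_beats_constant_predictor_on_signal(self, tiny_schema):
        # features carry the labels directly; learned val loss must undercut
        # the analytic BCE of the best constant predictor (the label mean)
        rng = np.random.default_rng(3)
        n = 300
        y = rng.uniform(0.05, 0.95, size=(n, 3))
        X = np.zeros((n, len(tiny_schema)))
        X[:, :3] = y
        X[:, 3:] = rng.uniform(size=(n, len(tiny_schema) - 3))
        m = build_model(tiny_schema, ModelConfig(embed_dim=4, seed=4))
        m, hist = train(
            m, X[:240], y[:240], X[240:], y[240:],
            TrainConfig(max_epochs=120, patience=120, seed=4),
        )
        ybar = y[:240].mean(axis=0)
        yv = y[240:]
        const_bce = float(
            (-(yv * np.log(ybar) + (1 - yv) * np.log(1 - ybar))).sum(axis=1).mean()
        )
        assert min(hist["val_loss"]) < const_bce

    def test_empty_training_set_rejected(self, model, tiny_schema):
        with pytest.raises(TrainingError, match="empty"):
            train(model, np.empty((0, len(tiny_schema))), np.empty((0, 3)),
                  _rows(tiny_schema, 2), np.zeros((2, 3)))

    def test_out_of_range_targets_rejected(self, model, tiny_schema):
        X = _rows(tiny_schema, 4)
        with pytest.raises(TrainingError, match=r"\[0, 1\]"):
            train(model, X, np.full((4, 3), 1.5), X, np.zeros((4, 3)))


class TestPredictAndSerialize:
    def test_predict_aligns_ids_and_roundtrips_csv(self, model, tiny_schema, tmp_path):
        t = make_table(_rows(tiny_schema, 5), tiny_schema.names)
        preds = predict(model, t)
        assert list(preds["patient_id"]) == t.patient_ids
        vals = preds[["lv", "pca", "fv"]].to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()
        path = tmp_path / "preds.csv"
        preds.to_csv(path, index=False)
        import pandas as pd

        back = pd.read_csv(path)
        np.testing.assert_allclose(back[["lv", "pca", "fv"]].to_numpy(), vals)

    def test_model_json_roundtrip_preserves_predictions(
        self, model, tiny_schema, tmp_path
    ):
        V = _rows(tiny_schema, 6)
        path = save_model(model, tmp_path / "m.json")
        back = load_model(path)
        np.testing.assert_array_equal(back.forward(V), model.forward(V))

    def test_baseline_json_roundtrip(self, tiny_schema, tmp_path):
        b = build_matched_baseline(tiny_schema)
        V = _rows(tiny_schema, 3)
        back = load_model(save_model(b, tmp_path / "b.json"))
        np.testing.assert_array_equal(back.forward(V), b.forward(V))

    def test_schema_mismatch_rejected(self, model):
        wrong = make_table(np.zeros((2, 3)), ["x", "y", "z"])
        with pytest.raises(ModelError, match="schema"):
            predict(model, wrong)
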