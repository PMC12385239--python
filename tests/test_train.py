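"""Splits, optimizers, metrics, ablations, profiling, small training runs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nbx import synthetic
from nbx._tensor import Tensor
from nbx.models import CnnConfig, HeadConfig, ModelConfig, VitConfig
from nbx.models.cnn import ConvStage
from nbx.models.full import BridgeClassifier
from nbx.optim import PRESETS, OptimizerSpec, make_optimizer
from nbx.train import (RunConfig, ablate, cross_validate, evaluate,
                       fixed_split, kfold_split, metrics_from_confusion,
                       profile, train)


def _manifest(n_per_class, classes=("a", "b")):
    rows = [{"path": f"{c}/{i}.png", "label": c, "is_synthetic": False,
             "mask_path": ""} for c in classes for i in range(n_per_class)]
    return pd.DataFrame(rows)


def tiny_model_config(side=16, num_classes=2):
    return ModelConfig(
        side=side,
        cnn=CnnConfig(backbone="tiny",
                      stages=(ConvStage(8, 3, 2), ConvStage(8, 3, 2)),
                      gate_reduction=4),
        vit=VitConfig(patch_size=8, embed_dim=16, depth=1, heads=2),
        head=HeadConfig(num_classes=num_classes, bridge_hidden=32,
                        classifier_hidden=32, lambda_x=0.0))


class TestFixedSplit:
    def test_balanced_80_20(self):
        m = _manifest(25, classes=("a", "b", "c", "d"))
        tr, va = fixed_split(m, frac=0.2, seed=0)
        assert len(tr) == 80 and len(va) == 20
        assert va["label"].value_counts().eq(5).all()

    def test_deterministic_per_seed(self):
        m = _manifest(20)
        tr1, va1 = fixed_split(m, seed=3)
        tr2, va2 = fixed_split(m, seed=3)
        pd.testing.assert_frame_equal(va1, va2)

    def test_parts_disjoint_over_random_manifests(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            sizes = rng.integers(3, 30, size=3)
            m = pd.concat([_manifest(int(s), classes=(c,)) for s, c in
                           zip(sizes, "xyz")], ignore_index=True)
            tr, va = fixed_split(m, seed=int(rng.integers(100)))
            assert not set(tr["path"]) & set(va["path"])
            assert len(tr) + len(va) == len(m)

    def test_singleton_class_rejected(self):
        m = pd.concat([_manifest(5, classes=("a",)),
                       _manifest(1, classes=("b",))], ignore_index=True)
        with pytest.raises(ValueError, match="single"):
            fixed_split(m)


class TestKfoldSplit:
    def test_ten_rows_five_folds(self):
        m = _manifest(5)
        folds = kfold_split(m, k=5, seed=0)
        assert len(folds) == 5
        assert all(len(va) == 2 for _, va in folds)
        union = sorted(p for _, va in folds for p in va["path"])
        assert union == sorted(m["path"])

    @given(st.integers(5, 60), st.integers(0, 2**16))
    @settings(deadline=None, max_examples=25)
    def test_folds_partition_any_manifest(self, n, seed):
        m = _manifest(n)
        folds = kfold_split(m, k=5, seed=seed)
        vals = [set(va["path"]) for _, va in folds]
        assert sum(len(v) for v in vals) == len(m)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not vals[i] & vals[j]
            assert not vals[i] & set(folds[i][0]["path"])

    def test_same_seed_same_folds(self):
        m = _manifest(13)
        f1 = kfold_split(m, seed=5)
        f2 = kfold_split(m, seed=5)
        for (_, v1), (_, v2) in zip(f1, f2):
            pd.testing.assert_frame_equal(v1, v2)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(_manifest(2, classes=("a",)), k=5)


class TestOptimizers:
    def test_sgd_preset_descends_quadratic(self):
        p = {"x": Tensor(np.array([5.0]), requires_grad=True)}
        opt = make_optimizer("sgd", p)
        values = []
        for _ in range(10):
            opt.zero_grad()
            loss = (p["x"] * p["x"]).sum()
            loss.backward()
            opt.step()
            values.append(abs(float(p["x"].data[0])))
        assert values[-1] < 5.0 and values[-1] < values[0]

    def test_fractional_exponent_zero_equals_plain_radam(self):
        def run(spec):
            rng = np.random.default_rng(0)
            p = {"w": Tensor(rng.normal(size=4), requires_grad=True)}
            opt = make_optimizer(spec, p)
            target = Tensor(np.array([1.0, -1.0, 2.0, 0.0]))
            traj = []
            for _ in range(25):
                opt.zero_grad()
                ((p["w"] - target) ** 2).sum().backward()
                opt.step()
                traj.append(p["w"].data.copy())
            return np.array(traj)

        frac0 = run(OptimizerSpec(name="fractional_radam", lr=5e-4,
                                  decay_exponent=0.0))
        plain = run(PRESETS["radam"])
        assert np.array_equal(frac0, plain)
        decayed = run(PRESETS["fractional_radam"])
        assert not np.array_equal(frac0, decayed)

    def test_nadam_preset_descends(self):
        p = {"x": Tensor(np.array([3.0]), requires_grad=True)}
        opt = make_optimizer("nadam", p)
        for _ in range(50):
            opt.zero_grad()
            (p["x"] * p["x"]).sum().backward()
            opt.step()
        assert abs(float(p["x"].data[0])) < 3.0

    def test_states_are_independent(self):
        p1 = {"x": Tensor(np.array([1.0]), requires_grad=True)}
        p2 = {"x": Tensor(np.array([1.0]), requires_grad=True)}
        o1 = make_optimizer("sgd", p1)
        o2 = make_optimizer("sgd", p2)
        p1["x"].grad = np.array([1.0])
        o1.step()
        assert o2.t == 0 and float(p2["x"].data[0]) == 1.0

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown optimizer"):
            make_optimizer("adamw", {})


class TestMetrics:
    def test_perfect_predictions(self):
        conf = np.diag([5, 7, 3])
        scores = np.eye(3)[np.repeat([0, 1, 2], [5, 7, 3])]
        y = np.repeat([0, 1, 2], [5, 7, 3])
        rep = metrics_from_confusion(conf, scores, y)
        assert rep.accuracy == 1.0 and rep.f1_macro == 1.0
        assert rep.roc_auc == 1.0

    def test_single_class_collapse_pattern(self):
        """All instances assigned to one class on a balanced binary set."""
        rep = metrics_from_confusion(np.array([[5, 0], [5, 0]]))
        assert rep.accuracy == pytest.approx(0.5)
        assert rep.recall_macro == pytest.approx(0.5)
        assert rep.f1_macro == pytest.approx(1 / 3)
        assert rep.precision_macro == pytest.approx(0.25)

    def test_identities(self):
        conf = np.array([[8, 2, 0], [1, 9, 0], [0, 3, 7]])
        rep = metrics_from_confusion(conf)
        assert rep.recall_weighted == pytest.approx(rep.accuracy)
        assert rep.confusion.sum(axis=1).tolist() == [10, 10, 10]

    def test_binary_auc_equals_mann_whitney(self, rng):
        y = rng.integers(0, 2, size=60)
        scores1 = rng.normal(size=60) + y        # informative scores
        probs = np.column_stack([1 - scores1, scores1])
        conf = np.array([[int(((y == 0) & (scores1 < 0.5)).sum()),
                          int(((y == 0) & (scores1 >= 0.5)).sum())],
                         [int(((y == 1) & (scores1 < 0.5)).sum()),
                          int(((y == 1) & (scores1 >= 0.5)).sum())]])
        rep = metrics_from_confusion(conf, probs, y)
        u = stats.mannwhitneyu(scores1[y == 1], scores1[y == 0],
                               alternative="two-sided").statistic
        expected = u / ((y == 1).sum() * (y == 0).sum())
        assert rep.roc_auc == pytest.approx(expected, abs=1e-10)


class TestAblate:
    def test_full_keeps_config_hash(self):
        base = tiny_model_config()
        assert ablate(base, "full").config_hash() == base.config_hash()

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown ablation"):
            ablate(tiny_model_config(), "no_everything")

    @pytest.mark.parametrize("name", ["no_bridge", "no_meta_xai", "no_morph",
                                      "no_vit", "cnn_only"])
    def test_ablated_models_forward(self, name, rng):
        cfg = ablate(tiny_model_config(), name)
        model = BridgeClassifier(cfg, seed=0)
        out = model.forward(rng.uniform(size=(2, 3, 16, 16)))
        assert out.probs.data.shape == (2, 2)
        assert np.allclose(out.probs.data.sum(axis=1), 1.0)
        if name in ("no_meta_xai", "cnn_only"):
            assert out.policy is None

    def test_cnn_only_has_fewer_parameters(self):
        base = tiny_model_config()
        full = BridgeClassifier(base, seed=0).parameter_count()
        only = BridgeClassifier(ablate(base, "cnn_only"), seed=0) \
            .parameter_count()
        assert only < full

    def test_no_morph_equals_gate_forced_to_one(self, rng):
        """no_morph forward equals the full forward with w := 1."""
        base = tiny_model_config()
        x = rng.uniform(size=(2, 3, 16, 16))
        nom = BridgeClassifier(ablate(base, "no_morph"), seed=0)
        full = BridgeClassifier(base, seed=0)
        # share every non-gate parameter, then force the gate open
        for k, v in nom.params.items():
            full.params[k] = v
        from nbx.models import cnn as cnn_mod
        orig = cnn_mod.morph_attention

        def forced(fmap, params):
            gated, gate = orig(fmap, params)
            ones = Tensor(np.ones_like(gate["w"].data))
            b, c = gate["w"].shape
            return fmap * ones.reshape(b, c, 1, 1), gate

        import nbx.models.full as full_mod
        full_mod.morph_attention, saved = forced, full_mod.morph_attention
        try:
            out_full = full.forward(x)
        finally:
            full_mod.morph_attention = saved
        out_nom = nom.forward(x)
        assert np.allclose(out_full.logits.data, out_nom.logits.data, atol=1e-10)


class TestProfile:
    def test_single_linear_layer_closed_form(self):
        from nbx.nn import num_params, param
        rng = np.random.default_rng(0)
        p = {"w": param(rng, (7, 11)), "b": param(rng, (7,), "zeros")}
        assert num_params(p) == 7 * 11 + 7

    def test_count_matches_array_enumeration(self):
        cfg = tiny_model_config()
        model = BridgeClassifier(cfg, seed=0)
        brute = sum(int(np.prod(t.data.shape)) for t in model.params.values())
        assert profile(cfg)["parameters"] == brute

    def test_cnn_only_cheaper_than_full(self):
        base = tiny_model_config()
        assert profile(ablate(base, "cnn_only"))["parameters"] < \
            profile(base)["parameters"]
        assert profile(ablate(base, "cnn_only"))["macs"] < \
            profile(base)["macs"]


@pytest.fixture(scope="module")
def separable_run(tmp_path_factory):
    """Train the tiny model on a 2-class separable synthetic set."""
    out = tmp_path_factory.mktemp("sep")
    spec = synthetic.DatasetSpec(
        class_names=["neg", "pos"], counts={"neg": 40, "pos": 40},
        image_side=16,
        class_morphology={
            "neg": synthetic.MorphologyDistribution(
                synthetic.CellParams(nucleus_radius_frac=0.12)),
            "pos": synthetic.MorphologyDistribution(
                synthetic.CellParams(nucleus_radius_frac=0.38))},
        seed=5)
    manifest = synthetic.generate_dataset(spec, out)
    cfg = tiny_model_config(side=16)
    run = RunConfig(epochs=6, batch_size=16, seed=0)
    tr, va = fixed_split(manifest, seed=0)
    model, hist = train(cfg, tr, va, "sgd", run)
    return manifest, cfg, run, tr, va, model, hist


class TestTraining:
    def test_history_has_one_row_per_epoch(self, separable_run):
        *_, hist = separable_run
        assert len(hist) == 6
        assert {"train_loss", "train_accuracy", "val_loss",
                "val_accuracy"} <= set(hist.columns)

    def test_separable_data_reaches_high_train_accuracy(self, separable_run):
        *_, hist = separable_run
        assert hist["train_accuracy"].iloc[-1] >= 0.95

    def test_beats_label_shuffled_control(self, separable_run):
        manifest, cfg, run, tr, va, model, hist = separable_run
        rng = np.random.default_rng(0)
        shuffled = tr.copy()
        shuffled["label"] = rng.permutation(shuffled["label"].values)
        _, hist_shuf = train(cfg, shuffled, va, "sgd", run)
        assert hist["val_accuracy"].iloc[-1] - \
            hist_shuf["val_accuracy"].iloc[-1] >= 0.3

    def test_training_is_bitwise_deterministic(self, separable_run):
        manifest, cfg, run, tr, va, model, hist = separable_run
        _, hist2 = train(cfg, tr, va, "sgd", run)
        pd.testing.assert_frame_equal(hist, hist2)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError, match="epochs"):
            RunConfig(epochs=0)

    def test_evaluate_on_validation(self, separable_run):
        manifest, cfg, run, tr, va, model, hist = separable_run
        rep = evaluate(model, va)
        assert rep.accuracy == pytest.approx(hist["val_accuracy"].iloc[-1])
        assert rep.confusion.sum() == len(va)

    def test_checkpoint_roundtrip(self, separable_run, tmp_path):
        manifest, cfg, run, tr, va, model, hist = separable_run
        path = tmp_path / "ck.npz"
        model.save(path, vocabulary=["neg", "pos"])
        loaded, meta = BridgeClassifier.load(path)
        assert meta["vocabulary"] == ["neg", "pos"]
        assert meta["config_hash"] == model.config.config_hash()
        x = np.random.default_rng(0).uniform(size=(2, 3, 16, 16))
        assert np.allclose(loaded.predict_probs(x), model.predict_probs(x))

    def test_gradients_reach_every_parameter_group(self, separable_run, rng):
        """One composite-loss step leaves no parameter group untouched."""
        from nbx.models.bridge import composite_loss
        from nbx.nn import zero_grads
        cfg = tiny_model_config()
        cfg.head.lambda_x = 0.1
        model = BridgeClassifier(cfg, seed=1)
        x = rng.uniform(size=(4, 3, 16, 16))
        y = np.array([0, 1, 0, 1])
        zero_grads(model.params)
        bundle = model.forward(x)
        quality = rng.uniform(0, 1, size=(4, 4))
        loss = composite_loss(bundle.logits, y, bundle.policy, quality,
                              lambda_x=0.1)
        loss.backward()
        groups = {"cnn.": False, "gate.": False, "vit.": False,
                  "concept.": False, "bridge.": False, "cls.": False,
                  "xai.": False}
        for name, p in model.params.items():
            for g in groups:
                if name.startswith(g) and p.grad is not None \
                        and np.linalg.norm(p.grad) > 0:
                    groups[g] = True
        assert all(groups.values()), groups


def test_cross_validation_on_separable_data(tmp_path):
    spec = synthetic.DatasetSpec(
        class_names=["neg", "pos"], counts={"neg": 25, "pos": 25},
        image_side=16,
        class_morphology={
            "neg": synthetic.MorphologyDistribution(
                synthetic.CellParams(nucleus_radius_frac=0.12)),
            "pos": synthetic.MorphologyDistribution(
                synthetic.CellParams(nucleus_radius_frac=0.38))},
        seed=9)
    manifest = synthetic.generate_dataset(spec, tmp_path)
    cfg = tiny_model_config(side=16)
    run = RunConfig(epochs=5, batch_size=16, seed=1)
    rep = cross_validate(cfg, manifest, "sgd", run, k=5)
    assert len(rep.per_fold) == 5
    accs = [m.accuracy for m in rep.per_fold]
    assert rep.accuracy == pytest.approx(np.mean(accs))
    assert min(accs) >= 0.9
    total = sum(len(va) for _, va in kfold_split(manifest, k=5, seed=1))
    assert rep.confusion.sum() == total


def test_mean_fold_accuracy_aggregation():
    """Fold accuracies (1.0, 0.9, 0.8, 0.9, 1.0) aggregate to 0.92."""
    from nbx.train import MetricsReport
    folds = []
    for acc in (1.0, 0.9, 0.8, 0.9, 1.0):
        right = int(acc * 10)
        conf = np.array([[right, 10 - right], [10 - right, right]])
        folds.append(metrics_from_confusion(conf))
    mean = MetricsReport(accuracy=float(np.mean([f.accuracy for f in folds])),
                         precision_macro=0, recall_macro=0, f1_macro=0,
                         precision_weighted=0, recall_weighted=0,
                         f1_weighted=0, confusion=np.zeros((2, 2)),
                         per_fold=folds)
    assert mean.mean_fold_accuracy == pytest.approx(0.92)


class TestBalanceModes:
    def _unbalanced(self):
        return _manifest(8, classes=("a",)).pipe(
            lambda df: pd.concat([df, _manifest(4, classes=("b",))],
                                 ignore_index=True))

    def test_paper_faithful_balances_before_split(self):
        from nbx.train import balanced_fixed_split
        run = RunConfig(seed=0, balance_mode="paper_faithful")
        tr, va = balanced_fixed_split(self._unbalanced(), run, "unused",
                                      materialize=False)
        # 8 + 8 rows balanced, then 80/20
        assert len(tr) + len(va) == 16
        assert set(tr["path"]) | set(va["path"])

    def test_split_first_keeps_validation_real(self):
        from nbx.train import balanced_fixed_split
        run = RunConfig(seed=0, balance_mode="split_first")
        tr, va = balanced_fixed_split(self._unbalanced(), run, "unused",
                                      materialize=False)
        assert not va["is_synthetic"].any()
        assert tr["label"].value_counts().nunique() == 1
        # no augmented derivative of a validation image in training
        synth = tr[tr["is_synthetic"]]
        assert not set(synth["source_path"]) & set(va["path"])

    def test_unknown_mode_rejected(self):
        from nbx.train import balanced_fixed_split
        run = RunConfig(seed=0, balance_mode="bogus")
        with pytest.raises(ValueError, match="balance_mode"):
            balanced_fixed_split(self._unbalanced(), run, "unused",
                                 materialize=False)


def test_model_config_yaml_roundtrip(tmp_path):
    cfg = tiny_model_config()
    cfg.to_yaml(tmp_path / "m.yaml")
    back = ModelConfig.from_yaml(tmp_path / "m.yaml")
    assert back.config_hash() == cfg.config_hash()
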