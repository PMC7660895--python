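"""Transfer-learning pipeline at reduced scale."""

import math

import numpy as np
import pytest

import starfunc as sf
from starfunc import nn
from starfunc.core import Function
from starfunc.encoder import EncodingConfig
from starfunc.train import (
    AblationFlags,
    TrainConfig,
    ablation_channel_indices,
    ablation_run,
    encode_allele_inputs,
    encode_diplotype_samples,
    pretrain_stage1,
    pretrain_stage2,
    stratified_holdout,
    train_final,
)

SPEC = sf.ArchitectureSpec(conv_filters=(16, 16, 16), conv_widths=(7, 5, 3),
                           pool_widths=(3, 3, 3), fc_sizes=(32,), dropout=0.0)


@pytest.fixture(scope="module")
def training_locus():
    return sf.generate_synthetic_locus((3, 3, 3), 600, 15, seed=7)


@pytest.fixture(scope="module")
def sim_data(training_locus):
    loc = training_locus
    train = sf.simulate_diplotypes(loc.definitions, loc.af_table, 80, seed=11)
    test = sf.simulate_diplotypes(loc.definitions, loc.af_table, 25, seed=12)
    return {
        "x_train": encode_diplotype_samples(train, loc),
        "y_train": [s.activity_score for s in train],
        "x_test": encode_diplotype_samples(test, loc),
        "y_test": [s.activity_score for s in test],
        "train": train,
    }


@pytest.fixture(scope="module")
def stage1(sim_data):
    cfg = TrainConfig(stage1_epochs=40, batch_size=32, learning_rate=3e-3,
                      patience=8, seed=5)
    return pretrain_stage1(sim_data["x_train"], sim_data["y_train"], SPEC, cfg)


class TestStratifiedHoldout:
    def test_each_class_contributes_ceiling_fraction(self, rng):
        labels = ["a"] * 23 + ["b"] * 7 + ["c"] * 41
        train_idx, hold_idx = stratified_holdout(labels, 0.10, rng)
        held = [labels[i] for i in hold_idx]
        assert held.count("a") == math.ceil(0.10 * 23)
        assert held.count("b") == math.ceil(0.10 * 7)
        assert held.count("c") == math.ceil(0.10 * 41)
        assert len(set(train_idx) & set(hold_idx)) == 0
        assert len(train_idx) + len(hold_idx) == len(labels)

    def test_tiny_class_rejected(self, rng):
        with pytest.raises(ValueError):
            stratified_holdout(["a", "b"], 0.5, rng)


class TestStage1:
    def test_learns_activity_score_at_reduced_scale(self, stage1, sim_data):
        net, report = stage1
        assert report["holdout_accuracy"] >= 0.95
        classes = report["classes"]
        pred = net.predict(sim_data["x_test"]).argmax(axis=1)
        truth = np.array([classes.index(s) for s in sim_data["y_test"]])
        assert float(np.mean(pred == truth)) >= 0.95

    def test_shuffled_labels_stay_near_chance(self, sim_data):
        rng = np.random.default_rng(0)
        y_shuffled = list(rng.permutation(sim_data["y_train"]))
        cfg = TrainConfig(stage1_epochs=8, batch_size=32, learning_rate=3e-3,
                          patience=8, seed=5)
        _, report = pretrain_stage1(sim_data["x_train"], y_shuffled, SPEC,
                                    cfg)
        assert report["holdout_accuracy"] <= 0.45  # 5 classes, chance 0.2

    def test_fixed_seed_reproduces_loss_trace(self, sim_data):
        cfg = TrainConfig(stage1_epochs=3, batch_size=32, seed=21)
        _, r1 = pretrain_stage1(sim_data["x_train"], sim_data["y_train"],
                                SPEC, cfg)
        _, r2 = pretrain_stage1(sim_data["x_train"], sim_data["y_train"],
                                SPEC, cfg)
        assert r1["train_loss"] == r2["train_loss"]

    def test_absent_class_rejected(self, sim_data):
        cfg = TrainConfig(seed=0)
        y = [0.0 if s == 2.0 else s for s in sim_data["y_train"]]
        with pytest.raises(ValueError, match="absent"):
            pretrain_stage1(sim_data["x_train"], y, SPEC, cfg)


class TestStage2:
    def test_conv_weights_start_from_stage1(self, stage1, sim_data):
        net1, _ = stage1
        cfg = TrainConfig(stage2_epochs=0, seed=5)
        activity = sf.simulate_activity_measurements(sim_data["train"],
                                                     noise_sd=0, seed=1)
        net2, _ = pretrain_stage2(sim_data["x_train"], activity, net1, SPEC,
                                  cfg)
        conv1 = [ly for ly in net1.layers if isinstance(ly, nn.Conv1D)]
        conv2 = [ly for ly in net2.layers if isinstance(ly, nn.Conv1D)]
        for a, b in zip(conv1, conv2):
            np.testing.assert_array_equal(a.W, b.W)
            np.testing.assert_array_equal(a.b, b.b)

    def test_noiseless_activity_regression(self, stage1, sim_data):
        net1, _ = stage1
        cfg = TrainConfig(stage2_epochs=40, batch_size=32,
                          learning_rate=3e-3, patience=8, seed=5)
        activity = sf.simulate_activity_measurements(sim_data["train"],
                                                     noise_sd=0, seed=1)
        _, report = pretrain_stage2(sim_data["x_train"], activity, net1,
                                    SPEC, cfg)
        assert report["holdout_r2"] >= 0.9

    def test_noisy_activity_matches_signal_to_noise_oracle(self, stage1,
                                                           sim_data):
        net1, _ = stage1
        slope, sd = 50.0, 26.0
        oracle = sf.expected_activity_r2(slope, sd, sim_data["y_train"])
        cfg = TrainConfig(stage2_epochs=40, batch_size=32,
                          learning_rate=3e-3, patience=8, seed=5)
        activity = sf.simulate_activity_measurements(
            sim_data["train"], slope=slope, noise_sd=sd, seed=2)
        _, report = pretrain_stage2(sim_data["x_train"], activity, net1,
                                    SPEC, cfg)
        assert report["holdout_r2"] == pytest.approx(oracle, abs=0.15)


@pytest.fixture(scope="module")
def star_inputs(training_locus):
    curated = [d for d in training_locus.definitions
               if d.function.is_curated]
    # suballele-style expansion so the per-class holdout is possible
    expanded, functions = [], []
    rng = np.random.default_rng(17)
    af_sites = [v for v, _ in training_locus.af_table.items()]
    for d in curated:
        for k in range(4):
            extra = {af_sites[i]
                     for i in rng.choice(len(af_sites), size=k,
                                         replace=False)}
            expanded.append(sf.StarAlleleDefinition(
                d.name, d.variants | frozenset(extra), d.function,
                suballele=f"{k:03d}" if k else None))
            functions.append(d.function)
    x = encode_allele_inputs(expanded, training_locus)
    return x, functions


class TestFinalStage:
    def test_separable_fixture_reaches_full_training_accuracy(
            self, star_inputs, stage1):
        x, functions = star_inputs
        net1, _ = stage1
        cfg = TrainConfig(final_epochs=40, batch_size=8, learning_rate=3e-3,
                          patience=10, ensemble_size=2, seed=5)
        bundle, report = train_final(x, functions, net1, SPEC, cfg)
        assert report["train_accuracy"] == 1.0

    def test_bundle_reload_identical_predictions(self, star_inputs, stage1,
                                                 tmp_path):
        x, functions = star_inputs
        net1, _ = stage1
        cfg = TrainConfig(final_epochs=5, batch_size=8, ensemble_size=2,
                          seed=6)
        bundle, _ = train_final(x, functions, net1, SPEC, cfg)
        bundle.save(tmp_path / "b")
        reloaded = sf.ModelBundle.load(tmp_path / "b")
        np.testing.assert_array_equal(bundle.scores(x), reloaded.scores(x))
        assert bundle.classify(x) == reloaded.classify(x)

    def test_missing_class_rejected(self, star_inputs):
        x, functions = star_inputs
        keep = [i for i, f in enumerate(functions) if f is not Function.NONE]
        cfg = TrainConfig(seed=0)
        with pytest.raises(ValueError, match="absent"):
            train_final(x[keep], [functions[i] for i in keep], None, SPEC,
                        cfg)

    def test_lineage_records_transfer(self, star_inputs, stage1):
        x, functions = star_inputs
        net1, _ = stage1
        cfg = TrainConfig(final_epochs=2, ensemble_size=1, batch_size=8,
                          seed=3)
        with_t, _ = train_final(x, functions, net1, SPEC, cfg)
        without_t, _ = train_final(x, functions, None, SPEC, cfg)
        assert with_t.lineage["transfer"] and not without_t.lineage["transfer"]
        assert with_t.lineage["stage2_digest"] is not None


class TestAblation:
    def test_channel_selection(self):
        full = EncodingConfig(channel_mode="full13")
        default = EncodingConfig()
        assert ablation_channel_indices(AblationFlags(), full, default) == \
            list(range(12))
        assert ablation_channel_indices(
            AblationFlags(use_annotations=False), full, default) == \
            [0, 1, 2, 3]
        single = ablation_channel_indices(
            AblationFlags(use_annotations=False,
                          single_annotation="deleterious"), full, default)
        assert len(single) == 5  # 4 nucleotides + 1 annotation

    def test_unknown_annotation_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ablation_channel_indices(
                AblationFlags(use_annotations=False,
                              single_annotation="conservation"),
                EncodingConfig(channel_mode="full13"), EncodingConfig())

    def test_annotation_and_transfer_help_on_flag_dependent_fixture(self):
        """Held-out alleles carry unseen variants, so without annotation
        channels the function is not predictable; the full pipeline wins."""
        loc = sf.generate_synthetic_locus((6, 6, 6), 500, 10, seed=23)
        full13 = EncodingConfig(channel_mode="full13")
        sim = sf.simulate_diplotypes(loc.definitions, loc.af_table, 60,
                                     seed=24)
        sim_x = encode_diplotype_samples(sim, loc, full13)
        curated = [d for d in loc.definitions if d.function.is_curated]
        train_defs = [d for i, d in enumerate(curated) if i % 3 != 2]
        test_defs = [d for i, d in enumerate(curated) if i % 3 == 2]
        # suballele-style expansion of the training alleles
        rng = np.random.default_rng(99)
        af_sites = [v for v, _ in loc.af_table.items()]
        expanded = []
        for d in train_defs:
            expanded.append(d)
            for k in range(1, 5):
                extra = {af_sites[i]
                         for i in rng.choice(len(af_sites),
                                             size=min(k, 3), replace=False)}
                expanded.append(sf.StarAlleleDefinition(
                    d.name, d.variants | frozenset(extra), d.function,
                    suballele=f"{k:03d}"))
        star_x = encode_allele_inputs(expanded, loc, full13)
        test_x = encode_allele_inputs(test_defs, loc, full13)
        spec = sf.ArchitectureSpec(conv_filters=(16, 16, 16),
                                   conv_widths=(7, 5, 3),
                                   pool_widths=(3, 3, 3), fc_sizes=(32,),
                                   dropout=0.0)
        cfg = TrainConfig(stage1_epochs=50, final_epochs=25, batch_size=32,
                          learning_rate=3e-3, final_learning_rate=1e-3,
                          patience=10, ensemble_size=3, seed=31)
        args = (sim_x, [s.activity_score for s in sim],
                star_x, [d.function for d in expanded],
                test_x, [d.function for d in test_defs], spec, cfg)
        full = ablation_run(AblationFlags(), *args)
        bare = ablation_run(AblationFlags(use_transfer=False,
                                          use_annotations=False), *args)
        assert full["n_channels"] == 24 and bare["n_channels"] == 8
        assert full["test_accuracy"] >= bare["test_accuracy"]
        assert full["test_accuracy"] >= 0.8
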