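"""End-to-end study workflows at desk scale.

These functions wire the synthetic locus generator, the diplotype
simulator, and the training stages into complete, seeded experiments. They
are what the acceptance checks and the examples run; each returns a plain
dict of the quantities it measured.
"""

from __future__ import annotations

import numpy as np

from .core import CYP2D6_WINDOW, GenomicWindow, ReferenceWindow
from .encoder import EncodingConfig, encode_haplotype
from .model import ArchitectureSpec
from .simulate import generate_synthetic_locus, simulate_diplotypes
from .train import TrainConfig, encode_diplotype_samples, pretrain_stage1


def encode_reference_haplotype(seed: int = 0,
                               window: GenomicWindow = CYP2D6_WINDOW,
                               config: EncodingConfig = EncodingConfig()):
    """Encode a haplotype over the full locus window.

    The reference sequence is drawn at random (the encoding geometry does
    not depend on its content); returns the encoded haplotype, whose row
    count equals the window length.
    """
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=window.length))
    reference = ReferenceWindow(window, seq)
    from .core import AnnotationTrackSet, VariantFlagTable

    tracks = AnnotationTrackSet(window)
    return encode_haplotype(reference, [], tracks, VariantFlagTable(), config)


def stage1_benchmark(
    seed: int = 0,
    window_length: int = 2000,
    n_alleles_per_class: int = 3,
    n_af_sites: int = 50,
    n_train_per_class: int = 1000,
    n_test_per_class: int = 200,
    spec: ArchitectureSpec | None = None,
    cfg: TrainConfig | None = None,
) -> dict:
    """Measure stage-1 learnability of the activity score at reduced scale.

    Generates a synthetic locus, simulates class-balanced AS-labeled
    diplotypes for training and testing, trains the five-way classifier,
    and reports held-out and test accuracy. Default problem size: 2 kb
    window, three star alleles per function class, 50 background sites,
    1000 training and 200 test diplotypes per AS class.
    """
    ss = np.random.SeedSequence(seed)
    s_locus, s_train, s_test, s_fit = [
        int(s) % (2 ** 31) for s in ss.generate_state(4)]
    locus = generate_synthetic_locus(
        (n_alleles_per_class,) * 3, window_length, n_af_sites, seed=s_locus)
    train = simulate_diplotypes(locus.definitions, locus.af_table,
                                n_train_per_class, seed=s_train)
    test = simulate_diplotypes(locus.definitions, locus.af_table,
                               n_test_per_class, seed=s_test)
    x_train = encode_diplotype_samples(train, locus)
    x_test = encode_diplotype_samples(test, locus)

    spec = spec or ArchitectureSpec.small()
    cfg = cfg or TrainConfig(stage1_epochs=10, batch_size=64,
                             learning_rate=1e-3, patience=3, seed=s_fit)
    net, report = pretrain_stage1(x_train,
                                  [s.activity_score for s in train],
                                  spec, cfg)
    classes = report["classes"]
    pred = net.predict(x_test).argmax(axis=1)
    truth = np.array([classes.index(s.activity_score) for s in test])
    return {
        "holdout_accuracy": report["holdout_accuracy"],
        "test_accuracy": float(np.mean(pred == truth)),
        "n_train": len(train),
        "n_test": len(test),
        "classes": classes,
        "epochs_run": len(report["train_loss"]),
    }


def simulation_quota_check(
    seed: int = 0,
    n_per_class: int = 10_000,
    window_length: int = 2000,
    n_af_sites: int = 50,
) -> dict:
    """Simulate the full pre-training quota and verify every label.

    Returns the sample count and how many labels match an independent
    recomputation of the activity score from the allele pair.
    """
    from .simulate import diplotype_activity_score

    ss = np.random.SeedSequence(seed)
    s_locus, s_sim = [int(s) % (2 ** 31) for s in ss.generate_state(2)]
    locus = generate_synthetic_locus((3, 3, 3), window_length, n_af_sites,
                                     seed=s_locus)
    samples = simulate_diplotypes(locus.definitions, locus.af_table,
                                  n_per_class, seed=s_sim)
    by_fun = {d.full_name: d.function for d in locus.definitions}
    n_correct = sum(
        s.activity_score == diplotype_activity_score(by_fun[s.allele1],
                                                     by_fun[s.allele2])
        for s in samples)
    return {"n_samples": len(samples), "n_labels_correct": n_correct,
            "n_per_class": n_per_class}
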