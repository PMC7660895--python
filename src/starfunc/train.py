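"""Three-stage transfer-learning pipeline producing a calibrated ensemble.

Stage 1 trains a five-way activity-score classifier on simulated, AS-labeled
diplotypes. Stage 2 transfers the convolutional weights into a regressor of
continuous metabolic activity (fully connected layers re-initialized).
Stage 3 transfers convolutional and fully connected weights into the final
two-sigmoid ordinal classifier of star-allele function, trains an ensemble
of members differing only in head initialization and minibatch order, and
calibrates the two score cutoffs on training scores. During each training
run 10% of samples per class are held out to monitor overfitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Function
from .encoder import EncodingConfig, encode_diplotype, encode_haplotype
from .model import (
    ArchitectureSpec,
    ModelBundle,
    build_network,
    ensemble_scores,
    fit_cutoffs,
    ordinal_targets,
    scores_to_function,
    transfer_parameters,
    _weights_digest,
)
from .simulate import DiplotypeSample, SyntheticLocus, activity_score_classes
from . import nn


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters shared by the three stages."""

    stage1_epochs: int = 30
    stage2_epochs: int = 30
    final_epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    final_learning_rate: float | None = None  # fine-tuning rate; defaults
    # to learning_rate — keep it at or below the pretraining rate so
    # fine-tuning on the small star-allele set does not erase the
    # transferred representation
    holdout_fraction: float = 0.10
    ensemble_size: int = 10
    patience: int = 5
    seed: int = 0

    @property
    def finetune_lr(self) -> float:
        return self.final_learning_rate \
            if self.final_learning_rate is not None else self.learning_rate

    def __post_init__(self) -> None:
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout fraction must be in (0, 1)")
        if self.ensemble_size < 1:
            raise ValueError("ensemble size must be >= 1")


def _child_seed(master: int, stream: int) -> int:
    return int(np.random.SeedSequence([master, stream]).generate_state(1)[0]
               % (2 ** 31))


# ---------------------------------------------------------------------------
# encoding helpers

def encode_diplotype_samples(
    samples: Sequence[DiplotypeSample],
    locus: SyntheticLocus,
    config: EncodingConfig = EncodingConfig(),
) -> np.ndarray:
    """Encode simulated diplotypes into a (n, L, 2C) uint8 array."""
    mats = []
    for s in samples:
        e1 = encode_haplotype(locus.reference, s.variants1, locus.tracks,
                              locus.flags, config, allele=s.allele1)
        e2 = encode_haplotype(locus.reference, s.variants2, locus.tracks,
                              locus.flags, config, allele=s.allele2)
        mats.append(encode_diplotype(e1, e2).matrix)
    return np.stack(mats)


def encode_allele_inputs(
    definitions: Sequence,
    locus: SyntheticLocus,
    config: EncodingConfig = EncodingConfig(),
) -> np.ndarray:
    """Encode star alleles as duplicated-haplotype diplotype inputs."""
    mats = []
    for d in definitions:
        e = encode_haplotype(locus.reference, d.variants, locus.tracks,
                             locus.flags, config, allele=d.full_name)
        mats.append(encode_diplotype(e, e).matrix)
    return np.stack(mats)


def stratified_holdout(labels: Sequence, fraction: float,
                       rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Split indices so each class contributes ceil(fraction * n_class).

    Returns ``(train_idx, holdout_idx)``.
    """
    labels = np.asarray(labels, dtype=object)
    hold: list[int] = []
    for cls in sorted(set(labels.tolist()), key=str):
        idx = np.flatnonzero(labels == cls)
        k = math.ceil(fraction * len(idx))
        if k >= len(idx):
            raise ValueError(
                f"class {cls!r} too small for holdout fraction {fraction}")
        hold.extend(rng.choice(idx, size=k, replace=False).tolist())
    hold_idx = np.sort(np.array(hold, dtype=int))
    mask = np.ones(len(labels), dtype=bool)
    mask[hold_idx] = False
    return np.flatnonzero(mask), hold_idx


# ---------------------------------------------------------------------------
# stage 1: activity-score classifier on simulated diplotypes

def pretrain_stage1(
    x: np.ndarray,
    activity_scores: Sequence[float],
    spec: ArchitectureSpec,
    cfg: TrainConfig,
    decreased_value: float = 0.5,
) -> tuple[nn.Network, dict]:
    """Train the five-way AS classifier; returns (network, report).

    ``x`` is the encoded diplotype array, ``activity_scores`` the AS labels.
    The report carries the class order, the held-out accuracy on the
    internal stratified holdout, and the loss trace.
    """
    classes = activity_score_classes(decreased_value)
    class_index = {c: i for i, c in enumerate(classes)}
    scores = list(activity_scores)
    missing = sorted(set(scores) - set(classes))
    if missing:
        raise ValueError(f"activity scores outside class set: {missing}")
    present = sorted(set(scores))
    if len(present) < 2:
        raise ValueError("need at least two activity-score classes to train")
    absent = [c for c in classes if c not in present]
    if absent:
        raise ValueError(f"activity-score class(es) absent from data: {absent}")
    y = np.array([class_index[s] for s in scores], dtype=int)

    rng = np.random.default_rng(_child_seed(cfg.seed, 1))
    train_idx, hold_idx = stratified_holdout(y, cfg.holdout_fraction, rng)
    net = build_network(spec, x.shape[1:], "as_classifier", rng,
                        n_classes=len(classes))
    hist = nn.fit(net, x[train_idx], y[train_idx],
                  epochs=cfg.stage1_epochs, batch_size=cfg.batch_size,
                  lr=cfg.learning_rate, rng=rng,
                  x_val=x[hold_idx], y_val=y[hold_idx],
                  patience=cfg.patience)
    pred = net.predict(x[hold_idx]).argmax(axis=1)
    report = {
        "classes": classes,
        "holdout_accuracy": float(np.mean(pred == y[hold_idx])),
        "train_loss": hist.train_loss,
        "val_loss": hist.val_loss,
    }
    return net, report


# ---------------------------------------------------------------------------
# stage 2: activity regression with transferred convolutions

def _r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def pretrain_stage2(
    x: np.ndarray,
    activity: np.ndarray,
    stage1_net: nn.Network,
    spec: ArchitectureSpec,
    cfg: TrainConfig,
) -> tuple[nn.Network, dict]:
    """Train the activity regressor from stage-1 convolutional weights.

    Convolutional weights are transferred exactly from the stage-1 network;
    fully connected layers start from fresh initialization. Activity values
    are standardized internally for optimization and predictions reported on
    the original scale. The report carries train and held-out R^2.
    """
    activity = np.asarray(activity, dtype=np.float32)
    rng = np.random.default_rng(_child_seed(cfg.seed, 2))
    net = build_network(spec, x.shape[1:], "activity_regressor", rng)
    transfer_parameters(stage1_net, net, scope="conv_only")

    n = len(x)
    idx = rng.permutation(n)
    k = max(1, math.ceil(cfg.holdout_fraction * n))
    hold_idx, train_idx = idx[:k], idx[k:]

    mu, sd = float(activity[train_idx].mean()), \
        float(activity[train_idx].std() or 1.0)
    y = (activity - mu) / sd
    hist = nn.fit(net, x[train_idx], y[train_idx],
                  epochs=cfg.stage2_epochs, batch_size=cfg.batch_size,
                  lr=cfg.learning_rate, rng=rng,
                  x_val=x[hold_idx], y_val=y[hold_idx],
                  patience=cfg.patience)
    pred = net.predict(x)[:, 0] * sd + mu
    report = {
        "train_r2": _r2(activity[train_idx], pred[train_idx]),
        "holdout_r2": _r2(activity[hold_idx], pred[hold_idx]),
        "activity_mean": mu,
        "activity_sd": sd,
        "train_loss": hist.train_loss,
    }
    return net, report


# ---------------------------------------------------------------------------
# stage 3: final ordinal classifier ensemble

def train_final(
    x: np.ndarray,
    functions: Sequence[Function],
    stage2_net: nn.Network | None,
    spec: ArchitectureSpec,
    cfg: TrainConfig,
    encoding: EncodingConfig = EncodingConfig(),
) -> tuple[ModelBundle, dict]:
    """Train the calibrated ordinal ensemble from curated star-allele inputs.

    ``x`` holds duplicated-haplotype diplotype encodings of curated alleles.
    Each ensemble member starts from the stage-2 weights (convolutional and
    fully connected layers; the two-unit head is freshly initialized per
    member) — or entirely from fresh weights when ``stage2_net`` is None.
    Cutoffs are fitted on the ensemble's training scores.
    """
    functions = list(functions)
    if any(not f.is_curated for f in functions):
        raise ValueError("training requires curated function labels only")
    present = {f for f in functions}
    missing = {Function.NONE, Function.DECREASED, Function.NORMAL} - present
    if missing:
        raise ValueError(
            f"function class(es) absent from training data: "
            f"{sorted(m.value for m in missing)}")
    targets = np.array([ordinal_targets(f) for f in functions], dtype=int)

    split_rng = np.random.default_rng(_child_seed(cfg.seed, 3))
    train_idx, hold_idx = stratified_holdout(
        [f.value for f in functions], cfg.holdout_fraction, split_rng)

    networks: list[nn.Network] = []
    member_seeds = []
    for m in range(cfg.ensemble_size):
        mseed = _child_seed(cfg.seed, 100 + m)
        member_seeds.append(mseed)
        rng = np.random.default_rng(mseed)
        net = build_network(spec, x.shape[1:], "ordinal", rng)
        if stage2_net is not None:
            transfer_parameters(stage2_net, net, scope="conv_and_fc")
        nn.fit(net, x[train_idx], targets[train_idx],
               epochs=cfg.final_epochs, batch_size=cfg.batch_size,
               lr=cfg.finetune_lr, rng=rng,
               x_val=x[hold_idx], y_val=targets[hold_idx],
               patience=cfg.patience)
        networks.append(net)

    train_scores = ensemble_scores(networks, x)
    cutoffs = fit_cutoffs(train_scores, targets)
    lineage = {
        "member_seeds": member_seeds,
        "stage2_digest": (_weights_digest(stage2_net)
                          if stage2_net is not None else None),
        "transfer": stage2_net is not None,
    }
    bundle = ModelBundle(networks=networks, cutoffs=cutoffs,
                         encoding=encoding, spec=spec, lineage=lineage)
    pred = [scores_to_function(a, b, cutoffs) for a, b in train_scores]
    report = {
        "train_accuracy": float(np.mean(
            [p == f for p, f in zip(pred, functions)])),
        "holdout_indices": hold_idx.tolist(),
        "cutoffs": (cutoffs.c_notnone, cutoffs.c_normal),
    }
    return bundle, report


# ---------------------------------------------------------------------------
# ablation harness

@dataclass(frozen=True)
class AblationFlags:
    """Which components the ablation run keeps."""

    use_transfer: bool = True
    use_annotations: bool = True
    single_annotation: str | None = None

    def __post_init__(self) -> None:
        if self.single_annotation is not None and self.use_annotations:
            raise ValueError(
                "single_annotation implies use_annotations=False")


def ablation_channel_indices(flags: AblationFlags,
                             full_config: EncodingConfig,
                             default_config: EncodingConfig
                             ) -> list[int]:
    """Per-haplotype channel indices kept under the ablation flags.

    Indices refer to a haplotype encoded with ``full_config`` (all
    annotations). The full model keeps the default configuration's
    channels; no-annotation runs keep the four nucleotide channels; a
    single-annotation run keeps exactly five channels.
    """
    full = list(full_config.annotations)
    if flags.single_annotation is not None:
        if flags.single_annotation not in full:
            raise ValueError(
                f"unknown annotation {flags.single_annotation!r}; "
                f"known: {full}")
        return list(range(4)) + [4 + full.index(flags.single_annotation)]
    if not flags.use_annotations:
        return list(range(4))
    return list(range(4)) + [4 + full.index(a)
                             for a in default_config.annotations]


def _slice_channels(x: np.ndarray, keep: list[int], c_full: int) -> np.ndarray:
    cols = keep + [c_full + k for k in keep]
    return np.ascontiguousarray(x[:, :, cols])


def ablation_run(
    flags: AblationFlags,
    sim_x: np.ndarray,
    sim_scores: Sequence[float],
    star_x: np.ndarray,
    star_functions: Sequence[Function],
    test_x: np.ndarray,
    test_functions: Sequence[Function],
    spec: ArchitectureSpec,
    cfg: TrainConfig,
    full_config: EncodingConfig | None = None,
    default_config: EncodingConfig = EncodingConfig(),
) -> dict:
    """Train one ablation configuration and report train/test accuracy.

    All inputs are encoded with the all-annotation channel layout; the
    harness slices channels according to ``flags``. With transfer enabled
    the stage-1 pretraining runs on the sliced simulated data so every
    configuration receives weights pretrained on its own input layout.
    """
    full_config = full_config or EncodingConfig(channel_mode="full13")
    keep = ablation_channel_indices(flags, full_config, default_config)
    c_full = full_config.n_channels
    sim_x_k = _slice_channels(sim_x, keep, c_full)
    star_x_k = _slice_channels(star_x, keep, c_full)
    test_x_k = _slice_channels(test_x, keep, c_full)

    stage_net = None
    if flags.use_transfer:
        # heads never transfer, so the five-way stage-1 network can seed the
        # ordinal members directly
        stage_net, _ = pretrain_stage1(sim_x_k, sim_scores, spec, cfg)

    bundle, _ = train_final(star_x_k, star_functions, stage_net, spec, cfg)
    train_pred = bundle.classify(star_x_k)
    test_pred = bundle.classify(test_x_k)
    return {
        "flags": flags,
        "n_channels": len(keep) * 2,
        "train_accuracy": float(np.mean(
            [p == f for p, f in zip(train_pred, star_functions)])),
        "test_accuracy": float(np.mean(
            [p == f for p, f in zip(test_pred, test_functions)])),
    }
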