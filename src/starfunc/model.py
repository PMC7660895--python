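"""Ordinal two-score model: architecture, targets, cutpoints, ensembling.

Three ordered function classes (none < decreased < normal) are represented
by two sigmoid outputs: the first ("not-none") separates no-function alleles
from the rest, the second ("normal") separates normal-function alleles from
the rest. Scores are mapped back to classes through a calibrated cutoff
pair, each cutoff chosen to maximize Youden's J (sensitivity + specificity
- 1) on training scores.

The network is a three-block convolutional stack (convolution - ReLU - max
pool), two dense layers with dropout, and an interchangeable head: a 5-way
activity-score classifier, a single linear activity regressor, or the
two-sigmoid ordinal head. Weights move between stages by exact layer-wise
transfer; ensembles average member scores.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import Function
from .encoder import EncodingConfig
from . import nn

HEAD_KINDS = {
    "as_classifier": "softmax",
    "activity_regressor": "linear",
    "ordinal": "sigmoid",
}


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of the three-block convolutional architecture."""

    conv_filters: tuple[int, ...] = (100, 64, 64)
    conv_widths: tuple[int, ...] = (19, 11, 7)
    pool_widths: tuple[int, ...] = (3, 4, 4)
    fc_sizes: tuple[int, ...] = (256, 256)
    dropout: float = 0.3

    def __post_init__(self) -> None:
        if not (len(self.conv_filters) == len(self.conv_widths)
                == len(self.pool_widths)):
            raise ValueError("conv block parameter lengths differ")
        if not self.conv_filters:
            raise ValueError("at least one convolution block required")

    @classmethod
    def small(cls) -> "ArchitectureSpec":
        """Reduced size for desk-scale windows (a few kb).

        Dropout is lighter than the full-scale default: with the smaller
        fully connected layers, heavy dropout stalls optimization on the
        sparse binary inputs.
        """
        return cls(conv_filters=(32, 32, 32), conv_widths=(19, 11, 7),
                   pool_widths=(4, 4, 4), fc_sizes=(64, 64), dropout=0.1)

    @classmethod
    def tiny(cls) -> "ArchitectureSpec":
        """Minimal sizes for sub-kb test windows."""
        return cls(conv_filters=(8, 8, 8), conv_widths=(7, 5, 3),
                   pool_widths=(3, 3, 3), fc_sizes=(16,), dropout=0.1)


@dataclass(frozen=True)
class CutoffPair:
    """Calibrated thresholds for the two ordinal scores."""

    c_notnone: float
    c_normal: float

    def __post_init__(self) -> None:
        for c in (self.c_notnone, self.c_normal):
            if not 0.0 < c < 1.0:
                raise ValueError(f"cutoff {c} outside (0, 1)")


def ordinal_targets(function: Function) -> tuple[int, int]:
    """Cumulative two-score targets: none (0,0), decreased (1,0), normal (1,1)."""
    if not function.is_curated:
        raise ValueError("uncurated function has no ordinal targets")
    rank = function.rank
    return (int(rank >= 1), int(rank >= 2))


def scores_to_function(s_notnone: float, s_normal: float,
                       cutoffs: CutoffPair) -> Function:
    """Map the two scores to a function class through the cutoffs.

    A score pair with not-none score at or below its cutoff is a no-function
    call; otherwise the normal-score cutoff separates normal from decreased
    (e.g. with cutoffs (0.5, 0.7), scores (0.6, 0.5) give decreased).
    """
    if s_notnone <= cutoffs.c_notnone:
        return Function.NONE
    if s_normal >= cutoffs.c_normal:
        return Function.NORMAL
    return Function.DECREASED


def _best_threshold(scores: np.ndarray, targets: np.ndarray) -> float:
    """Threshold maximizing Youden's J for the rule ``positive = score > c``.

    J is piecewise constant between consecutive unique score values; the
    returned cutoff is the midpoint of the optimal interval (edges fall back
    to midpoints with 0 and 1, scores being probabilities).
    """
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets, dtype=int)
    if scores.shape != targets.shape or scores.ndim != 1:
        raise ValueError("scores and targets must be 1-D and equal length")
    n_pos = int(targets.sum())
    n_neg = len(targets) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("degenerate sub-task: only one target class present")

    u = np.unique(scores)
    if len(u) == 1:
        raise ValueError("degenerate sub-task: all scores identical (J = 0)")
    # interval i covers c in [u[i], u[i+1]); edges extend to 0 and 1
    lows = np.concatenate([[0.0 if u[0] > 0 else u[0] - 1.0], u])
    highs = np.concatenate([u, [1.0 if u[-1] < 1 else u[-1] + 1.0]])
    best_j, best_c = -np.inf, None
    for lo, hi in zip(lows, highs):
        c = 0.5 * (lo + hi)
        pred = scores > c
        sens = (pred & (targets == 1)).sum() / n_pos
        spec = (~pred & (targets == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_c = j, c
    return float(best_c)


def fit_cutoffs(scores: np.ndarray, targets: np.ndarray) -> CutoffPair:
    """Fit both score cutoffs independently by maximizing Youden's J.

    ``scores`` and ``targets`` are (n, 2) arrays: columns are the not-none
    and normal sub-tasks.
    """
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets, dtype=int)
    if scores.ndim != 2 or scores.shape[1] != 2 or \
            scores.shape != targets.shape:
        raise ValueError("expected (n, 2) scores and matching targets")
    c1 = _best_threshold(scores[:, 0], targets[:, 0])
    c2 = _best_threshold(scores[:, 1], targets[:, 1])
    return CutoffPair(c_notnone=min(max(c1, 1e-9), 1 - 1e-9),
                      c_normal=min(max(c2, 1e-9), 1 - 1e-9))


# ---------------------------------------------------------------------------
# network construction and weight transfer

def build_network(spec: ArchitectureSpec, input_shape: tuple[int, int],
                  head_kind: str, rng: np.random.Generator,
                  n_classes: int = 5) -> nn.Network:
    """Build the three-block convolutional network with the requested head.

    ``input_shape`` is (L, channels); the first convolution spans the full
    channel depth. Raises with a sizing report if pooling exhausts the
    sequence length.
    """
    if head_kind not in HEAD_KINDS:
        raise ValueError(f"unknown head kind {head_kind!r}")
    head = HEAD_KINDS[head_kind]
    out_dim = {"softmax": n_classes, "linear": 1, "sigmoid": 2}[head]

    layers: list[nn.Layer] = []
    shape = tuple(input_shape)
    channels = shape[1]
    length = shape[0]
    for i, (nf, w, p) in enumerate(zip(spec.conv_filters, spec.conv_widths,
                                       spec.pool_widths)):
        conv = nn.Conv1D(channels, nf, w, rng)
        try:
            length, channels = conv.out_shape((length, channels))
            layers.append(conv)
            pool = nn.MaxPool1D(p)
            length, channels = pool.out_shape((length, channels))
        except ValueError as exc:
            raise ValueError(
                f"convolution block {i}: {exc} (input {input_shape}, "
                f"filters {spec.conv_filters}, widths {spec.conv_widths}, "
                f"pools {spec.pool_widths})") from exc
        layers.append(nn.ReLU())
        layers.append(pool)
    layers.append(nn.Flatten())
    features = length * channels
    for width in spec.fc_sizes:
        layers.append(nn.Dense(features, width, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Dropout(spec.dropout))
        features = width
    layers.append(nn.Dense(features, out_dim, rng))
    return nn.Network(layers, head=head, input_shape=input_shape)


def _layers_of(net: nn.Network, kind) -> list[nn.Layer]:
    return [ly for ly in net.layers if isinstance(ly, kind)]


def transfer_parameters(source: nn.Network, target: nn.Network,
                        scope: str) -> nn.Network:
    """Copy trained weights from ``source`` into ``target`` in place.

    ``scope="conv_only"`` copies every convolution layer; ``"conv_and_fc"``
    additionally copies every dense layer except the final output layer.
    Out-of-scope layers keep their fresh initialization. Copies are exact
    (bit-level equality).
    """
    if scope not in {"conv_only", "conv_and_fc"}:
        raise ValueError(f"unknown transfer scope {scope!r}")
    src_conv = _layers_of(source, nn.Conv1D)
    tgt_conv = _layers_of(target, nn.Conv1D)
    if len(src_conv) != len(tgt_conv):
        raise ValueError(
            f"conv layer count mismatch: {len(src_conv)} vs {len(tgt_conv)}")
    pairs = list(zip(src_conv, tgt_conv))
    if scope == "conv_and_fc":
        src_fc = _layers_of(source, nn.Dense)[:-1]
        tgt_fc = _layers_of(target, nn.Dense)[:-1]
        if len(src_fc) != len(tgt_fc):
            raise ValueError(
                f"dense layer count mismatch: {len(src_fc)} vs {len(tgt_fc)}")
        pairs += list(zip(src_fc, tgt_fc))
    for i, (s, t) in enumerate(pairs):
        for ps, pt in zip(s.params(), t.params()):
            if ps.shape != pt.shape:
                raise ValueError(
                    f"shape mismatch in transferred layer {i}: "
                    f"{ps.shape} vs {pt.shape}")
            pt[...] = ps
    return target


def ensemble_scores(networks: Sequence[nn.Network], x: np.ndarray,
                    batch_size: int = 64) -> np.ndarray:
    """Arithmetic mean of member scores; ``x`` is (n, L, 2C)."""
    if not networks:
        raise ValueError("empty ensemble")
    return np.mean([net.predict(x, batch_size=batch_size)
                    for net in networks], axis=0)


# ---------------------------------------------------------------------------
# bundle

def _weights_digest(net: nn.Network) -> str:
    h = hashlib.sha256()
    for p in net.params():
        h.update(np.ascontiguousarray(p).tobytes())
    return h.hexdigest()[:16]


@dataclass
class ModelBundle:
    """A trained ensemble with its cutoffs, encoding, and provenance."""

    networks: list[nn.Network]
    cutoffs: CutoffPair
    encoding: EncodingConfig
    spec: ArchitectureSpec
    lineage: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValueError("bundle requires at least one network")
        shapes = {net.input_shape for net in self.networks}
        if len(shapes) > 1:
            raise ValueError(f"members disagree on input shape: {shapes}")

    @property
    def input_shape(self) -> tuple[int, int]:
        return self.networks[0].input_shape

    def scores(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return ensemble_scores(self.networks, x, batch_size=batch_size)

    def classify(self, x: np.ndarray, batch_size: int = 64) -> list[Function]:
        s = self.scores(x, batch_size=batch_size)
        return [scores_to_function(a, b, self.cutoffs) for a, b in s]

    def member_digests(self) -> list[str]:
        return [_weights_digest(net) for net in self.networks]

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "n_members": len(self.networks),
            "input_shape": list(self.input_shape),
            "cutoffs": [self.cutoffs.c_notnone, self.cutoffs.c_normal],
            "encoding": asdict(self.encoding),
            "spec": asdict(self.spec),
            "lineage": self.lineage,
            "digests": self.member_digests(),
        }
        (directory / "bundle.json").write_text(json.dumps(meta, indent=2))
        for i, net in enumerate(self.networks):
            arrays = {f"p{j}": p for j, p in enumerate(net.params())}
            np.savez(directory / f"member_{i}.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        meta = json.loads((directory / "bundle.json").read_text())
        spec_d = meta["spec"]
        spec = ArchitectureSpec(
            conv_filters=tuple(spec_d["conv_filters"]),
            conv_widths=tuple(spec_d["conv_widths"]),
            pool_widths=tuple(spec_d["pool_widths"]),
            fc_sizes=tuple(spec_d["fc_sizes"]),
            dropout=spec_d["dropout"])
        encoding = EncodingConfig(**meta["encoding"])
        input_shape = tuple(meta["input_shape"])
        rng = np.random.default_rng(0)  # placeholder init, overwritten below
        networks = []
        for i in range(meta["n_members"]):
            net = build_network(spec, input_shape, "ordinal", rng)
            data = np.load(directory / f"member_{i}.npz")
            net.set_weights([data[f"p{j}"]
                             for j in range(len(net.params()))])
            networks.append(net)
        bundle = cls(networks=networks,
                     cutoffs=CutoffPair(*meta["cutoffs"]),
                     encoding=encoding, spec=spec,
                     lineage=meta.get("lineage", {}))
        if bundle.member_digests() != meta["digests"]:
            raise ValueError("weight digest mismatch after reload")
        return bundle
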