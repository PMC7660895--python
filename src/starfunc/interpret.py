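"""Reference-based attribution of predictions to input positions.

Predictions for a haplotype are explained relative to the variant-free
reference haplotype (*1): the attribution engine propagates multipliers
backwards through the network (DeepLIFT rescale rule; see
:mod:`starfunc.nn`) and assigns each input cell a contribution such that
all contributions sum exactly to the difference between the score of the
input and the score of the reference (summation-to-delta). Per-variant
importance aggregates contributions over all channels at the variant's
anchor position — both haplotype halves of a diplotype input, since the
halves are channel-concatenated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import GenomicWindow, VariantRecord
from .encoder import EncodedDiplotype, EncodedHaplotype
from . import nn


@dataclass
class AttributionMatrix:
    """Per-cell attributions for one output score of one input."""

    values: np.ndarray          # (L, C) float
    delta: float                # score(input) - score(reference)
    output_index: int
    input_matrix: np.ndarray
    reference_matrix: np.ndarray
    allele: str | None = None

    @property
    def total(self) -> float:
        return float(self.values.sum())


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, (EncodedHaplotype, EncodedDiplotype)):
        return x.matrix
    return np.asarray(x)


def attribute_sequence(
    network: nn.Network,
    encoded_input,
    encoded_reference,
    output_index: int = 0,
    post_activation: bool = True,
) -> AttributionMatrix:
    """Attribute one output score to every input cell.

    ``encoded_input`` and ``encoded_reference`` are encoded matrices (or
    encoded haplotype/diplotype objects) matching the network input shape.
    The result satisfies summation-to-delta: the attributions sum to
    ``score(input) - score(reference)``; an input identical to the
    reference receives exactly zero attributions.
    """
    x = _as_matrix(encoded_input)
    ref = _as_matrix(encoded_reference)
    if x.shape != tuple(network.input_shape):
        raise ValueError(
            f"input shape {x.shape} does not match network input "
            f"{network.input_shape}")
    if output_index < 0 or output_index >= network.output_dim:
        raise ValueError(
            f"output index {output_index} outside [0, {network.output_dim})")
    values, delta = network.deeplift(x, ref, output_index,
                                     post_activation=post_activation)
    allele = None
    if isinstance(encoded_input, EncodedHaplotype):
        allele = encoded_input.allele
    elif isinstance(encoded_input, EncodedDiplotype):
        allele = "/".join(str(a) for a in encoded_input.alleles)
    return AttributionMatrix(values=values, delta=delta,
                             output_index=output_index,
                             input_matrix=x, reference_matrix=ref,
                             allele=allele)


def variant_importance(
    attribution: AttributionMatrix,
    variants: Sequence[VariantRecord],
    window: GenomicWindow,
) -> dict[VariantRecord, float]:
    """Per-variant importance: channel sum of attributions at the anchor.

    Defined only for variant-bearing positions — positions where the input
    encoding actually differs from the reference; others raise.
    """
    diff = attribution.input_matrix != attribution.reference_matrix
    scores: dict[VariantRecord, float] = {}
    for v in variants:
        local = window.to_local(v.pos)
        if not diff[local].any():
            raise ValueError(
                f"position {v.pos} ({v.token()}) does not differ from the "
                "reference encoding; importance undefined")
        scores[v] = float(attribution.values[local].sum())
    return scores
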