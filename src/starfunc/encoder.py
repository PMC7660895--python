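"""Functional variant representation: sequence + annotation channel encoding.

A haplotype over the locus window is encoded as an L x C binary matrix.
The first four channels one-hot encode the nucleotide at each position after
applying the haplotype's variants; the remaining channels are binary
functional annotations. Insertions and deletions are collapsed to their
anchor position and marked with the dedicated INDEL channel so every
haplotype keeps the reference length L.

Two channel modes exist: the 12-channel default (4 nucleotides + 8
annotations, dropping the protein active-site channel) and a 13-channel mode
carrying all nine annotations. Annotation channels come in two scopes:
interval-track annotations (coding region, methylation marks, DNase
hypersensitivity, TFBS, eQTL, active-site codons) are set at every covered
position, while variant-scoped annotations (rare, deleterious, indel) are set
only at positions where the haplotype carries a non-reference allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    ANNOTATION_NAMES,
    TRACK_NAMES,
    AnnotationTrackSet,
    ReferenceWindow,
    StarAlleleDefinition,
    VariantFlagTable,
    VariantKind,
    VariantRecord,
)

NUCLEOTIDES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}

#: Variant-scoped annotation channels (set only at variant-bearing positions).
VARIANT_SCOPED = ("rare", "deleterious", "indel")


@dataclass(frozen=True)
class EncodingConfig:
    """Channel layout of the encoded haplotype matrix.

    channel_mode
        ``"paper12"`` (default): 4 nucleotide channels + 8 annotations,
        the active-site channel dropped. ``"full13"``: all 9 annotations.
    tracks_everywhere
        If True (default), interval-track channels are set at every covered
        position; if False they are set only at variant-bearing positions.
    """

    channel_mode: str = "paper12"
    tracks_everywhere: bool = True

    def __post_init__(self) -> None:
        if self.channel_mode not in {"paper12", "full13"}:
            raise ValueError(f"unknown channel mode {self.channel_mode!r}")

    @property
    def annotations(self) -> tuple[str, ...]:
        if self.channel_mode == "paper12":
            return tuple(a for a in ANNOTATION_NAMES if a != "active_site")
        return ANNOTATION_NAMES

    @property
    def n_channels(self) -> int:
        return 4 + len(self.annotations)


@dataclass
class EncodedHaplotype:
    """L x C binary matrix plus provenance."""

    matrix: np.ndarray  # uint8, shape (L, C)
    config: EncodingConfig
    allele: str | None = None
    variants: tuple[VariantRecord, ...] = ()

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]


@dataclass
class EncodedDiplotype:
    """Channel-wise concatenation of two encoded haplotypes (L x 2C)."""

    matrix: np.ndarray  # uint8, shape (L, 2C)
    config: EncodingConfig
    alleles: tuple[str | None, str | None] = (None, None)


def materialize_haplotype(
    reference: ReferenceWindow,
    variants: Iterable[VariantRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Apply variants to the reference, keeping the window length fixed.

    Returns ``(base_idx, indel_flag)``: per-position nucleotide indices into
    ``"ACGT"`` and a boolean INDEL mask. SNVs substitute the base at their
    position. Insertions keep length L by writing the first inserted base at
    the anchor position and raising the INDEL flag there; deletions leave the
    reference bases in place and raise the INDEL flag at the anchor.
    Overlapping variants (by reference span) and reference mismatches are
    rejected.
    """
    window = reference.window
    L = window.length
    base_idx = np.fromiter((_BASE_INDEX[b] for b in reference.sequence),
                           dtype=np.int8, count=L)
    indel = np.zeros(L, dtype=bool)

    ordered = sorted(variants, key=lambda v: v.pos)
    prev_end = -1
    prev_tok = ""
    for v in ordered:
        if v.contig != window.contig:
            raise ValueError(
                f"variant {v.token()} on wrong contig (window on "
                f"{window.contig!r})")
        lo, hi = v.ref_span
        if not window.contains(lo) or hi > window.end:
            raise ValueError(f"variant {v.token()} outside window")
        if lo < prev_end:
            raise ValueError(
                f"overlapping variants: {prev_tok} and {v.token()}")
        prev_end, prev_tok = hi, v.token()

        local = window.to_local(lo)
        expected = reference.sequence[local:local + len(v.ref)]
        if expected != v.ref:
            raise ValueError(
                f"reference mismatch for {v.token()}: window has "
                f"{expected!r} at position {lo}")
        if v.kind is VariantKind.SNV:
            base_idx[local] = _BASE_INDEX[v.alt]
        elif v.kind is VariantKind.INS:
            # collapse to anchor: first inserted base + INDEL flag
            base_idx[local] = _BASE_INDEX[v.alt[1]]
            indel[local] = True
        else:  # DEL
            indel[local] = True
    return base_idx, indel


def _variant_anchor_map(variants: Iterable[VariantRecord]
                        ) -> dict[int, VariantRecord]:
    return {v.pos: v for v in variants}


def annotation_vector(
    pos: int,
    variant: VariantRecord | None,
    tracks: AnnotationTrackSet,
    flags: VariantFlagTable,
    config: EncodingConfig = EncodingConfig(),
) -> np.ndarray:
    """Annotation bits for one window position (absolute coordinate).

    Track bits reflect interval membership; the rare/deleterious bits are set
    only when ``variant`` (the non-reference allele carried at this position,
    if any) is flagged in the authoritative flag table, and the indel bit
    when the variant is an insertion or deletion.
    """
    local = tracks.window.to_local(pos)
    bits = np.zeros(len(config.annotations), dtype=np.uint8)
    for i, name in enumerate(config.annotations):
        if name in VARIANT_SCOPED:
            continue
        if config.tracks_everywhere or variant is not None:
            bits[i] = tracks.covers(name, local)
    if variant is not None:
        rare, deleterious = flags.lookup(variant)
        ann = {"rare": rare, "deleterious": deleterious,
               "indel": variant.kind is not VariantKind.SNV}
        for i, name in enumerate(config.annotations):
            if name in ann:
                bits[i] = ann[name]
    return bits


def encode_haplotype(
    reference: ReferenceWindow,
    variants: Iterable[VariantRecord],
    tracks: AnnotationTrackSet,
    flags: VariantFlagTable,
    config: EncodingConfig = EncodingConfig(),
    allele: str | None = None,
) -> EncodedHaplotype:
    """Encode one haplotype as an L x C binary matrix."""
    variants = tuple(sorted(variants, key=lambda v: v.pos))
    base_idx, indel = materialize_haplotype(reference, variants)
    L = reference.window.length
    C = config.n_channels
    mat = np.zeros((L, C), dtype=np.uint8)
    mat[np.arange(L), base_idx] = 1

    names = config.annotations
    col = {name: 4 + i for i, name in enumerate(names)}

    # variant-scoped bits at anchor positions
    anchors = _variant_anchor_map(variants)
    for pos, v in anchors.items():
        local = reference.window.to_local(pos)
        if v not in flags:
            raise KeyError(f"variant {v.token()} absent from flag table")
        rare, deleterious = flags.lookup(v)
        if "rare" in col:
            mat[local, col["rare"]] = rare
        if "deleterious" in col:
            mat[local, col["deleterious"]] = deleterious
        mat[local, col["indel"]] = v.kind is not VariantKind.SNV

    # track-scoped bits
    for name in names:
        if name in VARIANT_SCOPED:
            continue
        mask = tracks.mask(name)
        if config.tracks_everywhere:
            mat[:, col[name]] = mask.astype(np.uint8)
        else:
            for pos in anchors:
                local = reference.window.to_local(pos)
                mat[local, col[name]] = mask[local]

    return EncodedHaplotype(matrix=mat, config=config, allele=allele,
                            variants=variants)


def encode_diplotype(e1: EncodedHaplotype,
                     e2: EncodedHaplotype) -> EncodedDiplotype:
    """Concatenate two encoded haplotypes along the channel axis.

    The first haplotype occupies channels ``0..C-1``, the second
    ``C..2C-1``. Single-haplotype prediction duplicates one haplotype into
    both halves.
    """
    if e1.matrix.shape != e2.matrix.shape:
        raise ValueError(
            f"shape mismatch: {e1.matrix.shape} vs {e2.matrix.shape}")
    if e1.config != e2.config:
        raise ValueError("encoding configs differ between haplotypes")
    return EncodedDiplotype(
        matrix=np.concatenate([e1.matrix, e2.matrix], axis=1),
        config=e1.config, alleles=(e1.allele, e2.allele))


def annotation_counts(
    variants: Iterable[VariantRecord],
    tracks: AnnotationTrackSet,
    flags: VariantFlagTable,
) -> np.ndarray:
    """Nine annotation counts over a haplotype's variants (baseline features).

    Each entry is the number of variants carrying the corresponding
    annotation, in the canonical order of :data:`ANNOTATION_NAMES`. Track
    annotations are evaluated at the variant anchor position.
    """
    counts = np.zeros(len(ANNOTATION_NAMES), dtype=np.int64)
    window = tracks.window
    masks = {name: tracks.mask(name) for name in TRACK_NAMES}
    for v in variants:
        local = window.to_local(v.pos)
        rare, deleterious = flags.lookup(v)
        for i, name in enumerate(ANNOTATION_NAMES):
            if name == "rare":
                counts[i] += rare
            elif name == "deleterious":
                counts[i] += deleterious
            elif name == "indel":
                counts[i] += v.kind is not VariantKind.SNV
            else:
                counts[i] += bool(masks[name][local])
    return counts


def encode_definitions(
    definitions: Sequence[StarAlleleDefinition],
    reference: ReferenceWindow,
    tracks: AnnotationTrackSet,
    flags: VariantFlagTable,
    config: EncodingConfig = EncodingConfig(),
) -> dict[str, EncodedHaplotype]:
    """Encode every star-allele definition, keyed by full allele name."""
    return {
        d.full_name: encode_haplotype(reference, d.variants, tracks, flags,
                                      config, allele=d.full_name)
        for d in definitions
    }
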