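"""Core domain types for the CYP2D6 star-allele function predictor.

The locus of interest is the CYP2D6 gene on chromosome 22 (hg19). Haplotypes
at this locus are named with the star-allele nomenclature (*1, *2, ...); each
star allele is defined by a set of core variants and carries a curated
function label (normal / decreased / no function), or is "uncurated" when
curators have not assigned one. Diplotypes (ordered pairs of haplotypes) map
to a clinical activity score by summing per-allele values.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

_ACGT = frozenset("ACGT")

#: Capture window of the CYP2D6 locus on hg19, 0-based half-open.
#: Spans the gene body plus 2,103 bp upstream and 934 bp downstream flank.
CYP2D6_WINDOW: "GenomicWindow"


class Function(enum.Enum):
    """Curated star-allele function label, ordered none < decreased < normal."""

    NONE = "none"
    DECREASED = "decreased"
    NORMAL = "normal"
    UNCURATED = "uncurated"

    @property
    def is_curated(self) -> bool:
        return self is not Function.UNCURATED

    @property
    def rank(self) -> int:
        """Ordinal rank among curated labels (none=0, decreased=1, normal=2)."""
        if not self.is_curated:
            raise ValueError("uncurated function has no ordinal rank")
        return {"none": 0, "decreased": 1, "normal": 2}[self.value]

    @classmethod
    def parse(cls, text: str) -> "Function":
        """Parse a function label case-insensitively.

        Curator vocabulary such as "Uncertain", "Unknown", "not available",
        "No function", "Decreased function" is accepted.
        """
        t = text.strip().lower().replace("_", " ")
        if t in {"uncertain", "unknown", "not available", "n/a", "uncurated"}:
            return cls.UNCURATED
        t = t.removesuffix(" function").strip()
        mapping = {"no": cls.NONE, "none": cls.NONE,
                   "decreased": cls.DECREASED, "normal": cls.NORMAL}
        if t not in mapping:
            raise ValueError(f"unknown function label: {text!r}")
        return mapping[t]


class VariantKind(enum.Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"


@dataclass(frozen=True)
class GenomicWindow:
    """A contiguous genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"window end ({self.end}) must exceed start ({self.start})")
        if self.start < 0:
            raise ValueError("window start must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def to_local(self, pos: int) -> int:
        """Convert an absolute coordinate to a window-relative offset."""
        if not self.contains(pos):
            raise ValueError(f"position {pos} outside window {self}")
        return pos - self.start


CYP2D6_WINDOW = GenomicWindow("chr22", 42_521_567, 42_528_984)


@dataclass(frozen=True)
class ReferenceWindow:
    """Reference sequence over a genomic window (uppercase A/C/G/T only)."""

    window: GenomicWindow
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.window.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != window length "
                f"{self.window.length}")
        bad = [i for i, b in enumerate(self.sequence) if b not in _ACGT]
        if bad:
            raise ValueError(
                f"non-ACGT character {self.sequence[bad[0]]!r} at window "
                f"offset {bad[0]}")

    def base_at(self, pos: int) -> str:
        return self.sequence[self.window.to_local(pos)]


_VARIANT_TOKEN = re.compile(
    r"^(?P<contig>[^:]+):(?P<pos>\d+):(?P<ref>[ACGT]+):(?P<alt>[ACGT]+)$")


@dataclass(frozen=True, order=True)
class VariantRecord:
    """A small sequence variant in left-aligned minimal representation.

    ``pos`` is 0-based. SNVs have single-base ref and alt; insertions and
    deletions carry a shared single anchor base (VCF-style), e.g. T>TA for an
    insertion and TA>T for a deletion. Non-minimal records are rejected.
    """

    contig: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        for s in (self.ref, self.alt):
            if set(s) - _ACGT:
                raise ValueError(f"non-ACGT allele in {self.token()}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt in {self.token()}")
        if len(self.ref) == len(self.alt):
            if len(self.ref) != 1:
                raise ValueError(
                    f"multi-nucleotide substitution not supported: "
                    f"{self.token()}")
        else:
            # indel: single anchor base, no shared suffix beyond it
            if self.ref[0] != self.alt[0]:
                raise ValueError(
                    f"indel must share a leading anchor base: {self.token()}")
            if min(len(self.ref), len(self.alt)) != 1:
                raise ValueError(
                    f"indel not in minimal representation: {self.token()}")

    @property
    def kind(self) -> VariantKind:
        if len(self.ref) == len(self.alt):
            return VariantKind.SNV
        return VariantKind.INS if len(self.alt) > len(self.ref) else VariantKind.DEL

    @property
    def ref_span(self) -> tuple[int, int]:
        """Half-open interval of reference positions consumed by the variant."""
        return self.pos, self.pos + len(self.ref)

    def token(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_token(cls, token: str) -> "VariantRecord":
        m = _VARIANT_TOKEN.match(token.strip())
        if not m:
            raise ValueError(f"malformed variant token: {token!r}")
        return cls(m["contig"], int(m["pos"]), m["ref"], m["alt"])


@dataclass(frozen=True)
class StarAlleleDefinition:
    """A named star allele: a variant set plus a curated function label."""

    name: str
    variants: frozenset[VariantRecord]
    function: Function
    suballele: str | None = None

    def __post_init__(self) -> None:
        if not self.variants and self.name.lstrip("*") not in {"1"}:
            raise ValueError(
                f"star allele {self.name} has no variants but is not the "
                "reference allele *1")

    @property
    def full_name(self) -> str:
        return self.name if self.suballele is None else \
            f"{self.name}.{self.suballele}"


class VariantFlagTable:
    """Per-variant binary flags: rare in the population, and deleterious.

    Flags are precomputed upstream (population frequency filters and
    deleteriousness predictors, with loss-of-function calls taking
    precedence); this table is authoritative for the encoder.
    """

    def __init__(self, flags: Mapping[tuple[int, str, str],
                                      tuple[bool, bool]] | None = None):
        self._flags: dict[tuple[int, str, str], tuple[bool, bool]] = dict(
            flags or {})

    @staticmethod
    def _key(v: VariantRecord) -> tuple[int, str, str]:
        return (v.pos, v.ref, v.alt)

    def add(self, variant: VariantRecord, rare: bool, deleterious: bool) -> None:
        key = self._key(variant)
        if key in self._flags:
            raise ValueError(f"duplicate flag entry for {variant.token()}")
        self._flags[key] = (bool(rare), bool(deleterious))

    def lookup(self, variant: VariantRecord) -> tuple[bool, bool]:
        try:
            return self._flags[self._key(variant)]
        except KeyError:
            raise KeyError(
                f"variant {variant.token()} absent from flag table") from None

    def __contains__(self, variant: VariantRecord) -> bool:
        return self._key(variant) in self._flags

    def __len__(self) -> int:
        return len(self._flags)

    def items(self):
        return self._flags.items()


#: Canonical annotation order used throughout the package. The first eight
#: form the default encoding; active_site (a protein-level annotation) is the
#: ninth and is included in ``full13`` mode and in baseline count vectors.
ANNOTATION_NAMES: tuple[str, ...] = (
    "coding", "rare", "deleterious", "indel",
    "methylation", "dnase", "tfbs", "eqtl", "active_site",
)

#: Annotations derived from genomic interval tracks (set at every covered
#: position); the remaining three (rare, deleterious, indel) are properties
#: of the carried variant.
TRACK_NAMES: tuple[str, ...] = (
    "coding", "methylation", "dnase", "tfbs", "eqtl", "active_site",
)


class AnnotationTrackSet:
    """Named interval tracks over a window (half-open, window-relative)."""

    def __init__(self, window: GenomicWindow,
                 intervals: Mapping[str, Iterable[tuple[int, int]]] | None = None):
        self.window = window
        self._intervals: dict[str, list[tuple[int, int]]] = {
            name: [] for name in TRACK_NAMES}
        for name, ivs in (intervals or {}).items():
            for s, e in ivs:
                self.add(name, s, e)

    def add(self, name: str, start: int, end: int) -> None:
        """Add a window-relative half-open interval to a track."""
        if name not in self._intervals:
            raise KeyError(f"unknown track {name!r}; known: {TRACK_NAMES}")
        if end <= start:
            raise ValueError(f"empty/inverted interval [{start}, {end})")
        if start < 0 or end > self.window.length:
            raise ValueError(
                f"interval [{start}, {end}) outside window of length "
                f"{self.window.length}")
        self._intervals[name].append((start, end))

    def intervals(self, name: str) -> list[tuple[int, int]]:
        return sorted(self._intervals[name])

    def mask(self, name: str):
        """Boolean membership mask of window length for one track."""
        import numpy as np

        m = np.zeros(self.window.length, dtype=bool)
        for s, e in self._intervals[name]:
            m[s:e] = True
        return m

    def covers(self, name: str, local_pos: int) -> bool:
        return any(s <= local_pos < e for s, e in self._intervals[name])


class AlleleFrequencyTable:
    """Population alternate-allele frequencies for background variant sites."""

    def __init__(self, freqs: Mapping[VariantRecord, float] | None = None):
        self._freqs: dict[VariantRecord, float] = {}
        for v, f in (freqs or {}).items():
            self.add(v, f)

    def add(self, variant: VariantRecord, freq: float) -> None:
        if not 0.0 <= freq <= 1.0:
            raise ValueError(
                f"allele frequency {freq} for {variant.token()} outside [0, 1]")
        if variant in self._freqs:
            raise ValueError(f"duplicate frequency entry for {variant.token()}")
        self._freqs[variant] = float(freq)

    def items(self) -> list[tuple[VariantRecord, float]]:
        return sorted(self._freqs.items(), key=lambda kv: kv[0])

    def sites(self) -> set[int]:
        return {v.pos for v in self._freqs}

    def __len__(self) -> int:
        return len(self._freqs)


@dataclass
class PredictionRecord:
    """One row of a prediction table (mirrors the published supplement layout)."""

    allele: str
    suballele: str | None
    score_notnone: float
    score_normal: float
    predicted_function: Function
    curated_function: Function = Function.UNCURATED
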