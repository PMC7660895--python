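"""Diplotype simulation and synthetic locus fixtures.

The activity-score (AS) system assigns each curated star allele a value
(0 for no function, 0.5 — or 0.25 by configuration — for decreased
function, 1 for normal function); a diplotype's AS is the sum over its two
alleles, giving the five classes {0, 0.5, 1, 1.5, 2} at the default
decreased value. Simulated diplotypes pair random curated alleles and add
background variation: at every site of a population allele-frequency table,
each haplotype independently carries the alternate allele with probability
equal to its population frequency.

The synthetic locus generator builds a fully self-consistent miniature
study system — random reference window, star alleles per function class
with class-informative annotation flags, interval tracks, a flag table
covering every emitted variant, and a background allele-frequency table —
so the complete pipeline runs without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    AlleleFrequencyTable,
    AnnotationTrackSet,
    Function,
    GenomicWindow,
    ReferenceWindow,
    StarAlleleDefinition,
    VariantFlagTable,
    VariantRecord,
)

DEFAULT_DECREASED_VALUE = 0.5


def allele_activity_value(function: Function,
                          decreased_value: float = DEFAULT_DECREASED_VALUE
                          ) -> float:
    """Per-allele activity value: none 0, decreased 0.5 (or 0.25), normal 1."""
    if not function.is_curated:
        raise ValueError(
            "uncurated alleles have no activity value and cannot be simulated")
    return {Function.NONE: 0.0, Function.DECREASED: float(decreased_value),
            Function.NORMAL: 1.0}[function]


def diplotype_activity_score(f1: Function, f2: Function,
                             decreased_value: float = DEFAULT_DECREASED_VALUE
                             ) -> float:
    """Diplotype activity score: sum of the two per-allele values."""
    return allele_activity_value(f1, decreased_value) + \
        allele_activity_value(f2, decreased_value)


def activity_score_classes(decreased_value: float = DEFAULT_DECREASED_VALUE
                           ) -> list[float]:
    """All AS values reachable by some pair of curated function labels."""
    curated = [Function.NONE, Function.DECREASED, Function.NORMAL]
    return sorted({diplotype_activity_score(a, b, decreased_value)
                   for a in curated for b in curated})


@dataclass(frozen=True)
class DiplotypeSample:
    """A simulated diplotype: allele pair, per-haplotype variants, AS label."""

    allele1: str
    allele2: str
    variants1: frozenset[VariantRecord]
    variants2: frozenset[VariantRecord]
    activity_score: float
    measured_activity: float | None = None


def simulate_diplotypes(
    definitions: Sequence[StarAlleleDefinition],
    af_table: AlleleFrequencyTable,
    n_per_class: int,
    seed: int | np.random.Generator,
    decreased_value: float = DEFAULT_DECREASED_VALUE,
) -> list[DiplotypeSample]:
    """Simulate ``n_per_class`` diplotypes for every activity-score class.

    Ordered pairs of curated alleles are drawn uniformly within each AS
    class (equivalent in distribution to rejection-sampling uniform pairs
    into class quotas). Background alternates are added per haplotype as
    independent Bernoulli draws at each allele-frequency site; sites must
    be disjoint from every star-allele variant site.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    curated = [d for d in definitions if d.function.is_curated]
    if not curated:
        raise ValueError("no curated star alleles to simulate from")

    core_sites = {v.pos for d in curated for v in d.variants}
    af_entries = af_table.items()
    clash = [v for v, _ in af_entries if v.pos in core_sites]
    if clash:
        raise ValueError(
            f"allele-frequency site(s) collide with star-allele core sites: "
            f"{[v.token() for v in clash[:3]]}")

    # ordered pairs grouped by AS class
    pairs_by_class: dict[float, list[tuple[int, int]]] = {}
    for i, a in enumerate(curated):
        for j, b in enumerate(curated):
            score = diplotype_activity_score(a.function, b.function,
                                             decreased_value)
            pairs_by_class.setdefault(score, []).append((i, j))
    classes = activity_score_classes(decreased_value)
    missing = [c for c in classes if c not in pairs_by_class]
    if missing:
        raise ValueError(
            f"no allele pair realizes activity-score class(es) {missing}")

    af_variants = [v for v, _ in af_entries]
    af_freqs = np.array([f for _, f in af_entries])

    def background() -> frozenset[VariantRecord]:
        if not af_variants:
            return frozenset()
        carry = rng.random(len(af_variants)) < af_freqs
        return frozenset(v for v, c in zip(af_variants, carry) if c)

    samples: list[DiplotypeSample] = []
    for score in classes:
        pairs = pairs_by_class[score]
        picks = rng.integers(0, len(pairs), size=n_per_class)
        for k in picks:
            i, j = pairs[k]
            a, b = curated[i], curated[j]
            samples.append(DiplotypeSample(
                allele1=a.full_name, allele2=b.full_name,
                variants1=a.variants | background(),
                variants2=b.variants | background(),
                activity_score=score))
    return samples


def simulate_activity_measurements(
    samples: Sequence[DiplotypeSample],
    slope: float = 50.0,
    intercept: float = 0.0,
    noise_sd: float = 26.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Synthetic metabolic-activity measurements, linear in the AS plus noise.

    Emulates an in vitro enzymatic activity readout (percent of reference):
    ``activity = intercept + slope * AS + N(0, noise_sd)``. With the default
    slope 50 an AS of 2 (two normal alleles) sits at 100% of reference, and
    the default noise gives the AS about two thirds of the variance —
    comparable to how much of real liver-microsome activity the score
    explains. This is a stand-in signal for pre-training, not real assay
    data.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    scores = np.array([s.activity_score for s in samples], dtype=float)
    return intercept + slope * scores + rng.normal(0.0, noise_sd,
                                                   size=len(scores))


def expected_activity_r2(slope: float, noise_sd: float,
                         as_values: Sequence[float]) -> float:
    """Closed-form R^2 of AS vs simulated activity under class balance.

    ``R^2 = s^2 Var(AS) / (s^2 Var(AS) + sigma^2)`` for AS uniform over
    ``as_values``.
    """
    var_as = float(np.var(np.asarray(as_values, dtype=float)))
    signal = slope ** 2 * var_as
    if signal == 0 and noise_sd == 0:
        raise ValueError("degenerate: no signal and no noise")
    return signal / (signal + noise_sd ** 2)


# ---------------------------------------------------------------------------
# synthetic locus fixtures

@dataclass
class SyntheticLocus:
    """Everything the pipeline needs, generated from a seed."""

    reference: ReferenceWindow
    definitions: list[StarAlleleDefinition]
    tracks: AnnotationTrackSet
    flags: VariantFlagTable
    af_table: AlleleFrequencyTable


def generate_synthetic_locus(
    n_alleles_per_class: tuple[int, int, int] = (3, 3, 3),
    window_length: int = 2000,
    n_af_sites: int = 50,
    seed: int | np.random.Generator = 0,
    contig: str = "chrS",
    n_uncurated: int = 0,
) -> SyntheticLocus:
    """Generate a self-consistent synthetic locus.

    The reference is a random sequence over a window ``[0, window_length)``.
    A coding track covers the interior of the window (emulating the gene
    body inside a capture window with flanking sequence); the remaining
    tracks are random intervals. Star alleles carry class-informative
    variants inside the coding region:

    * no function — one rare *and deleterious* coding variant (a
      loss-of-function-like lesion), plus optional benign passengers;
    * decreased function — one rare, non-deleterious coding variant;
    * normal function — one or two common, benign variants.

    Background allele-frequency sites are placed outside the coding track
    with frequencies in [0.05, 0.5), i.e. common polymorphisms whose
    ``rare`` flag is 0 under the population-frequency rule, so background
    variation never mimics a class signal. Every emitted variant appears in
    the flag table. The same seed regenerates identical tables.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if window_length < 100:
        raise ValueError("window_length must be >= 100")
    if n_af_sites < 0 or any(n <= 0 for n in n_alleles_per_class):
        raise ValueError("counts must be positive")

    window = GenomicWindow(contig, 0, window_length)
    seq = "".join(rng.choice(list("ACGT"), size=window_length))
    reference = ReferenceWindow(window, seq)

    # coding region occupies the interior ~10%..80% of the window
    cds_start = int(0.10 * window_length)
    cds_end = int(0.80 * window_length)
    tracks = AnnotationTrackSet(window)
    tracks.add("coding", cds_start, cds_end)
    for name in ("methylation", "dnase", "tfbs", "eqtl", "active_site"):
        for _ in range(int(rng.integers(1, 4))):
            s = int(rng.integers(0, window_length - 20))
            e = s + int(rng.integers(5, 60))
            tracks.add(name, s, min(e, window_length))

    used_sites: set[int] = set()

    def fresh_site(lo: int, hi: int) -> int:
        # keep a 1-bp gap so single-base variants never overlap
        for _ in range(10_000):
            p = int(rng.integers(lo, hi))
            if all(abs(p - q) > 1 for q in used_sites):
                used_sites.add(p)
                return p
        raise RuntimeError("could not place a variant site; window too small")

    def snv_at(pos: int) -> VariantRecord:
        ref = reference.sequence[pos]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return VariantRecord(contig, pos, ref, str(alt))

    def indel_at(pos: int) -> VariantRecord:
        ref = reference.sequence[pos]
        if rng.random() < 0.5:
            ins = str(rng.choice(list("ACGT")))
            return VariantRecord(contig, pos, ref, ref + ins)
        nxt = reference.sequence[pos + 1]
        return VariantRecord(contig, pos, ref + nxt, ref)

    flags = VariantFlagTable()
    definitions: list[StarAlleleDefinition] = []
    n_none, n_dec, n_norm = n_alleles_per_class
    allele_no = 2  # *1 is the reference allele

    def add_allele(function: Function, variants: set[VariantRecord]) -> None:
        nonlocal allele_no
        definitions.append(StarAlleleDefinition(
            name=f"*{allele_no}", variants=frozenset(variants),
            function=function))
        allele_no += 1

    for _ in range(n_none):
        pos = fresh_site(cds_start, cds_end - 2)
        lesion = indel_at(pos) if rng.random() < 0.3 else snv_at(pos)
        flags.add(lesion, rare=True, deleterious=True)
        variants = {lesion}
        if rng.random() < 0.5:  # benign passenger outside coding
            passenger = snv_at(fresh_site(0, cds_start))
            flags.add(passenger, rare=False, deleterious=False)
            variants.add(passenger)
        add_allele(Function.NONE, variants)

    for _ in range(n_dec):
        v = snv_at(fresh_site(cds_start, cds_end - 2))
        flags.add(v, rare=True, deleterious=False)
        add_allele(Function.DECREASED, {v})

    for _ in range(n_norm):
        variants = set()
        for _ in range(int(rng.integers(1, 3))):
            v = snv_at(fresh_site(cds_end, window_length - 2))
            flags.add(v, rare=False, deleterious=False)
            variants.add(v)
        add_allele(Function.NORMAL, variants)

    for _ in range(n_uncurated):
        v = snv_at(fresh_site(cds_start, cds_end - 2))
        flags.add(v, rare=bool(rng.random() < 0.5), deleterious=False)
        add_allele(Function.UNCURATED, {v})

    af_table = AlleleFrequencyTable()
    for _ in range(n_af_sites):
        # background sites avoid the coding track so common variation never
        # carries a class-informative flag pattern
        if rng.random() < 0.5:
            pos = fresh_site(0, cds_start - 2) if cds_start > 2 else \
                fresh_site(cds_end, window_length - 2)
        else:
            pos = fresh_site(cds_end, window_length - 2)
        v = snv_at(pos)
        freq = float(rng.uniform(0.05, 0.5))
        flags.add(v, rare=freq < 0.05, deleterious=False)
        af_table.add(v, freq)

    return SyntheticLocus(reference=reference, definitions=definitions,
                          tracks=tracks, flags=flags, af_table=af_table)
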