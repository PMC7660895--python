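"""Readers and writers for the external file formats.

All coordinates on disk and in memory are 0-based half-open. Loaders reject
malformed records rather than repairing them, reporting the offending line
or position.

Formats:

* reference sequence — FASTA (read via pyfaidx)
* star-allele definitions — TSV with columns ``allele``, ``suballele``,
  ``variants`` (semicolon-joined ``contig:pos:ref:alt`` tokens, ``.`` for the
  reference allele), ``function``
* variant flags — TSV ``contig  pos  ref  alt  rare  deleterious``
* allele frequencies — TSV ``contig  pos  ref  alt  freq``
* annotation tracks — 3-column BED per track
* predictions — TSV mirroring the published supplementary table layout
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from pyfaidx import Fasta

from .core import (
    AlleleFrequencyTable,
    AnnotationTrackSet,
    Function,
    GenomicWindow,
    PredictionRecord,
    ReferenceWindow,
    StarAlleleDefinition,
    VariantFlagTable,
    VariantRecord,
)


# ---------------------------------------------------------------------------
# reference

def load_reference_window(fasta_path: str | Path,
                          window: GenomicWindow) -> ReferenceWindow:
    """Extract the reference sequence for ``window`` from a FASTA file."""
    fasta = Fasta(str(fasta_path), as_raw=True, rebuild=False)
    try:
        if window.contig not in fasta:
            raise ValueError(
                f"contig {window.contig!r} not present in {fasta_path}")
        contig_len = len(fasta[window.contig])
        if window.end > contig_len:
            raise ValueError(
                f"window [{window.start}, {window.end}) exceeds contig "
                f"{window.contig} length {contig_len}")
        seq = str(fasta[window.contig][window.start:window.end]).upper()
    finally:
        fasta.close()
    return ReferenceWindow(window, seq)  # validates length and alphabet


def write_reference_fasta(path: str | Path, contig: str, sequence: str,
                          width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# star-allele definitions

_DEF_COLUMNS = ("allele", "suballele", "variants", "function")


def _validate_variant(v: VariantRecord, window: GenomicWindow) -> None:
    if v.contig != window.contig:
        raise ValueError(
            f"variant {v.token()} on contig {v.contig!r}, window is on "
            f"{window.contig!r}")
    lo, hi = v.ref_span
    if not (window.contains(lo) and hi <= window.end):
        raise ValueError(f"variant {v.token()} outside window {window}")


def load_star_allele_table(path: str | Path,
                           window: GenomicWindow) -> list[StarAlleleDefinition]:
    """Load star-allele definitions, validating each variant against ``window``."""
    defs: list[StarAlleleDefinition] = []
    seen: set[tuple[str, str | None]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or \
                tuple(reader.fieldnames) != _DEF_COLUMNS:
            raise ValueError(
                f"expected columns {_DEF_COLUMNS}, got {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            sub = row["suballele"].strip() or None
            if sub == ".":
                sub = None
            key = (row["allele"].strip(), sub)
            if key in seen:
                raise ValueError(
                    f"duplicate (allele, suballele) row {key} at line {lineno}")
            seen.add(key)
            vtext = row["variants"].strip()
            variants: set[VariantRecord] = set()
            if vtext not in {"", "."}:
                for token in vtext.split(";"):
                    v = VariantRecord.from_token(token)
                    _validate_variant(v, window)
                    variants.add(v)
            defs.append(StarAlleleDefinition(
                name=key[0], suballele=sub,
                variants=frozenset(variants),
                function=Function.parse(row["function"])))
    return defs


def write_star_allele_table(defs: Sequence[StarAlleleDefinition],
                            path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_DEF_COLUMNS)
        for d in defs:
            tokens = ";".join(v.token() for v in sorted(d.variants))
            w.writerow([d.name, d.suballele or ".", tokens or ".",
                        d.function.value])


# ---------------------------------------------------------------------------
# annotation tracks (BED3)

def load_annotation_tracks(bed_paths_by_name: Mapping[str, str | Path],
                           window: GenomicWindow) -> AnnotationTrackSet:
    """Load BED3 interval files into a track set, clipping to the window.

    Intervals entirely outside the window are dropped; intervals on a
    different contig are an error.
    """
    tracks = AnnotationTrackSet(window)
    for name, path in bed_paths_by_name.items():
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: BED line has fewer than 3 fields")
                contig, start, end = parts[0], int(parts[1]), int(parts[2])
                if contig != window.contig:
                    raise ValueError(
                        f"{path}:{lineno}: interval on contig {contig!r}, "
                        f"window is on {window.contig!r}")
                if end <= start:
                    raise ValueError(
                        f"{path}:{lineno}: empty/inverted interval")
                s = max(start, window.start)
                e = min(end, window.end)
                if s < e:
                    tracks.add(name, s - window.start, e - window.start)
    return tracks


def write_bed(intervals: Iterable[tuple[int, int]], path: str | Path,
              window: GenomicWindow) -> None:
    """Write window-relative intervals as absolute BED3."""
    with open(path, "w") as fh:
        for s, e in sorted(intervals):
            fh.write(f"{window.contig}\t{window.start + s}\t"
                     f"{window.start + e}\n")


# ---------------------------------------------------------------------------
# variant flag table

def load_variant_flag_table(path: str | Path,
                            window: GenomicWindow) -> VariantFlagTable:
    table = VariantFlagTable()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        expected = ("contig", "pos", "ref", "alt", "rare", "deleterious")
        if reader.fieldnames is None or tuple(reader.fieldnames) != expected:
            raise ValueError(
                f"expected columns {expected}, got {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            v = VariantRecord(row["contig"], int(row["pos"]), row["ref"],
                              row["alt"])
            _validate_variant(v, window)
            rare, dele = row["rare"].strip(), row["deleterious"].strip()
            if rare not in {"0", "1"} or dele not in {"0", "1"}:
                raise ValueError(
                    f"{path}:{lineno}: flags must be 0/1, got "
                    f"rare={rare!r} deleterious={dele!r}")
            table.add(v, rare == "1", dele == "1")
    return table


def write_variant_flag_table(table: VariantFlagTable, path: str | Path,
                             contig: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig", "pos", "ref", "alt", "rare", "deleterious"])
        for (pos, ref, alt), (rare, dele) in sorted(table.items()):
            w.writerow([contig, pos, ref, alt, int(rare), int(dele)])


# ---------------------------------------------------------------------------
# allele-frequency table

def load_allele_frequency_table(path: str | Path,
                                window: GenomicWindow) -> AlleleFrequencyTable:
    table = AlleleFrequencyTable()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        expected = ("contig", "pos", "ref", "alt", "freq")
        if reader.fieldnames is None or tuple(reader.fieldnames) != expected:
            raise ValueError(
                f"expected columns {expected}, got {reader.fieldnames}")
        for lineno, row in enumerate(reader, start=2):
            v = VariantRecord(row["contig"], int(row["pos"]), row["ref"],
                              row["alt"])
            _validate_variant(v, window)
            freq = float(row["freq"])
            if not 0.0 <= freq <= 1.0:
                raise ValueError(
                    f"{path}:{lineno}: allele frequency {freq} outside [0, 1]")
            table.add(v, freq)
    return table


def write_allele_frequency_table(table: AlleleFrequencyTable,
                                 path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig", "pos", "ref", "alt", "freq"])
        for v, f in table.items():
            w.writerow([v.contig, v.pos, v.ref, v.alt, f"{f:.6g}"])


# ---------------------------------------------------------------------------
# prediction tables

_PRED_COLUMNS = ("allele", "suballele", "score_notnone", "score_normal",
                 "predicted_function", "curated_function")


def write_prediction_table(records: Sequence[PredictionRecord],
                           path: str | Path) -> None:
    """Write predictions as TSV; scores round-trip losslessly at 6 decimals."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PRED_COLUMNS)
        for r in records:
            w.writerow([r.allele, r.suballele or ".",
                        f"{r.score_notnone:.6f}", f"{r.score_normal:.6f}",
                        r.predicted_function.value, r.curated_function.value])


def load_prediction_table(path: str | Path) -> list[PredictionRecord]:
    records: list[PredictionRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or \
                tuple(reader.fieldnames) != _PRED_COLUMNS:
            raise ValueError(
                f"expected columns {_PRED_COLUMNS}, got {reader.fieldnames}")
        for row in reader:
            sub = row["suballele"]
            records.append(PredictionRecord(
                allele=row["allele"],
                suballele=None if sub == "." else sub,
                score_notnone=float(row["score_notnone"]),
                score_normal=float(row["score_normal"]),
                predicted_function=Function.parse(row["predicted_function"]),
                curated_function=Function.parse(row["curated_function"])))
    return records
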