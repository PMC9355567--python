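"""From sequencing reads to per-lineage count matrices.

Amplicon reads carry an inline index, a constant left flank, a random DNA
barcode, and a constant right flank.  Each barcode identifies one lineage:
a (plasmid library, clone, insertion mutation) triple recorded in a
barcode map.  Processing is: quality/index filtering -> barcode extraction
-> error correction against the known barcode set -> tallying into a
lineage x timepoint count matrix per (library, clone) assay.

Error correction uses the single-bp-deletion-neighborhood method: a raw
barcode is assigned to a known barcode exactly when the set of strings
obtained by deleting one base from the raw barcode (plus the raw barcode
itself) intersects the analogous set of exactly one known barcode.  This
recovers single substitutions and single indels while remaining
unambiguous by construction; raw barcodes whose neighborhood touches two
known barcodes, or none, are left unassigned.
"""

from __future__ import annotations

import gzip
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

VALID_BASES = set("ACGTN")

#: categories used when tallying reads that could not be assigned
UNASSIGNED_CATEGORIES = ("no_flank", "ambiguous", "no_neighbor", "bad_length")


class FastqFormatError(ValueError):
    """Raised for a structurally malformed FASTQ record."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read restricted to the fields the pipeline uses."""

    sequence: str
    quality: tuple[int, ...]  # phred scores, one per base
    inline_index: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence and quality must have equal length")
        if not set(self.sequence) <= VALID_BASES:
            raise ValueError(f"invalid bases in read: {self.sequence!r}")


@dataclass(frozen=True)
class BarcodePattern:
    """Anchored barcode layout: constant flanks around a variable barcode.

    ``max_flank_mismatches`` substitutions are tolerated in each flank;
    the barcode length must fall in ``[min_length, max_length]``.
    """

    left_flank: str
    right_flank: str
    min_length: int
    max_length: int
    max_flank_mismatches: int = 0


def read_fastq(path: str | Path, index_length: int = 0) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` from a FASTQ file (gzip-transparent).

    The inline index is taken as the first ``index_length`` bases of each
    read; the remainder is the searchable sequence.  Quality is decoded as
    phred+33 (the only encoding produced by current instruments).

    Raises
    ------
    FastqFormatError
        Naming the record offset, if a record is malformed.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        parser = FastqGeneralIterator(handle)
        record = 0
        while True:
            try:
                _title, seq, qual = next(parser)
            except StopIteration:
                return
            except ValueError as err:
                raise FastqFormatError(
                    f"malformed FASTQ record at offset {record}: {err}"
                ) from err
            scores = tuple(ord(ch) - 33 for ch in qual)
            yield ReadRecord(
                sequence=seq[index_length:].upper(),
                quality=scores[index_length:],
                inline_index=seq[:index_length].upper(),
            )
            record += 1


def filter_reads(
    reads: Iterable[ReadRecord],
    expected_index: str,
    min_quality: int = 20,
    max_low_quality_bases: int = 0,
    region: slice | None = None,
) -> Iterator[ReadRecord]:
    """Keep reads whose inline index matches exactly and whose barcode
    region has at most ``max_low_quality_bases`` bases below
    ``min_quality``.

    ``region`` restricts the quality check to the barcode region of the
    read; ``None`` checks the whole read.  Order is preserved.
    """
    for read in reads:
        if read.inline_index != expected_index:
            continue
        scores = read.quality if region is None else read.quality[region]
        low = sum(1 for q in scores if q < min_quality)
        if low > max_low_quality_bases:
            continue
        yield read


def _find_with_mismatches(haystack: str, needle: str, max_mm: int) -> int:
    """Leftmost start of ``needle`` in ``haystack`` allowing substitutions."""
    if max_mm == 0:
        return haystack.find(needle)
    n = len(needle)
    for start in range(len(haystack) - n + 1):
        mm = 0
        for a, b in zip(haystack[start : start + n], needle):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        else:
            return start
    return -1


def extract_barcode(read: ReadRecord, pattern: BarcodePattern) -> str | None:
    """Extract the barcode between the pattern's flanks, or ``None``.

    Both flanks must be found (within the pattern's mismatch tolerance)
    and the intervening sequence must have an admissible length.
    """
    seq = read.sequence
    if pattern.max_flank_mismatches == 0:
        regex = re.compile(
            re.escape(pattern.left_flank)
            + f"([ACGTN]{{{pattern.min_length},{pattern.max_length}}})"
            + re.escape(pattern.right_flank)
        )
        match = regex.search(seq)
        return match.group(1) if match else None
    left = _find_with_mismatches(seq, pattern.left_flank, pattern.max_flank_mismatches)
    if left < 0:
        return None
    bc_start = left + len(pattern.left_flank)
    for bc_len in range(pattern.min_length, pattern.max_length + 1):
        rest = seq[bc_start + bc_len :]
        if len(rest) < len(pattern.right_flank):
            break
        if (
            _find_with_mismatches(
                rest[: len(pattern.right_flank)],
                pattern.right_flank,
                pattern.max_flank_mismatches,
            )
            == 0
        ):
            return seq[bc_start : bc_start + bc_len]
    return None


def _deletion_neighborhood(s: str) -> set[str]:
    """All strings from deleting one position of ``s``, plus ``s`` itself."""
    return {s} | {s[:i] + s[i + 1 :] for i in range(len(s))}


class BarcodeCorrector:
    """Single-bp-deletion-neighborhood error correction.

    An index maps every string in each known barcode's deletion
    neighborhood to the set of known barcodes owning it; a raw barcode is
    assigned when the union of known barcodes over its own neighborhood
    has exactly one member.  A raw barcode that is itself a known barcode
    is always assigned to itself.
    """

    def __init__(self, known: Iterable[str]):
        self.known = set(known)
        lengths = {len(k) for k in self.known}
        if len(lengths) != 1:
            raise ValueError("known barcodes must share a single length")
        (self.length,) = lengths
        self._index: dict[str, set[str]] = {}
        for k in self.known:
            for neighbor in _deletion_neighborhood(k):
                self._index.setdefault(neighbor, set()).add(k)

    def correct(self, raw: str) -> str | None:
        """Return the assigned known barcode, or ``None`` (unassigned)."""
        if raw in self.known:
            return raw
        if abs(len(raw) - self.length) > 1:
            return None
        candidates: set[str] = set()
        for neighbor in _deletion_neighborhood(raw):
            candidates |= self._index.get(neighbor, set())
            if len(candidates) > 1:
                return None
        return next(iter(candidates)) if len(candidates) == 1 else None

    def classify(self, raw: str) -> tuple[str | None, str]:
        """Like :meth:`correct` but also name the failure category."""
        if raw in self.known:
            return raw, "assigned"
        if abs(len(raw) - self.length) > 1:
            return None, "bad_length"
        candidates: set[str] = set()
        for neighbor in _deletion_neighborhood(raw):
            candidates |= self._index.get(neighbor, set())
        if len(candidates) == 1:
            return next(iter(candidates)), "assigned"
        return None, "ambiguous" if candidates else "no_neighbor"


@dataclass
class BarcodeMap:
    """Barcode -> (library, clone, mutation) lookup with neutral flags.

    The neutral flag marks the neutral reference mutations used to zero
    the fitness scale in each assay.
    """

    table: pd.DataFrame  # index: barcode; columns: library_id, clone_id, mutation_id, neutral_flag

    REQUIRED = ("library_id", "clone_id", "mutation_id", "neutral_flag")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"barcode map missing columns: {missing}")
        if not self.table.index.is_unique:
            raise ValueError("barcodes must be unique")
        neutral_per_clone = self.table.groupby(
            ["library_id", "clone_id"], observed=True
        )["neutral_flag"].any()
        if not neutral_per_clone.all():
            bad = neutral_per_clone[~neutral_per_clone].index.tolist()
            raise ValueError(f"clones without a neutral reference mutation: {bad}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeMap":
        table = pd.read_csv(path, sep="\t", index_col="barcode")
        table["neutral_flag"] = table["neutral_flag"].astype(bool)
        return cls(table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="barcode")

    @property
    def barcodes(self) -> set[str]:
        return set(self.table.index)


@dataclass
class TallyResult:
    """Per-assay count matrices plus unassigned bookkeeping."""

    counts: dict[tuple[str, str], pd.DataFrame]  # (library, clone) -> barcode x timepoint
    unassigned: Counter = field(default_factory=Counter)

    @property
    def n_assigned(self) -> int:
        return int(sum(df.to_numpy().sum() for df in self.counts.values()))

    @property
    def n_unassigned(self) -> int:
        return int(sum(self.unassigned.values()))


def tally_counts(
    assignments: Iterable[tuple[str | None, int]],
    barcode_map: BarcodeMap,
    timepoints: Iterable[int],
    unassigned_categories: Iterable[str] | None = None,
) -> TallyResult:
    """Tally (barcode, timepoint) assignments into one count matrix per
    (library, clone) assay.

    ``assignments`` yields corrected barcodes (``None`` for unassigned
    reads).  Every non-``None`` barcode must be in the map and every
    timepoint must be declared in ``timepoints``.
    """
    timepoints = sorted(timepoints)
    tp_set = set(timepoints)
    table = barcode_map.table
    tallies: dict[tuple[str, int], int] = Counter()
    unassigned: Counter = Counter()
    for barcode, timepoint in assignments:
        if timepoint not in tp_set:
            raise ValueError(f"timepoint {timepoint} not declared in config")
        if barcode is None:
            unassigned["unassigned"] += 1
            continue
        if barcode not in barcode_map.barcodes:
            raise KeyError(f"assigned barcode {barcode!r} absent from map")
        tallies[(barcode, timepoint)] += 1
    counts: dict[tuple[str, str], pd.DataFrame] = {}
    for (library, clone), sub in table.groupby(
        ["library_id", "clone_id"], observed=True, sort=True
    ):
        frame = pd.DataFrame(0, index=sub.index, columns=timepoints, dtype=int)
        for barcode in sub.index:
            for tp in timepoints:
                hit = tallies.get((barcode, tp))
                if hit:
                    frame.at[barcode, tp] = hit
        counts[(library, clone)] = frame
    result = TallyResult(counts=counts, unassigned=unassigned)
    if unassigned_categories:
        for cat in unassigned_categories:
            result.unassigned.setdefault(cat, 0)
    return result


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a lineage x timepoint count matrix as TSV."""
    counts.to_csv(path, sep="\t", index_label="lineage")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a lineage x timepoint count matrix written by
    :func:`write_counts_tsv`; columns come back as integer timepoints."""
    df = pd.read_csv(path, sep="\t", index_col="lineage")
    df.columns = [int(c) for c in df.columns]
    return df
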