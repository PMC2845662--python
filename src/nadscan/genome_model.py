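"""Core genomic types, interval algebra, and tabular readers/writers.

Coordinates are 0-based half-open (``[start, end)``) everywhere in memory;
BED is the on-disk dialect for interval lists.  Chromosome names are matched
by exact string comparison — no ``chr`` prefix normalization is attempted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import __version__


class ValidationError(ValueError):
    """Raised when a record violates a structural invariant."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; carries the line number."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def size(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class ChromosomeMap:
    """Ordered chromosome-name -> length table."""

    def __init__(self, entries: Iterable[tuple[str, int]]):
        self._lengths: dict[str, int] = {}
        for name, length in entries:
            if name in self._lengths:
                raise ValidationError(f"duplicate chromosome name {name!r}")
            if length <= 0:
                raise ValidationError(
                    f"chromosome {name!r} has non-positive length {length}"
                )
            self._lengths[name] = int(length)
        if not self._lengths:
            raise ValidationError("chromosome map is empty")

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __len__(self) -> int:
        return len(self._lengths)

    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def items(self):
        return self._lengths.items()

    def validate_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self:
            raise ValidationError(f"interval on unknown chromosome {iv.chrom!r}")
        if iv.end > self.length(iv.chrom):
            raise ValidationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.length(iv.chrom)}"
            )


@dataclass
class ProbeSignalTrack:
    """Sorted probe midpoints with log2(naDNA/gDNA) values for one replicate."""

    chrom: str
    positions: np.ndarray
    values: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValidationError("positions and values must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValidationError(
                f"probe positions on {self.chrom} not strictly increasing"
            )

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass
class ReadSet:
    """Mapped read positions: (chrom, 0-based start, length) records."""

    records: list[tuple[str, int, int]]
    unique_only: bool = True

    def __post_init__(self) -> None:
        for i, (chrom, start, length) in enumerate(self.records):
            if start < 0 or length <= 0:
                raise ValidationError(
                    f"read record {i} ({chrom}, {start}, {length}) invalid: "
                    "require start >= 0 and length > 0"
                )

    def __len__(self) -> int:
        return len(self.records)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome (n, 2) arrays of [start, end) read spans, sorted."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, length in self.records:
            out.setdefault(chrom, []).append((start, start + length))
        return {
            c: np.array(sorted(spans), dtype=np.int64).reshape(-1, 2)
            for c, spans in out.items()
        }


@dataclass
class FeatureTable:
    """Annotated intervals carrying a class label and a feature name."""

    records: list[tuple[GenomicInterval, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for iv, class_label, _name in self.records:
            if not class_label:
                raise ValidationError(f"feature {iv} has empty class label")

    def __len__(self) -> int:
        return len(self.records)

    def class_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, label, _ in self.records:
            seen.setdefault(label)
        return list(seen)


DETECTION_LABELS = ("both", "acgh_only", "seq_only")


@dataclass
class NADRecord:
    """One fused domain of the final catalog."""

    interval: GenomicInterval
    detection: str
    read_count: int = 0
    significance_quantile: float | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.detection not in DETECTION_LABELS:
            raise ValidationError(
                f"detection label {self.detection!r} not in {DETECTION_LABELS}"
            )
        if self.read_count < 0:
            raise ValidationError("read_count must be >= 0")


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def union_merge(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge intervals into a disjoint, sorted set covering the same bases.

    Abutting intervals (``[0,10)`` + ``[10,20)``) are merged: the result
    covers exactly the union of input bases with the fewest records.
    """
    ivs = sorted(intervals)
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def intersect_sets(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-pair intersection of two internally disjoint interval sets."""
    a = sorted(a)
    b = sorted(b)
    _check_disjoint(a, "A")
    _check_disjoint(b, "B")
    out: list[GenomicInterval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        x, y = a[i], b[j]
        if x.chrom != y.chrom:
            if x.chrom < y.chrom:
                i += 1
            else:
                j += 1
            continue
        lo = max(x.start, y.start)
        hi = min(x.end, y.end)
        if lo < hi:
            out.append(GenomicInterval(x.chrom, lo, hi))
        if x.end <= y.end:
            i += 1
        else:
            j += 1
    return out


def total_span(intervals: Iterable[GenomicInterval]) -> int:
    """Total bases covered by a disjoint interval set."""
    return sum(iv.size for iv in intervals)


def _check_disjoint(sorted_ivs: Sequence[GenomicInterval], tag: str) -> None:
    for prev, nxt in zip(sorted_ivs, sorted_ivs[1:]):
        if prev.chrom == nxt.chrom and nxt.start < prev.end:
            raise ValidationError(
                f"interval set {tag} is not disjoint near "
                f"{prev.chrom}:{prev.start}-{prev.end}; apply union_merge first"
            )


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

_HEADER = f"# nadscan v{__version__}"


def _open_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line


def read_interval_table(path, fmt: str = "bed") -> FeatureTable:
    """Read a BED3/BED4+ (or equivalent TSV) file into a :class:`FeatureTable`.

    Column 4 (if present) is the feature name; column 5 (if present) is the
    class label, else the name doubles as the class label, else ``"."``.
    """
    if fmt not in ("bed", "tsv"):
        raise ValueError(f"unknown format {fmt!r}")
    records = []
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: coordinates {fields[1]!r}/{fields[2]!r} "
                "are not integers"
            ) from None
        if start >= end:
            raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
        name = fields[3] if len(fields) > 3 else "."
        label = fields[4] if len(fields) > 4 else (name if name != "." else ".")
        records.append((GenomicInterval(chrom, start, end), label, name))
    return FeatureTable(records)


def read_intervals(path, fmt: str = "bed") -> list[GenomicInterval]:
    """Read a BED file as bare intervals (names/labels dropped)."""
    return [iv for iv, _, _ in read_interval_table(path, fmt).records]


def write_interval_table(records, path, fmt: str = "bed") -> None:
    """Write intervals / feature records / NAD records as sorted BED.

    Accepts ``GenomicInterval``, ``(interval, class_label, name)`` tuples, or
    :class:`NADRecord` (name column becomes ``id|detection``).
    """
    if fmt not in ("bed", "tsv"):
        raise ValueError(f"unknown format {fmt!r}")
    rows = []
    for rec in records:
        if isinstance(rec, NADRecord):
            iv = rec.interval
            rows.append((iv.chrom, iv.start, iv.end, f"{rec.id}|{rec.detection}"))
        elif isinstance(rec, GenomicInterval):
            rows.append((rec.chrom, rec.start, rec.end, "."))
        else:
            iv, label, name = rec
            rows.append((iv.chrom, iv.start, iv.end, name, label))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_chromosome_map(path) -> ChromosomeMap:
    """Read a two-column (chrom, length) TSV."""
    entries = []
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        try:
            entries.append((fields[0], int(fields[1])))
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: length {fields[1]!r} is not an integer"
            ) from None
    return ChromosomeMap(entries)


def write_chromosome_map(chrom_map: ChromosomeMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for name, length in chrom_map.items():
            fh.write(f"{name}\t{length}\n")


def read_probe_tracks(path) -> dict[str, list[ProbeSignalTrack]]:
    """Read a (chrom, position, value, replicate) TSV.

    Returns ``{replicate_id: [ProbeSignalTrack per chromosome]}``.
    """
    rows: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns")
        chrom, pos_s, val_s, rep = fields[:4]
        try:
            pos, val = int(pos_s), float(val_s)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad position/value") from None
        rows.setdefault((rep, chrom), []).append((pos, val))
    out: dict[str, list[ProbeSignalTrack]] = {}
    for (rep, chrom), pv in sorted(rows.items()):
        pv.sort()
        positions = np.array([p for p, _ in pv], dtype=np.int64)
        values = np.array([v for _, v in pv], dtype=float)
        out.setdefault(rep, []).append(
            ProbeSignalTrack(chrom, positions, values, replicate_id=rep)
        )
    return out


def write_probe_tracks(tracks: Iterable[ProbeSignalTrack], path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for t in tracks:
            for pos, val in zip(t.positions, t.values):
                fh.write(f"{t.chrom}\t{pos}\t{val:.6g}\t{t.replicate_id}\n")


def read_reads(path, unique_only: bool = True) -> ReadSet:
    """Read a BED-like (chrom, start, end) file into a :class:`ReadSet`."""
    records = []
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad coordinates") from None
        if end <= start:
            raise ValidationError(f"{path}:{lineno}: read end {end} <= start {start}")
        records.append((fields[0], start, end - start))
    return ReadSet(records, unique_only=unique_only)


def write_reads(reads: ReadSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for chrom, start, length in sorted(reads.records):
            fh.write(f"{chrom}\t{start}\t{start + length}\n")


def ensure_dir(path) -> None:
    os.makedirs(path, exist_ok=True)
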