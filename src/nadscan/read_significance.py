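"""Empirical read-count significance for called domains.

Each domain's read count is ranked against the counts of 1,000 random
same-chromosome regions of the same size; the mid-rank quantile of the
observed count in that null distribution is reported together with its
quartile label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_model import ChromosomeMap, GenomicInterval, ReadSet, ValidationError
from .nad_assembly import NADCatalog

DEFAULT_N_RANDOM = 1000


@dataclass
class SignificanceResult:
    nad_id: str
    observed_count: int
    random_counts: np.ndarray
    quantile: float
    quartile_label: str


class _ReadIndex:
    """Sorted start/end arrays per chromosome for O(log n) overlap counting."""

    def __init__(self, reads: ReadSet):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, spans in reads.by_chrom().items():
            self._starts[chrom] = np.sort(spans[:, 0])
            self._ends[chrom] = np.sort(spans[:, 1])

    def count(self, chrom: str, start, end):
        """Reads overlapping [start, end) by >= 1 bp: start < end_q and
        end > start_q.  Vectorized over array-valued start/end."""
        if chrom not in self._starts:
            return np.zeros_like(np.asarray(start)) if np.ndim(start) else 0
        n_start_before = np.searchsorted(self._starts[chrom], end, side="left")
        n_end_before = np.searchsorted(self._ends[chrom], start, side="right")
        return n_start_before - n_end_before


def count_reads_in(reads: ReadSet, interval: GenomicInterval) -> int:
    """Number of reads overlapping the interval by >= 1 bp (half-open)."""
    return int(_ReadIndex(reads).count(interval.chrom, interval.start, interval.end))


def sample_random_regions(
    chrom_map: ChromosomeMap,
    chrom: str,
    size_bp: int,
    n: int = DEFAULT_N_RANDOM,
    seed: int | np.random.Generator = 0,
) -> list[GenomicInterval]:
    """Uniform same-chromosome regions of exactly ``size_bp`` (with
    replacement); deterministic for a fixed seed."""
    length = chrom_map.length(chrom)
    if size_bp > length:
        raise ValidationError(
            f"region size {size_bp} exceeds chromosome {chrom} length {length}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    starts = rng.integers(0, length - size_bp + 1, size=n)
    return [GenomicInterval(chrom, int(s), int(s) + size_bp) for s in starts]


def empirical_quantile(observed: int, random_counts) -> tuple[float, str]:
    """Mid-rank quantile of ``observed`` within ``random_counts`` and its
    quartile label (Q1..Q4)."""
    counts = np.asarray(random_counts)
    if counts.size == 0:
        raise ValidationError("random_counts must be non-empty")
    n = counts.size
    quantile = (np.sum(counts < observed) + 0.5 * np.sum(counts == observed)) / n
    quartile = int(np.ceil(4 * max(quantile, 1e-12)))
    return float(quantile), f"Q{min(quartile, 4)}"


def score_catalog(
    catalog: NADCatalog,
    reads: ReadSet,
    chrom_map: ChromosomeMap,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int = 0,
) -> list[SignificanceResult]:
    """Attach read counts and empirical quantiles to every catalog record.

    Mutates the records in place (read_count, significance_quantile) and
    returns the detailed per-domain results.
    """
    index = _ReadIndex(reads)
    rng = np.random.default_rng(seed)
    results = []
    for rec in catalog.records:
        iv = rec.interval
        observed = int(index.count(iv.chrom, iv.start, iv.end))
        length = chrom_map.length(iv.chrom)
        if iv.size > length:
            raise ValidationError(
                f"domain {rec.id} larger than its chromosome — bad input"
            )
        starts = rng.integers(0, length - iv.size + 1, size=n_random)
        random_counts = np.asarray(
            index.count(iv.chrom, starts, starts + iv.size)
        )
        quantile, label = empirical_quantile(observed, random_counts)
        rec.read_count = observed
        rec.significance_quantile = quantile
        results.append(
            SignificanceResult(rec.id, observed, random_counts, quantile, label)
        )
    return results
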