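"""Read-coverage domain calling.

Mapped reads are reduced to a presence/absence bit per fixed genomic segment
(default: 100-bp segments spaced every 1,000 bp), a running mean smooths the
bit track (default window: 100 points, i.e. 0.1 Mb of genome), and anchors
whose smoothed value strictly exceeds the per-chromosome percentile become
domain calls.  Borders are taken deterministically from the flagged anchor
runs; no manual curation step exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acgh_caller import CandidateDomainSet, _runs
from .genome_model import ChromosomeMap, GenomicInterval, ReadSet, ValidationError

DEFAULT_SEGMENT_LENGTH = 100
DEFAULT_SPACING = 1000
DEFAULT_WINDOW_POINTS = 100
DEFAULT_PERCENTILE = 98.0


@dataclass
class BinarySegmentTrack:
    """Presence/absence of reads per segment anchor on one chromosome.

    Bit ``k`` covers the segment ``[k*spacing, k*spacing + segment_length)``.
    """

    chrom: str
    bits: np.ndarray
    segment_length: int = DEFAULT_SEGMENT_LENGTH
    spacing: int = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.segment_length > self.spacing:
            raise ValidationError("segment_length must be <= spacing")


@dataclass
class SmoothedTrack:
    chrom: str
    values: np.ndarray
    segment_length: int = DEFAULT_SEGMENT_LENGTH
    spacing: int = DEFAULT_SPACING
    window_points: int = DEFAULT_WINDOW_POINTS


def n_segments(chrom_length: int, segment_length: int, spacing: int) -> int:
    """Number of whole segments fitting on a chromosome."""
    if chrom_length < segment_length:
        return 0
    return (chrom_length - segment_length) // spacing + 1


def binarize_reads(
    reads: ReadSet,
    chrom_map: ChromosomeMap,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    spacing: int = DEFAULT_SPACING,
) -> dict[str, BinarySegmentTrack]:
    """Build per-chromosome binary occupancy tracks.

    A segment is marked 1 iff at least one read overlaps it by >= 1 bp;
    read multiplicity is discarded.
    """
    if segment_length > spacing:
        raise ValidationError("segment_length must be <= spacing")
    tracks = {}
    for chrom, length in chrom_map.items():
        n = n_segments(length, segment_length, spacing)
        tracks[chrom] = BinarySegmentTrack(
            chrom, np.zeros(n, dtype=np.uint8), segment_length, spacing
        )
    for i, (chrom, start, length) in enumerate(reads.records):
        if chrom not in chrom_map:
            raise ValidationError(f"read {i} on unknown chromosome {chrom!r}")
        end = start + length
        if end > chrom_map.length(chrom):
            raise ValidationError(
                f"read {i} ({chrom}:{start}-{end}) extends past chromosome "
                f"end {chrom_map.length(chrom)}"
            )
        track = tracks[chrom]
        if track.bits.size == 0:
            continue
        # segment k overlaps [start, end) iff k*spacing < end and
        # k*spacing + segment_length > start
        k_lo = max(0, -(-(start - segment_length + 1) // spacing))
        k_hi = min(track.bits.size - 1, (end - 1) // spacing)
        if k_lo <= k_hi:
            track.bits[k_lo : k_hi + 1] = 1
    return tracks


def running_mean(
    track: BinarySegmentTrack,
    window_points: int = DEFAULT_WINDOW_POINTS,
    mode: str = "centered",
) -> SmoothedTrack:
    """Smooth the bit track with a truncated running mean.

    ``centered`` (default): value[i] = mean of bits over indices
    ``[i - w//2, i + w//2]`` clipped to the track; ``trailing``: mean over
    ``[i - w + 1, i]`` clipped.  ``window_points=1`` is the identity.
    """
    if window_points < 1:
        raise ValidationError("window_points must be >= 1")
    bits = track.bits
    if bits.size == 0:
        raise ValidationError(f"empty segment track on {track.chrom}")
    idx = np.arange(bits.size)
    if mode == "centered":
        half = window_points // 2
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half, bits.size - 1)
    elif mode == "trailing":
        lo = np.maximum(idx - window_points + 1, 0)
        hi = idx
    else:
        raise ValueError(f"unknown running-mean mode {mode!r}")
    csum = np.concatenate(([0.0], np.cumsum(bits.astype(float))))
    values = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return SmoothedTrack(
        track.chrom, values, track.segment_length, track.spacing, window_points
    )


def call_seq_domains(
    smoothed: dict[str, SmoothedTrack], percentile: float = DEFAULT_PERCENTILE
) -> CandidateDomainSet:
    """Threshold each chromosome at its own running-mean percentile.

    Anchors with value strictly above the per-chromosome threshold are
    flagged; a maximal run of flagged anchors ``k_first..k_last`` becomes
    ``[k_first*spacing, k_last*spacing + segment_length)``.
    """
    if not (0 < percentile < 100):
        raise ValidationError("percentile must lie in (0, 100)")
    intervals: list[GenomicInterval] = []
    thresholds = {}
    for chrom, track in smoothed.items():
        if track.values.size == 0:
            continue
        threshold = float(np.percentile(track.values, percentile))
        thresholds[chrom] = threshold
        flagged = track.values > threshold
        for first, last in _runs(flagged):
            intervals.append(
                GenomicInterval(
                    chrom,
                    first * track.spacing,
                    last * track.spacing + track.segment_length,
                )
            )
    intervals.sort()
    return CandidateDomainSet(
        platform="seq",
        intervals=intervals,
        threshold_value=float("nan") if not thresholds else max(thresholds.values()),
        threshold_percentile=percentile,
    )


def call_seq_nads(
    reads: ReadSet,
    chrom_map: ChromosomeMap,
    segment_length: int = DEFAULT_SEGMENT_LENGTH,
    spacing: int = DEFAULT_SPACING,
    window_points: int = DEFAULT_WINDOW_POINTS,
    percentile: float = DEFAULT_PERCENTILE,
    mode: str = "centered",
) -> CandidateDomainSet:
    """Convenience wrapper: binarize -> running mean -> percentile call."""
    tracks = binarize_reads(reads, chrom_map, segment_length, spacing)
    smoothed = {
        chrom: running_mean(t, window_points, mode)
        for chrom, t in tracks.items()
        if t.bits.size > 0
    }
    return call_seq_domains(smoothed, percentile)
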