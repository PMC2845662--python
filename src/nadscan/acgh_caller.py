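"""aCGH domain calling: running-window means, percentile thresholding,
replicate intersection.

Each replicate is processed independently: a probe-anchored running-window
mean (window truncated at chromosome ends), a genome-wide percentile cut on
those means, and maximal runs of strictly-above-threshold probes.  The final
candidate set is the base-pair intersection across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_model import (
    GenomicInterval,
    ProbeSignalTrack,
    ValidationError,
    intersect_sets,
    union_merge,
)

DEFAULT_WINDOW_BP = 100_000
DEFAULT_PERCENTILE = 85.0


@dataclass
class WindowedSignal:
    """Per-probe running-window means for one chromosome."""

    chrom: str
    anchor_positions: np.ndarray
    window_means: np.ndarray
    window_bp: int = DEFAULT_WINDOW_BP

    def __post_init__(self) -> None:
        self.anchor_positions = np.asarray(self.anchor_positions, dtype=np.int64)
        self.window_means = np.asarray(self.window_means, dtype=float)
        if self.anchor_positions.shape != self.window_means.shape:
            raise ValidationError("one window mean per anchor required")


@dataclass
class CandidateDomainSet:
    """Disjoint candidate domains from one platform."""

    platform: str  # "acgh" | "seq"
    intervals: list[GenomicInterval] = field(default_factory=list)
    threshold_value: float = float("nan")
    threshold_percentile: float = float("nan")


def window_mean_acgh(
    track: ProbeSignalTrack, window_bp: int = DEFAULT_WINDOW_BP
) -> WindowedSignal:
    """Probe-anchored running-window mean.

    For each probe *p* the mean is taken over all same-chromosome probes with
    ``|position - position_p| <= window_bp / 2``; the window is truncated at
    chromosome ends (no padding).
    """
    if len(track) == 0:
        raise ValidationError(f"empty probe track on {track.chrom}")
    if window_bp <= 0:
        raise ValidationError("window_bp must be > 0")
    values = track.values
    if np.any(~np.isfinite(values)):
        raise ValidationError(
            f"non-finite probe value on {track.chrom}; pre-filter the track"
        )
    pos = track.positions
    half = window_bp / 2.0
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    csum = np.concatenate(([0.0], np.cumsum(values)))
    means = (csum[hi] - csum[lo]) / (hi - lo)
    return WindowedSignal(track.chrom, pos, means, window_bp)


def threshold_relevant(
    windowed: list[WindowedSignal],
    percentile: float = DEFAULT_PERCENTILE,
    min_probes_per_region: int = 1,
) -> CandidateDomainSet:
    """Flag probes whose window mean strictly exceeds the replicate-wide
    percentile and collapse runs of flagged probes into intervals.

    The threshold is the linear-interpolation percentile of *all* window
    means of the replicate (genome-wide sample distribution).  A maximal run
    of consecutive flagged probes on one chromosome becomes the interval
    ``[first_probe_position, last_probe_position + 1)``.
    """
    if not (0 < percentile < 100):
        raise ValidationError("percentile must lie in (0, 100)")
    if not windowed:
        raise ValidationError("no windowed signal supplied")
    all_means = np.concatenate([w.window_means for w in windowed])
    threshold = float(np.percentile(all_means, percentile))
    intervals: list[GenomicInterval] = []
    for w in windowed:
        flagged = w.window_means > threshold
        for first, last in _runs(flagged):
            if last - first + 1 < min_probes_per_region:
                continue
            intervals.append(
                GenomicInterval(
                    w.chrom,
                    int(w.anchor_positions[first]),
                    int(w.anchor_positions[last]) + 1,
                )
            )
    return CandidateDomainSet(
        platform="acgh",
        intervals=union_merge(intervals),
        threshold_value=threshold,
        threshold_percentile=percentile,
    )


def _runs(mask: np.ndarray):
    """Yield (first_index, last_index) of maximal True runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        yield int(idx[s]), int(idx[e])


def call_acgh_nads(
    replicates: list[list[ProbeSignalTrack]],
    window_bp: int = DEFAULT_WINDOW_BP,
    percentile: float = DEFAULT_PERCENTILE,
    min_probes_per_region: int = 1,
) -> CandidateDomainSet:
    """Run the full aCGH caller: per-replicate window means + thresholding,
    then base-pair intersection of the per-replicate region sets.

    ``replicates`` is a list (one entry per replicate) of per-chromosome
    probe tracks.  All replicates must cover the same chromosome set.
    """
    if not replicates:
        raise ValidationError("at least one replicate required")
    chrom_sets = [frozenset(t.chrom for t in rep) for rep in replicates]
    if len(set(chrom_sets)) != 1:
        raise ValidationError(
            f"replicate chromosome sets differ: {sorted(set(chrom_sets))}"
        )
    per_rep: list[CandidateDomainSet] = []
    for rep in replicates:
        windowed = [window_mean_acgh(t, window_bp) for t in rep]
        per_rep.append(
            threshold_relevant(windowed, percentile, min_probes_per_region)
        )
    merged = per_rep[0].intervals
    for other in per_rep[1:]:
        merged = intersect_sets(merged, other.intervals)
    return CandidateDomainSet(
        platform="acgh",
        intervals=merged,
        threshold_value=per_rep[0].threshold_value,
        threshold_percentile=percentile,
    )
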