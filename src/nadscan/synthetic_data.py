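"""Simulators: genomes with planted domains, replicate aCGH tracks, read
sets, and clustered feature annotations.

Signal models are deliberately minimal two-level (background vs domain)
processes — exactly the structure the percentile-threshold callers assume.
All generators stream sub-seeds from one master seed and are bit-reproducible
for a fixed :class:`SimulationConfig`.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .genome_model import (
    ChromosomeMap,
    FeatureTable,
    GenomicInterval,
    ProbeSignalTrack,
    ReadSet,
    ValidationError,
)


@dataclass
class FeatureClassSpec:
    """One simulated annotation class."""

    label: str
    genome_density_per_mb: float
    nad_fold: float = 1.0
    length_bp: int = 1000
    cluster_size: int = 1


@dataclass
class SimulationConfig:
    chrom_lengths: list[int] = field(default_factory=lambda: [60_000_000] * 2)
    n_planted: int = 8
    size_log_range: tuple[int, int] = (800_000, 2_500_000)
    min_gap_bp: int = 500_000
    probe_spacing_median_bp: int = 6270
    acgh_effect_log2: float = 1.0
    acgh_noise_sd: float = 0.3
    n_replicates: int = 2
    n_reads: int = 150_000
    read_enrichment_fold: float = 5.0
    read_length_mean_bp: int = 217
    read_length_sd_bp: int = 20
    feature_classes: list[FeatureClassSpec] = field(
        default_factory=lambda: [
            FeatureClassSpec("satellite", 2.0, 10.0),
            FeatureClassSpec("gene", 10.0, 1.0),
        ]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.chrom_lengths):
            raise ValidationError("chromosome lengths must be positive")
        if self.size_log_range[0] <= 0 or (
            self.size_log_range[1] < self.size_log_range[0]
        ):
            raise ValidationError("bad planted size range")
        if self.min_gap_bp < 100_000:
            # keep planted truths un-joinable by the assembly's gap rule
            raise ValidationError("min_gap_bp must be >= 100000")

    def chrom_map(self) -> ChromosomeMap:
        return ChromosomeMap(
            (f"chr{i + 1}", length) for i, length in enumerate(self.chrom_lengths)
        )

    def _rng(self, stream: str) -> np.random.Generator:
        # crc32 gives a process-independent stream key (hash() is salted)
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(stream.encode())])
        )


def plant_nads(config: SimulationConfig) -> list[GenomicInterval]:
    """Place non-overlapping truth domains, log-uniform in size, uniform in
    position subject to a minimum pairwise gap."""
    rng = config._rng("plant")
    chrom_map = config.chrom_map()
    if config.n_planted == 0:
        return []
    lo, hi = config.size_log_range
    sizes = np.exp(rng.uniform(math.log(lo), math.log(hi), config.n_planted))
    sizes = sizes.astype(np.int64)
    if sizes.sum() >= 0.5 * chrom_map.total_bp():
        raise ValidationError("planted domains would cover >= 50% of the genome")
    names = chrom_map.names
    weights = np.array([chrom_map.length(c) for c in names], dtype=float)
    weights /= weights.sum()
    placed: list[GenomicInterval] = []
    for size in sizes:
        for _attempt in range(1000):
            chrom = names[rng.choice(len(names), p=weights)]
            length = chrom_map.length(chrom)
            if size >= length:
                continue
            start = int(rng.integers(0, length - size + 1))
            cand = GenomicInterval(chrom, start, start + int(size))
            pad = config.min_gap_bp
            if all(
                not (
                    p.chrom == cand.chrom
                    and cand.start - pad < p.end
                    and p.start < cand.end + pad
                )
                for p in placed
            ):
                placed.append(cand)
                break
        else:
            raise ValidationError(
                "could not place all planted domains; reduce n_planted or sizes"
            )
    return sorted(placed)


def _truth_by_chrom(truth: list[GenomicInterval]) -> dict[str, np.ndarray]:
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in truth:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: np.array(sorted(spans), dtype=np.int64).reshape(-1, 2)
        for c, spans in out.items()
    }


def _in_truth(positions: np.ndarray, spans: np.ndarray) -> np.ndarray:
    """Boolean mask: position falls inside a truth span (half-open)."""
    if spans.size == 0:
        return np.zeros(positions.shape, dtype=bool)
    i = np.searchsorted(spans[:, 0], positions, side="right") - 1
    valid = i >= 0
    inside = np.zeros(positions.shape, dtype=bool)
    inside[valid] = positions[valid] < spans[i[valid], 1]
    return inside


def simulate_acgh(
    truth: list[GenomicInterval], config: SimulationConfig
) -> list[list[ProbeSignalTrack]]:
    """Replicate aCGH tracks: probe gaps i.i.d. exponential with the target
    median spacing; value = effect * 1[probe in truth] + N(0, noise_sd),
    noise independent across replicates.

    Returns one list of per-chromosome tracks per replicate; probe positions
    are shared across replicates (one array design)."""
    rng = config._rng("acgh")
    chrom_map = config.chrom_map()
    spans = _truth_by_chrom(truth)
    scale = config.probe_spacing_median_bp / math.log(2)
    design: dict[str, np.ndarray] = {}
    for chrom, length in chrom_map.items():
        n_guess = int(length / config.probe_spacing_median_bp * 1.8) + 16
        gaps = rng.exponential(scale, n_guess)
        pos = np.unique(np.cumsum(gaps).astype(np.int64))
        pos = pos[(pos > 0) & (pos < length)]
        design[chrom] = pos
    replicates = []
    for rep in range(config.n_replicates):
        tracks = []
        for chrom in chrom_map.names:
            pos = design[chrom]
            signal = np.where(
                _in_truth(pos, spans.get(chrom, np.empty((0, 2), dtype=np.int64))),
                config.acgh_effect_log2,
                0.0,
            )
            noise = (
                rng.normal(0.0, config.acgh_noise_sd, pos.size)
                if config.acgh_noise_sd > 0
                else 0.0
            )
            tracks.append(
                ProbeSignalTrack(chrom, pos, signal + noise, f"rep{rep + 1}")
            )
        replicates.append(tracks)
    return replicates


def probe_design(replicates: list[list[ProbeSignalTrack]]) -> dict[str, np.ndarray]:
    """Probe positions per chromosome from the first replicate's tracks."""
    return {t.chrom: t.positions for t in replicates[0]}


def simulate_reads(
    truth: list[GenomicInterval], config: SimulationConfig
) -> ReadSet:
    """Reads with a two-level start density (background 1, domains
    ``read_enrichment_fold``) and Gaussian lengths (floor 30 bp)."""
    if config.n_reads <= 0:
        raise ValidationError("n_reads must be > 0")
    rng = config._rng("reads")
    chrom_map = config.chrom_map()
    spans = _truth_by_chrom(truth)
    fold = config.read_enrichment_fold
    # piecewise-constant start density segments: (chrom, start, end, weight)
    segments: list[tuple[str, int, int, float]] = []
    for chrom, length in chrom_map.items():
        cursor = 0
        for s, e in spans.get(chrom, np.empty((0, 2), dtype=np.int64)):
            if cursor < s:
                segments.append((chrom, cursor, int(s), 1.0))
            segments.append((chrom, int(s), int(e), fold))
            cursor = int(e)
        if cursor < length:
            segments.append((chrom, cursor, length, 1.0))
    masses = np.array([(e - s) * w for _, s, e, w in segments])
    probs = masses / masses.sum()
    choices = rng.choice(len(segments), size=config.n_reads, p=probs)
    offsets = rng.random(config.n_reads)
    lengths = np.maximum(
        rng.normal(config.read_length_mean_bp, config.read_length_sd_bp,
                   config.n_reads),
        30,
    ).astype(np.int64)
    records = []
    for k, off, read_len in zip(choices, offsets, lengths):
        chrom, s, e, _w = segments[k]
        start = s + int(off * (e - s))
        start = min(start, chrom_map.length(chrom) - int(read_len))
        records.append((chrom, max(start, 0), int(read_len)))
    return ReadSet(records, unique_only=True)


def simulate_features(
    truth: list[GenomicInterval], config: SimulationConfig
) -> FeatureTable:
    """Poisson-placed features per class, with density multiplied by
    ``nad_fold`` inside truth domains; ``cluster_size > 1`` lays features in
    tandem runs to mimic gene clusters."""
    rng = config._rng("features")
    chrom_map = config.chrom_map()
    spans = _truth_by_chrom(truth)
    records: list[tuple[GenomicInterval, str, str]] = []
    for spec in config.feature_classes:
        if spec.genome_density_per_mb < 0:
            raise ValidationError(f"negative density for class {spec.label!r}")
        if spec.genome_density_per_mb == 0:
            continue
        counter = 0
        for chrom, length in chrom_map.items():
            chrom_spans = spans.get(chrom, np.empty((0, 2), dtype=np.int64))
            segs: list[tuple[int, int, float]] = []
            cursor = 0
            for s, e in chrom_spans:
                if cursor < s:
                    segs.append((cursor, int(s), 1.0))
                segs.append((int(s), int(e), spec.nad_fold))
                cursor = int(e)
            if cursor < length:
                segs.append((cursor, length, 1.0))
            for s, e, mult in segs:
                lam = spec.genome_density_per_mb * mult * (e - s) / 1e6
                n_units = rng.poisson(lam / max(spec.cluster_size, 1))
                for _ in range(n_units):
                    anchor = int(rng.integers(s, e))
                    for j in range(max(spec.cluster_size, 1)):
                        f_start = anchor + j * (spec.length_bp + 100)
                        f_end = f_start + spec.length_bp
                        if f_end > length:
                            break
                        counter += 1
                        records.append(
                            (
                                GenomicInterval(chrom, f_start, f_end),
                                spec.label,
                                f"{spec.label}_{chrom}_{counter}",
                            )
                        )
    records.sort(key=lambda r: r[0])
    return FeatureTable(records)
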