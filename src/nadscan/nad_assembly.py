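"""Fusion of aCGH and read-coverage candidate domains into the final catalog.

Overlapping candidates from the two platforms are clustered (single linkage,
>= 1 bp overlap) and each cluster yields one fused domain.  Cluster borders
follow the aCGH extremes where array probes exist near the merged border;
where probes are absent the sequencing limits win.  Adjacent domains closer
than a gap threshold are then joined, detection-source labels assigned, and
catalog summary statistics computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .acgh_caller import CandidateDomainSet
from .genome_model import (
    GenomicInterval,
    NADRecord,
    ValidationError,
    total_span,
    union_merge,
)

DEFAULT_JOIN_GAP_BP = 100_000
#: twice the array's median probe spacing — the scale at which a probe
#: "should" exist if the region were covered by the design
DEFAULT_PROBE_TOLERANCE_BP = 2 * 6270


@dataclass
class NADCatalog:
    records: list[NADRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ivs = [r.interval for r in self.records]
        if ivs != sorted(ivs):
            raise ValidationError("catalog records must be sorted by (chrom, start)")
        for a, b in zip(ivs, ivs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValidationError(
                    f"catalog intervals overlap near {a.chrom}:{a.start}-{a.end}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def intervals(self) -> list[GenomicInterval]:
        return [r.interval for r in self.records]

    def detection_counts(self) -> dict[str, int]:
        counts = {"both": 0, "acgh_only": 0, "seq_only": 0}
        for r in self.records:
            counts[r.detection] += 1
        return counts


@dataclass
class CatalogStats:
    n_domains: int
    total_bp: int
    median_size_bp: float | None
    size_histogram: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_domains": self.n_domains,
                "total_bp": self.total_bp,
                "median_size_bp": self.median_size_bp,
                "size_histogram": self.size_histogram,
            },
            indent=2,
        )


def fuse_cross_platform(
    acgh: CandidateDomainSet,
    seq: CandidateDomainSet,
    probes: dict[str, np.ndarray],
    probe_tolerance_bp: int = DEFAULT_PROBE_TOLERANCE_BP,
) -> list[tuple[GenomicInterval, str]]:
    """Fuse overlapping cross-platform candidates into single domains.

    Returns ``(interval, detection_label)`` pairs.  For each cluster border,
    the aCGH extreme is used when the cluster contains aCGH members and a
    probe lies within ``probe_tolerance_bp`` of the overall cluster extreme
    (the array covered that border region); otherwise the overall extreme —
    which then comes from the sequencing call — is kept.
    """
    for chrom, pos in probes.items():
        arr = np.asarray(pos)
        if arr.size and np.any(np.diff(arr) < 0):
            raise ValidationError(f"probe positions on {chrom} are unsorted")
    tagged = [(iv, "acgh") for iv in acgh.intervals] + [
        (iv, "seq") for iv in seq.intervals
    ]
    tagged.sort(key=lambda t: t[0])
    fused: list[tuple[GenomicInterval, str]] = []
    cluster: list[tuple[GenomicInterval, str]] = []
    for item in tagged:
        if cluster and (
            item[0].chrom != cluster[-1][0].chrom
            or item[0].start >= max(iv.end for iv, _ in cluster)
        ):
            fused.append(_resolve_cluster(cluster, probes, probe_tolerance_bp))
            cluster = []
        cluster.append(item)
    if cluster:
        fused.append(_resolve_cluster(cluster, probes, probe_tolerance_bp))
    return fused


def _probe_near(probes, chrom: str, position: int, tol: int) -> bool:
    pos = np.asarray(probes.get(chrom, ()))
    if pos.size == 0:
        return False
    i = np.searchsorted(pos, position)
    best = np.inf
    if i < pos.size:
        best = min(best, abs(int(pos[i]) - position))
    if i > 0:
        best = min(best, abs(int(pos[i - 1]) - position))
    return best <= tol


def _resolve_cluster(cluster, probes, tol) -> tuple[GenomicInterval, str]:
    chrom = cluster[0][0].chrom
    platforms = {p for _, p in cluster}
    lo_all = min(iv.start for iv, _ in cluster)
    hi_all = max(iv.end for iv, _ in cluster)
    if platforms == {"acgh", "seq"}:
        label = "both"
        lo_acgh = min(iv.start for iv, p in cluster if p == "acgh")
        hi_acgh = max(iv.end for iv, p in cluster if p == "acgh")
        lo = lo_acgh if _probe_near(probes, chrom, lo_all, tol) else lo_all
        hi = hi_acgh if _probe_near(probes, chrom, hi_all, tol) else hi_all
    else:
        label = "acgh_only" if platforms == {"acgh"} else "seq_only"
        lo, hi = lo_all, hi_all
    return GenomicInterval(chrom, lo, hi), label


def join_adjacent(
    domains: list[tuple[GenomicInterval, str]],
    max_gap_bp: int = DEFAULT_JOIN_GAP_BP,
) -> list[tuple[GenomicInterval, str]]:
    """Join same-chromosome neighbours separated by a gap strictly below
    ``max_gap_bp``; labels of joined members combine to ``both`` when mixed.

    A single left-to-right sweep reaches the fixed point because joining can
    only extend the right edge of the current domain.
    """
    ordered = sorted(domains, key=lambda t: t[0])
    out: list[tuple[GenomicInterval, str]] = []
    for iv, label in ordered:
        if out:
            prev, prev_label = out[-1]
            if prev.chrom == iv.chrom and iv.start - prev.end < max_gap_bp:
                merged_label = prev_label if prev_label == label else "both"
                out[-1] = (
                    GenomicInterval(prev.chrom, prev.start, max(prev.end, iv.end)),
                    merged_label,
                )
                continue
        out.append((iv, label))
    return out


def label_detection(
    fused: list[tuple[GenomicInterval, str]],
    acgh: CandidateDomainSet,
    seq: CandidateDomainSet,
) -> list[NADRecord]:
    """Assign final detection labels by overlap against the platform sets."""
    records = []
    for i, (iv, _label) in enumerate(sorted(fused, key=lambda t: t[0])):
        hits_acgh = any(iv.overlaps(a) for a in acgh.intervals)
        hits_seq = any(iv.overlaps(s) for s in seq.intervals)
        if hits_acgh and hits_seq:
            detection = "both"
        elif hits_acgh:
            detection = "acgh_only"
        elif hits_seq:
            detection = "seq_only"
        else:
            raise ValidationError(
                f"domain {iv.chrom}:{iv.start}-{iv.end} overlaps neither "
                "platform set — assembly is inconsistent"
            )
        records.append(
            NADRecord(interval=iv, detection=detection, id=f"NAD{i + 1:03d}")
        )
    return records


def assemble_catalog(
    acgh: CandidateDomainSet,
    seq: CandidateDomainSet,
    probes: dict[str, np.ndarray],
    probe_tolerance_bp: int = DEFAULT_PROBE_TOLERANCE_BP,
    max_gap_bp: int = DEFAULT_JOIN_GAP_BP,
) -> NADCatalog:
    """Full assembly: fuse -> join -> label."""
    fused = fuse_cross_platform(acgh, seq, probes, probe_tolerance_bp)
    joined = join_adjacent(fused, max_gap_bp)
    records = label_detection(joined, acgh, seq)
    return NADCatalog(
        records=records,
        provenance={
            "acgh_percentile": acgh.threshold_percentile,
            "seq_percentile": seq.threshold_percentile,
            "probe_tolerance_bp": probe_tolerance_bp,
            "join_gap_bp": max_gap_bp,
        },
    )


# histogram over the catalog's size range, log-spaced
_HIST_RANGE_BP = (100_000, 10_000_000)


def lower_median(values) -> float:
    """Median using the lower of the two central order statistics for even n."""
    v = sorted(values)
    if not v:
        raise ValidationError("median of empty sequence")
    return float(v[(len(v) - 1) // 2])


def catalog_stats(catalog: NADCatalog, n_bins: int = 20) -> CatalogStats:
    sizes = [r.interval.size for r in catalog.records]
    if not sizes:
        return CatalogStats(0, 0, None, {"edges": [], "counts": []})
    edges = np.geomspace(
        min(_HIST_RANGE_BP[0], min(sizes)),
        max(_HIST_RANGE_BP[1], max(sizes)),
        n_bins + 1,
    )
    counts, _ = np.histogram(sizes, bins=edges)
    # independent check against interval algebra
    assert sum(sizes) == total_span(union_merge(catalog.intervals()))
    return CatalogStats(
        n_domains=len(sizes),
        total_bp=int(sum(sizes)),
        median_size_bp=lower_median(sizes),
        size_histogram={"edges": edges.tolist(), "counts": counts.tolist()},
    )


def write_catalog_tsv(catalog: NADCatalog, path) -> None:
    """Sidecar TSV: id, chrom, start, end, size, detection, read_count,
    significance_quantile."""
    with open(path, "w") as fh:
        fh.write(
            "id\tchrom\tstart\tend\tsize\tdetection\tread_count\t"
            "significance_quantile\n"
        )
        for r in catalog.records:
            q = "" if r.significance_quantile is None else f"{r.significance_quantile:.4f}"
            fh.write(
                f"{r.id}\t{r.interval.chrom}\t{r.interval.start}\t"
                f"{r.interval.end}\t{r.interval.size}\t{r.detection}\t"
                f"{r.read_count}\t{q}\n"
            )
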