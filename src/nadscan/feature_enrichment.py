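"""Feature-class enrichment statistics of a domain catalog versus the genome.

Per feature class: 2x2 Fisher exact tests (one- or two-sided), fold density
(per-bp density in domains over genome-wide density, genome *including*
domain bases), and per-domain density t-tests against the genome mean with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_model import (
    ChromosomeMap,
    FeatureTable,
    GenomicInterval,
    ValidationError,
)


@dataclass
class EnrichmentRow:
    class_label: str
    count_in_nads: int
    count_genome: int
    bp_in_nads: int
    bp_genome: int
    fold_density: float
    odds_ratio: float
    p_value: float
    p_adjusted: float
    alternative: str


@dataclass
class DensityTestRow:
    feature_name: str
    per_nad_densities: np.ndarray
    genome_mean: float
    t_statistic: float
    p_value: float
    p_adjusted: float


def _domain_lookup(domains: list[GenomicInterval]):
    """Per-chromosome sorted (starts, ends) arrays for membership queries;
    requires a disjoint sorted domain set."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in domains:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out[chrom] = (
            np.array([i.start for i in ivs], dtype=np.int64),
            np.array([i.end for i in ivs], dtype=np.int64),
        )
    return out


def count_overlaps(
    features: FeatureTable,
    domains: list[GenomicInterval],
    chrom_map: ChromosomeMap | None = None,
    mode: str = "midpoint",
) -> dict[str, tuple[int, int]]:
    """Per-class (count_in_domains, count_genome) feature counts.

    ``midpoint`` mode (default): a feature is inside iff its midpoint falls in
    a domain, so every feature is counted exactly once.  ``any_overlap`` mode:
    >= 1 bp of overlap suffices.
    """
    if mode not in ("midpoint", "any_overlap"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    lookup = _domain_lookup(domains)
    counts: dict[str, list[int]] = {}
    for iv, label, _name in features.records:
        if chrom_map is not None and iv.chrom not in chrom_map:
            raise ValidationError(f"feature on unknown chromosome {iv.chrom!r}")
        inside = False
        if iv.chrom in lookup:
            starts, ends = lookup[iv.chrom]
            if mode == "midpoint":
                mid = iv.midpoint()
                i = np.searchsorted(starts, mid, side="right") - 1
                inside = i >= 0 and mid < ends[i]
            else:
                i = np.searchsorted(starts, iv.end, side="left") - 1
                inside = i >= 0 and iv.start < ends[i]
        c = counts.setdefault(label, [0, 0])
        c[1] += 1
        if inside:
            c[0] += 1
    return {label: (c[0], c[1]) for label, c in counts.items()}


def fisher_enrichment(
    count_in: int,
    count_genome: int,
    universe_in: int,
    universe_total: int,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Fisher exact test of the 2x2 table

        [[class in domains,     class outside    ],
         [non-class in domains, non-class outside]]

    Returns (odds_ratio, p_value).  The odds ratio is the sample OR with a
    Haldane 0.5 correction when any cell is zero; degenerate margins give
    p = 1 and OR = nan.
    """
    a = count_in
    b = count_genome - count_in
    c = universe_in - count_in
    d = (universe_total - count_genome) - c
    if min(a, b, c, d) < 0:
        raise ValidationError(
            f"inconsistent 2x2 table ({a}, {b}, {c}, {d}); check the universe"
        )
    if alternative not in ("greater", "less", "two-sided", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    alt = "two-sided" if alternative == "two_sided" else alternative
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return float("nan"), 1.0
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alt)
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def fold_density(
    count_in: int, bp_in: int, count_genome: int, bp_genome: int
) -> float:
    """Per-bp feature density in domains over the genome-wide density
    (the genome background includes the domain bases)."""
    if bp_in <= 0 or bp_genome <= 0:
        raise ValidationError("bp_in and bp_genome must be > 0")
    if count_genome == 0:
        return float("nan")
    return (count_in / bp_in) / (count_genome / bp_genome)


def density_ttest(per_nad_values, genome_mean: float) -> tuple[float, float]:
    """One-sample two-sided t-test of per-domain densities against the
    genome mean.  Zero-variance inputs: p = 1 if the common value equals the
    genome mean, else p = 0 (degenerate, flagged by t = inf)."""
    values = np.asarray(per_nad_values, dtype=float)
    if values.size < 2:
        raise ValidationError("need >= 2 domain densities for a t-test")
    if np.ptp(values) == 0:
        if values[0] == genome_mean:
            return 0.0, 1.0
        return float("inf") if values[0] > genome_mean else float("-inf"), 0.0
    t, p = stats.ttest_1samp(values, genome_mean)
    return float(t), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank downwards
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def dedupe_by_name(features: FeatureTable) -> FeatureTable:
    """Drop duplicate feature records sharing a name (first occurrence kept)."""
    seen: set[str] = set()
    kept = []
    for rec in features.records:
        if rec[2] in seen:
            continue
        seen.add(rec[2])
        kept.append(rec)
    return FeatureTable(kept)


def enrichment_table(
    features: FeatureTable,
    domains: list[GenomicInterval],
    chrom_map: ChromosomeMap,
    alternative: str = "greater",
    mode: str = "midpoint",
) -> list[EnrichmentRow]:
    """One EnrichmentRow per feature class, BH-adjusted across classes."""
    per_class = count_overlaps(features, domains, chrom_map, mode)
    bp_in = sum(iv.size for iv in domains)
    bp_genome = chrom_map.total_bp()
    universe_in = sum(c_in for c_in, _ in per_class.values())
    universe_total = sum(c_gen for _, c_gen in per_class.values())
    rows = []
    for label, (c_in, c_gen) in sorted(per_class.items()):
        odds, p = fisher_enrichment(
            c_in, c_gen, universe_in, universe_total, alternative
        )
        rows.append(
            EnrichmentRow(
                class_label=label,
                count_in_nads=c_in,
                count_genome=c_gen,
                bp_in_nads=bp_in,
                bp_genome=bp_genome,
                fold_density=fold_density(c_in, bp_in, c_gen, bp_genome),
                odds_ratio=odds,
                p_value=p,
                p_adjusted=float("nan"),
                alternative=alternative,
            )
        )
    adjusted = bh_adjust([r.p_value for r in rows])
    for row, p_adj in zip(rows, adjusted):
        row.p_adjusted = float(p_adj)
    return rows


def write_enrichment_tsv(rows: list[EnrichmentRow], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "class\tcount_in_nads\tcount_genome\tbp_in_nads\tbp_genome\t"
            "fold_density\todds_ratio\tp_value\tp_adjusted\talternative\n"
        )
        for r in rows:
            fh.write(
                f"{r.class_label}\t{r.count_in_nads}\t{r.count_genome}\t"
                f"{r.bp_in_nads}\t{r.bp_genome}\t{r.fold_density:.6g}\t"
                f"{r.odds_ratio:.6g}\t{r.p_value:.6g}\t{r.p_adjusted:.6g}\t"
                f"{r.alternative}\n"
            )
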