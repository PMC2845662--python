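"""Pipeline orchestration: simulate -> call -> assemble -> score -> enrich.

Every stage writes plain BED/TSV/JSON files into the run directory so any
stage can be rerun in isolation, and a manifest records the configuration
hash, seeds, package version and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict

import numpy as np

from . import __version__
from .acgh_caller import call_acgh_nads
from .feature_enrichment import enrichment_table, write_enrichment_tsv
from .genome_model import (
    ChromosomeMap,
    GenomicInterval,
    ValidationError,
    ensure_dir,
    intersect_sets,
    read_chromosome_map,
    read_interval_table,
    read_intervals,
    read_probe_tracks,
    read_reads,
    total_span,
    union_merge,
    write_chromosome_map,
    write_interval_table,
    write_probe_tracks,
    write_reads,
)
from .nad_assembly import (
    assemble_catalog,
    catalog_stats,
    write_catalog_tsv,
)
from .read_significance import score_catalog
from .seq_caller import call_seq_nads
from .synthetic_data import (
    FeatureClassSpec,
    SimulationConfig,
    plant_nads,
    probe_design,
    simulate_acgh,
    simulate_features,
    simulate_reads,
)

log = logging.getLogger("nadscan")

# section -> allowed keys; unknown sections or keys are rejected up front
_SCHEMA: dict[str, set[str]] = {
    "run": {"outdir", "seed", "log_level"},
    "simulation": {
        "chrom_lengths", "n_planted", "size_log_range", "min_gap_bp",
        "probe_spacing_median_bp", "acgh_effect_log2", "acgh_noise_sd",
        "n_replicates", "n_reads", "read_enrichment_fold",
        "read_length_mean_bp", "read_length_sd_bp", "feature_classes", "seed",
    },
    "inputs": {"chrom_sizes", "probe_signal", "reads", "features"},
    "acgh": {"window_bp", "percentile", "min_probes_per_region"},
    "seq": {
        "segment_length", "spacing", "window_points", "percentile",
        "unique_only", "mode",
    },
    "assembly": {"probe_tolerance_bp", "join_gap_bp"},
    "significance": {"n_random", "seed"},
    "enrichment": {"alternative", "mode"},
}


def validate_config(config: dict) -> dict:
    """Schema-check a nested pipeline config; returns the config unchanged."""
    if not isinstance(config, dict):
        raise ValidationError("pipeline config must be a mapping")
    for section, content in config.items():
        if section not in _SCHEMA:
            raise ValidationError(f"unknown config section {section!r}")
        if not isinstance(content, dict):
            raise ValidationError(f"config section {section!r} must be a mapping")
        unknown = set(content) - _SCHEMA[section]
        if unknown:
            raise ValidationError(
                f"unknown keys in section {section!r}: {sorted(unknown)}"
            )
    if "simulation" not in config and "inputs" not in config:
        raise ValidationError("config needs a 'simulation' or an 'inputs' section")
    return config


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _sim_config(section: dict, default_seed: int) -> SimulationConfig:
    kwargs = dict(section)
    if "feature_classes" in kwargs:
        kwargs["feature_classes"] = [
            FeatureClassSpec(**fc) if isinstance(fc, dict) else fc
            for fc in kwargs["feature_classes"]
        ]
    if "size_log_range" in kwargs:
        kwargs["size_log_range"] = tuple(kwargs["size_log_range"])
    kwargs.setdefault("seed", default_seed)
    return SimulationConfig(**kwargs)


def run_pipeline(config: dict, outdir: str | None = None) -> dict:
    """Run every stage; returns a result dict (catalog, stats, manifest...).

    ``outdir`` overrides ``config['run']['outdir']``; files are only written
    when an output directory is known.
    """
    validate_config(config)
    run_cfg = config.get("run", {})
    outdir = outdir or run_cfg.get("outdir")
    seed = int(run_cfg.get("seed", 0))
    if outdir:
        ensure_dir(outdir)

    def path(name: str) -> str:
        return os.path.join(outdir, name)

    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": {},
    }

    truth: list[GenomicInterval] | None = None
    features = None
    if "simulation" in config:
        sim = _sim_config(config["simulation"], seed)
        chrom_map = sim.chrom_map()
        truth = plant_nads(sim)
        replicates = simulate_acgh(truth, sim)
        reads = simulate_reads(truth, sim)
        features = simulate_features(truth, sim)
        log.info("simulate: %d truth domains, %d reads, %d features",
                 len(truth), len(reads), len(features))
        if outdir:
            write_chromosome_map(chrom_map, path("chrom_sizes.tsv"))
            write_interval_table(truth, path("truth.bed"))
            write_probe_tracks(
                [t for rep in replicates for t in rep], path("probes.tsv")
            )
            write_reads(reads, path("reads.bed"))
            write_interval_table(features.records, path("features.bed"))
        manifest["stages"]["simulate"] = {
            "truth_domains": len(truth),
            "reads": len(reads),
            "features": len(features),
        }
    else:
        inputs = config["inputs"]
        chrom_map = read_chromosome_map(inputs["chrom_sizes"])
        rep_map = read_probe_tracks(inputs["probe_signal"])
        replicates = [rep_map[rep] for rep in sorted(rep_map)]
        reads = read_reads(
            inputs["reads"],
            unique_only=config.get("seq", {}).get("unique_only", True),
        )
        if "features" in inputs:
            features = read_interval_table(inputs["features"])

    acgh_cfg = config.get("acgh", {})
    acgh_set = call_acgh_nads(
        replicates,
        window_bp=acgh_cfg.get("window_bp", 100_000),
        percentile=acgh_cfg.get("percentile", 85.0),
        min_probes_per_region=acgh_cfg.get("min_probes_per_region", 1),
    )
    log.info("acgh: %d candidate regions (threshold %.4f)",
             len(acgh_set.intervals), acgh_set.threshold_value)
    manifest["stages"]["acgh"] = {
        "regions": len(acgh_set.intervals),
        "threshold": acgh_set.threshold_value,
    }

    seq_cfg = config.get("seq", {})
    seq_set = call_seq_nads(
        reads,
        chrom_map,
        segment_length=seq_cfg.get("segment_length", 100),
        spacing=seq_cfg.get("spacing", 1000),
        window_points=seq_cfg.get("window_points", 100),
        percentile=seq_cfg.get("percentile", 98.0),
        mode=seq_cfg.get("mode", "centered"),
    )
    log.info("seq: %d candidate regions", len(seq_set.intervals))
    manifest["stages"]["seq"] = {"regions": len(seq_set.intervals)}

    asm_cfg = config.get("assembly", {})
    catalog = assemble_catalog(
        acgh_set,
        seq_set,
        probes={t.chrom: t.positions for t in replicates[0]},
        probe_tolerance_bp=asm_cfg.get("probe_tolerance_bp", 2 * 6270),
        max_gap_bp=asm_cfg.get("join_gap_bp", 100_000),
    )
    log.info("assemble: %d domains (%s)", len(catalog), catalog.detection_counts())
    manifest["stages"]["assemble"] = {
        "domains": len(catalog),
        "detection": catalog.detection_counts(),
    }

    sig_cfg = config.get("significance", {})
    score_catalog(
        catalog,
        reads,
        chrom_map,
        n_random=sig_cfg.get("n_random", 1000),
        seed=int(sig_cfg.get("seed", seed)),
    )
    stats = catalog_stats(catalog)
    manifest["stages"]["stats"] = {
        "n_domains": stats.n_domains,
        "total_bp": stats.total_bp,
        "median_size_bp": stats.median_size_bp,
    }

    enrichment = None
    if features is not None and len(features) and len(catalog):
        enr_cfg = config.get("enrichment", {})
        enrichment = enrichment_table(
            features,
            catalog.intervals(),
            chrom_map,
            alternative=enr_cfg.get("alternative", "greater"),
            mode=enr_cfg.get("mode", "midpoint"),
        )
        manifest["stages"]["enrich"] = {"classes": len(enrichment)}

    if truth is not None:
        manifest["truth_recovery"] = truth_recovery(
            truth, catalog.intervals(), chrom_map
        )

    if outdir:
        write_interval_table(catalog.records, path("nads.bed"))
        write_catalog_tsv(catalog, path("nads.tsv"))
        with open(path("stats.json"), "w") as fh:
            fh.write(stats.to_json())
        if enrichment is not None:
            write_enrichment_tsv(enrichment, path("enrichment.tsv"))
        with open(path("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return {
        "chrom_map": chrom_map,
        "truth": truth,
        "acgh": acgh_set,
        "seq": seq_set,
        "catalog": catalog,
        "stats": stats,
        "enrichment": enrichment,
        "manifest": manifest,
    }


def truth_recovery(
    truth: list[GenomicInterval],
    called: list[GenomicInterval],
    chrom_map: ChromosomeMap,
) -> dict:
    """Planted-base recovery and background false-positive fractions."""
    truth_u = union_merge(truth)
    called_u = union_merge(called)
    truth_bp = total_span(truth_u)
    called_bp = total_span(called_u)
    shared_bp = total_span(intersect_sets(truth_u, called_u))
    background_bp = chrom_map.total_bp() - truth_bp
    return {
        "truth_bp": truth_bp,
        "called_bp": called_bp,
        "recovered_fraction": shared_bp / truth_bp if truth_bp else float("nan"),
        "false_positive_fraction": (
            (called_bp - shared_bp) / background_bp if background_bp else 0.0
        ),
    }


def compare_catalogs(
    a: list[GenomicInterval], b: list[GenomicInterval]
) -> dict:
    """Symmetric base-overlap statistics between two catalogs."""
    a_u = union_merge(a)
    b_u = union_merge(b)
    shared = total_span(intersect_sets(a_u, b_u))
    union_bp = total_span(union_merge(a_u + b_u))
    from .nad_assembly import lower_median

    reciprocal = []
    for iv in a_u:
        ov = total_span(intersect_sets([iv], b_u))
        reciprocal.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "overlap_fraction": ov / iv.size,
            }
        )
    return {
        "shared_bp": shared,
        "jaccard": shared / union_bp if union_bp else float("nan"),
        "a_total_bp": total_span(a_u),
        "b_total_bp": total_span(b_u),
        "a_median_size_bp": lower_median([iv.size for iv in a_u]) if a_u else None,
        "b_median_size_bp": lower_median([iv.size for iv in b_u]) if b_u else None,
        "a_reciprocal": reciprocal,
    }


def simulation_fixture(config: SimulationConfig):
    """Generate all pipeline inputs in memory (used by tests and the CLI)."""
    truth = plant_nads(config)
    replicates = simulate_acgh(truth, config)
    reads = simulate_reads(truth, config)
    features = simulate_features(truth, config)
    return {
        "chrom_map": config.chrom_map(),
        "truth": truth,
        "replicates": replicates,
        "probes": probe_design(replicates) if replicates else {},
        "reads": reads,
        "features": features,
        "config": asdict(config),
    }
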