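import numpy as np
import pytest

from nadscan.acgh_caller import CandidateDomainSet
from nadscan.genome_model import (
    GenomicInterval,
    NADRecord,
    ValidationError,
    total_span,
    union_merge,
)
from nadscan.nad_assembly import (
    NADCatalog,
    assemble_catalog,
    catalog_stats,
    fuse_cross_platform,
    join_adjacent,
    label_detection,
    lower_median,
    write_catalog_tsv,
)

MB = 1_000_000


def _sets(acgh_ivs, seq_ivs):
    return (
        CandidateDomainSet("acgh", list(acgh_ivs)),
        CandidateDomainSet("seq", list(seq_ivs)),
    )


class TestFuse:
    def test_border_precedence_worked_example(self):
        # aCGH [1.0, 2.0) Mb overlaps seq [1.8, 2.5) Mb; probes only up to
        # 2.05 Mb, so the left border is aCGH-backed, the right is the seq
        # limit
        acgh, seq = _sets(
            [GenomicInterval("chr1", 1 * MB, 2 * MB)],
            [GenomicInterval("chr1", int(1.8 * MB), int(2.5 * MB))],
        )
        probes = {"chr1": np.arange(900_000, 2_050_000, 6000)}
        fused = fuse_cross_platform(acgh, seq, probes, probe_tolerance_bp=12_540)
        assert fused == [(GenomicInterval("chr1", 1 * MB, int(2.5 * MB)), "both")]

    def test_probe_near_seq_border_keeps_acgh_limits(self):
        acgh, seq = _sets(
            [GenomicInterval("chr1", 1 * MB, 2 * MB)],
            [GenomicInterval("chr1", int(1.8 * MB), int(2.5 * MB))],
        )
        probes = {"chr1": np.arange(900_000, 2_600_000, 6000)}
        fused = fuse_cross_platform(acgh, seq, probes, probe_tolerance_bp=12_540)
        assert fused == [(GenomicInterval("chr1", 1 * MB, 2 * MB), "both")]

    def test_identical_intervals_both(self):
        iv = GenomicInterval("chr1", 0, MB)
        acgh, seq = _sets([iv], [iv])
        fused = fuse_cross_platform(acgh, seq, {"chr1": np.array([0, MB])})
        assert fused == [(iv, "both")]

    def test_seq_only_passthrough(self):
        iv = GenomicInterval("chr1", 5 * MB, 6 * MB)
        acgh, seq = _sets([], [iv])
        fused = fuse_cross_platform(acgh, seq, {})
        assert fused == [(iv, "seq_only")]

    def test_unsorted_probes_rejected(self):
        acgh, seq = _sets([GenomicInterval("chr1", 0, 10)], [])
        with pytest.raises(ValidationError):
            fuse_cross_platform(acgh, seq, {"chr1": np.array([50, 10])})

    def test_abutting_not_fused(self):
        # >= 1 bp overlap required: [0,1M) and [1M,2M) stay separate clusters
        acgh, seq = _sets(
            [GenomicInterval("chr1", 0, MB)], [GenomicInterval("chr1", MB, 2 * MB)]
        )
        fused = fuse_cross_platform(acgh, seq, {})
        assert len(fused) == 2


class TestJoin:
    def test_gap_below_threshold_joined(self):
        out = join_adjacent(
            [
                (GenomicInterval("chr1", 0, MB), "acgh_only"),
                (GenomicInterval("chr1", int(1.05 * MB), 2 * MB), "acgh_only"),
            ]
        )
        assert out == [(GenomicInterval("chr1", 0, 2 * MB), "acgh_only")]

    def test_gap_exactly_threshold_not_joined(self):
        domains = [
            (GenomicInterval("chr1", 0, MB), "acgh_only"),
            (GenomicInterval("chr1", int(1.1 * MB), 2 * MB), "acgh_only"),
        ]
        assert join_adjacent(domains, max_gap_bp=100_000) == domains

    def test_chain_collapses_transitively(self):
        # three domains, each separated by a 50 kb gap
        domains = [
            (GenomicInterval("chr1", i * 100_000, i * 100_000 + 50_000), "seq_only")
            for i in range(3)
        ]
        out = join_adjacent(domains)
        assert out == [(GenomicInterval("chr1", 0, 250_000), "seq_only")]

    def test_mixed_labels_become_both(self):
        out = join_adjacent(
            [
                (GenomicInterval("chr1", 0, MB), "acgh_only"),
                (GenomicInterval("chr1", MB + 10, 2 * MB), "seq_only"),
            ]
        )
        assert out[0][1] == "both"

    def test_different_chromosomes_never_joined(self):
        domains = [
            (GenomicInterval("chr1", 0, MB), "both"),
            (GenomicInterval("chr2", MB + 10, 2 * MB), "both"),
        ]
        assert join_adjacent(domains) == domains


class TestLabels:
    def test_cluster_label_assignment(self):
        acgh, seq = _sets(
            [GenomicInterval("chr1", 0, MB)],
            [GenomicInterval("chr1", MB // 2, 2 * MB)],
        )
        records = label_detection(
            [(GenomicInterval("chr1", 0, 2 * MB), "both")], acgh, seq
        )
        assert records[0].detection == "both"

    def test_counts_sum_to_catalog_size(self):
        acgh, seq = _sets(
            [GenomicInterval("chr1", 0, MB), GenomicInterval("chr1", 5 * MB, 6 * MB)],
            [GenomicInterval("chr1", 10 * MB, 11 * MB)],
        )
        catalog = assemble_catalog(acgh, seq, {})
        counts = catalog.detection_counts()
        assert sum(counts.values()) == len(catalog)
        assert counts["acgh_only"] == 2 and counts["seq_only"] == 1

    def test_orphan_domain_is_internal_error(self):
        acgh, seq = _sets([GenomicInterval("chr1", 0, MB)], [])
        with pytest.raises(ValidationError):
            label_detection(
                [(GenomicInterval("chr2", 0, MB), "both")], acgh, seq
            )

    def test_empty_catalog(self):
        acgh, seq = _sets([], [])
        assert label_detection([], acgh, seq) == []


class TestStats:
    def test_single_domain(self):
        catalog = NADCatalog(
            [NADRecord(GenomicInterval("chr1", 0, 500_000), "both", id="n1")]
        )
        stats = catalog_stats(catalog)
        assert stats.n_domains == 1
        assert stats.total_bp == 500_000
        assert stats.median_size_bp == 500_000

    def test_median_odd(self):
        sizes = [100_000, 200_000, 400_000]
        records = [
            NADRecord(GenomicInterval("chr1", i * MB, i * MB + s), "both", id=str(i))
            for i, s in enumerate(sizes)
        ]
        assert catalog_stats(NADCatalog(records)).median_size_bp == 200_000

    def test_lower_median_even(self):
        assert lower_median([1, 2, 3, 4]) == 2
        assert lower_median([5]) == 5
        with pytest.raises(ValidationError):
            lower_median([])

    def test_empty_catalog_flagged(self):
        stats = catalog_stats(NADCatalog([]))
        assert stats.n_domains == 0 and stats.median_size_bp is None

    def test_total_bp_matches_per_base_count(self, rng):
        starts = np.cumsum(rng.integers(200_000, 500_000, size=10))
        records = [
            NADRecord(GenomicInterval("chr1", int(s), int(s) + 150_000), "both",
                      id=f"n{i}")
            for i, s in enumerate(starts)
        ]
        catalog = NADCatalog(records)
        stats = catalog_stats(catalog)
        # independent boolean-array count
        from _oracles import baseset_union

        mask = baseset_union(catalog.intervals(), int(starts[-1]) + 200_000)
        assert stats.total_bp == int(mask.sum())


class TestAssemblyInvariants:
    def _random_candidates(self, rng):
        acgh_ivs = union_merge(
            GenomicInterval("chr1", int(s), int(s + z))
            for s, z in zip(
                rng.integers(0, 40 * MB, 15), rng.integers(50_000, 2 * MB, 15)
            )
        )
        seq_ivs = union_merge(
            GenomicInterval("chr1", int(s), int(s + z))
            for s, z in zip(
                rng.integers(0, 40 * MB, 15), rng.integers(50_000, 2 * MB, 15)
            )
        )
        return _sets(acgh_ivs, seq_ivs)

    def test_idempotent(self, rng):
        probes = {"chr1": np.arange(0, 42 * MB, 6270)}
        for _ in range(10):
            acgh, seq = self._random_candidates(rng)
            catalog = assemble_catalog(acgh, seq, probes)
            again = assemble_catalog(
                CandidateDomainSet("acgh", catalog.intervals()),
                CandidateDomainSet("seq", catalog.intervals()),
                probes,
            )
            assert again.intervals() == catalog.intervals()

    def test_inputs_covered_and_extras_tracked(self, rng):
        probes = {"chr1": np.arange(0, 42 * MB, 6270)}
        for _ in range(10):
            acgh, seq = self._random_candidates(rng)
            catalog = assemble_catalog(acgh, seq, probes)
            from nadscan.genome_model import intersect_sets

            out = union_merge(catalog.intervals())
            # aCGH input bases are always preserved (borders follow aCGH);
            # seq bases can be trimmed at probe-covered cluster borders
            acgh_in = union_merge(acgh.intervals)
            assert total_span(intersect_sets(acgh_in, out)) == total_span(acgh_in)
            # bases beyond the union of inputs can only come from joined gaps
            inputs = union_merge(acgh.intervals + seq.intervals)
            extra = total_span(out) - total_span(intersect_sets(inputs, out))
            n_possible_joins = max(len(inputs) - len(out), 0)
            assert extra <= n_possible_joins * 100_000

    def test_catalog_requires_sorted_disjoint(self):
        with pytest.raises(ValidationError):
            NADCatalog(
                [
                    NADRecord(GenomicInterval("chr1", 0, MB), "both", id="a"),
                    NADRecord(GenomicInterval("chr1", MB // 2, 2 * MB), "both",
                              id="b"),
                ]
            )

    def test_sidecar_tsv(self, tmp_path):
        catalog = NADCatalog(
            [NADRecord(GenomicInterval("chr1", 0, MB), "both", 42, 0.99, "NAD001")]
        )
        path = tmp_path / "nads.tsv"
        write_catalog_tsv(catalog, path)
        lines = path.read_text().splitlines()
        assert lines[1].split("\t") == [
            "NAD001", "chr1", "0", str(MB), str(MB), "both", "42", "0.9900",
        ]
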