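"""Co-bound region calling, checked against a brute-force single-linkage oracle."""

import numpy as np
import pytest

from cardioreg.cooccupancy import (
    enumerate_patterns,
    inter_summit_distances,
    merge_cobound,
    pattern_frequencies,
    cobinding_vs_signal,
    tss_distance_by_ntf,
)
from cardioreg.intervals import GeneModel
from tests.conftest import make_summit


def brute_force_single_linkage(positions, d):
    """O(n^2) union-find oracle: cluster ids for summit positions."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= d:
                parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


def as_partition(regions):
    """Frozenset-of-frozensets of summit positions, for set equality."""
    return frozenset(
        frozenset((p.chrom, p.summit, p.tf) for p in r.members)
        for r in regions
    )


class TestMergeCobound:
    def test_basic_grouping(self):
        peaks = {
            "TFA": [make_summit(1000, "TFA")],
            "TFB": [make_summit(1250, "TFB")],
            "TFC": [make_summit(5000, "TFC")],
        }
        regions = merge_cobound(peaks, d=300)
        patterns = sorted("+".join(sorted(r.pattern)) for r in regions)
        assert patterns == ["TFA+TFB", "TFC"]

    def test_chain_transitivity(self):
        summits = [make_summit(p, tf) for p, tf in
                   [(250, "TFA"), (500, "TFB"), (750, "TFC")]]
        regions = merge_cobound(summits, d=300)
        assert len(regions) == 1 and regions[0].n_tf == 3

    def test_d_zero_keeps_unique_positions_apart(self):
        summits = [make_summit(p, tf) for p, tf in
                   [(100, "TFA"), (101, "TFB"), (101, "TFC")]]
        regions = merge_cobound(summits, d=0)
        assert len(regions) == 2  # the two co-located summits join

    def test_negative_d_rejected(self):
        with pytest.raises(ValueError):
            merge_cobound([make_summit(100)], d=-1)

    @pytest.mark.parametrize("d", [0, 50, 300, 1000])
    def test_matches_brute_force_oracle(self, d, rng):
        for _ in range(25):
            n = int(rng.integers(2, 200))
            pos = rng.integers(200, 100_000, size=n)
            tfs = rng.choice(["TFA", "TFB", "TFC"], size=n)
            summits = [make_summit(int(p), str(t)) for p, t in zip(pos, tfs)]
            regions = merge_cobound(summits, d=d)
            labels = brute_force_single_linkage([p.summit for p in summits], d)
            oracle = {}
            for s, lab in zip(summits, labels):
                oracle.setdefault(lab, set()).add((s.chrom, s.summit, s.tf))
            assert as_partition(regions) == frozenset(
                frozenset(v) for v in oracle.values()
            )

    def test_partition_property(self, rng):
        summits = [make_summit(int(p), str(t)) for p, t in zip(
            rng.integers(200, 50_000, 120),
            rng.choice(["TFA", "TFB"], 120))]
        regions = merge_cobound(summits, d=300)
        assert sum(len(r.members) for r in regions) == len(summits)

    def test_invariant_under_input_order(self, rng):
        summits = [make_summit(int(p), str(t)) for p, t in zip(
            rng.integers(200, 20_000, 60),
            rng.choice(["TFA", "TFB", "TFC"], 60))]
        shuffled = list(summits)
        rng.shuffle(shuffled)
        assert as_partition(merge_cobound(summits, 300)) == as_partition(
            merge_cobound(shuffled, 300)
        )

    def test_region_count_monotone_in_d(self, rng):
        summits = [make_summit(int(p)) for p in rng.integers(200, 50_000, 150)]
        counts = [len(merge_cobound(summits, d)) for d in (0, 50, 300, 1000)]
        assert counts == sorted(counts, reverse=True)


class TestEnumeratePatterns:
    def test_panel_counts(self):
        panels = {7: 128, 6: 64, 1: 2}
        for n, expected in panels.items():
            count, patterns = enumerate_patterns([f"TF{i}" for i in range(n)])
            assert count == expected
            assert len(patterns) == expected
            assert frozenset() in patterns  # subset count includes empty

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            enumerate_patterns(["TFA", "TFA"])


class TestInterSummitDistances:
    def test_successive_differences(self):
        summits = [make_summit(p) for p in (100, 200, 10_000)]
        assert inter_summit_distances(summits).tolist() == [100, 9_800]

    def test_single_summit_empty(self):
        assert len(inter_summit_distances([make_summit(100)])) == 0

    def test_per_chromosome_separation(self):
        summits = [make_summit(100, chrom="chr1"),
                   make_summit(109, chrom="chr2")]
        assert len(inter_summit_distances(summits)) == 0

    def test_tss_exclusion_flag(self):
        genes = [GeneModel("g1", "chr1", 1000)]
        summits = [make_summit(p) for p in (500, 1500, 50_000, 60_000)]
        d_all = inter_summit_distances(summits)
        d_excl = inter_summit_distances(
            summits, genes, exclude_tss_within=2000
        )
        assert len(d_all) == 3 and len(d_excl) == 1
        assert d_excl.tolist() == [10_000]


class TestPatternAndSignalTables:
    def test_pattern_frequencies_sum_to_regions(self, rng):
        summits = [make_summit(int(p), str(t)) for p, t in zip(
            rng.integers(200, 50_000, 100),
            rng.choice(["TFA", "TFB", "TFC"], 100))]
        regions = merge_cobound(summits, 300)
        freqs = pattern_frequencies(regions)
        assert sum(freqs.values()) == len(regions)

    def test_pattern_frequencies_empty(self):
        assert pattern_frequencies([]) == {}

    def test_constant_signal_gives_flat_bins(self):
        summits = [make_summit(p, tf, signal=2.0) for p, tf in
                   [(100, "TFA"), (200, "TFB"), (10_000, "TFC"),
                    (50_000, "TFA")]]
        tab = cobinding_vs_signal(merge_cobound(summits, 300))
        assert np.allclose(tab["mean_signal"], 2.0)

    def test_tss_distance_zero_on_tss(self):
        genes = [GeneModel("g1", "chr1", 1000)]
        regions = merge_cobound([make_summit(1000)], 300)
        tab = tss_distance_by_ntf(regions, genes)
        assert tab["distance"].tolist() == [0]

    def test_tss_distance_requires_genes(self):
        regions = merge_cobound([make_summit(1000)], 300)
        with pytest.raises(ValueError):
            tss_distance_by_ntf(regions, [])
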