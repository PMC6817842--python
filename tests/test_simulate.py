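import numpy as np
import pytest
from scipy import stats

from cardioreg.chs import chs_score
from cardioreg.cooccupancy import inter_summit_distances
from cardioreg.simulate import (
    SimConfig,
    make_enhancer_labels,
    make_enrichment_dataset,
    make_genes_expression,
    make_genome,
    make_h3k27ac_tracks,
    make_motif_sequences,
    make_mpra_counts,
    make_tf_summits,
)
from cardioreg.permutation import MappableSpace, mappable_space
from cardioreg.intervals import GenomeInterval


class TestConfig:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(gc=1.2)
        with pytest.raises(ValueError):
            SimConfig(cluster_fraction=-0.1)

    def test_streams_are_independent(self):
        cfg = SimConfig(seed=3)
        a = cfg.rng("genome").integers(0, 1_000_000, 5)
        b = cfg.rng("summits").integers(0, 1_000_000, 5)
        assert not np.array_equal(a, b)


class TestGenome:
    def test_determinism(self, small_cfg):
        s1, m1 = make_genome(small_cfg)
        s2, m2 = make_genome(small_cfg)
        assert s1 == s2
        assert all(
            np.array_equal(m1.segments[c], m2.segments[c])
            for c in m1.segments
        )

    def test_gc_content(self):
        cfg = SimConfig(seed=5, n_chrom=1, chrom_length=1_000_000, gc=0.5)
        seqs, _ = make_genome(cfg)
        s = seqs["chr1"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert gc == pytest.approx(0.5, abs=0.01)

    def test_no_gaps_gives_constant_mappability(self):
        cfg = SimConfig(seed=5, chrom_length=100_000, map_gap_lengths=())
        _, track = make_genome(cfg)
        for c in track.values:
            assert np.all(track.values[c] == 1.0)

    def test_gap_lengths_straddle_exclusion_boundary(self, small_cfg):
        _, track = make_genome(small_cfg)
        space = mappable_space(track)
        # only the >500 bp low-mappability gaps are excluded
        expected_excluded = sum(
            l for l in small_cfg.map_gap_lengths if l > 500
        ) * small_cfg.n_chrom
        total = small_cfg.n_chrom * small_cfg.chrom_length
        assert space.total_bp == total - expected_excluded


class TestSummits:
    def test_unclustered_distances_unimodal(self):
        cfg = SimConfig(seed=8, chrom_length=2_000_000, summits_per_tf=150,
                        cluster_fraction=0.0)
        peaks, truth = make_tf_summits(cfg)
        assert (truth["cluster_id"] == -1).all()
        pooled = [p for v in peaks.values() for p in v]
        d = inter_summit_distances(pooled)
        # no short-distance mode: < 300 bp gaps are the uniform-rate tail
        frac_short = np.mean(np.asarray(d) < 300)
        assert frac_short < 0.25

    def test_clustered_fraction_in_truth(self, small_cfg):
        peaks, truth = make_tf_summits(small_cfg)
        frac = (truth["cluster_id"] >= 0).mean()
        assert frac == pytest.approx(small_cfg.cluster_fraction, abs=0.1)

    def test_full_panel_pattern(self):
        cfg = SimConfig(seed=8, chrom_length=2_000_000, summits_per_tf=50)
        # pattern distribution concentrated on size 7
        probs = np.zeros(6)
        probs[-1] = 1.0
        _, truth = make_tf_summits(cfg, pattern_sizes=probs)
        clustered = truth[truth["cluster_id"] >= 0]
        assert (clustered.groupby("cluster_id")["tf"].nunique() == 7).all()

    def test_signal_increases_with_cluster_size(self, small_cfg):
        peaks, truth = make_tf_summits(small_cfg)
        pooled = {(p.chrom, p.summit, p.tf): p.signal
                  for v in peaks.values() for p in v}
        truth = truth.assign(
            signal=[pooled[(r.chrom, r.summit, r.tf)]
                    for r in truth.itertuples()]
        )
        means = truth.groupby("cluster_size")["signal"].mean()
        assert means.loc[means.index.max()] > means.loc[1]


class TestH3k27acTracks:
    def test_noise_free_chs_matches_truth(self, small_cfg):
        tracks, regions, truth = make_h3k27ac_tracks(
            small_cfg, n_regions=100, noise=False
        )
        scored = chs_score(
            regions, tracks["heart"], tracks["liver"], tracks["forebrain"]
        )
        err = np.abs(
            np.array([s.chs for s in scored]) - truth["chs_true"].to_numpy()
        )
        assert err.max() < 1e-9

    def test_identical_tissues_score_one(self, small_cfg):
        tracks, regions, truth = make_h3k27ac_tracks(
            small_cfg, n_regions=50, frac_heart_specific=0.0, noise=False
        )
        # non-specific regions have matched tissue means; CHS near 1
        assert np.median(truth["chs_true"]) == pytest.approx(1.0, abs=0.15)


class TestMotifSequences:
    def test_full_frequency_plants_everywhere(self, small_cfg, pwm_a, pwm_b):
        seqs, truth = make_motif_sequences(
            small_cfg, pwm_a, pwm_b, "+-", 4, n_seqs=30, arrangement_freq=1.0
        )
        assert truth["planted"].all()
        assert len(seqs) == 30 and all(len(s) == 200 for s in seqs)

    def test_zero_frequency_plants_none(self, small_cfg, pwm_a, pwm_b):
        _, truth = make_motif_sequences(
            small_cfg, pwm_a, pwm_b, n_seqs=30, arrangement_freq=0.0
        )
        assert not truth["planted"].any()


class TestMpraCounts:
    def test_determinism(self):
        cfg = SimConfig(seed=17)
        c1, t1 = make_mpra_counts(cfg, n_test=50, n_negative=30)
        c2, t2 = make_mpra_counts(cfg, n_test=50, n_negative=30)
        assert np.array_equal(c1.dna_counts, c2.dna_counts)
        assert np.array_equal(c1.rna_counts, c2.rna_counts)

    def test_truth_activities_match_config(self):
        cfg = SimConfig(seed=17)
        _, truth = make_mpra_counts(cfg, n_test=20, n_negative=10)
        for cls, act in cfg.activity_map.items():
            assert (truth.loc[truth["class"] == cls,
                              "activity_true"] == act).all()


class TestEnrichmentDataset:
    def test_null_and_planted_hit_rates(self):
        cfg = SimConfig(seed=19, chrom_length=1_000_000)
        space = MappableSpace((GenomeInterval("chr1", 0, 1_000_000),))
        from cardioreg.intervals import GeneModel
        genes = [GeneModel(f"g{i}", "chr1", 40_000 + 90_000 * i)
                 for i in range(10)]
        regions, p0 = make_enrichment_dataset(
            cfg, space, genes, d=5_000, n_query=400, fold=3.0
        )
        from cardioreg.permutation import tss_windows
        from cardioreg.intervals import overlaps
        windows = tss_windows(genes, 5_000)
        hit = np.mean([
            any(overlaps(r, w) for w in windows) for r in regions
        ])
        assert hit == pytest.approx(min(1.0, 3 * p0), abs=3 * np.sqrt(
            p0 * (1 - p0) / 400) + 0.02)


class TestEnhancerLabels:
    def test_label_rate_monotone_in_ntf(self):
        table, truth = make_enhancer_labels(SimConfig(seed=23), n=2000)
        rate = truth.groupby("n_tf_true")["label"].mean()
        rho = stats.spearmanr(rate.index, rate.to_numpy()).statistic
        assert rho > 0.9
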