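import numpy as np
import pytest

from cardioreg.motifs import (
    PWM,
    CompositePWM,
    arrangement_scan,
    build_composites,
    central_enrichment,
    dinucleotide_shuffle,
    fano_factor,
    has_hit,
    inter_motif_distance,
    motif_enrichment,
    revcomp,
    scan,
)
from cardioreg.simulate import SimConfig, make_motif_sequences
from tests.conftest import near_consensus_pwm


def brute_force_scan(seq, pwm, threshold):
    """Per-window oracle: enumerate every window on both strands."""
    hits = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        lo = pwm.log_odds
        w = pwm.width
        for i in range(len(s) - w + 1):
            window = s[i : i + w]
            if "N" in window:
                continue
            score = sum(
                lo[j, "ACGT".index(b)] for j, b in enumerate(window)
            )
            pos = i if strand == "+" else len(seq) - w - i
            if score >= threshold:
                hits.append((pos, strand, round(float(score), 9)))
    return sorted(hits)


class TestScan:
    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = PWM("U", np.full((4, 4), 0.25))
        hits = scan("ACGTACGTACGT", pwm, threshold=0.0)
        # every N-free window on both strands scores exactly 0
        assert len(hits) == 2 * (12 - 4 + 1)
        assert np.allclose(hits["score"], 0.0)

    def test_planted_consensus_found_once_forward(self, pwm_a, rng):
        bg = "".join(rng.choice(list("AC"), 60))  # consensus-free background
        seq = bg[:30] + pwm_a.consensus() + bg[30:]
        hits = scan(seq, pwm_a)
        fwd = hits[hits["strand"] == "+"]
        assert list(fwd["position"]) == [30]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed, pwm_a):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), 300, p=[0.24] * 4 + [0.04]))
        thr = 0.5 * pwm_a.max_score
        got = sorted(
            (int(r.position), r.strand, round(float(r.score), 9))
            for r in scan(seq, pwm_a, threshold=thr).itertuples()
        )
        assert got == brute_force_scan(seq, pwm_a, thr)

    def test_revcomp_symmetry(self, pwm_a, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        h1 = scan(seq, pwm_a)
        h2 = scan(revcomp(seq), pwm_a)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (len(seq) - pwm_a.width - int(r.position), flip[r.strand])
            for r in h2.itertuples()
        )
        assert mirrored == sorted(
            (int(r.position), r.strand) for r in h1.itertuples()
        )

    def test_short_sequence_yields_no_hits(self, pwm_a):
        assert len(scan("ACG", pwm_a)) == 0


class TestComposites:
    def test_widths_and_count(self, pwm_a, pwm_b):
        comps = build_composites(pwm_a, pwm_b)
        assert len(comps) == 36
        c = CompositePWM.build(pwm_a, pwm_b, "++", 4)
        assert c.width == pwm_a.width + 4 + pwm_b.width
        assert np.allclose(
            c.matrix[pwm_a.width : pwm_a.width + 4], 0.25
        )

    def test_spacer_zero_is_direct_concatenation(self, pwm_a, pwm_b):
        c = CompositePWM.build(pwm_a, pwm_b, "++", 0)
        assert np.allclose(
            c.matrix, np.vstack([pwm_a.matrix, pwm_b.matrix])
        )

    def test_minus_minus_is_revcomp_of_swapped_plus_plus(self, pwm_a, pwm_b):
        mm = CompositePWM.build(pwm_a, pwm_b, "--", 3)
        pp = CompositePWM.build(pwm_b, pwm_a, "++", 3)
        assert np.allclose(mm.matrix, pp.matrix[::-1, ::-1])

    def test_strand_symmetric_positivity(self, pwm_a, pwm_b, rng):
        comp = CompositePWM.build(pwm_a, pwm_b, "+-", 2)
        rc = PWM("rc", comp.matrix[::-1, ::-1])
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 100))
            assert has_hit(seq, comp) == has_hit(seq, rc)


class TestFano:
    def test_equal_values_give_zero(self):
        assert fano_factor(np.full(36, 0.3)) == pytest.approx(0.0, abs=1e-12)

    def test_printed_form_scales_cubically(self, rng):
        v = rng.random(36)
        f1 = fano_factor(v)
        f3 = fano_factor(3 * v)
        assert f3 == pytest.approx(27 * f1)

    def test_standard_form_scales_linearly(self, rng):
        v = rng.random(36)
        assert fano_factor(3 * v, printed_form=False) == pytest.approx(
            3 * fano_factor(v, printed_form=False)
        )


class TestEnrichmentStatistics:
    def test_motif_enrichment_recovers_planted_motif(self, pwm_a, rng):
        targets = []
        for _ in range(60):
            bg = "".join(rng.choice(list("ACGT"), 100))
            off = int(rng.integers(0, 90))
            targets.append(bg[:off] + pwm_a.consensus() + bg[off + pwm_a.width:])
        background = ["".join(rng.choice(list("ACGT"), 100)) for _ in range(60)]
        pct_t, pct_b, p = motif_enrichment(targets, background, pwm_a)
        assert pct_t >= 95
        assert p < 1e-6

    def test_empty_target_set_errors(self, pwm_a):
        with pytest.raises(ValueError):
            motif_enrichment([], None, pwm_a)

    def test_central_enrichment_detects_centered_hits(self, pwm_a, rng):
        seqs = []
        for _ in range(40):
            bg = "".join(rng.choice(list("AC"), 1000))
            mid = 500 - pwm_a.width // 2
            seqs.append(bg[:mid] + pwm_a.consensus() + bg[mid + pwm_a.width:])
        ratio, p = central_enrichment(seqs, pwm_a)
        assert ratio > 3
        assert p < 1e-6

    def test_central_enrichment_flat_for_uniform_hits(self, pwm_a, rng):
        seqs = []
        for _ in range(200):
            bg = "".join(rng.choice(list("AC"), 1000))
            off = int(rng.integers(0, 1000 - pwm_a.width))
            seqs.append(bg[:off] + pwm_a.consensus() + bg[off + pwm_a.width:])
        ratio, p = central_enrichment(seqs, pwm_a)
        assert 0.3 < ratio < 3
        assert p > 0.001

    def test_no_hits_flagged_not_crash(self, pwm_a):
        ratio, p = central_enrichment(["ACACACAC" * 100], pwm_a)
        assert np.isnan(ratio) and p == 1.0

    def test_dinucleotide_shuffle_preserves_composition(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 500))
        shuffled = dinucleotide_shuffle(seq, rng)
        def dinucs(s):
            out = {}
            for a, b in zip(s, s[1:]):
                out[a + b] = out.get(a + b, 0) + 1
            return out
        assert dinucs(seq) == dinucs(shuffled)
        assert shuffled != seq  # astronomically unlikely to collide


class TestArrangements:
    def test_planted_arrangement_is_argmax(self, pwm_a, pwm_b):
        cfg = SimConfig(seed=21)
        seqs, _ = make_motif_sequences(
            cfg, pwm_a, pwm_b, "+-", 4, n_seqs=120, arrangement_freq=0.25
        )
        res = arrangement_scan(seqs, pwm_a, pwm_b)
        assert res.best == ("+-", 4)
        assert len(res.table) == 36

    def test_all_equal_enrichment_gives_zero_fano(self, pwm_a, pwm_b):
        res_fano = fano_factor(np.full(36, 0.5))
        assert res_fano == pytest.approx(0.0, abs=1e-12)

    def test_fraction_outputs_bounded(self, pwm_a, pwm_b):
        cfg = SimConfig(seed=22)
        seqs, _ = make_motif_sequences(cfg, pwm_a, pwm_b, n_seqs=40)
        res = arrangement_scan(seqs, pwm_a, pwm_b)
        assert ((res.table["enrichment"] >= 0)
                & (res.table["enrichment"] <= 1)).all()

    def test_inter_motif_distance_planted_spacing(self, pwm_a, pwm_b, rng):
        seqs = []
        for _ in range(20):
            bg = "".join(rng.choice(list("AC"), 120))
            s = (bg[:20] + pwm_a.consensus()
                 + bg[20:33] + pwm_b.consensus())
            seqs.append(s + bg[: 120 - len(s)])
        dists, skipped = inter_motif_distance(seqs, pwm_a, pwm_b)
        assert skipped == 0
        # planted |startB - startA| = width_a + 13
        assert np.median(dists) == pwm_a.width + 13

    def test_missing_partner_skipped_and_counted(self, pwm_a, pwm_b, rng):
        bg = "".join(rng.choice(list("AC"), 100))
        seq_a_only = bg[:10] + pwm_a.consensus() + bg[10 + pwm_a.width:]
        dists, skipped = inter_motif_distance([seq_a_only], pwm_a, pwm_b)
        assert len(dists) == 0 and skipped == 1
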