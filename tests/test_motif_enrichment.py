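import itertools

import numpy as np
import pytest
from scipy import stats

from cistrome_compare import motif_enrichment as me
from cistrome_compare.formats import GenomicInterval, PWM, Peak

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def sharp_pwm(consensus, motif_id="M"):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.full((len(consensus), 4), 0.01)
    for i, b in enumerate(consensus):
        m[i, idx[b]] = 0.97
    return PWM(motif_id, m)


class TestRefinePeak:
    def test_wide_peak_refined_to_summit_window(self):
        p = Peak(GenomicInterval("chr1", 1000, 2000), 1500)
        r = me.refine_peak(p)
        assert (r.interval.start, r.interval.end) == (1250, 1750)

    def test_narrow_peak_kept_whole(self):
        p = Peak(GenomicInterval("chr1", 1000, 1100), 1050)
        r = me.refine_peak(p)
        assert (r.interval.start, r.interval.end) == (1000, 1100)

    def test_asymmetric_intersection(self):
        p = Peak(GenomicInterval("chr1", 0, 600), 100)
        r = me.refine_peak(p)
        assert (r.interval.start, r.interval.end) == (0, 350)


class TestFlankingControls:
    def test_abutting_equal_length_controls(self):
        r = me.refine_peak(Peak(GenomicInterval("chr1", 1000, 2000), 1500))
        pair = me.flanking_controls(r, chrom_length=10_000)
        assert (pair.upstream.start, pair.upstream.end) == (750, 1250)
        assert (pair.downstream.start, pair.downstream.end) == (1750, 2250)
        assert len(pair.upstream) + len(pair.downstream) == 2 * len(r.interval)

    def test_upstream_clipped_at_chromosome_start(self):
        r = me.RefinedPeak(
            GenomicInterval("chr1", 0, 500),
            Peak(GenomicInterval("chr1", 0, 500), 250),
        )
        pair = me.flanking_controls(r, chrom_length=10_000)
        assert pair.upstream is None
        assert (pair.downstream.start, pair.downstream.end) == (500, 1000)


class TestScanPwm:
    def test_consensus_is_hit_at_position_zero(self):
        pwm = sharp_pwm("ACGTAC")
        hits = me.scan_pwm(pwm.consensus, pwm, p_threshold=1e-3)
        assert any(h.position == 0 and h.strand == "+" for h in hits)

    def test_all_n_sequence_has_no_hits(self):
        pwm = sharp_pwm("ACGTAC")
        assert me.scan_pwm("N" * 30, pwm, 0.5) == []

    def test_sequence_shorter_than_motif(self):
        assert me.scan_pwm("ACG", sharp_pwm("ACGTAC"), 0.5) == []

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        pwm = PWM("rnd", rng.dirichlet([0.5] * 4, size=5))
        ints = np.round(me.log_odds_matrix(pwm) * 1000).astype(int)
        # oracle: exact null from enumerating all 4^5 words
        word_scores = [
            sum(int(ints[j, b]) for j, b in enumerate(w))
            for w in itertools.product(range(4), repeat=5)
        ]

        def oracle_p(s):
            return sum(1 for x in word_scores if x >= s) / len(word_scores)

        seq = "".join(rng.choice(list("ACGT"), 20))
        for thr in (0.05, 0.01):
            expected = []
            for pos in range(20 - 5 + 1):
                for strand in "+-":
                    w = seq[pos:pos + 5]
                    if strand == "-":
                        w = "".join(COMP[c] for c in reversed(w))
                    s = sum(int(ints[j, "ACGT".index(b)]) for j, b in enumerate(w))
                    p = oracle_p(s)
                    if p <= thr:
                        expected.append((pos, strand, round(p, 12)))
            got = [(h.position, h.strand, round(h.p, 12))
                   for h in me.scan_pwm(seq, pwm, thr)]
            assert sorted(got) == sorted(expected)

    def test_strand_symmetric_for_rc_palindrome(self):
        pwm = sharp_pwm("ACGT" * 2)  # reverse-complement palindrome
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 200)) + pwm.consensus
        hits = me.scan_pwm(seq, pwm, 1e-3)
        by_strand = {"+": set(), "-": set()}
        for h in hits:
            by_strand[h.strand].add(h.position)
        assert by_strand["+"] == by_strand["-"]


class TestChiSquared:
    def test_matches_textbook_formula(self):
        # 30 hits / 1000 positions vs 10 hits / 2000 positions
        table = np.array([[30, 970], [10, 1990]], dtype=float)
        stat, p = me.chi_squared_2x2(table)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        exp = row * col / table.sum()
        oracle = ((table - exp) ** 2 / exp).sum()
        assert stat == pytest.approx(oracle)
        assert p == pytest.approx(stats.chi2.sf(oracle, 1))
        # cross-check against scipy's uncorrected contingency test
        s2, p2, _, _ = stats.chi2_contingency(table, correction=False)
        assert stat == pytest.approx(s2) and p == pytest.approx(p2)


class TestEnrichment:
    def _genome_with_plants(self, n_peaks, plant_in_peak, plant_in_ctrl, pwm):
        rng = np.random.default_rng(7)
        length = 20_000 * n_peaks
        seq = list("".join(rng.choice(list("ACGT"), length)))
        peaks = []
        for i in range(n_peaks):
            summit = 10_000 + 20_000 * i
            peaks.append(Peak(GenomicInterval("chr1", summit - 400, summit + 400), summit))
            if plant_in_peak:
                pos = summit - len(pwm) // 2
                seq[pos:pos + len(pwm)] = list(pwm.consensus)
            if plant_in_ctrl:
                pos = summit + 300  # inside the downstream control
                seq[pos:pos + len(pwm)] = list(pwm.consensus)
        return {"chr1": "".join(seq)}, peaks

    def test_null_identity_equal_density(self):
        # no occurrences anywhere: pseudocounted ES is exactly 1
        pwm = sharp_pwm("ACGTACGTGA")
        genome, peaks = self._genome_with_plants(4, False, False, pwm)
        genome = {"chr1": "A" * len(genome["chr1"])}  # motif absent everywhere
        res = me.motif_enrichment(peaks, genome, pwm)
        assert res.hits_peak == 0 and res.hits_control == 0
        assert res.es == pytest.approx(1.0)
        assert res.log2_es == pytest.approx(0.0)

    def test_hits_only_in_peaks_enriched(self):
        pwm = sharp_pwm("ACGTACGTGA")
        genome, peaks = self._genome_with_plants(8, True, False, pwm)
        res = me.motif_enrichment(peaks, genome, pwm)
        assert res.hits_peak >= 8
        assert res.es > 1 and res.log2_es > 1
        assert res.p < 1e-4

    def test_control_hits_deplete(self):
        pwm = sharp_pwm("ACGTACGTGA")
        genome, peaks = self._genome_with_plants(8, False, True, pwm)
        res = me.motif_enrichment(peaks, genome, pwm)
        assert res.hits_control >= 8 and res.es < 1

    def test_es_invariant_to_peak_order(self):
        pwm = sharp_pwm("ACGTACGTGA")
        genome, peaks = self._genome_with_plants(5, True, False, pwm)
        res_fwd = me.motif_enrichment(peaks, genome, pwm)
        res_rev = me.motif_enrichment(peaks[::-1], genome, pwm)
        assert res_fwd.es == pytest.approx(res_rev.es)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert me.bh_fdr([0.05])[0] == pytest.approx(0.05)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(me.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(me.bh_fdr([1.0, 1.0, 1.0]), 1.0)


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(50):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            ps.append(me.compare_enrichment_groups(a, b)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(3.0, 0.3, size=10)
        b = rng.normal(0.0, 0.3, size=10)
        _, p = me.compare_enrichment_groups(a, b)
        assert p < 1e-3
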