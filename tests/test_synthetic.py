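import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cistrome_compare import synthetic
from cistrome_compare.synthetic import SimulationConfig


def small_config(**kw):
    base = dict(seed=3, n_chroms=1, chrom_length=1_000_000, n_genes=100)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateGenome:
    def test_tss_spacing_and_count(self):
        genome, genes = synthetic.generate_genome(small_config())
        assert len(genes) == 100
        tss = [g.tss for g in genes]
        assert set(np.diff(tss)) == {10_000}
        assert {g.strand for g in genes} == {"+", "-"}

    def test_deterministic_under_seed(self):
        g1, _ = synthetic.generate_genome(small_config())
        g2, _ = synthetic.generate_genome(small_config())
        assert g1 == g2

    def test_gc_fraction_near_half(self):
        genome, _ = synthetic.generate_genome(small_config())
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.49 <= gc <= 0.51

    def test_too_short_genome_rejected(self):
        with pytest.raises(Exception):
            SimulationConfig(n_chroms=1, chrom_length=50_000, n_genes=100)


class TestPlantBinding:
    def test_full_sharing_gives_identical_nonspecial_peak_sets(self):
        cfg = small_config(shared_site_fraction=1.0)
        genome, genes = synthetic.generate_genome(cfg)
        truth = synthetic.plant_binding(cfg, genes, genome)
        lines = cfg.cell_lines[1:]
        ref = [(p.interval, p.summit) for p in truth.true_peaks[lines[0]]]
        for line in lines[1:]:
            assert [(p.interval, p.summit) for p in truth.true_peaks[line]] == ref

    def test_every_special_peak_contains_planted_consensus(self):
        cfg = small_config()
        genome, genes = synthetic.generate_genome(cfg)
        truth = synthetic.plant_binding(cfg, genes, genome)
        consensus = synthetic.planted_pwm().consensus
        for peak in truth.true_peaks[cfg.special_line_id]:
            seq = genome[peak.interval.chrom][peak.interval.start:peak.interval.end]
            assert consensus in seq

    def test_planted_positions_inside_special_peaks(self):
        cfg = small_config()
        genome, genes = synthetic.generate_genome(cfg)
        truth = synthetic.plant_binding(cfg, genes, genome)
        special = truth.true_peaks[cfg.special_line_id]
        for chrom, pos, motif_id, _ in truth.planted_motif_positions:
            assert any(
                p.interval.chrom == chrom
                and p.interval.start <= pos < p.interval.end
                for p in special
            )

    def test_special_line_less_promoter_proximal(self, default_sim):
        truth, cfg = default_sim.truth, default_sim.config
        tss = {g.chrom: [] for g in default_sim.genes}
        for g in default_sim.genes:
            tss[g.chrom].append(g.tss)

        def proximal_fraction(peaks):
            near = sum(
                1
                for p in peaks
                if min(abs(p.summit - t) for t in tss[p.interval.chrom]) <= 1000
            )
            return near / len(peaks)

        special = proximal_fraction(truth.true_peaks[cfg.special_line_id])
        others = [proximal_fraction(truth.true_peaks[l]) for l in cfg.cell_lines[1:]]
        assert special < min(others)


class TestSimulateCoverage:
    def test_noiseless_summit_height(self):
        cfg = small_config(noise_sd=0.0, n_replicates_per_line=1)
        genome, genes = synthetic.generate_genome(cfg)
        truth = synthetic.plant_binding(cfg, genes, genome)
        tracks = synthetic.simulate_coverage(truth, cfg)
        track = tracks[(cfg.special_line_id, 1)]
        cov = track.coverage_array("chr1", cfg.chrom_length)
        assert cov.max() == pytest.approx(1.0 + cfg.peak_signal_mean)
        peak = truth.true_peaks[cfg.special_line_id][0]
        block = (peak.summit // cfg.coverage_step) * cfg.coverage_step
        assert cov[block] == pytest.approx(1.0 + cfg.peak_signal_mean)

    def test_within_line_correlation_exceeds_cross_line(self, default_sim):
        from cistrome_compare.signal_analysis import bin_signal

        cfg = default_sim.config

        def binned(line, rep):
            b = bin_signal(default_sim.tracks[(line, rep)], 100)
            return np.concatenate([b[c] for c in sorted(b)])

        special = cfg.special_line_id
        within = stats.pearsonr(binned(special, 1), binned(special, 2))[0]
        cross = stats.pearsonr(binned(special, 1), binned("line2", 1))[0]
        # replicates share every peak; only the background noise differs
        assert within > 0.6
        assert within > cross + 0.2


class TestSimulateCohort:
    def test_no_effect_means_equal_target_nontarget_expression(self):
        cfg = small_config(effect_up=0.0, n_patients=400)
        genome, genes = synthetic.generate_genome(cfg)
        truth = synthetic.plant_binding(cfg, genes, genome)
        cohort = synthetic.simulate_cohort(truth, cfg, genes)
        targets = truth.true_targets[cfg.special_line_id]
        in_t = cohort.expression.index.isin(targets)
        t, p = stats.ttest_ind(
            cohort.expression.values[in_t].ravel(),
            cohort.expression.values[~in_t].ravel(),
        )
        assert p > 0.01

    def test_special_targets_higher_in_er_positive(self, default_sim):
        cohort = default_sim.cohort
        truth, cfg = default_sim.truth, default_sim.config
        targets = truth.true_targets[cfg.special_line_id]
        er_pos = cohort.clinical["er_status"] == "+"
        sub = cohort.expression.loc[cohort.expression.index.isin(targets)]
        t, p = stats.ttest_ind(
            sub.loc[:, er_pos.values].values.ravel(),
            sub.loc[:, ~er_pos.values].values.ravel(),
        )
        assert t > 0 and p < 1e-10

    def test_activities_anticorrelated_with_er_sign_structure(self, default_sim):
        act = default_sim.truth.patient_activities
        er = default_sim.truth.er_labels == "+"
        assert act.loc[er.values, "a_special"].mean() > 0.5
        assert act.loc[er.values, "a_other"].mean() < -0.5


class TestDeterminism:
    def test_write_simulation_byte_identical(self, tmp_path):
        cfg = small_config(n_patients=30)
        p1, p2 = tmp_path / "a", tmp_path / "b"
        synthetic.write_simulation(synthetic.simulate(cfg), p1)
        synthetic.write_simulation(synthetic.simulate(cfg), p2)
        for f1 in sorted(p1.iterdir()):
            f2 = p2 / f1.name
            assert f1.read_bytes() == f2.read_bytes(), f1.name
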