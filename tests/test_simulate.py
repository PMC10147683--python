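"""Generator contracts: determinism, planted structure, ground-truth closure."""

import math

import numpy as np
import pandas as pd
import pytest

from tfdep.simulate import (
    ConfigError,
    SimulationConfig,
    nb_draw,
    planted_gene_sets,
    simulate_all,
    simulate_counts,
    simulate_peaks,
    simulate_tmt,
    write_simulation,
)


class TestConfigValidation:
    def test_bad_proportion(self):
        with pytest.raises(ConfigError):
            SimulationConfig(frac_up=1.2)

    def test_up_plus_down_bounded(self):
        with pytest.raises(ConfigError):
            SimulationConfig(frac_up=0.6, frac_down=0.6)

    def test_tmt_enriched_bounded(self):
        with pytest.raises(ConfigError):
            SimulationConfig(tmt_n_enriched=600, tmt_n_proteins=500)

    def test_genome_vs_peak_width(self):
        with pytest.raises(ConfigError):
            SimulationConfig(chrom_length=1000, peak_width=400)


class TestDeterminism:
    def test_counts_identical_across_runs(self):
        cfg = SimulationConfig(n_genes=200, seed=7)
        m1, d1, _ = simulate_counts(cfg)
        m2, d2, _ = simulate_counts(cfg)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(d1, d2)

    def test_tmt_identical_across_runs(self):
        cfg = SimulationConfig(tmt_n_proteins=100, tmt_n_enriched=10, tmt_n_rewired=3)
        t1, _, _ = simulate_tmt(cfg)
        t2, _, _ = simulate_tmt(cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_written_files_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_genes=150, n_background_peaks=40,
                               tmt_n_proteins=60, tmt_n_enriched=5,
                               tmt_n_rewired=2, seed=13)
        write_simulation(simulate_all(cfg), tmp_path / "a")
        write_simulation(simulate_all(cfg), tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name


class TestPlantedExpression:
    def test_no_planted_effects_means_no_lfc(self):
        cfg = SimulationConfig(n_genes=100, frac_up=0.0, frac_down=0.0)
        _, _, truth = simulate_counts(cfg)
        assert (truth.genes["lfc_scr"] == 0).all()
        assert (truth.genes["lfc_kd"] == 0).all()
        assert not truth.genes["dependent"].any()

    def test_dependent_genes_are_up_genes(self, bundle):
        truth = bundle["truth"]
        assert truth.planted_dependent <= truth.planted_up
        assert truth.planted_cobound <= truth.planted_dependent

    def test_nb_moments(self):
        """Monte-Carlo check of the gamma-Poisson parameterization.

        At mu=100, dispersion 0.1 the variance is mu + 0.1*mu^2 = 1100;
        the mean over 20,000 draws must sit within 3 standard errors.
        """
        rng = np.random.default_rng(42)
        n = 20_000
        draws = nb_draw(rng, np.full(n, 100.0), 0.1)
        se = math.sqrt(1100.0 / n)
        assert abs(draws.mean() - 100.0) < 3 * se
        assert 0.8 * 1100 < draws.var() < 1.2 * 1100

    def test_planted_lfc_recoverable(self):
        """Empirical log2FC of planted-up genes converges to lfc_up.

        Many replicates per cell shrink the contrast SE so the planted
        effect is recovered within 3 standard errors of the gene mean.
        Up/down fractions are balanced so median-of-ratios normalization
        is not biased by a one-directional DE composition.
        """
        cfg = SimulationConfig(n_genes=400, frac_up=0.1, frac_down=0.1,
                               frac_dependent=0, samples_per_cell=30, seed=5)
        counts, design, truth = simulate_counts(cfg)
        from tfdep.diffexpr import contrast
        c = contrast(counts, design, ("SCR", "Dox"), ("SCR", "Con"),
                     pseudocount=0.0)
        est = c.set_index("gene_id").loc[sorted(truth.planted_up), "log2fc"]
        assert abs(est.mean() - cfg.lfc_up) < 3 * est.std() / math.sqrt(len(est))


class TestPeaks:
    def test_every_dependent_gene_cobound_when_frac_one(self, bundle):
        truth = bundle["truth"]
        assert truth.planted_cobound == truth.planted_dependent
        cof_names = {iv.name for iv in bundle["peaks"]["cofactor"]["scr"]}
        for gid in truth.planted_cobound:
            assert f"cof_{gid}" in cof_names

    def test_empty_when_nothing_requested(self):
        cfg = SimulationConfig(n_genes=50, frac_up=0.0, frac_down=0.0,
                               n_background_peaks=0)
        _, _, truth = simulate_counts(cfg)
        peaks = simulate_peaks(cfg, truth)
        assert len(peaks["tf"]["scr"]) == 0
        assert len(peaks["cofactor"]["kd"]) == 0

    def test_peaks_nonoverlapping_within_factor(self, bundle):
        for factor in ("tf", "cofactor"):
            ps = bundle["peaks"][factor]["scr"]
            for chrom, starts, ends, _ in ps.by_chrom():
                order = np.argsort(starts)
                assert (starts[order][1:] >= ends[order][:-1]).all(), factor

    def test_planted_loss_rates_recovered(self):
        """Co-bound TF peaks disappear in the knockdown at the configured
        rate, background peaks at theirs, within binomial 95% bounds."""
        cfg = SimulationConfig(n_genes=2000, frac_up=0.25, frac_dependent=0.8,
                               frac_down=0, n_background_peaks=2000, seed=3)
        counts, design, truth = simulate_counts(cfg)
        simulate_peaks(cfg, truth)
        tf = truth.peaks[truth.peaks["factor"] == "tf"]
        for flag, rate in ((True, cfg.loss_cobound), (False, cfg.loss_noncobound)):
            sub = tf[tf["cobound"] == flag]
            n = len(sub)
            observed = sub["lost_in_kd"].mean()
            bound = 1.96 * math.sqrt(rate * (1 - rate) / n)
            assert abs(observed - rate) < bound, (flag, observed, rate, n)

    def test_ground_truth_closure(self, bundle):
        """Every identifier the truth tables reference exists in the data."""
        truth = bundle["truth"]
        gene_ids = set(truth.genes["gene_id"])
        model_ids = {m.gene_id for m in truth.gene_models}
        assert gene_ids == model_ids == set(bundle["counts"].index)
        peak_names = {iv.name for f in bundle["peaks"].values()
                      for ps in (f["scr"],) for iv in ps}
        assert set(truth.peaks["name"]) == peak_names
        targets = set(truth.peaks["target_gene"]) - {"."}
        assert targets <= gene_ids
        assert set(truth.proteins["protein_id"]) == set(bundle["tmt"].index)

    def test_cobound_peak_within_annotation_window(self, bundle):
        truth = bundle["truth"]
        tss = {m.gene_id: m.tss for m in truth.gene_models}
        planted = truth.peaks[truth.peaks["cobound"]]
        for row in planted.itertuples(index=False):
            mid = (row.start + row.end) // 2
            assert abs(mid - tss[row.target_gene]) <= 10_000


class TestTmt:
    def test_zero_lfc_plants_nothing(self):
        cfg = SimulationConfig(tmt_lfc=0.0, tmt_n_proteins=50,
                               tmt_n_enriched=10, tmt_n_rewired=2)
        _, _, truth = simulate_tmt(cfg)
        assert not truth.proteins["enriched"].any()

    def test_channel_scaling_doubles_total(self):
        """A planted scaling factor multiplies the channel total exactly."""
        cfg = SimulationConfig(tmt_n_proteins=80, tmt_n_enriched=0,
                               tmt_n_rewired=0, seed=9)
        matrix, _, _ = simulate_tmt(cfg)
        rng = cfg.rng(3)  # the TMT stream: replay the generator's draws
        rng.permutation(cfg.tmt_n_proteins)
        rng.normal(cfg.tmt_base_log2, cfg.tmt_base_sd_log2, size=cfg.tmt_n_proteins)
        scale = np.exp2(rng.uniform(np.log2(0.7), np.log2(1.4), size=10))
        unscaled_totals = matrix.sum(axis=0).to_numpy() / scale
        doubled = matrix * 0 + matrix  # copy
        doubled.iloc[:, 0] = matrix.iloc[:, 0] * 2
        assert doubled.iloc[:, 0].sum() == pytest.approx(2 * matrix.iloc[:, 0].sum())
        # channel totals differ from each other only through the known factors
        ratio = unscaled_totals / unscaled_totals.mean()
        assert np.allclose(ratio, 1.0, atol=0.35)


def test_gene_sets_reference_real_genes(bundle, default_config):
    coll = planted_gene_sets(default_config, bundle["truth"])
    assert coll["PLANTED_DEPENDENT"] == bundle["truth"].planted_dependent
    universe = set(bundle["truth"].genes["gene_id"])
    for _, members in coll.items():
        assert members <= universe
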