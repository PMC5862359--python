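"""Simulator: unit-mean factors, conditional NB law, plate-induced correlation."""

import numpy as np
import pytest

import platesum as ps
from platesum.sim import SCENARIOS, SimulationConfig


class TestFactorSampling:
    def test_zero_sigma_gives_exact_ones(self, rng):
        assert np.all(ps.sample_plate_effects(50, 4, 0.0, rng) == 1.0)
        assert np.all(ps.sample_cell_factors(70, 0.0, rng) == 1.0)

    @pytest.mark.parametrize("sigma", [0.25, 0.5, 1.0])
    def test_plate_effects_have_unit_mean(self, sigma):
        rng = np.random.default_rng(5)
        draws = ps.sample_plate_effects(200_000, 5, sigma, rng)
        mc_se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 1.0) < 4 * mc_se

    def test_log_variance_matches_parameterization(self):
        rng = np.random.default_rng(6)
        draws = ps.sample_plate_effects(500_000, 2, 0.5, rng)
        logs = np.log(draws)
        assert np.var(logs) == pytest.approx(0.25, rel=0.02)

    def test_cell_factors_unit_mean_and_independent_of_plate_effects(self):
        rng = np.random.default_rng(7)
        delta = ps.sample_plate_effects(100_000, 1, 0.5, rng)
        theta = ps.sample_cell_factors(100_000, 0.3, rng)
        mc_se = theta.std() / np.sqrt(theta.size)
        assert abs(theta.mean() - 1.0) < 4 * mc_se
        corr = np.corrcoef(delta[:, 0], theta)[0, 1]
        assert abs(corr) < 4 / np.sqrt(theta.size)

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            ps.sample_plate_effects(10, 2, -0.1, rng)


class TestSpikeDE:
    def test_zero_fraction_all_null(self):
        cfg = ps.SimulationConfig(n_genes=100, de_fraction=0.0)
        true_de, lfc, mult = ps.spike_de(cfg)
        assert not true_de.any()
        assert np.all(lfc == 0) and np.all(mult == 1)

    def test_floor_count_and_exact_fold_changes(self):
        cfg = ps.SimulationConfig(n_genes=1000, de_fraction=0.1, de_log2fc=1.5, seed=3)
        true_de, lfc, mult = ps.spike_de(cfg)
        assert true_de.sum() == 100
        ratio = mult[:, 1] / mult[:, 0]
        assert set(np.round(np.log2(ratio[true_de]), 12)) <= {1.5, -1.5}
        assert np.array_equal(true_de, lfc != 0)

    def test_spike_requires_two_groups(self):
        with pytest.raises(ValueError):
            cfg = ps.SimulationConfig(n_genes=10, n_groups=3, de_fraction=0.5)
            ps.spike_de(cfg)


class TestSimulateDataset:
    def test_noiseless_limit_recovers_means(self):
        # no plate/cell variability, Poisson counts: sample mean ~ mu
        cfg = ps.SimulationConfig(
            n_genes=200, sigma_plate=0.0, sigma_theta=0.0, nb_dispersion=0.0,
            nb_dispersion_log_sd=0.0, sd_log_mu=1.0, seed=11,
        )
        ds = ps.simulate_dataset(cfg)
        assert np.all(ds.plate_effects == 1.0) and np.all(ds.cell_factors == 1.0)
        n = ds.counts.shape[1]
        mu_hat = ds.counts.mean(axis=1)
        # reconstruct mu from the same stream position is awkward; use the
        # Poisson relation var ~ mean instead
        var = ds.counts.var(axis=1, ddof=1)
        big = mu_hat > 5
        ratio = var[big] / mu_hat[big]
        assert abs(ratio.mean() - 1.0) < 4 * ratio.std(ddof=1) / np.sqrt(big.sum())
        assert n >= 300

    def test_default_design_shape(self):
        cfg = ps.SimulationConfig(n_genes=50, seed=0)
        ds = ps.simulate_dataset(cfg)
        n_cells = ds.counts.shape[1]
        assert 300 <= n_cells <= 600
        assert ds.design.n_plates == 6
        assert len(ds.design.groups) == 2
        assert ds.counts.min() >= 0
        assert np.issubdtype(ds.counts.dtype, np.integer)

    def test_same_seed_bit_identical(self):
        cfg = ps.scenario("default", n_genes=80, seed=42)
        a, b = ps.simulate_dataset(cfg), ps.simulate_dataset(cfg)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.plate_effects, b.plate_effects)
        assert np.array_equal(a.true_log2fc, b.true_log2fc)

    def test_conditional_nb_variance(self):
        # delta = theta = 1: empirical variance across cells ~ mu + phi mu^2
        phi = 0.4
        cfg = ps.SimulationConfig(
            n_genes=2000, sigma_plate=0.0, sigma_theta=0.0, nb_dispersion=phi,
            nb_dispersion_log_sd=0.0, mean_log_mu=np.log(50.0), sd_log_mu=0.0,
            cells_per_plate_range=(100, 100), seed=13,
        )
        ds = ps.simulate_dataset(cfg)
        mu = 50.0
        expected_var = mu + phi * mu**2
        var = ds.counts.var(axis=1, ddof=1)
        se = var.std(ddof=1) / np.sqrt(var.size)
        assert abs(var.mean() - expected_var) < 4 * se

    def test_plate_effect_induces_within_plate_correlation(self):
        def mean_within_plate_corr(sigma_plate, seed):
            cfg = ps.SimulationConfig(
                n_genes=400, sigma_plate=sigma_plate, sigma_theta=0.0,
                mean_log_mu=np.log(20.0), sd_log_mu=0.5,
                cells_per_plate_range=(40, 40), seed=seed,
            )
            ds = ps.simulate_dataset(cfg)
            x = ds.counts.astype(float)
            # residuals after removing the group mean per gene
            for g in ds.design.groups:
                mask = ds.design.cell_group == g
                x[:, mask] -= x[:, mask].mean(axis=1, keepdims=True)
            corrs = []
            plate_idx = ds.design.plate_index()
            for k in range(ds.design.n_plates):
                cols = np.flatnonzero(plate_idx == k)
                c = np.corrcoef(x[:, cols], rowvar=False)
                corrs.append(c[np.triu_indices_from(c, k=1)].mean())
            return np.mean(corrs)

        with_effect = mean_within_plate_corr(0.5, 21)
        without = mean_within_plate_corr(0.0, 22)
        assert with_effect > 0.1
        assert abs(without) < 0.02

    def test_zero_inflation_increases_zero_fraction(self):
        base = ps.simulate_dataset(ps.scenario("default", n_genes=300, seed=5))
        zinb = ps.simulate_dataset(ps.scenario("zinb", n_genes=300, seed=5))
        assert (zinb.counts == 0).mean() > (base.counts == 0).mean() + 0.1


class TestScenarios:
    def test_named_modifications(self):
        default = SimulationConfig()
        assert ps.scenario("no_plate_effect").sigma_plate == 0.0
        assert ps.scenario("half_plate_effect").sigma_plate == default.sigma_plate / 2
        assert ps.scenario("more_plates").plates_per_group > default.plates_per_group
        assert ps.scenario("variable_libsizes").sigma_theta > default.sigma_theta
        lo, hi = ps.scenario("variable_cell_numbers").cells_per_plate_range
        dlo, dhi = default.cells_per_plate_range
        assert lo < dlo and hi > dhi
        assert ps.scenario("zinb").zero_inflation == 0.2
        assert set(SCENARIOS) == {
            "default", "no_plate_effect", "half_plate_effect", "variable_libsizes",
            "variable_cell_numbers", "more_plates", "zinb",
        }

    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(ValueError, match="no_plate_effect"):
            ps.scenario("bogus")


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"cells_per_plate_range": (10, 5)},
            {"sigma_plate": -1.0},
            {"de_fraction": 1.5},
            {"zero_inflation": 1.0},
        ],
    )
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_plate_spanning_groups_rejected(self):
        with pytest.raises(ValueError, match="single group"):
            ps.PlateDesign(
                cell_plate=np.array(["P1", "P1"]), cell_group=np.array(["A", "B"])
            )
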