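"""Generative model, mean-map synthesis, and rejection-rate machinery."""

import numpy as np
import pandas as pd
import pytest

import spicetest as st


class TestMakeMeanMaps:
    @pytest.mark.parametrize("rho", [0.0, -0.15, -0.04, 0.6])
    def test_target_correlation_is_exact(self, rho):
        maps = st.make_mean_maps(500, rho, seed=3)
        assert maps.rho_empirical == pytest.approx(rho, abs=1e-10)
        assert st.similarity(maps.m1, maps.m2) == pytest.approx(
            rho, abs=1e-10
        )

    def test_large_v_matches_atlas_scale(self):
        maps = st.make_mean_maps(10_242, -0.15, seed=1)
        assert maps.n_locations == 10_242
        assert maps.rho_empirical == pytest.approx(-0.15, abs=1e-10)

    def test_maps_are_standardized(self):
        maps = st.make_mean_maps(400, -0.3, seed=5)
        for m in (maps.m1, maps.m2):
            assert m.mean() == pytest.approx(0.0, abs=1e-12)
            assert m.std() == pytest.approx(1.0, abs=1e-12)

    def test_smoothness_raises_lag1_autocorrelation(self):
        def lag1(v):
            return float(np.corrcoef(v[:-1], v[1:])[0, 1])

        rough = st.make_mean_maps(2000, -0.15, seed=8)
        smooth = st.make_mean_maps(2000, -0.15, smoothness=5.0, seed=8)
        assert lag1(smooth.m1) > lag1(rough.m1)
        assert smooth.rho_empirical == pytest.approx(-0.15, abs=1e-10)

    def test_invalid_rho_rejected(self):
        for rho in (1.0, -1.0, 1.5):
            with pytest.raises(ValueError, match="rho_target"):
                st.make_mean_maps(100, rho)

    def test_rho_empirical_field_is_validated(self):
        maps = st.make_mean_maps(100, 0.2, seed=0)
        with pytest.raises(ValueError, match="does not match"):
            st.MeanMapPair(maps.m1, maps.m2, 0.5)


class TestSimulateDataset:
    def test_seeded_reproducibility(self, mean_maps_500):
        cfg = st.SimulationConfig(
            n=10, sigma_a_sq=1.0, sigma_e_sq=1.0, mean_maps=mean_maps_500,
            seed=99,
        )
        d1 = st.simulate_dataset(cfg)
        d2 = st.simulate_dataset(cfg)
        assert np.array_equal(d1.x, d2.x) and np.array_equal(d1.y, d2.y)

    def test_null_case_rows_center_on_mean_maps(self, mean_maps_500):
        """With sigma_a^2 = 0 every subject signal equals 1, so each row is
        the mean map plus independent noise."""
        cfg = st.SimulationConfig(
            n=200, sigma_a_sq=0.0, sigma_e_sq=0.5, mean_maps=mean_maps_500,
            seed=12,
        )
        data = st.simulate_dataset(cfg)
        resid = data.x - mean_maps_500.m1[None, :]
        # residuals are pure N(0, 0.5) noise
        assert resid.mean() == pytest.approx(0.0, abs=0.01)
        assert resid.var() == pytest.approx(0.5, rel=0.05)

    def test_vanishing_noise_recovers_signed_map_correlation(
        self, mean_maps_500
    ):
        """As sigma_e^2 -> 0, each within-subject similarity approaches rho:
        both maps scale by the same a_i, and Pearson correlation is
        invariant to a common (even negative) rescaling."""
        cfg = st.SimulationConfig(
            n=30, sigma_a_sq=3.0, sigma_e_sq=1e-12, mean_maps=mean_maps_500,
            seed=21,
        )
        data = st.simulate_dataset(cfg)
        rho = mean_maps_500.rho_empirical
        for i in range(cfg.n):
            r = st.similarity(data.x[i], data.y[i])
            assert r == pytest.approx(rho, abs=1e-4)

    def test_within_exceeds_between_under_alternative(self, mean_maps_500):
        cfg = st.SimulationConfig(
            n=40, sigma_a_sq=2.0, sigma_e_sq=1.0, mean_maps=mean_maps_500,
            seed=5,
        )
        data = st.simulate_dataset(cfg)
        c = st.cross_similarity_matrix(data)
        within = np.abs(np.diag(c)).mean()
        off = np.abs(c[~np.eye(cfg.n, dtype=bool)]).mean()
        assert within > off

    def test_config_validation(self, mean_maps_500):
        with pytest.raises(ValueError):
            st.SimulationConfig(
                n=1, sigma_a_sq=0, sigma_e_sq=1, mean_maps=mean_maps_500
            )
        with pytest.raises(ValueError):
            st.SimulationConfig(
                n=5, sigma_a_sq=-0.1, sigma_e_sq=1, mean_maps=mean_maps_500
            )
        with pytest.raises(ValueError):
            st.SimulationConfig(
                n=5, sigma_a_sq=0, sigma_e_sq=0.0, mean_maps=mean_maps_500
            )


class TestRejectionRate:
    def test_single_replicate_is_bernoulli(self, mean_maps_500):
        cfg = st.SimulationConfig(
            n=10, sigma_a_sq=0.5, sigma_e_sq=1.0, mean_maps=mean_maps_500,
            n_replicates=1, k_permutations=99, seed=1,
        )
        res = st.rejection_rate(cfg)
        assert res.rate in (0.0, 1.0)
        assert res.se == 0.0

    def test_replicates_rerunnable_in_isolation(self, mean_maps_500):
        """The documented per-replicate seed derivation reproduces any single
        replicate's p-value outside rejection_rate."""
        cfg = st.SimulationConfig(
            n=15, sigma_a_sq=1.0, sigma_e_sq=1.0, mean_maps=mean_maps_500,
            n_replicates=5, k_permutations=49, seed=31,
        )
        res = st.rejection_rate(cfg)
        for r in range(cfg.n_replicates):
            sim_seed, perm_seed = st.replicate_seed_pair(cfg.seed, r)
            data = st.simulate_dataset(cfg, np.random.default_rng(sim_seed))
            single = st.spice_test(data, k=cfg.k_permutations, seed=perm_seed)
            assert single.p_value == res.p_values[r]

    def test_strong_signal_power_near_one(self, mean_maps_500):
        cfg = st.SimulationConfig(
            n=100, sigma_a_sq=3.0, sigma_e_sq=0.5, mean_maps=mean_maps_500,
            n_replicates=50, k_permutations=199, seed=8,
        )
        res = st.rejection_rate(cfg)
        assert res.rate >= 0.95


class TestPowerGrid:
    def test_long_format_schema_and_determinism(self, mean_maps_500):
        configs = st.make_grid(
            ns=[10, 20],
            sigma_a_sqs=[0.0, 2.0],
            sigma_e_sqs=[1.0],
            mean_maps=mean_maps_500,
            n_replicates=10,
            k_permutations=49,
            seed=77,
        )
        t1 = st.power_grid(configs)
        t2 = st.power_grid(configs)
        assert list(t1.columns) == [
            "n", "sigma_a_sq", "sigma_e_sq", "rho", "alpha", "replicates",
            "rejections", "rate", "se", "seed",
        ]
        assert len(t1) == 4
        pd.testing.assert_frame_equal(t1, t2)
        assert (t1["rho"] == mean_maps_500.rho_empirical).all()

    def test_tsv_round_trip(self, mean_maps_500, tmp_path):
        configs = st.make_grid(
            [5], [0.0], [1.0], mean_maps_500, n_replicates=4,
            k_permutations=19, seed=3,
        )
        table = st.power_grid(configs)
        out = tmp_path / "grid.tsv"
        from spicetest.simulation import write_grid_tsv

        write_grid_tsv(table, out)
        back = pd.read_csv(out, sep="\t")
        assert list(back.columns) == list(table.columns)
        assert back.shape == table.shape

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            st.power_grid([])

    def test_grid_spec_parsing(self, tmp_path):
        from spicetest.simulation import read_grid_spec

        spec_file = tmp_path / "grid.yaml"
        spec_file.write_text(
            "n: [10, 20]\nsigma_a_sq: 0.5\nsigma_e_sq: [1.0]\n"
            "rho: -0.15\nreplicates: 5\nseed: 4\n"
        )
        spec = read_grid_spec(spec_file)
        assert spec["n"] == [10, 20]
        assert spec["sigma_a_sq"] == [0.5]
        assert spec["rho"] == [-0.15]
        assert spec["replicates"] == 5
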