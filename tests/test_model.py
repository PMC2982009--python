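import numpy as np
import pytest

from ecoturnover import (
    SimulationConfig,
    SpeciesProfile,
    alpha_sweep,
    ar1_filter,
    default_alpha_grid,
    pairwise_median_r,
    simulate_assemblage,
    simulate_species,
)


def _profiles(means, sds):
    return [
        SpeciesProfile(f"s{i}", m, s, 1.0) for i, (m, s) in enumerate(zip(means, sds))
    ]


class TestSimulateSpecies:
    def test_zero_noise_is_constant_at_the_mean(self):
        p = SpeciesProfile("a", 4.0, 0.0, 1.0)
        out = simulate_species(0.6, p, rng=np.random.default_rng(0))
        assert np.allclose(out, 4.0)
        assert out.shape == (30,)

    def test_white_noise_moments(self):
        # alpha = 0: kept states are iid Normal(mean, sd)
        p = SpeciesProfile("a", 10.0, 2.0, 1.0)
        rng = np.random.default_rng(1)
        draws = np.concatenate(
            [
                simulate_species(0.0, p, rng=rng, clamp_negative=False)
                for _ in range(400)
            ]
        )
        assert draws.mean() == pytest.approx(10.0, abs=0.1)
        assert draws.std(ddof=1) == pytest.approx(2.0, abs=0.1)

    def test_stationary_variance_recovery(self):
        # long-run variance sd^2 / (1 - alpha^2)
        p = SpeciesProfile("a", 0.0, 1.0, 1.0)
        out = simulate_species(
            0.6,
            p,
            years_total=4000,
            years_keep=2000,
            rng=np.random.default_rng(2),
            clamp_negative=False,
        )
        assert np.var(out, ddof=1) == pytest.approx(1 / (1 - 0.36), rel=0.1)

    def test_years_keep_exceeding_total_is_an_error(self):
        with pytest.raises(ValueError):
            simulate_species(0.0, SpeciesProfile("a", 1, 1, 1), 10, 20)

    def test_clamp_policy(self):
        p = SpeciesProfile("a", 0.0, 5.0, 1.0)
        clamped = simulate_species(0.0, p, rng=np.random.default_rng(3))
        raw = simulate_species(
            0.0, p, rng=np.random.default_rng(3), clamp_negative=False
        )
        assert clamped.min() >= 0
        assert raw.min() < 0
        assert np.array_equal(clamped, np.maximum(raw, 0))


class TestSimulateAssemblage:
    def test_zero_noise_matrix_of_means(self):
        sim = simulate_assemblage(
            _profiles([3.0, 8.0], [0.0, 0.0]), 0.2, rng=np.random.default_rng(0)
        )
        assert np.allclose(sim.matrix.values[0], 3.0)
        assert np.allclose(sim.matrix.values[1], 8.0)

    def test_species_independence_at_alpha_zero(self):
        sim = simulate_assemblage(
            _profiles([100.0] * 40, [10.0] * 40), 0.0, rng=np.random.default_rng(4)
        )
        r, _, _ = pairwise_median_r(sim.matrix)
        assert abs(r + 1 / 29) < 0.05  # near the permutation-null centre -1/(n-1)

    def test_empty_profiles_is_an_error(self):
        with pytest.raises(ValueError):
            simulate_assemblage([], 0.0)

    def test_ar1_filter_recursion(self):
        z = np.array([1.0, 2.0, 3.0])
        y = ar1_filter(z, 0.5)
        assert np.allclose(y, [1.0, 2.5, 4.25])


class TestAlphaSweep:
    def test_default_grid_has_41_values(self):
        grid = default_alpha_grid()
        assert len(grid) == 41
        assert grid[0] == -1.0 and grid[-1] == 1.0
        assert np.allclose(np.diff(grid), 0.05)

    def test_deterministic_degenerate_case(self):
        # sd = 0 everywhere: predicted N1 equals N1 of the means vector
        from ecoturnover import hill_n1

        profs = _profiles([4.0, 2.0, 1.0, 1.0], [0.0] * 4)
        cfg = SimulationConfig(alpha_grid=np.array([0.0]), n_replicates=1, seed=0)
        sweep = alpha_sweep(profs, cfg, metric_names=("N1",))
        assert sweep.mean.loc[0.0, "N1"] == pytest.approx(hill_n1([4, 2, 1, 1]))

    def test_fixed_seed_bit_identical_and_grid_stable(self):
        profs = _profiles([10.0, 5.0, 2.0], [2.0, 1.0, 0.5])
        cfg = SimulationConfig(
            alpha_grid=np.array([-0.5, 0.0, 0.5]), n_replicates=20, seed=11
        )
        a = alpha_sweep(profs, cfg, metric_names=("N1", "BrayCurtis"))
        b = alpha_sweep(profs, cfg, metric_names=("N1", "BrayCurtis"))
        assert a.mean.equals(b.mean)
        # removing a grid point leaves the other cells untouched
        cfg2 = SimulationConfig(alpha_grid=np.array([0.0, 0.5]), n_replicates=20, seed=11)
        c = alpha_sweep(profs, cfg2, metric_names=("N1", "BrayCurtis"))
        assert np.allclose(c.mean.loc[0.5], a.mean.loc[0.5])

    def test_extreme_alpha_skips_degenerate_years_not_errors(self):
        profs = _profiles([1.0, 0.5], [2.0, 2.0])
        cfg = SimulationConfig(alpha_grid=np.array([1.0]), n_replicates=5, seed=3)
        sweep = alpha_sweep(profs, cfg, metric_names=("N1", "MRS"))
        assert int(sweep.n_skipped.loc[1.0, "N1"]) > 0

    def test_tidy_frame_shape(self):
        profs = _profiles([10.0, 5.0], [1.0, 1.0])
        cfg = SimulationConfig(alpha_grid=np.array([0.0, 0.5]), n_replicates=5, seed=1)
        sweep = alpha_sweep(profs, cfg, metric_names=("N1", "MRS"))
        frame = sweep.to_frame()
        assert set(frame.columns) == {"alpha", "metric", "mean", "rep_sd", "n_skipped"}
        assert len(frame) == 4

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            alpha_sweep(_profiles([1.0], [0.0]), metric_names=("nope",))
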