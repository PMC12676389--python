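"""Generator contracts: signal model, stationarity, determinism, patterns."""

import numpy as np
import pytest
from pydantic import ValidationError

from smfretglue.config import MovieConfig, PatternConfig, SimulationConfig
from smfretglue.simulate import (
    simulate_movie,
    simulate_particle_pattern,
    simulate_traces,
)


class TestTraceSignalModel:
    def test_symmetric_state_splits_intensity_equally(self, noise_free_config):
        traces, _ = simulate_traces(noise_free_config, 1)
        np.testing.assert_allclose(traces[0].donor_raw, 500.0)
        np.testing.assert_allclose(traces[0].acceptor_raw, 500.0)

    def test_leakage_fraction_of_donor_appears_in_acceptor(self, noise_free_config):
        cfg = noise_free_config.model_copy(
            update={"state_means": (0.0,), "leakage_alpha": 0.07}
        )
        traces, _ = simulate_traces(cfg, 1)
        np.testing.assert_allclose(traces[0].donor_raw, 1000.0)
        np.testing.assert_allclose(traces[0].acceptor_raw, 70.0)

    @pytest.mark.parametrize("gamma", [0.5, 1.0, 2.5])
    def test_gamma_weighted_total_is_conserved(self, noise_free_config, gamma):
        """gamma*Id + Ia == I_tot per frame without bleaching/noise/leakage."""
        cfg = noise_free_config.model_copy(
            update={
                "state_means": (0.5, 0.9),
                "state_occupancies": (0.25, 0.75),
                "gamma_range": (gamma, gamma),
            }
        )
        traces, _ = simulate_traces(cfg, 3)
        for tr in traces:
            np.testing.assert_allclose(
                gamma * tr.donor_raw + tr.acceptor_raw, 1000.0, rtol=1e-12
            )

    def test_two_state_occupancy_matches_stationary_distribution(self):
        """Long-run state occupancy vs the closed-form stationary distribution
        of the symmetric 2-state chain (rates 0.5/s each way -> pi = 1/2)."""
        cfg = SimulationConfig(
            state_means=(0.3, 0.8),
            state_occupancies=(0.5, 0.5),
            transition_rates=((0.0, 0.5), (0.5, 0.0)),
            donor_bleach_lifetime=1e9,
            acceptor_bleach_lifetime=1e9,
            shot_noise=False,
            read_noise_sigma=0.0,
            background_level=0.0,
            leakage_alpha=0.0,
            gamma_range=(1.0, 1.0),
            n_frames_donor_exc=500,
            seed=7,
        )
        _, truth = simulate_traces(cfg, 20)  # 10 000 molecule-frames
        states = np.concatenate([m.states for m in truth.molecules])
        occ = np.mean(states == 1)
        # binomial sampling error with ~frame-correlation inflation
        n_eff = states.size * cfg.frame_period * 1.0  # ~1 independent sample/s
        se = np.sqrt(0.25 / n_eff)
        assert abs(occ - 0.5) < 4 * se

    def test_bleach_truth_within_donor_segment(self):
        cfg = SimulationConfig(seed=3, n_frames_donor_exc=300)
        _, truth = simulate_traces(cfg, 50)
        for m in truth.molecules:
            for b in (m.acceptor_bleach_frame, m.donor_bleach_frame):
                assert b is None or 0 <= b < 300

    def test_determinism_same_seed_identical(self):
        cfg = SimulationConfig(seed=11)
        t1, _ = simulate_traces(cfg, 5)
        t2, _ = simulate_traces(cfg, 5)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.donor_raw, b.donor_raw)
            np.testing.assert_array_equal(a.acceptor_raw, b.acceptor_raw)
            np.testing.assert_array_equal(a.direct_acceptor, b.direct_acceptor)


class TestConfigValidation:
    def test_occupancies_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="state_occupancies"):
            SimulationConfig(state_means=(0.3, 0.8), state_occupancies=(0.3, 0.3))

    def test_negative_rates_rejected(self):
        with pytest.raises(ValidationError, match="transition_rates"):
            SimulationConfig(
                state_means=(0.3, 0.8),
                state_occupancies=(0.5, 0.5),
                transition_rates=((0.0, -1.0), (0.5, 0.0)),
            )

    def test_leakage_alpha_bounds(self):
        with pytest.raises(ValidationError, match="leakage_alpha"):
            SimulationConfig(leakage_alpha=1.5)

    def test_frame_counts_positive(self):
        with pytest.raises(ValidationError, match="frame counts"):
            SimulationConfig(n_frames_donor_exc=0)


class TestMovie:
    def test_zero_molecules_gives_flat_background(self):
        cfg = SimulationConfig(seed=0, n_frames_donor_exc=5, n_frames_acceptor_exc=2)
        movie, _ = simulate_movie(cfg, MovieConfig(noise_free=True, image_shape=(64, 64)), 0)
        np.testing.assert_allclose(movie.donor, cfg.background_level)
        np.testing.assert_allclose(movie.acceptor, cfg.background_level)

    def test_aperture_recovers_most_of_spot_mass(self, noise_free_config):
        """Sum over a 7-px-diameter aperture captures >= 98% of a sigma=1.2
        Gaussian spot (analytic mass within r=3.5: 1 - exp(-r^2/2 sigma^2))."""
        cfg = noise_free_config.model_copy(update={"n_frames_donor_exc": 30})
        movie, truth = simulate_movie(
            cfg, MovieConfig(noise_free=True, image_shape=(64, 64)), 1
        )
        x, y = truth.molecules[0].position_donor
        yy, xx = np.mgrid[0:64, 0:64]
        mask = (xx - x) ** 2 + (yy - y) ** 2 <= 3.5**2
        total = movie.donor[0][mask].sum() - cfg.background_level * mask.sum()
        analytic = 1 - np.exp(-(3.5**2) / (2 * 1.2**2))
        assert total / 500.0 >= 0.98 * analytic
        assert total / 500.0 >= 0.98  # whole-number floor used by the extraction stage

    def test_channel_transform_maps_truth_positions_exactly(self):
        cfg = SimulationConfig(seed=5, n_frames_donor_exc=5, n_frames_acceptor_exc=2)
        mconf = MovieConfig(noise_free=True, image_shape=(128, 128))
        _, truth = simulate_movie(cfg, mconf, 10)
        t = mconf.transform_matrix()
        for m in truth.molecules:
            x, y = m.position_donor
            mapped = t @ np.array([x, y, 1.0])
            np.testing.assert_allclose(mapped[:2], m.position_acceptor, atol=1e-12)

    def test_movie_determinism(self):
        cfg = SimulationConfig(seed=2, n_frames_donor_exc=20, n_frames_acceptor_exc=2)
        mconf = MovieConfig(image_shape=(96, 96))
        m1, _ = simulate_movie(cfg, mconf, 8)
        m2, _ = simulate_movie(cfg, mconf, 8)
        np.testing.assert_array_equal(m1.donor, m2.donor)
        np.testing.assert_array_equal(m1.acceptor, m2.acceptor)

    def test_placement_error_when_too_crowded(self):
        cfg = SimulationConfig(seed=0, n_frames_donor_exc=5, n_frames_acceptor_exc=1)
        with pytest.raises(ValueError, match="could not place"):
            simulate_movie(
                cfg, MovieConfig(image_shape=(64, 64), min_separation=30.0), 50
            )


class TestParticlePattern:
    def test_fixed_cluster_sizes_recorded_in_truth(self):
        conf = PatternConfig(
            n_clusters=3, cluster_sigma=20.0, field_size=(5000.0, 5000.0),
            min_center_separation_factor=25.0,
        )
        pattern, truth = simulate_particle_pattern(conf, seed=1, cluster_sizes=[2, 4, 6])
        assert truth.cluster_sizes == [2, 4, 6]
        assert len(pattern.points) == 12
        assert sorted(np.bincount(truth.point_labels).tolist()) == [2, 4, 6]

    def test_empty_pattern(self):
        conf = PatternConfig(n_clusters=0, background_density=0.0)
        pattern, truth = simulate_particle_pattern(conf, seed=0)
        assert len(pattern.points) == 0

    def test_shifted_poisson_mean_size(self):
        """Sizes ~ 1 + Poisson(5): empirical mean within 3 SE of 6."""
        conf = PatternConfig(
            n_clusters=100, cluster_size_mean=6.0, field_size=(60000.0, 60000.0)
        )
        _, truth = simulate_particle_pattern(conf, seed=4)
        sizes = np.asarray(truth.cluster_sizes, dtype=float)
        se = np.sqrt(5.0 / 100)
        assert abs(sizes.mean() - 6.0) < 3 * se

    def test_background_points_are_singleton_labels(self):
        conf = PatternConfig(
            n_clusters=2, background_density=1.0, field_size=(5000.0, 5000.0),
        )
        pattern, truth = simulate_particle_pattern(conf, seed=2)
        bg = truth.point_labels[truth.point_labels >= 2]
        assert len(bg) == len(set(bg.tolist()))
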