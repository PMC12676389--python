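"""FRET efficiency, histogram conventions, mixture fitting, idealization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smfretglue.fret import (
    HIST_RANGE,
    N_BINS,
    compute_fret,
    ensemble_histogram,
    fit_two_gaussian,
    idealize_trace,
    molecule_histogram,
    population_fractions,
)
from smfretglue.types import EnsembleHistogram, FretTrace


def hist_from_samples(samples_per_molecule):
    fts = [
        FretTrace(molecule_id=f"m{i}", efficiency=np.asarray(e), n_excluded=0)
        for i, e in enumerate(samples_per_molecule)
    ]
    return ensemble_histogram(fts)


class TestComputeFret:
    @pytest.mark.parametrize(
        "ia, idn, gamma, expected",
        [
            (100.0, 100.0, 1.0, 0.5),
            (0.0, 100.0, 1.0, 0.0),
            (100.0, 25.0, 2.0, 100.0 / 150.0),
        ],
    )
    def test_printed_formula(self, ia, idn, gamma, expected):
        assert compute_fret(ia, idn, gamma) == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_is_nan(self):
        e = compute_fret(np.array([0.0, 10.0]), np.array([0.0, 10.0]), 1.0)
        assert np.isnan(e[0]) and np.isfinite(e[1])

    def test_gamma_must_be_positive(self):
        with pytest.raises(ValueError):
            compute_fret(1.0, 1.0, 0.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        ia=st.floats(0.1, 1e4),
        idn=st.floats(0.1, 1e4),
        gamma=st.floats(0.1, 10.0),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, ia, idn, gamma, c):
        assert compute_fret(c * ia, c * idn, gamma) == pytest.approx(
            compute_fret(ia, idn, gamma), rel=1e-12
        )


class TestMoleculeHistogram:
    def test_all_values_at_half_fall_in_bin_15(self):
        hist, n_out = molecule_histogram(np.full(100, 0.50))
        assert n_out == 0
        assert hist[15] == 1.0
        assert hist.sum() == pytest.approx(1.0)

    def test_left_edge_inclusive(self):
        hist, _ = molecule_histogram(np.array([-0.25]))
        assert hist[0] == 1.0

    def test_right_edge_closed(self):
        hist, _ = molecule_histogram(np.array([1.25]))
        assert hist[29] == 1.0

    def test_out_of_range_counted_and_mass_conserved(self):
        values = np.array([0.5, 0.5, 2.0, -1.0])
        hist, n_out = molecule_histogram(values)
        assert n_out == 2
        assert hist.sum() == pytest.approx(1.0)

    def test_no_in_range_values_raises(self):
        with pytest.raises(ValueError):
            molecule_histogram(np.array([5.0]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_normalization_property(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0.6, 0.4, 200)
        in_range = ((values >= HIST_RANGE[0]) & (values <= HIST_RANGE[1])).sum()
        if in_range == 0:
            return
        hist, n_out = molecule_histogram(values)
        assert hist.shape == (N_BINS,)
        assert hist.sum() == pytest.approx(1.0, abs=1e-9)
        assert in_range + n_out == 200


class TestEnsembleHistogram:
    def test_single_molecule_equals_its_histogram_with_zero_sem(self):
        e = np.array([0.5, 0.5, 0.9])
        hist = hist_from_samples([e])
        expected, _ = molecule_histogram(e)
        np.testing.assert_allclose(hist.ensemble_mean, expected)
        np.testing.assert_allclose(hist.ensemble_sem, 0.0)

    def test_two_concentrated_molecules_average_to_half_each(self):
        lo = HIST_RANGE[0]
        width = (HIST_RANGE[1] - HIST_RANGE[0]) / N_BINS
        e5 = np.full(10, lo + 5.5 * width)
        e25 = np.full(10, lo + 25.5 * width)
        hist = hist_from_samples([e5, e25])
        assert hist.ensemble_mean[5] == pytest.approx(0.5)
        assert hist.ensemble_mean[25] == pytest.approx(0.5)
        assert hist.ensemble_mean.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_analytic_mixture_density(self):
        """200 molecules drawn from 0.3 N(0.4, 0.05) + 0.7 N(0.9, 0.05): the
        ensemble histogram matches the analytically binned mixture within
        3x the binomial standard error per bin."""
        from scipy.stats import norm

        rng = np.random.default_rng(8)
        n_mol, n_frames = 200, 150
        samples = []
        for _ in range(n_mol):
            comp = rng.random(n_frames) < 0.3
            e = np.where(
                comp, rng.normal(0.4, 0.05, n_frames), rng.normal(0.9, 0.05, n_frames)
            )
            samples.append(e)
        hist = hist_from_samples(samples)
        edges = hist.bin_edges
        analytic = 0.3 * np.diff(norm.cdf(edges, 0.4, 0.05)) + 0.7 * np.diff(
            norm.cdf(edges, 0.9, 0.05)
        )
        se = np.sqrt(analytic * (1 - analytic) / (n_mol * n_frames))
        assert np.all(np.abs(hist.ensemble_mean - analytic) < 3 * se + 1e-4)


class TestTwoGaussianFit:
    def make_exact_mixture(self, f_low, mu=(0.35, 0.85), sigma=(0.05, 0.05)):
        from scipy.stats import norm

        edges = np.linspace(*HIST_RANGE, N_BINS + 1)
        mass = f_low * np.diff(norm.cdf(edges, mu[0], sigma[0])) + (
            1 - f_low
        ) * np.diff(norm.cdf(edges, mu[1], sigma[1]))
        return EnsembleHistogram(
            bin_edges=edges,
            per_molecule=mass[None, :] / mass.sum(),
            ensemble_mean=mass / mass.sum(),
            ensemble_sem=np.zeros(N_BINS),
            n_molecules=1,
            n_excluded_values=0,
        )

    def test_exact_mixture_recovered(self):
        hist = self.make_exact_mixture(0.30)
        fit = fit_two_gaussian(hist)
        assert fit.means[0] == pytest.approx(0.35, abs=0.005)
        assert fit.means[1] == pytest.approx(0.85, abs=0.005)
        assert fit.fractions[0] == pytest.approx(0.30, abs=0.01)
        assert fit.fractions[1] == pytest.approx(0.70, abs=0.01)

    def test_component_ordering_enforced(self):
        hist = self.make_exact_mixture(0.30)
        fit = fit_two_gaussian(hist, init=[0.7, 0.9, 0.05, 0.3, 0.3, 0.05])
        assert fit.means[0] < fit.means[1]

    def test_single_mode_collapses_second_component(self):
        from scipy.stats import norm

        edges = np.linspace(*HIST_RANGE, N_BINS + 1)
        mass = np.diff(norm.cdf(edges, 0.9, 0.06))
        hist = EnsembleHistogram(
            bin_edges=edges, per_molecule=mass[None, :], ensemble_mean=mass,
            ensemble_sem=np.zeros(N_BINS), n_molecules=1, n_excluded_values=0,
        )
        fit = fit_two_gaussian(hist)
        assert max(fit.fractions) >= 0.99

    def test_fit_mass_self_consistency(self):
        """Integrated fitted model reproduces total histogram mass within 2%."""
        hist = self.make_exact_mixture(0.4, sigma=(0.06, 0.08))
        fit = fit_two_gaussian(hist)
        assert sum(fit.areas) == pytest.approx(hist.ensemble_mean.sum(), rel=0.02)

    def test_shared_sigma_mode(self):
        hist = self.make_exact_mixture(0.30)
        fit = fit_two_gaussian(hist, shared_sigma=True)
        assert fit.sigmas[0] == pytest.approx(fit.sigmas[1], abs=1e-9)
        assert fit.fractions[0] == pytest.approx(0.30, abs=0.02)


class TestPopulationFractions:
    def test_identical_molecules_zero_sem(self):
        rng = np.random.default_rng(0)
        e = np.concatenate([rng.normal(0.4, 0.05, 60), rng.normal(0.9, 0.05, 140)])
        hist = hist_from_samples([e] * 20)
        fit = fit_two_gaussian(hist)
        out = population_fractions(fit, hist, n_boot=50, seed=1)
        assert out.fraction_sem == (0.0, 0.0)

    def test_no_bootstrap_leaves_sem_unset(self):
        hist = hist_from_samples([np.array([0.4, 0.9, 0.9])] * 3)
        fit = fit_two_gaussian(hist)
        out = population_fractions(fit, hist, n_boot=0)
        assert out.fraction_sem is None

    def test_bootstrap_sem_tracks_molecule_variability(self):
        rng = np.random.default_rng(3)
        samples = []
        for _ in range(80):
            f = rng.uniform(0.1, 0.5)
            n = 120
            comp = rng.random(n) < f
            samples.append(
                np.where(comp, rng.normal(0.4, 0.06, n), rng.normal(0.9, 0.06, n))
            )
        hist = hist_from_samples(samples)
        fit = fit_two_gaussian(hist)
        out = population_fractions(fit, hist, n_boot=100, seed=2)
        assert out.fraction_sem is not None
        assert 0.0 < out.fraction_sem[0] < 0.1


class TestIdealize:
    def test_noiseless_alternating_states_recovered_exactly(self):
        e = np.concatenate([np.full(50, 0.3), np.full(50, 0.8)] * 2)
        path, dwells, static = idealize_trace(e, frame_period=0.1)
        assert not static
        assert dwells == [(0, 5.0), (1, 5.0), (0, 5.0), (1, 5.0)]

    def test_constant_trace_is_static(self):
        rng = np.random.default_rng(0)
        e = 0.9 + rng.normal(0, 0.05, 300)
        path, dwells, static = idealize_trace(e, frame_period=0.1)
        assert static
        assert len(dwells) == 1

    def test_dwell_times_sum_to_trace_length(self):
        rng = np.random.default_rng(1)
        e = np.where(rng.random(400) < 0.5, 0.3, 0.8) + rng.normal(0, 0.05, 400)
        path, dwells, _ = idealize_trace(e, frame_period=0.1)
        assert sum(d for _, d in dwells) == pytest.approx(40.0)

    def test_dwell_recovery_on_simulated_dynamics(self):
        """Two-state chain at 0.5/s each way, 10 frames/s: mean dwell within
        20% of 2 s (censored edge dwells excluded)."""
        from smfretglue.config import SimulationConfig
        from smfretglue.simulate import _frame_transition_matrix, _sample_states

        cfg = SimulationConfig(
            state_means=(0.3, 0.8),
            state_occupancies=(0.5, 0.5),
            transition_rates=((0.0, 0.5), (0.5, 0.0)),
        )
        p = _frame_transition_matrix(cfg)
        pi = cfg.stationary_distribution()
        rng = np.random.default_rng(5)
        dwells = []
        for _ in range(120):
            states = _sample_states(rng, p, pi, 800)
            e = np.array([0.3, 0.8])[states] + rng.normal(0, 0.06, 800)
            _, dw, static = idealize_trace(e, frame_period=0.1, seed=0)
            if not static and len(dw) > 2:
                dwells.extend(d for _, d in dw[1:-1])
        assert abs(np.mean(dwells) - 2.0) / 2.0 <= 0.20
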