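"""Registration, spot detection/pairing, and aperture trace extraction."""

import numpy as np
import pytest

from conftest import render_spot_image
from smfretglue.config import ImagingParams, MovieConfig, SimulationConfig
from smfretglue.imaging import (
    RegistrationError,
    TraceSkipped,
    detect_spots,
    extract_trace,
    pair_spots,
    register_channels,
)
from smfretglue.simulate import simulate_movie, simulate_traces
from smfretglue.types import MovieStack, SpotPair


def fiducial_positions(seed=0, n=15, shape=(200, 200), margin=25, min_sep=15):
    rng = np.random.default_rng(seed)
    pos = []
    while len(pos) < n:
        p = rng.uniform(margin, shape[0] - margin, 2)
        if all(np.hypot(*(p - q)) >= min_sep for q in pos):
            pos.append(p)
    return np.asarray(pos)


class TestRegisterChannels:
    def test_identity_for_identical_images(self):
        img = render_spot_image((200, 200), fiducial_positions())
        reg = register_channels(img, img)
        np.testing.assert_allclose(reg.transform.params, np.eye(3), atol=1e-6)
        assert reg.rms_residual < 1e-6

    def test_known_translation_recovered(self):
        pos = fiducial_positions(seed=1)
        donor = render_spot_image((200, 200), pos)
        acceptor = render_spot_image((200, 200), pos + np.array([3.0, -2.0]))
        reg = register_channels(donor, acceptor)
        # acceptor -> donor mapping undoes the shift
        assert reg.transform.params[0, 2] == pytest.approx(-3.0, abs=0.1)
        assert reg.transform.params[1, 2] == pytest.approx(2.0, abs=0.1)

    def test_known_rotation_recovered(self):
        pos = fiducial_positions(seed=2, n=12)
        theta = np.deg2rad(1.0)
        center = np.array([100.0, 100.0])
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        pos_rot = (pos - center) @ rot.T + center
        donor = render_spot_image((200, 200), pos)
        acceptor = render_spot_image((200, 200), pos_rot)
        reg = register_channels(donor, acceptor)
        rec = np.rad2deg(np.arctan2(-reg.transform.params[1, 0],
                                    reg.transform.params[0, 0]))
        assert rec == pytest.approx(1.0, abs=0.05)

    def test_too_few_fiducials_raises(self):
        img = render_spot_image((100, 100), np.array([[50.0, 50.0]]))
        with pytest.raises(RegistrationError):
            register_channels(img, img)

    def test_collinear_fiducials_raise(self):
        pos = np.array([[30.0, 50.0], [60.0, 50.0], [90.0, 50.0], [120.0, 50.0]])
        img = render_spot_image((160, 160), pos)
        with pytest.raises(RegistrationError, match="collinear"):
            register_channels(img, img)

    def test_round_trip_forward_inverse(self):
        pos = fiducial_positions(seed=3)
        donor = render_spot_image((200, 200), pos)
        acceptor = render_spot_image((200, 200), pos + np.array([1.5, 2.5]))
        reg = register_channels(donor, acceptor)
        pts = np.array([[10.0, 20.0], [100.0, 150.0], [55.5, 71.2]])
        back = reg.donor_to_acceptor(reg.acceptor_to_donor(pts))
        np.testing.assert_allclose(back, pts, atol=1e-9)


class TestDetectSpots:
    def test_flat_image_yields_nothing(self):
        assert len(detect_spots(np.full((50, 50), 7.0))) == 0

    def test_single_spot_subpixel_accuracy(self):
        img = render_spot_image((60, 60), np.array([[20.0, 30.0]]))
        spots = detect_spots(img)
        assert len(spots) == 1
        assert np.hypot(spots[0][0] - 20.0, spots[0][1] - 30.0) < 0.5

    def test_recall_precision_at_moderate_snr(self):
        """50 spots with peak SNR 8: recall and precision >= 0.95."""
        pos = fiducial_positions(seed=7, n=50, shape=(300, 300), min_sep=12)
        peak = 1000.0 / (2 * np.pi * 1.2**2)
        img = render_spot_image(
            (300, 300), pos, noise_sigma=peak / 8.0, seed=7
        )
        spots = detect_spots(img, threshold_sigma=4.0)
        matched = sum(
            np.min(np.sum((pos - s) ** 2, axis=1)) < 2.0**2 for s in spots
        )
        assert matched / 50 >= 0.95
        assert matched / max(len(spots), 1) >= 0.95

    def test_translation_equivariance(self):
        pos = fiducial_positions(seed=9, n=10)
        img = render_spot_image((200, 200), pos)
        shifted = render_spot_image((200, 200), pos + np.array([4.0, 6.0]))
        s0 = detect_spots(img)
        s1 = detect_spots(shifted)
        s0 = s0[np.lexsort(s0.T)]
        s1 = s1[np.lexsort(s1.T)]
        np.testing.assert_allclose(s1 - s0, [[4.0, 6.0]] * len(s0), atol=0.05)


class TestPairSpots:
    def _identity_reg(self):
        pos = fiducial_positions(seed=4)
        img = render_spot_image((200, 200), pos)
        return register_channels(img, img)

    def test_exact_match_pairs_all_with_zero_distance(self):
        reg = self._identity_reg()
        spots = np.array([[10.0, 10.0], [50.0, 80.0]])
        pairs = pair_spots(spots, spots, reg)
        assert all(not p.donor_only for p in pairs)
        assert all(p.pairing_distance < 1e-9 for p in pairs)

    def test_unmatched_donor_flagged_donor_only(self):
        reg = self._identity_reg()
        pairs = pair_spots(
            np.array([[10.0, 10.0], [100.0, 100.0]]),
            np.array([[10.0, 10.0]]),
            reg,
            max_pair_distance=2.0,
        )
        flags = {tuple(np.round(p.donor_xy)): p.donor_only for p in pairs}
        assert flags[(10.0, 10.0)] is False
        assert flags[(100.0, 100.0)] is True

    def test_each_acceptor_spot_used_once(self):
        reg = self._identity_reg()
        donors = np.array([[10.0, 10.0], [11.5, 10.0]])
        acceptors = np.array([[10.5, 10.0]])
        pairs = pair_spots(donors, acceptors, reg)
        assert sum(not p.donor_only for p in pairs) == 1

    def test_acceptor_only_contaminants_never_pair_without_donor(self):
        """Spots present only in the acceptor channel produce no pair."""
        reg = self._identity_reg()
        donors = np.array([[20.0, 20.0]])
        acceptors = np.array([[20.0, 20.0], [150.0, 150.0], [90.0, 40.0]])
        pairs = pair_spots(donors, acceptors, reg)
        assert len([p for p in pairs if not p.donor_only]) == 1


class TestExtractTrace:
    def _movie_from_stack(self, stack):
        n = stack.shape[0]
        return MovieStack(
            donor=stack, acceptor=stack.copy(), frame_period=0.1,
            donor_exc_range=(0, n - 1), acceptor_exc_range=(n - 1, n),
        )

    def _pair(self, x, y):
        return SpotPair(
            donor_xy=(x, y), acceptor_xy=(x, y), acceptor_xy_native=(x, y),
            pairing_distance=0.0, donor_only=False,
        )

    def test_uniform_image_nets_to_zero(self):
        stack = np.full((5, 100, 100), 13.0)
        tr = extract_trace(self._movie_from_stack(stack), self._pair(50.0, 50.0))
        np.testing.assert_allclose(tr.donor_raw - tr.bg_donor, 0.0, atol=1e-9)
        np.testing.assert_allclose(tr.acceptor_raw - tr.bg_acceptor, 0.0, atol=1e-9)

    def test_edge_spot_skipped(self):
        stack = np.zeros((5, 100, 100))
        with pytest.raises(TraceSkipped, match="edge"):
            extract_trace(self._movie_from_stack(stack), self._pair(3.0, 50.0))

    def test_crowded_spot_skipped(self):
        stack = np.zeros((5, 100, 100))
        movie = self._movie_from_stack(stack)
        others = np.array([[50.0, 50.0], [53.0, 50.0]])
        with pytest.raises(TraceSkipped, match="crowded"):
            extract_trace(movie, self._pair(50.0, 50.0), other_spots_donor=others)

    def test_noise_free_molecule_recovers_intensities_within_2pct(
        self, noise_free_config
    ):
        """Rendered E = 0.5 molecule: extracted Id ~ Ia ~ 500 per frame within
        aperture truncation (~1.5%)."""
        cfg = noise_free_config.model_copy(update={"n_frames_donor_exc": 40})
        movie, truth = simulate_movie(
            cfg, MovieConfig(noise_free=True, image_shape=(96, 96)), 1
        )
        x, y = truth.molecules[0].position_donor
        xa, ya = truth.molecules[0].position_acceptor
        pair = SpotPair(
            donor_xy=(x, y), acceptor_xy=(x, y), acceptor_xy_native=(xa, ya),
            pairing_distance=0.0, donor_only=False,
        )
        tr = extract_trace(movie, pair)
        donor = tr.donor_raw - tr.bg_donor
        acceptor = tr.acceptor_raw - tr.bg_acceptor
        np.testing.assert_allclose(donor, 500.0, rtol=0.02)
        np.testing.assert_allclose(acceptor, 500.0, rtol=0.02)

    def test_movie_trace_equivalence_with_simulated_truth(self):
        """Noise-free rendered dynamics reproduce simulate_traces output
        within 2% (aperture truncation only), correlation >= 0.99."""
        cfg = SimulationConfig(
            seed=6, shot_noise=False, read_noise_sigma=0.0, background_level=0.0,
            n_frames_donor_exc=200,
            donor_bleach_lifetime=1e9, acceptor_bleach_lifetime=1e9,
        )
        movie, truth = simulate_movie(
            cfg, MovieConfig(noise_free=True, image_shape=(128, 128)), 4
        )
        reference, _ = simulate_traces(cfg, 4)
        from smfretglue.imaging import extract_all_traces

        traces, _ = extract_all_traces(movie)
        assert len(traces) == 4
        pos = {m.molecule_id: m.position_donor for m in truth.molecules}
        for tr in traces:
            mid = min(
                pos,
                key=lambda k: (pos[k][0] - tr.spot.donor_xy[0]) ** 2
                + (pos[k][1] - tr.spot.donor_xy[1]) ** 2,
            )
            want = next(r for r in reference if r.molecule_id == mid)
            got = tr.donor_raw - tr.bg_donor
            ratio = got / np.clip(want.donor_raw, 1e-9, None)
            assert np.all(np.abs(ratio - ratio.mean()) < 0.02)
            assert ratio.mean() == pytest.approx(1.0, abs=0.02)
            if np.std(got) > 0 and np.std(want.donor_raw) > 0:
                assert np.corrcoef(got, want.donor_raw)[0, 1] >= 0.99
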