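"""Synthetic smFRET traces, two-channel TIRF movies, and gold-particle patterns.

The signal model: a molecule in a state with FRET efficiency E and
per-molecule detection-imbalance factor gamma emits expected background-free
intensities

    Ia = E * I_tot            (acceptor channel, before leakage)
    Id = (1 - E) * I_tot / gamma

so the corrected estimator Ia / (Ia + gamma * Id) returns E exactly, the
gamma-weighted total gamma*Id + Ia is conserved at I_tot through both state
transitions and acceptor photobleaching, and the standard bleach-step
estimator gamma = dIa/dId is exact on noise-free traces. Donor leakage adds
alpha * Id to the raw acceptor channel. Photobleaching is single-step
exponential per fluorophore; the acceptor bleach clock runs only while the
acceptor is excited (via FRET during the donor segment). Shot noise is
Poisson on expected counts, followed by additive Gaussian read noise.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .config import MovieConfig, PatternConfig, SimulationConfig
from .types import GoldParticleSet, GroundTruth, MoleculeTruth, MovieStack, RawTrace


def _frame_transition_matrix(config: SimulationConfig) -> np.ndarray:
    q = config.rate_matrix()
    return expm(q * config.frame_period)


def _sample_states(
    rng: np.random.Generator, p: np.ndarray, pi: np.ndarray, n_frames: int
) -> np.ndarray:
    n_states = p.shape[0]
    states = np.empty(n_frames, dtype=np.int64)
    if n_states == 1:
        states[:] = 0
        return states
    cum = np.cumsum(p, axis=1)
    states[0] = rng.choice(n_states, p=pi)
    u = rng.random(n_frames)
    for t in range(1, n_frames):
        states[t] = np.searchsorted(cum[states[t - 1]], u[t])
    return states


def _bleach_frame(rng: np.random.Generator, lifetime_s: float, frame_period: float) -> int:
    return int(rng.exponential(lifetime_s) / frame_period)


def _single_fluorophore_signal(
    rng: np.random.Generator,
    config: SimulationConfig,
    p: np.ndarray,
    pi: np.ndarray,
    gamma: float,
) -> tuple[np.ndarray, np.ndarray, bool, int | None, int | None, np.ndarray]:
    """Expected (noise-free, background-free) donor/acceptor signal of one
    donor-acceptor pair, plus acceptor survival at the end of the donor segment."""
    n = config.n_frames_donor_exc
    means = np.asarray(config.state_means, dtype=float)
    states = _sample_states(rng, p, pi, n)
    e = means[states]
    b_d = _bleach_frame(rng, config.donor_bleach_lifetime, config.frame_period)
    b_a = _bleach_frame(rng, config.acceptor_bleach_lifetime, config.frame_period)
    if b_d <= b_a:
        b_a_eff = None  # acceptor stops being excited when the donor dies
    else:
        b_a_eff = b_a if b_a < n else None
    b_d_eff = b_d if b_d < n else None
    t = np.arange(n)
    donor_alive = t < (b_d_eff if b_d_eff is not None else n)
    acceptor_alive = t < (b_a_eff if b_a_eff is not None else n)
    i_tot = config.total_intensity
    e_eff = np.where(acceptor_alive, e, 0.0)
    ia = e_eff * i_tot * donor_alive
    idn = (1.0 - e_eff) * i_tot / gamma * donor_alive
    acceptor_survives = b_a_eff is None
    return idn, ia, acceptor_survives, b_a_eff, b_d_eff, states


def _apply_noise(
    rng: np.random.Generator, expected: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    expected = np.clip(expected, 0.0, None)
    out = rng.poisson(expected).astype(float) if config.shot_noise else expected.copy()
    if config.read_noise_sigma > 0:
        out += rng.normal(0.0, config.read_noise_sigma, size=expected.shape)
    return out


def _assemble_raw_trace(
    rng: np.random.Generator,
    config: SimulationConfig,
    molecule_id: str,
    donor_sig: np.ndarray,
    acceptor_sig: np.ndarray,
    direct_sig: float,
) -> RawTrace:
    bg = config.background_level
    donor_raw = _apply_noise(rng, donor_sig + bg, config)
    acceptor_raw = _apply_noise(
        rng, acceptor_sig + config.leakage_alpha * donor_sig + bg, config
    )
    direct = _apply_noise(
        rng, np.full(config.n_frames_acceptor_exc, direct_sig + bg), config
    )
    noise_sigma = float(np.sqrt(config.read_noise_sigma**2 + max(bg, 0.0)))
    return RawTrace(
        molecule_id=molecule_id,
        donor_raw=donor_raw,
        acceptor_raw=acceptor_raw,
        bg_donor=np.full(len(donor_raw), bg),
        bg_acceptor=np.full(len(donor_raw), bg),
        frame_period=config.frame_period,
        direct_acceptor=direct,
        direct_bg_mean=bg,
        direct_bg_sigma=noise_sigma,
    )


def simulate_traces(
    config: SimulationConfig, n_molecules: int
) -> tuple[list[RawTrace], GroundTruth]:
    """Generate per-molecule raw intensity traces with full ground truth.

    Randomness flows from ``config.seed`` through per-molecule sub-streams, so
    outputs are reproducible and independent of generation order.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    root = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(root.spawn(1)[0])
    children = root.spawn(n_molecules + 1)[1:]
    p = _frame_transition_matrix(config)
    pi = config.stationary_distribution()

    cf = config.contaminant_fractions
    classes = master.choice(
        ["donor_only", "acceptor_only", "aggregate", "good"],
        size=n_molecules,
        p=[cf.donor_only, cf.acceptor_only, cf.aggregate,
           1.0 - cf.donor_only - cf.acceptor_only - cf.aggregate],
    )

    traces: list[RawTrace] = []
    truth = GroundTruth()
    lo, hi = config.gamma_range
    n = config.n_frames_donor_exc
    for m in range(n_molecules):
        rng = np.random.default_rng(children[m])
        mol_id = f"mol{m:05d}"
        gamma = float(rng.uniform(lo, hi))
        mclass = str(classes[m])
        states = None
        if mclass == "good":
            idn, ia, acc_alive, b_a, b_d, states = _single_fluorophore_signal(
                rng, config, p, pi, gamma
            )
            direct = config.total_intensity if acc_alive else 0.0
        elif mclass == "donor_only":
            b_d = _bleach_frame(rng, config.donor_bleach_lifetime, config.frame_period)
            b_d = b_d if b_d < n else None
            alive = np.arange(n) < (b_d if b_d is not None else n)
            idn = config.total_intensity / gamma * alive
            ia = np.zeros(n)
            b_a, direct = None, 0.0
        elif mclass == "acceptor_only":
            # no donor: dark during donor excitation, bright under direct excitation
            idn = np.zeros(n)
            ia = np.zeros(n)
            b_a, b_d, direct = None, None, config.total_intensity
        else:  # aggregate: 2-3 independent donor-acceptor pairs at one spot
            k = int(rng.integers(2, 4))
            idn = np.zeros(n)
            ia = np.zeros(n)
            n_alive = 0
            b_a_list, b_d_list = [], []
            for _ in range(k):
                d1, a1, alive1, ba1, bd1, _ = _single_fluorophore_signal(
                    rng, config, p, pi, gamma
                )
                idn += d1
                ia += a1
                n_alive += int(alive1)
                if ba1 is not None:
                    b_a_list.append(ba1)
                if bd1 is not None:
                    b_d_list.append(bd1)
            direct = config.total_intensity * n_alive
            b_a = max(b_a_list) if b_a_list else None
            b_d = max(b_d_list) if b_d_list else None
        traces.append(_assemble_raw_trace(rng, config, mol_id, idn, ia, direct))
        truth.molecules.append(
            MoleculeTruth(
                molecule_id=mol_id,
                mclass=mclass,
                gamma=gamma,
                acceptor_bleach_frame=b_a,
                donor_bleach_frame=b_d,
                states=states,
            )
        )
    return traces, truth


def synthesize_trace(
    donor_levels: list[tuple[int, float]],
    acceptor_levels: list[tuple[int, float]],
    n_frames: int,
    noise_sigma: float = 0.0,
    background: float = 0.0,
    leakage_alpha: float = 0.0,
    direct_signal: float = 0.0,
    n_direct: int = 10,
    frame_period: float = 0.1,
    molecule_id: str = "synthetic",
    seed: int = 0,
) -> RawTrace:
    """Hand-built piecewise-constant RawTrace for targeted tests.

    ``*_levels`` are (start_frame, level) pairs of the *true* per-channel
    signals; each level holds until the next start frame. ``leakage_alpha``
    adds the donor leakage a real raw acceptor trace would carry. Gaussian
    noise only (no shot noise) so the noise scale is exact.
    """
    rng = np.random.default_rng(seed)

    def build(levels: list[tuple[int, float]]) -> np.ndarray:
        x = np.zeros(n_frames)
        for i, (start, level) in enumerate(levels):
            stop = levels[i + 1][0] if i + 1 < len(levels) else n_frames
            x[start:stop] = level
        return x

    donor_sig = build(donor_levels)
    donor = donor_sig + background
    acceptor = build(acceptor_levels) + leakage_alpha * donor_sig + background
    if noise_sigma > 0:
        donor = donor + rng.normal(0, noise_sigma, n_frames)
        acceptor = acceptor + rng.normal(0, noise_sigma, n_frames)
    direct = np.full(n_direct, direct_signal + background)
    if noise_sigma > 0:
        direct = direct + rng.normal(0, noise_sigma, n_direct)
    return RawTrace(
        molecule_id=molecule_id,
        donor_raw=donor,
        acceptor_raw=acceptor,
        bg_donor=np.full(n_frames, background),
        bg_acceptor=np.full(n_frames, background),
        frame_period=frame_period,
        direct_acceptor=direct,
        direct_bg_mean=background,
        direct_bg_sigma=noise_sigma,
    )


# ---------------------------------------------------------------------------
# movie rendering


def _place_positions(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_sep: float,
    margin: float,
    max_tries: int = 20000,
) -> np.ndarray:
    h, w = shape
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise ValueError("image too small for the requested edge margin")
    positions: list[tuple[float, float]] = []
    tries = 0
    while len(positions) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} molecules with min separation {min_sep}"
            )
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in positions):
            positions.append((x, y))
    return np.asarray(positions, dtype=float).reshape(-1, 2)


def _render_spots(
    stack: np.ndarray,
    positions: np.ndarray,
    intensities: np.ndarray,
    psf_sigma: float,
) -> None:
    """Add diffraction-limited Gaussian spots in place.

    ``intensities`` has shape (T, n_spots): total counts per frame per spot.
    """
    t_dim, h, w = stack.shape
    r = int(np.ceil(4 * psf_sigma)) + 1
    for k, (x, y) in enumerate(positions):
        x0, y0 = int(round(x)), int(round(y))
        xs = np.arange(max(0, x0 - r), min(w, x0 + r + 1))
        ys = np.arange(max(0, y0 - r), min(h, y0 + r + 1))
        gx = np.exp(-((xs - x) ** 2) / (2 * psf_sigma**2))
        gy = np.exp(-((ys - y) ** 2) / (2 * psf_sigma**2))
        template = np.outer(gy, gx) / (2 * np.pi * psf_sigma**2)
        stack[:, ys[0]:ys[-1] + 1, xs[0]:xs[-1] + 1] += (
            intensities[:, k, None, None] * template[None, :, :]
        )


def simulate_movie(
    config: SimulationConfig,
    movie: MovieConfig,
    n_molecules: int,
) -> tuple[MovieStack, GroundTruth]:
    """Render simulated molecules as two-channel TIRF stacks.

    Donor-channel positions are drawn with a minimum separation; acceptor
    positions follow the configured donor->acceptor affine exactly, so
    registration and pairing are testable against known truth. Registration
    images (all spots bright, noise-free) are attached to the stack.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    h, w = movie.image_shape
    tmat = movie.transform_matrix()
    pos_d = _place_positions(
        rng, n_molecules, (h, w), movie.min_separation, movie.edge_margin
    )
    pos_a = (
        (tmat @ np.column_stack([pos_d, np.ones(len(pos_d))]).T).T[:, :2]
        if len(pos_d)
        else pos_d
    )
    if pos_a.size and (
        pos_a[:, 0].min() < 2 or pos_a[:, 1].min() < 2
        or pos_a[:, 0].max() > w - 3 or pos_a[:, 1].max() > h - 3
    ):
        raise ValueError("channel transform pushes spots outside the image")

    noisefree = SimulationConfig(
        **{**config.model_dump(), "shot_noise": False, "read_noise_sigma": 0.0,
           "background_level": 0.0}
    )
    traces, truth = simulate_traces(noisefree, max(n_molecules, 1))
    n_don = config.n_frames_donor_exc
    n_acc = config.n_frames_acceptor_exc
    n_tot = n_don + n_acc
    donor_stack = np.full((n_tot, h, w), config.background_level, dtype=np.float64)
    acceptor_stack = np.full((n_tot, h, w), config.background_level, dtype=np.float64)

    if n_molecules > 0:
        donor_int = np.zeros((n_tot, n_molecules))
        acceptor_int = np.zeros((n_tot, n_molecules))
        for k, tr in enumerate(traces[:n_molecules]):
            donor_sig = tr.donor_raw  # noise- and background-free by construction
            acceptor_sig = tr.acceptor_raw  # includes donor leakage
            donor_int[:n_don, k] = donor_sig
            acceptor_int[:n_don, k] = acceptor_sig
            acceptor_int[n_don:, k] = np.mean(tr.direct_acceptor) if n_acc else 0.0
            truth.molecules[k].position_donor = (float(pos_d[k, 0]), float(pos_d[k, 1]))
            truth.molecules[k].position_acceptor = (
                float(pos_a[k, 0]), float(pos_a[k, 1])
            )
        _render_spots(donor_stack, pos_d, donor_int, movie.psf_sigma)
        _render_spots(acceptor_stack, pos_a, acceptor_int, movie.psf_sigma)

    if not movie.noise_free:
        if config.shot_noise:
            donor_stack = rng.poisson(np.clip(donor_stack, 0, None)).astype(np.float64)
            acceptor_stack = rng.poisson(
                np.clip(acceptor_stack, 0, None)
            ).astype(np.float64)
        if movie.pixel_read_noise > 0:
            donor_stack += rng.normal(0, movie.pixel_read_noise, donor_stack.shape)
            acceptor_stack += rng.normal(
                0, movie.pixel_read_noise, acceptor_stack.shape
            )

    reg_d = np.full((h, w), config.background_level, dtype=np.float64)
    reg_a = np.full((h, w), config.background_level, dtype=np.float64)
    if n_molecules > 0:
        amp = np.full((1, n_molecules), movie.registration_spot_intensity)
        _render_spots(reg_d[None, :, :], pos_d, amp, movie.psf_sigma)
        _render_spots(reg_a[None, :, :], pos_a, amp, movie.psf_sigma)

    stack = MovieStack(
        donor=donor_stack,
        acceptor=acceptor_stack,
        frame_period=config.frame_period,
        donor_exc_range=(0, n_don),
        acceptor_exc_range=(n_don, n_tot),
        reg_donor=reg_d,
        reg_acceptor=reg_a,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# gold-particle point patterns


def simulate_particle_pattern(
    config: PatternConfig,
    seed: int = 0,
    image_id: str = "img0",
    condition_label: str = "vehicle",
    cluster_sizes: list[int] | None = None,
) -> tuple[GoldParticleSet, GroundTruth]:
    """Clustered 2D point pattern with known per-point cluster membership.

    Cluster centers are separated by at least
    ``min_center_separation_factor * cluster_sigma``; members scatter
    isotropically (Gaussian, sigma = cluster_sigma) around their center.
    Background points are uniform with the given density (per square micron)
    and labeled as singletons.
    """
    rng = np.random.default_rng(seed)
    w, h = config.field_size
    sep = config.min_center_separation_factor * config.cluster_sigma
    margin = 4 * config.cluster_sigma
    if config.n_clusters > 0 and (w - 2 * margin <= 0 or h - 2 * margin <= 0):
        raise ValueError("field too small for the requested cluster layout")
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < config.n_clusters:
        tries += 1
        if tries > 20000:
            raise ValueError(
                f"could not place {config.n_clusters} cluster centers "
                f"with separation {sep}"
            )
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= sep**2 for cx, cy in centers):
            centers.append((x, y))

    if cluster_sizes is None:
        sizes = 1 + rng.poisson(config.cluster_size_mean - 1.0, size=config.n_clusters)
    else:
        if len(cluster_sizes) != config.n_clusters:
            raise ValueError("cluster_sizes length must equal n_clusters")
        sizes = np.asarray(cluster_sizes, dtype=int)

    pts: list[np.ndarray] = []
    labels: list[int] = []
    for ci, ((cx, cy), size) in enumerate(zip(centers, sizes)):
        got = 0
        while got < size:
            p = rng.normal([cx, cy], config.cluster_sigma)
            if 0 <= p[0] <= w and 0 <= p[1] <= h:
                pts.append(p)
                labels.append(ci)
                got += 1
    area_um2 = (w / 1000.0) * (h / 1000.0)
    n_bg = rng.poisson(config.background_density * area_um2)
    next_label = config.n_clusters
    for _ in range(int(n_bg)):
        pts.append(rng.uniform([0, 0], [w, h]))
        labels.append(next_label)
        next_label += 1

    points = np.asarray(pts).reshape(-1, 2)
    pattern = GoldParticleSet(
        points=points,
        image_id=image_id,
        condition_label=condition_label,
        field_dimensions=(w, h),
    )
    truth = GroundTruth(
        point_labels=np.asarray(labels, dtype=int),
        cluster_sizes=sorted(int(s) for s in sizes),
    )
    return pattern, truth
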