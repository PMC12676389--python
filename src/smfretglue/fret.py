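"""FRET efficiency, population histograms, two-Gaussian fits, idealization.

Per frame E = Ia / (Ia + gamma * Id), computed over pre-acceptor-bleach
frames only. Per-molecule values are binned into 30 intervals across
[-0.25, 1.25] and normalized per molecule; the ensemble histogram is the
unweighted average over molecules, giving every molecule equal weight
regardless of trace length. State populations come from the areas of a
two-Gaussian model fitted to the ensemble histogram, with uncertainties from
a molecule-level bootstrap.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .config import CorrectionParams, FitParams
from .types import CorrectedTrace, EnsembleHistogram, FretTrace, GaussianMixtureFit

HIST_RANGE = (-0.25, 1.25)
N_BINS = 30


def compute_fret(
    acceptor: np.ndarray | float, donor: np.ndarray | float, gamma: float
) -> np.ndarray | float:
    """E = Ia / (Ia + gamma * Id); zero denominators return NaN (excluded later)."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    ia = np.asarray(acceptor, dtype=float)
    idn = np.asarray(donor, dtype=float)
    denom = ia + gamma * idn
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(denom != 0, ia / denom, np.nan)
    if np.ndim(acceptor) == 0 and np.ndim(donor) == 0:
        return float(e)
    return e


def fret_trace(
    trace: CorrectedTrace, exclusion: int = 3
) -> Optional[FretTrace]:
    """Frame-wise E over the pre-acceptor-bleach segment.

    Frames within ``exclusion`` of the bleach step are dropped; frames after
    acceptor bleach are undefined and never included.
    """
    if trace.gamma is None or trace.acceptor_bleach_frame is None:
        return None
    end = max(trace.acceptor_bleach_frame - exclusion, 0)
    if end < 1:
        return None
    e = compute_fret(trace.acceptor[:end], trace.donor[:end], trace.gamma)
    e = np.asarray(e)
    valid = np.isfinite(e)
    return FretTrace(
        molecule_id=trace.molecule_id,
        efficiency=e[valid],
        n_excluded=int((~valid).sum()),
    )


def molecule_histogram(
    e_values: np.ndarray,
    n_bins: int = N_BINS,
    hist_range: tuple[float, float] = HIST_RANGE,
) -> tuple[np.ndarray, int]:
    """Normalized per-molecule histogram.

    Bins are half-open [edge_i, edge_i+1) with the last bin closed at the
    upper range limit (numpy's convention). Counts are divided by the number
    of in-range values; out-of-range values are excluded and counted.
    Returns (histogram, n_out_of_range); raises if no value is in range.
    """
    e = np.asarray(e_values, dtype=float)
    e = e[np.isfinite(e)]
    lo, hi = hist_range
    in_range = (e >= lo) & (e <= hi)
    n_in = int(in_range.sum())
    if n_in == 0:
        raise ValueError("no in-range FRET values for this molecule")
    counts, _ = np.histogram(e[in_range], bins=n_bins, range=hist_range)
    return counts / n_in, int(e.size - n_in)


def ensemble_histogram(
    fret_traces: Sequence[FretTrace],
    n_bins: int = N_BINS,
    hist_range: tuple[float, float] = HIST_RANGE,
) -> EnsembleHistogram:
    """Average of per-molecule normalized histograms with per-bin SEM."""
    rows = []
    ids = []
    n_excluded = 0
    for ft in fret_traces:
        try:
            hist, n_out = molecule_histogram(ft.efficiency, n_bins, hist_range)
        except ValueError:
            n_excluded += ft.efficiency.size
            continue
        n_excluded += n_out + ft.n_excluded
        rows.append(hist)
        ids.append(ft.molecule_id)
    if not rows:
        raise ValueError("no molecules with in-range FRET values")
    per_molecule = np.vstack(rows)
    mean = per_molecule.mean(axis=0)
    if per_molecule.shape[0] > 1:
        sem = per_molecule.std(axis=0, ddof=1) / np.sqrt(per_molecule.shape[0])
    else:
        sem = np.zeros(n_bins)
    edges = np.linspace(hist_range[0], hist_range[1], n_bins + 1)
    return EnsembleHistogram(
        bin_edges=edges,
        per_molecule=per_molecule,
        ensemble_mean=mean,
        ensemble_sem=sem,
        n_molecules=per_molecule.shape[0],
        n_excluded_values=n_excluded,
        molecule_ids=ids,
    )


def _two_gaussian_model(params: np.ndarray, x: np.ndarray, width: float) -> np.ndarray:
    a1, mu1, s1, a2, mu2, s2 = params
    g1 = a1 * width * np.exp(-0.5 * ((x - mu1) / s1) ** 2) / (s1 * np.sqrt(2 * np.pi))
    g2 = a2 * width * np.exp(-0.5 * ((x - mu2) / s2) ** 2) / (s2 * np.sqrt(2 * np.pi))
    return g1 + g2


def _fit_mixture_once(
    centers: np.ndarray,
    target: np.ndarray,
    width: float,
    init: np.ndarray,
    shared_sigma: bool,
    sigma_bounds: tuple[float, float] = (0.01, 0.2),
) -> tuple[np.ndarray, float, bool]:
    lo_x, hi_x = centers[0] - width / 2, centers[-1] + width / 2
    s_lo, s_hi = sigma_bounds
    if shared_sigma:
        def resid(p):
            full = np.array([p[0], p[1], p[2], p[3], p[4], p[2]])
            return _two_gaussian_model(full, centers, width) - target

        p0 = init[[0, 1, 2, 3, 4]]
        bounds = ([0, lo_x, s_lo, 0, lo_x], [10, hi_x, s_hi, 10, hi_x])
    else:
        def resid(p):
            return _two_gaussian_model(p, centers, width) - target

        p0 = init
        bounds = ([0, lo_x, s_lo, 0, lo_x, s_lo], [10, hi_x, s_hi, 10, hi_x, s_hi])
    p0 = np.clip(p0, bounds[0], bounds[1])
    try:
        sol = least_squares(resid, p0, bounds=bounds, max_nfev=2000)
    except Exception:
        return init, np.inf, False
    p = sol.x
    if shared_sigma:
        p = np.array([p[0], p[1], p[2], p[3], p[4], p[2]])
    rss = float(np.sum(sol.fun**2))
    # status 0 (max evaluations) can still carry an excellent solution on a
    # flat landscape; judge by the residual, not the stop reason
    ok = np.isfinite(rss) and (sol.status > 0 or rss < 1e-8)
    return p, rss, ok


def fit_two_gaussian(
    hist: EnsembleHistogram,
    init: Optional[Sequence[float]] = None,
    shared_sigma: bool = False,
    sigma_bounds: tuple[float, float] = (0.01, 0.2),
) -> GaussianMixtureFit:
    """Two-Gaussian least-squares fit of the ensemble histogram.

    The model is A1*N(mu1, s1) + A2*N(mu2, s2) integrated per bin (evaluated
    at bin centers times the bin width), with multi-start initialization and
    components ordered by mean after the fit. Population fractions are the
    normalized Gaussian areas. Component widths are bounded (default
    sigma <= 0.2): a conformational state's peak width is set by shot noise
    plus modest heterogeneity, and an unbounded broad component degenerates
    into a tail-correction that absorbs minority states.
    """
    centers = hist.bin_centers
    width = float(hist.bin_edges[1] - hist.bin_edges[0])
    target = hist.ensemble_mean

    inits: list[np.ndarray] = []
    if init is not None:
        inits.append(np.asarray(init, dtype=float))
    # moment-based start: split mass at the overall mean
    total = target.sum()
    mu_all = float((centers * target).sum() / max(total, 1e-12))
    for gap in (0.2, 0.35):
        inits.append(np.array([total / 2, mu_all - gap, 0.08,
                               total / 2, mu_all + gap, 0.08]))
    inits.append(np.array([0.3, 0.4, 0.06, 0.7, 0.9, 0.06]))
    inits.append(np.array([0.5, 0.3, 0.1, 0.5, 0.7, 0.1]))

    best: tuple[np.ndarray, float, bool] | None = None
    for p0 in inits:
        p, rss, ok = _fit_mixture_once(centers, target, width, p0, shared_sigma, sigma_bounds)
        if ok and (best is None or rss < best[1]):
            best = (p, rss, ok)
    if best is None:
        raise RuntimeError("two-Gaussian fit failed to converge from all starts")
    p, rss, _ = best
    a1, mu1, s1, a2, mu2, s2 = p
    if mu1 > mu2:  # enforce mu_low < mu_high
        a1, mu1, s1, a2, mu2, s2 = a2, mu2, s2, a1, mu1, s1
    if abs(mu2 - mu1) < 0.5 * max(s1, s2):
        # sub-resolution split of a single mode: not identifiable as two
        # states; collapse onto one component
        def single_resid(p):
            a, mu, s = p
            return (
                a * width * np.exp(-0.5 * ((centers - mu) / s) ** 2)
                / (s * np.sqrt(2 * np.pi))
                - target
            )

        lo_x, hi_x = centers[0], centers[-1]
        sol = least_squares(
            single_resid,
            np.clip([a1 + a2, (mu1 + mu2) / 2, max(s1, s2)],
                    [0, lo_x, sigma_bounds[0]], [10, hi_x, sigma_bounds[1]]),
            bounds=([0, lo_x, sigma_bounds[0]], [10, hi_x, sigma_bounds[1]]),
            max_nfev=2000,
        )
        a, mu, s = sol.x
        a1, mu1, s1 = 0.0, mu, s
        a2, mu2, s2 = a, mu, s
        rss = float(np.sum(sol.fun**2))
    area = a1 + a2
    fractions = (a1 / area, a2 / area) if area > 0 else (float("nan"), float("nan"))
    return GaussianMixtureFit(
        means=(float(mu1), float(mu2)),
        sigmas=(float(s1), float(s2)),
        areas=(float(a1), float(a2)),
        fractions=(float(fractions[0]), float(fractions[1])),
        fraction_sem=None,
        rss=rss,
        n_molecules=hist.n_molecules,
        converged=True,
    )


def population_fractions(
    fit: GaussianMixtureFit,
    hist: EnsembleHistogram,
    n_boot: int = 200,
    seed: int = 0,
    shared_sigma: bool = False,
    sigma_bounds: tuple[float, float] = (0.01, 0.2),
) -> GaussianMixtureFit:
    """Attach bootstrap SEMs to the fitted population fractions.

    Molecules are resampled with replacement, the ensemble histogram is
    re-averaged and refit (warm-started at the point fit), and the SD of the
    fractions over replicates is reported. ``n_boot = 0`` leaves SEMs unset.
    """
    if n_boot == 0:
        return fit
    rng = np.random.default_rng(seed)
    centers = hist.bin_centers
    width = float(hist.bin_edges[1] - hist.bin_edges[0])
    warm = np.array([
        fit.areas[0], fit.means[0], fit.sigmas[0],
        fit.areas[1], fit.means[1], fit.sigmas[1],
    ])
    n = hist.per_molecule.shape[0]
    fracs = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        target = hist.per_molecule[idx].mean(axis=0)
        p, rss, ok = _fit_mixture_once(centers, target, width, warm, shared_sigma, sigma_bounds)
        if not ok or not np.isfinite(rss):
            failures += 1
            continue
        a1, mu1, _, a2, mu2, _ = p
        if mu1 > mu2:
            a1, a2 = a2, a1
        area = a1 + a2
        if area <= 0:
            failures += 1
            continue
        fracs.append(a1 / area)
    warning = failures > 0.2 * n_boot
    if fracs:
        sd = float(np.std(np.asarray(fracs), ddof=1)) if len(fracs) > 1 else 0.0
        sem: Optional[tuple[float, float]] = (sd, sd)
    else:
        sem, warning = None, True
    return GaussianMixtureFit(
        means=fit.means,
        sigmas=fit.sigmas,
        areas=fit.areas,
        fractions=fit.fractions,
        fraction_sem=sem,
        rss=fit.rss,
        n_molecules=fit.n_molecules,
        converged=fit.converged,
        bootstrap_warning=warning,
    )


def idealize_trace(
    efficiency: np.ndarray,
    frame_period: float = 0.1,
    n_states: int = 2,
    seed: int = 0,
    method: str = "hmm",
) -> tuple[np.ndarray, list[tuple[int, float]], bool]:
    """Two-state idealization of a FRET trajectory.

    ``method='hmm'`` fits a Gaussian-emission hidden Markov model and takes
    the most probable state path; ``method='threshold'`` is a simple midpoint
    fallback. States are relabeled by ascending mean E. Returns
    (state path, dwell list of (state, seconds), is_static).
    """
    e = np.asarray(efficiency, dtype=float)
    if e.size < 20:
        raise ValueError("trace too short to idealize (< 20 frames)")

    if method == "threshold":
        mid = 0.5 * (np.quantile(e, 0.1) + np.quantile(e, 0.9))
        path = (e > mid).astype(int)
    elif method == "hmm":
        import logging

        from hmmlearn.hmm import GaussianHMM

        logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)
        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=100,
            random_state=seed,
            init_params="stc",
        )
        q = np.quantile(e, np.linspace(0.15, 0.85, n_states))
        model.means_ = q.reshape(-1, 1)
        x = e.reshape(-1, 1)
        try:
            model.fit(x)
            path = model.predict(x)
            order = np.argsort(model.means_.ravel())
        except Exception:
            path = np.zeros(e.size, dtype=int)
            order = np.arange(n_states)
        relabel = np.empty(n_states, dtype=int)
        relabel[order] = np.arange(n_states)
        path = relabel[path]
    else:
        raise ValueError("method must be 'hmm' or 'threshold'")

    # a split whose state means are not separated beyond the frame noise is
    # an overfit of a one-state trace: collapse it to a single static state
    if len(np.unique(path)) > 1:
        mus = np.array([e[path == s].mean() for s in np.unique(path)])
        diffs = np.diff(e)
        noise = 1.4826 * np.median(np.abs(diffs)) / np.sqrt(2.0) if diffs.size else 0.0
        if mus.max() - mus.min() < 3.0 * noise:
            path = np.zeros(e.size, dtype=int)

    # collapse to dwells
    dwells: list[tuple[int, float]] = []
    start = 0
    for t in range(1, e.size + 1):
        if t == e.size or path[t] != path[t - 1]:
            dwells.append((int(path[start]), (t - start) * frame_period))
            start = t
    is_static = len(np.unique(path)) == 1
    return path, dwells, is_static


def analyze_traces(
    traces: list[CorrectedTrace],
    passed_ids: set[str],
    params: FitParams,
    correction: CorrectionParams,
    seed: int = 0,
) -> tuple[list[FretTrace], EnsembleHistogram, GaussianMixtureFit]:
    """QC-passed traces -> E series -> ensemble histogram -> population fit."""
    fts = []
    for t in traces:
        if t.molecule_id not in passed_ids:
            continue
        ft = fret_trace(t, exclusion=correction.step_exclusion)
        if ft is not None and ft.efficiency.size:
            if params.idealize:
                try:
                    path, dwells, static = idealize_trace(
                        ft.efficiency, frame_period=t.frame_period, seed=seed
                    )
                    ft.idealized_state, ft.dwell_times, ft.is_static = (
                        path, dwells, static
                    )
                except ValueError:
                    pass
            fts.append(ft)
    hist = ensemble_histogram(fts, params.n_bins, params.hist_range)
    fit = fit_two_gaussian(
        hist, shared_sigma=params.shared_sigma, sigma_bounds=params.sigma_bounds
    )
    fit = population_fractions(
        fit, hist, n_boot=params.n_bootstrap, seed=seed,
        shared_sigma=params.shared_sigma, sigma_bounds=params.sigma_bounds,
    )
    return fts, hist, fit
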