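"""Penalized least-squares change-point detection for photobleaching steps.

The working detector is PELT-style optimal partitioning of a
piecewise-constant-mean model with an L2 cost and a penalty of
``penalty_factor * sigma^2 * log(n)``, where sigma is estimated robustly from
median absolute frame-to-frame differences. Downward mean changes larger than
``min_step_sigma * sigma`` are reported as bleach steps.

``exhaustive_changepoints`` is a brute-force reference that scans every
placement of a fixed number of change points; it shares no code with the
penalized detector and exists as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # numba accelerates the O(n) inner loop; the numpy fallback is identical
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _pelt(cs1: np.ndarray, cs2: np.ndarray, beta: float) -> np.ndarray:
    """Optimal partitioning with PELT pruning.

    cs1/cs2 are cumulative sums of x and x^2 with a leading zero. Returns the
    ``last change point`` back-pointer array of length n+1.
    """
    n = cs1.shape[0] - 1
    f = np.empty(n + 1)
    f[0] = -beta
    last = np.zeros(n + 1, dtype=np.int64)
    cand = np.empty(n + 1, dtype=np.int64)
    cand[0] = 0
    n_cand = 1
    for t in range(1, n + 1):
        best = 1e300
        besti = 0
        for k in range(n_cand):
            i = cand[k]
            seg = t - i
            s1 = cs1[t] - cs1[i]
            cost = (cs2[t] - cs2[i]) - s1 * s1 / seg
            v = f[i] + cost + beta
            if v < best:
                best = v
                besti = i
        f[t] = best
        last[t] = besti
        # prune candidates that can never win again
        m = 0
        for k in range(n_cand):
            i = cand[k]
            seg = t - i
            s1 = cs1[t] - cs1[i]
            cost = (cs2[t] - cs2[i]) - s1 * s1 / seg
            if f[i] + cost <= f[t]:
                cand[m] = i
                m += 1
        cand[m] = t
        n_cand = m + 1
    return last


def estimate_noise_sigma(x: np.ndarray) -> float:
    """Robust noise scale from median absolute successive differences."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    mad = np.median(np.abs(np.diff(x)))
    return float(1.4826 * mad / np.sqrt(2.0))


@dataclass
class Segmentation:
    breakpoints: list[int]  # first index of each new segment (ascending)
    means: np.ndarray  # one mean per segment (len(breakpoints) + 1)
    sigma: float

    def segments(self, n: int) -> list[tuple[int, int]]:
        bounds = [0, *self.breakpoints, n]
        return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def segment_piecewise_constant(
    x: np.ndarray, penalty_factor: float = 3.0, sigma: float | None = None
) -> Segmentation:
    """Segment a series into piecewise-constant levels.

    Change points are first indices of new segments. A zero noise estimate
    (noise-free input) falls back to exact level changes.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return Segmentation([], np.array([x.mean() if n else 0.0]), 0.0)
    if sigma is None:
        sigma = estimate_noise_sigma(x)
    if sigma <= 0:
        bps = list(np.nonzero(np.diff(x) != 0)[0] + 1)
    else:
        beta = penalty_factor * sigma * sigma * np.log(n)
        cs1 = np.concatenate(([0.0], np.cumsum(x)))
        cs2 = np.concatenate(([0.0], np.cumsum(x * x)))
        last = _pelt(cs1, cs2, float(beta))
        bps = []
        t = n
        while t > 0:
            i = int(last[t])
            if i > 0:
                bps.append(i)
            t = i
        bps.reverse()
    bounds = [0, *bps, n]
    means = np.array([x[bounds[i]:bounds[i + 1]].mean() for i in range(len(bounds) - 1)])
    return Segmentation(bps, means, float(sigma))


@dataclass
class StepResult:
    step_frames: list[int]  # downward bleach-step locations, ascending
    step_sizes: list[float]  # positive magnitudes of the drops
    segmentation: Segmentation


def detect_bleach_steps(
    signal: np.ndarray,
    penalty_factor: float = 3.0,
    min_step_sigma: float = 3.0,
    sigma: float | None = None,
) -> StepResult:
    """Detect downward intensity steps (candidate photobleaching events).

    Only downward mean changes larger than ``min_step_sigma * sigma`` count;
    upward changes (donor recovery at acceptor bleach, state transitions)
    partition the series but are never reported as bleach steps.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 20:
        raise ValueError("signal too short for step detection (< 20 frames)")
    seg = segment_piecewise_constant(x, penalty_factor=penalty_factor, sigma=sigma)
    thr = min_step_sigma * seg.sigma
    frames: list[int] = []
    sizes: list[float] = []
    for k, bp in enumerate(seg.breakpoints):
        delta = seg.means[k + 1] - seg.means[k]
        if delta < 0 and -delta >= thr:
            frames.append(bp)
            sizes.append(-delta)
    return StepResult(frames, sizes, seg)


def bleach_rungs(
    seg: Segmentation,
    min_step_sigma: float = 3.0,
    dynamics_end: int | None = None,
) -> list[int]:
    """Downward steps attributable to photobleaching rather than state dynamics.

    A downward change point counts as a bleach rung when it is large
    (>= ``min_step_sigma`` sigma), *permanent* — the pre-step level is never
    regained, so reversible anticorrelated state transitions are excluded —
    and one of the following marks it as a fluorophore loss rather than the
    final dwell of a dynamic molecule before its terminal bleach:

    * terminal: every later level stays at the post-step level (this is the
      bleach itself), or
    * monotone context: no earlier upward step of comparable size (a clean
      staircase with no dynamics), or
    * continued dynamics: an upward step of comparable size occurs later, at
      a permanently reduced ceiling — the signature of losing one fluorophore
      of several while the remainder keeps switching states.

    The one permanent downward step that fails all three marks — entry into a
    final low-FRET dwell immediately followed by the terminal bleach — is the
    hindsight-irreversible state transition this rule is built to skip.

    ``dynamics_end`` marks the frame after which FRET dynamics cannot occur
    (e.g. the acceptor bleach, for the donor channel): permanent downward
    steps at or after it are always rungs.
    """
    thr = max(min_step_sigma * seg.sigma, 1e-12)
    tol = 3.0 * seg.sigma
    means = seg.means
    n_bp = len(seg.breakpoints)
    ups_before = np.zeros(n_bp, dtype=bool)
    seen_up = False
    for k in range(n_bp):
        ups_before[k] = seen_up
        if means[k + 1] - means[k] >= thr:
            seen_up = True
    out: list[int] = []
    for k, bp in enumerate(seg.breakpoints):
        drop = means[k] - means[k + 1]
        if drop < thr:
            continue
        later = means[k + 1:]
        if later.max() > means[k] - thr:
            continue  # pre-step level regained: dynamics, not bleaching
        if dynamics_end is not None and bp >= dynamics_end:
            out.append(bp)  # past the dynamics regime: permanence suffices
            continue
        terminal = np.all(np.abs(later - later[0]) <= tol)
        later_up = any(
            means[j + 1] - means[j] >= thr for j in range(k + 1, n_bp)
        )
        if terminal or not ups_before[k] or later_up:
            out.append(bp)
    return out


def _seg_cost_tables(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cs1 = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))
    return cs1, cs2


def _cost(cs1: np.ndarray, cs2: np.ndarray, i, j):
    """SSE of segment x[i:j] around its mean (vectorized over i, j arrays;
    empty or inverted segments get infinite cost)."""
    seg = j - i
    s1 = cs1[j] - cs1[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        cost = (cs2[j] - cs2[i]) - s1 * s1 / seg
    return np.where(seg > 0, cost, np.inf)


def exhaustive_changepoints(x: np.ndarray, k: int) -> tuple[int, ...]:
    """Brute-force least-squares placement of exactly k change points (k <= 2).

    Scans all placements; intended as an independent reference for small
    problems, not for production use.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if k == 0:
        return ()
    cs1, cs2 = _seg_cost_tables(x)
    idx = np.arange(1, n)
    if k == 1:
        costs = _cost(cs1, cs2, 0, idx) + _cost(cs1, cs2, idx, n)
        return (int(idx[np.argmin(costs)]),)
    if k == 2:
        i = idx[:, None]
        j = idx[None, :]
        total = np.where(
            j > i,
            _cost(cs1, cs2, 0, i) + _cost(cs1, cs2, i, j) + _cost(cs1, cs2, j, n),
            np.inf,
        )
        flat = int(np.argmin(total))
        return (int(idx[flat // idx.size]), int(idx[flat % idx.size]))
    raise ValueError("exhaustive search implemented for k <= 2 only")
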