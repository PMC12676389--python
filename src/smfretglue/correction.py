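"""Trace corrections: background, donor leakage, bleach steps, gamma, SNR.

Correction order: per-frame background subtraction, leakage subtraction
(acceptor -= alpha * donor), change-point segmentation of both channels,
bleach annotation, then the per-molecule quantities the selection criteria
test (gamma at the acceptor bleach, SNR of the total intensity,
donor/acceptor anticorrelation).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.ndimage import median_filter

from .changepoint import (
    Segmentation,
    detect_bleach_steps,
    estimate_noise_sigma,
    bleach_rungs,
    segment_piecewise_constant,
)
from .config import CorrectionParams
from .types import CorrectedTrace, RawTrace


def subtract_leakage(
    acceptor_raw: np.ndarray, donor: np.ndarray, alpha: float
) -> np.ndarray:
    """Remove donor emission leaking into the acceptor channel.

    Ia(t) = Ia_raw(t) - alpha * Id(t), element-wise. Linear and invertible
    given alpha and the donor series.
    """
    acceptor_raw = np.asarray(acceptor_raw, dtype=float)
    donor = np.asarray(donor, dtype=float)
    if acceptor_raw.shape != donor.shape:
        raise ValueError("acceptor and donor series must have the same length")
    if not (0.0 <= alpha < 1.0):
        raise ValueError("alpha must lie in [0, 1)")
    return acceptor_raw - alpha * donor


def _terminal_zero_frame(
    signal: np.ndarray, seg: Segmentation, step_frames: list[int]
) -> Optional[int]:
    """Bleach frame: last detected downward step whose terminal level is ~zero."""
    if not step_frames:
        return None
    last = step_frames[-1]
    tail = signal[last:]
    if tail.size == 0:
        return None
    tol = max(3.0 * seg.sigma / np.sqrt(tail.size), 1e-9)
    # allow a generous absolute tolerance scaled by per-frame noise
    if abs(float(tail.mean())) <= max(tol, 0.5 * seg.sigma):
        return last
    return None


def estimate_gamma(
    donor: np.ndarray,
    acceptor: np.ndarray,
    acceptor_bleach_frame: int,
    window: int = 50,
    exclusion: int = 3,
    end_frame: Optional[int] = None,
) -> tuple[Optional[float], Optional[str]]:
    """Gamma from intensity changes at acceptor photobleaching.

    gamma = (mean Ia before - mean Ia after) / (mean Id after - mean Id before),
    with means over ``window`` frames on each side of the bleach, excluding
    ``exclusion`` frames around the step. Returns (None, reason) when the
    windows do not fit or the donor shows no recovery.
    """
    b = acceptor_bleach_frame
    end = end_frame if end_frame is not None else len(donor)
    pre_start = b - exclusion - window
    post_end = b + exclusion + window
    if pre_start < 0 or post_end > end:
        return None, "gamma_window"
    pre = slice(pre_start, b - exclusion)
    post = slice(b + exclusion, post_end)
    d_ia = float(np.mean(acceptor[pre]) - np.mean(acceptor[post]))
    d_id = float(np.mean(donor[post]) - np.mean(donor[pre]))
    if d_id <= 0:
        return None, "gamma_undefined"
    return d_ia / d_id, None


def compute_snr(
    donor: np.ndarray,
    acceptor: np.ndarray,
    end_frame: Optional[int] = None,
    median_window: int = 5,
    min_frames: int = 20,
    cap: float = 1e6,
) -> tuple[Optional[float], Optional[str]]:
    """Signal-to-noise ratio of the total intensity before acceptor bleach.

    SNR = mean(Id + Ia) / std of the high-frequency residual of (Id + Ia)
    after subtracting a running median. Noise-free traces report the cap.
    """
    end = end_frame if end_frame is not None else len(donor)
    total = np.asarray(donor[:end], dtype=float) + np.asarray(acceptor[:end], dtype=float)
    if total.size < min_frames:
        return None, "short"
    residual = total - median_filter(total, size=median_window, mode="nearest")
    noise = float(np.std(residual))
    if noise <= 0:
        return cap, None
    return min(float(np.mean(total)) / noise, cap), None


def compute_anticorrelation(
    donor: np.ndarray,
    acceptor: np.ndarray,
    end_frame: Optional[int] = None,
    min_frames: int = 20,
) -> Optional[float]:
    """Pearson correlation of frame-to-frame differences of the two channels."""
    end = end_frame if end_frame is not None else len(donor)
    dd = np.diff(np.asarray(donor[:end], dtype=float))
    da = np.diff(np.asarray(acceptor[:end], dtype=float))
    if dd.size < min_frames - 1:
        return None
    if np.std(dd) == 0 or np.std(da) == 0:
        return None
    return float(np.corrcoef(dd, da)[0, 1])


def _is_dynamic(signal: np.ndarray, end_frame: int) -> bool:
    """Excess low-frequency variance marks state dynamics (vs. pure noise)."""
    x = np.asarray(signal[:end_frame], dtype=float)
    if x.size < 20:
        return False
    noise = estimate_noise_sigma(x)
    if noise <= 0:
        return float(np.std(x)) > 0
    return float(np.std(x)) > 1.5 * noise


def _opposite_sign_bleach_steps(
    donor: np.ndarray,
    acceptor: np.ndarray,
    bleach_frame: int,
    sigma_d: float,
    sigma_a: float,
    window: int = 20,
    exclusion: int = 3,
) -> bool:
    """Acceptor drops while the donor rises at the acceptor bleach."""
    pre = slice(max(0, bleach_frame - exclusion - window), bleach_frame - exclusion)
    post = slice(bleach_frame + exclusion,
                 min(len(donor), bleach_frame + exclusion + window))
    if donor[pre].size < 3 or donor[post].size < 3:
        return False
    d_step = float(np.mean(donor[post]) - np.mean(donor[pre]))
    a_step = float(np.mean(acceptor[post]) - np.mean(acceptor[pre]))
    tol_d = 2.0 * sigma_d / np.sqrt(max(donor[pre].size, 1))
    tol_a = 2.0 * sigma_a / np.sqrt(max(acceptor[pre].size, 1))
    return d_step > tol_d and a_step < -tol_a


def correct_trace(raw: RawTrace, params: CorrectionParams) -> CorrectedTrace:
    """Full per-molecule correction and annotation pass."""
    if getattr(raw, "corrected", False):
        raise ValueError("trace has already been corrected (idempotence guard)")
    donor = np.asarray(raw.donor_raw, dtype=float) - np.asarray(raw.bg_donor, dtype=float)
    acceptor_bgsub = (
        np.asarray(raw.acceptor_raw, dtype=float) - np.asarray(raw.bg_acceptor, dtype=float)
    )
    acceptor = subtract_leakage(acceptor_bgsub, donor, params.leakage_alpha)

    steps_a = detect_bleach_steps(
        acceptor, penalty_factor=params.step_penalty,
        min_step_sigma=params.min_step_sigma,
    )
    steps_d = detect_bleach_steps(
        donor, penalty_factor=params.step_penalty,
        min_step_sigma=params.min_step_sigma,
    )
    b_a = _terminal_zero_frame(acceptor, steps_a.segmentation, steps_a.step_frames)
    irrev_a = bleach_rungs(steps_a.segmentation, params.min_step_sigma)
    # donor dynamics cannot outlive the acceptor: past its bleach, every
    # permanent donor drop is a bleach rung
    irrev_d = bleach_rungs(
        steps_d.segmentation, params.min_step_sigma, dynamics_end=b_a
    )
    b_d = None
    if irrev_d:
        b_d = _terminal_zero_frame(donor, steps_d.segmentation, irrev_d)

    end = b_a if b_a is not None else (b_d if b_d is not None else raw.n_frames)

    gamma, gamma_reason = (None, "no_acceptor_bleach")
    if b_a is not None:
        gamma, gamma_reason = estimate_gamma(
            donor, acceptor, b_a,
            window=params.gamma_window,
            exclusion=params.step_exclusion,
            end_frame=b_d if (b_d is not None and b_d > b_a) else raw.n_frames,
        )

    snr, snr_reason = compute_snr(
        donor, acceptor, end_frame=end,
        median_window=params.snr_median_window,
        min_frames=params.min_prebleach_frames,
        cap=params.snr_cap,
    )
    r = compute_anticorrelation(
        donor, acceptor, end_frame=end, min_frames=params.min_prebleach_frames
    )
    dynamic = _is_dynamic(acceptor, end)

    bleach_anti = False
    if b_a is not None:
        bleach_anti = _opposite_sign_bleach_steps(
            donor, acceptor, b_a,
            sigma_d=steps_d.segmentation.sigma,
            sigma_a=steps_a.segmentation.sigma,
            exclusion=params.step_exclusion,
        )

    # identity check: a clean in-movie acceptor bleach already evidences the
    # acceptor; otherwise demand direct-excitation signal above background
    if b_a is not None:
        acceptor_confirmed: Optional[bool] = None
    else:
        n_direct = max(len(raw.direct_acceptor), 1)
        threshold = 3.0 * raw.direct_bg_sigma / np.sqrt(n_direct)
        acceptor_confirmed = raw.direct_acceptor_signal > threshold

    return CorrectedTrace(
        molecule_id=raw.molecule_id,
        donor=donor,
        acceptor=acceptor,
        frame_period=raw.frame_period,
        gamma=gamma,
        gamma_reason=gamma_reason,
        acceptor_bleach_frame=b_a,
        donor_bleach_frame=b_d,
        acceptor_step_count=len(irrev_a),
        donor_step_count=len(irrev_d),
        snr=snr,
        snr_reason=snr_reason,
        anticorrelation_r=r,
        is_dynamic=dynamic,
        bleach_steps_anticorrelated=bleach_anti,
        acceptor_confirmed=acceptor_confirmed,
    )


def correct_traces(raws: list[RawTrace], params: CorrectionParams) -> list[CorrectedTrace]:
    return [correct_trace(r, params) for r in raws]
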