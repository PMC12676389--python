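"""Trace selection: the five criteria plus acceptor-identity confirmation.

Criteria, evaluated in order (the first failure becomes the reject reason;
pass/fail itself is order-independent):

1. ``snr``          — signal-to-noise ratio >= 5 (inclusive).
2. ``acceptor_single_step_before_donor`` — exactly one irreversible acceptor
   bleach step, strictly before any donor bleach (or the donor never bleaches).
3. ``gamma_in_bounds`` — 0.5 <= gamma <= 2.5 (inclusive).
4. ``anticorrelated`` — differenced donor/acceptor Pearson r at or below the
   threshold for dynamic traces; traces locked in one state are judged by
   opposite-sign intensity steps at the acceptor bleach instead.
5. ``donor_single_step`` — at most one donor bleach step, applied only if a
   donor bleach occurs ("if present" -> not-applicable otherwise).
6. ``acceptor_confirmed`` — direct-excitation acceptor signal above
   background, not-applicable when an in-movie acceptor bleach already
   confirmed the fluorophore.
"""

from __future__ import annotations

import pandas as pd

from .config import CorrectionParams
from .types import CorrectedTrace, QCReport

CRITERIA = (
    "snr",
    "acceptor_single_step_before_donor",
    "gamma_in_bounds",
    "anticorrelated",
    "donor_single_step",
    "acceptor_confirmed",
)


def apply_qc(trace: CorrectedTrace, params: CorrectionParams) -> QCReport:
    """Evaluate every criterion on a corrected trace (boundary values pass)."""
    results: dict[str, str] = {}

    # (1) SNR >= threshold
    if trace.snr is None:
        results["snr"] = "fail"
    else:
        results["snr"] = "pass" if trace.snr >= params.snr_threshold else "fail"

    # (2) single-step acceptor photobleaching prior to donor bleaching
    ok = (
        trace.acceptor_step_count == 1
        and trace.acceptor_bleach_frame is not None
        and (
            trace.donor_bleach_frame is None
            or trace.acceptor_bleach_frame < trace.donor_bleach_frame
        )
    )
    results["acceptor_single_step_before_donor"] = "pass" if ok else "fail"

    # (3) gamma within bounds
    lo, hi = params.gamma_bounds
    if trace.gamma is None:
        results["gamma_in_bounds"] = "fail"
    else:
        results["gamma_in_bounds"] = "pass" if lo <= trace.gamma <= hi else "fail"

    # (4) anticorrelated donor/acceptor fluctuations
    if trace.is_dynamic and trace.anticorrelation_r is not None:
        results["anticorrelated"] = (
            "pass"
            if trace.anticorrelation_r <= params.anticorrelation_threshold
            else "fail"
        )
    else:
        # static molecule (or undefined r): judge by the bleach-step signature
        results["anticorrelated"] = (
            "pass" if trace.bleach_steps_anticorrelated else "fail"
        )

    # (5) single-step donor bleaching, if present
    if trace.donor_step_count == 0:
        results["donor_single_step"] = "not-applicable"
    else:
        results["donor_single_step"] = (
            "pass" if trace.donor_step_count == 1 else "fail"
        )

    # identity confirmation by direct acceptor excitation
    if trace.acceptor_confirmed is None:
        results["acceptor_confirmed"] = "not-applicable"
    else:
        results["acceptor_confirmed"] = "pass" if trace.acceptor_confirmed else "fail"

    reject = next((c for c in CRITERIA if results[c] == "fail"), None)
    return QCReport(
        molecule_id=trace.molecule_id,
        passed=reject is None,
        criterion_results=results,
        reject_reason=reject,
    )


def apply_qc_batch(
    traces: list[CorrectedTrace], params: CorrectionParams
) -> list[QCReport]:
    return [apply_qc(t, params) for t in traces]


def qc_summary(reports: list[QCReport]) -> pd.DataFrame:
    """Per-criterion accounting: each rejection attributed to its first failure."""
    rows = []
    total = len(reports)
    accepted = sum(r.passed for r in reports)
    rows.append({"category": "total", "count": total})
    rows.append({"category": "accepted", "count": accepted})
    rows.append({"category": "rejected", "count": total - accepted})
    for c in CRITERIA:
        rows.append(
            {
                "category": f"fail_{c}",
                "count": sum(1 for r in reports if r.reject_reason == c),
            }
        )
    return pd.DataFrame(rows)


def reports_frame(reports: list[QCReport]) -> pd.DataFrame:
    """One row per molecule, one column per criterion."""
    rows = []
    for r in reports:
        row: dict = {"molecule_id": r.molecule_id, "passed": r.passed,
                     "reject_reason": r.reject_reason or ""}
        row.update(r.criterion_results)
        rows.append(row)
    return pd.DataFrame(rows)
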