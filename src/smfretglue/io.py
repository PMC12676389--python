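"""Readers and writers for the shared on-disk formats.

Traces travel as CSV (one row per molecule-frame, donor- and
acceptor-excitation segments distinguished by ``excitation_segment``) with a
JSON sidecar holding per-molecule scalars; movies as one multi-page TIFF per
channel plus a JSON sidecar with the excitation schedule. All writers are
deterministic: no timestamps, sorted keys, fixed float formatting.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .types import GroundTruth, MoleculeTruth, MovieStack, QCReport, RawTrace

FLOAT_FMT = "%.10g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_traces_csv(traces: list[RawTrace], path: str | Path) -> None:
    path = Path(path)
    frames = []
    meta = {}
    for tr in traces:
        n = tr.n_frames
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame": np.arange(n),
                    "I_donor_raw": tr.donor_raw,
                    "I_acceptor_raw": tr.acceptor_raw,
                    "bg_donor": tr.bg_donor,
                    "bg_acceptor": tr.bg_acceptor,
                    "excitation_segment": "donor",
                }
            )
        )
        nd = len(tr.direct_acceptor)
        if nd:
            frames.append(
                pd.DataFrame(
                    {
                        "molecule_id": tr.molecule_id,
                        "frame": np.arange(n, n + nd),
                        "I_donor_raw": np.nan,
                        "I_acceptor_raw": tr.direct_acceptor,
                        "bg_donor": np.nan,
                        "bg_acceptor": tr.direct_bg_mean,
                        "excitation_segment": "acceptor",
                    }
                )
            )
        meta[tr.molecule_id] = {
            "frame_period": tr.frame_period,
            "direct_bg_mean": tr.direct_bg_mean,
            "direct_bg_sigma": tr.direct_bg_sigma,
        }
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=FLOAT_FMT)
    _sidecar(path).write_text(json.dumps(meta, sort_keys=True, indent=1))


def read_traces_csv(path: str | Path) -> list[RawTrace]:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    out = []
    for mol_id, grp in df.groupby("molecule_id", sort=True):
        don = grp[grp.excitation_segment == "donor"].sort_values("frame")
        acc = grp[grp.excitation_segment == "acceptor"].sort_values("frame")
        m = meta.get(str(mol_id), {})
        out.append(
            RawTrace(
                molecule_id=str(mol_id),
                donor_raw=don.I_donor_raw.to_numpy(float),
                acceptor_raw=don.I_acceptor_raw.to_numpy(float),
                bg_donor=don.bg_donor.to_numpy(float),
                bg_acceptor=don.bg_acceptor.to_numpy(float),
                frame_period=float(m.get("frame_period", 0.1)),
                direct_acceptor=acc.I_acceptor_raw.to_numpy(float),
                direct_bg_mean=float(m.get("direct_bg_mean", 0.0)),
                direct_bg_sigma=float(m.get("direct_bg_sigma", 0.0)),
            )
        )
    return out


def write_movie(movie: MovieStack, out_dir: str | Path, prefix: str = "movie") -> dict:
    """Two multi-page TIFFs (float32) plus a JSON schedule sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "donor": out_dir / f"{prefix}_donor.tif",
        "acceptor": out_dir / f"{prefix}_acceptor.tif",
        "meta": out_dir / f"{prefix}_meta.json",
    }
    tifffile.imwrite(paths["donor"], movie.donor.astype(np.float32))
    tifffile.imwrite(paths["acceptor"], movie.acceptor.astype(np.float32))
    if movie.reg_donor is not None:
        paths["reg_donor"] = out_dir / f"{prefix}_reg_donor.tif"
        paths["reg_acceptor"] = out_dir / f"{prefix}_reg_acceptor.tif"
        tifffile.imwrite(paths["reg_donor"], movie.reg_donor.astype(np.float32))
        tifffile.imwrite(paths["reg_acceptor"], movie.reg_acceptor.astype(np.float32))
    meta = {
        "frame_period": movie.frame_period,
        "donor_exc_range": list(movie.donor_exc_range),
        "acceptor_exc_range": list(movie.acceptor_exc_range),
    }
    paths["meta"].write_text(json.dumps(meta, sort_keys=True, indent=1))
    return {k: str(v) for k, v in paths.items()}


def read_movie(
    donor_tif: str | Path,
    acceptor_tif: str | Path,
    meta_json: str | Path,
    reg_donor_tif: Optional[str | Path] = None,
    reg_acceptor_tif: Optional[str | Path] = None,
) -> MovieStack:
    meta = json.loads(Path(meta_json).read_text())
    return MovieStack(
        donor=tifffile.imread(donor_tif).astype(np.float64),
        acceptor=tifffile.imread(acceptor_tif).astype(np.float64),
        frame_period=float(meta["frame_period"]),
        donor_exc_range=tuple(meta["donor_exc_range"]),
        acceptor_exc_range=tuple(meta["acceptor_exc_range"]),
        reg_donor=(
            tifffile.imread(reg_donor_tif).astype(np.float64)
            if reg_donor_tif
            else None
        ),
        reg_acceptor=(
            tifffile.imread(reg_acceptor_tif).astype(np.float64)
            if reg_acceptor_tif
            else None
        ),
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload: dict = {"molecules": []}
    for m in truth.molecules:
        payload["molecules"].append(
            {
                "molecule_id": m.molecule_id,
                "class": m.mclass,
                "gamma": m.gamma,
                "acceptor_bleach_frame": m.acceptor_bleach_frame,
                "donor_bleach_frame": m.donor_bleach_frame,
                "position_donor": list(m.position_donor) if m.position_donor else None,
                "position_acceptor": (
                    list(m.position_acceptor) if m.position_acceptor else None
                ),
            }
        )
    if truth.point_labels is not None:
        payload["point_labels"] = [int(x) for x in truth.point_labels]
    if truth.cluster_sizes is not None:
        payload["cluster_sizes"] = [int(x) for x in truth.cluster_sizes]
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    truth = GroundTruth()
    for m in payload.get("molecules", []):
        truth.molecules.append(
            MoleculeTruth(
                molecule_id=m["molecule_id"],
                mclass=m["class"],
                gamma=m["gamma"],
                acceptor_bleach_frame=m["acceptor_bleach_frame"],
                donor_bleach_frame=m["donor_bleach_frame"],
                position_donor=(
                    tuple(m["position_donor"]) if m.get("position_donor") else None
                ),
                position_acceptor=(
                    tuple(m["position_acceptor"]) if m.get("position_acceptor") else None
                ),
            )
        )
    if "point_labels" in payload:
        truth.point_labels = np.asarray(payload["point_labels"], dtype=int)
    if "cluster_sizes" in payload:
        truth.cluster_sizes = payload["cluster_sizes"]
    return truth


def write_points_csv(sets, path: str | Path) -> None:
    rows = []
    for s in sets:
        for x, y in s.points:
            rows.append(
                {
                    "image_id": s.image_id,
                    "condition": s.condition_label,
                    "x_nm": x,
                    "y_nm": y,
                }
            )
    pd.DataFrame(rows).to_csv(Path(path), index=False, float_format=FLOAT_FMT)


def read_points_csv(path: str | Path, field_dimensions=(1e9, 1e9)):
    from .types import GoldParticleSet

    df = pd.read_csv(path)
    out = []
    for (img, cond), grp in df.groupby(["image_id", "condition"], sort=True):
        out.append(
            GoldParticleSet(
                points=grp[["x_nm", "y_nm"]].to_numpy(float),
                image_id=str(img),
                condition_label=str(cond),
                field_dimensions=field_dimensions,
            )
        )
    return out


def corrected_frame(traces) -> pd.DataFrame:
    """Per-molecule scalar record of the correction stage."""
    rows = []
    for t in traces:
        rows.append(
            {
                "molecule_id": t.molecule_id,
                "gamma": t.gamma if t.gamma is not None else np.nan,
                "gamma_reason": t.gamma_reason or "",
                "acceptor_bleach_frame": (
                    t.acceptor_bleach_frame if t.acceptor_bleach_frame is not None else -1
                ),
                "donor_bleach_frame": (
                    t.donor_bleach_frame if t.donor_bleach_frame is not None else -1
                ),
                "acceptor_step_count": t.acceptor_step_count,
                "donor_step_count": t.donor_step_count,
                "snr": t.snr if t.snr is not None else np.nan,
                "anticorrelation_r": (
                    t.anticorrelation_r if t.anticorrelation_r is not None else np.nan
                ),
                "is_dynamic": t.is_dynamic,
            }
        )
    return pd.DataFrame(rows)


def write_qc_reports(reports: list[QCReport], path: str | Path) -> None:
    from .qc import reports_frame

    reports_frame(reports).to_csv(Path(path), index=False)
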