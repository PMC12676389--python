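"""End-to-end orchestration: simulate -> extract -> correct -> qc -> analyze,
plus the nanocluster branch, from a single serializable configuration.

A single global seed fans out to per-stage sub-seeds by stable hashing of the
stage name, so toggling stages never shifts another stage's randomness, and a
rerun of the same configuration reproduces every output byte for byte (no
timestamps are written). The manifest records per-stage counts and SHA-256
hashes of every file written.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import io as fio
from .config import RunConfig, stage_seed, validate_config
from .correction import correct_traces
from .fret import analyze_traces
from .nanocluster import cluster_size_stats, compare_conditions
from .qc import apply_qc_batch, qc_summary
from .simulate import simulate_movie, simulate_particle_pattern, simulate_traces


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the enabled stages; returns (and writes) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "files": {},
    }

    sim_config = config.simulation.model_copy(
        update={"seed": stage_seed(config.seed, "simulate")}
    )

    # --- simulate (+ extract, in movie mode) -------------------------------
    if config.mode == "movie":
        movie, truth = simulate_movie(sim_config, config.movie, config.n_molecules)
        fio.write_movie(movie, out, prefix="movie")
        from .imaging import extract_all_traces

        raw_traces, counts = extract_all_traces(movie, config.imaging)
        manifest["stages"]["extract"] = counts
    else:
        raw_traces, truth = simulate_traces(sim_config, config.n_molecules)
    fio.write_ground_truth(truth, out / "ground_truth.json")
    fio.write_traces_csv(raw_traces, out / "traces.csv")
    manifest["stages"]["simulate"] = {
        "n_molecules": len(raw_traces),
        "mode": config.mode,
        "seed": sim_config.seed,
    }

    # --- correct + qc ------------------------------------------------------
    corrected = correct_traces(raw_traces, config.correction)
    fio.corrected_frame(corrected).to_csv(
        out / "corrected.csv", index=False, float_format=fio.FLOAT_FMT
    )
    reports = apply_qc_batch(corrected, config.correction)
    fio.write_qc_reports(reports, out / "qc.csv")
    summary = qc_summary(reports)
    summary.to_csv(out / "qc_summary.csv", index=False)
    manifest["stages"]["qc"] = {
        row["category"]: int(row["count"]) for _, row in summary.iterrows()
    }

    # --- analyze -----------------------------------------------------------
    passed = {r.molecule_id for r in reports if r.passed}
    if passed:
        fts, hist, fit = analyze_traces(
            corrected,
            passed,
            config.fit,
            config.correction,
            seed=stage_seed(config.seed, "analyze"),
        )
        import pandas as pd

        pd.DataFrame(
            {
                "bin_center": hist.bin_centers,
                "mean": hist.ensemble_mean,
                "sem": hist.ensemble_sem,
            }
        ).to_csv(out / "histogram.csv", index=False, float_format=fio.FLOAT_FMT)
        fit_payload = {
            "means": list(fit.means),
            "sigmas": list(fit.sigmas),
            "areas": list(fit.areas),
            "fractions": list(fit.fractions),
            "fraction_sem": list(fit.fraction_sem) if fit.fraction_sem else None,
            "rss": fit.rss,
            "n_molecules": fit.n_molecules,
            "bootstrap_seed": stage_seed(config.seed, "analyze"),
            "n_bootstrap": config.fit.n_bootstrap,
            "fraction_definition": "gaussian_area_share",
        }
        (out / "fit.json").write_text(json.dumps(fit_payload, sort_keys=True, indent=1))
        manifest["stages"]["analyze"] = {
            "n_molecules": hist.n_molecules,
            "low_state_fraction": fit.fractions[0],
        }

    # --- nanocluster branch ------------------------------------------------
    if config.patterns and config.clusters:
        sets = []
        for cond, pconf in sorted(config.patterns.items()):
            for i in range(pconf.n_images):
                pat, _ = simulate_particle_pattern(
                    pconf,
                    seed=stage_seed(config.seed, f"pattern:{cond}:{i}"),
                    image_id=f"{cond}_{i}",
                    condition_label=cond,
                )
                sets.append(pat)
        fio.write_points_csv(sets, out / "points.csv")
        stats = cluster_size_stats(sets, config.clusters.linkage_radius)
        payload = {
            cond: {
                "n_clusters": len(s.cluster_sizes),
                "n_particles": int(np.sum(s.cluster_sizes)),
                "mean_size": float(np.mean(s.cluster_sizes)) if s.cluster_sizes else 0.0,
                "frequency": {str(k): v for k, v in s.frequency_distribution.items()},
            }
            for cond, s in sorted(stats.items())
        }
        conds = sorted(stats)
        if len(conds) >= 2:
            stat, p, flag = compare_conditions(
                stats[conds[0]].cluster_sizes,
                stats[conds[1]].cluster_sizes,
                test=config.clusters.test,
            )
            payload["comparison"] = {
                "conditions": conds[:2],
                "test": config.clusters.test,
                "statistic": stat,
                "p_value": p,
                "zero_variance": flag,
            }
        (out / "clusters.json").write_text(json.dumps(payload, sort_keys=True, indent=1))
        manifest["stages"]["clusters"] = {
            c: len(stats[c].cluster_sizes) for c in conds
        }

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def run_from_text(config_text: str, out_dir: str | Path, seed: int | None = None) -> dict:
    config = validate_config(config_text)
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    return run_pipeline(config, out_dir)
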