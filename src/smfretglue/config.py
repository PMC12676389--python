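"""Configuration models for every pipeline stage.

All configuration is declared with pydantic so that unknown keys, reversed
bounds, or inconsistent cross-field settings fail loudly with the offending
field named, and so that a run configuration serializes/round-trips exactly
(the reproducibility contract of the pipeline).
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ContaminantFractions(_StrictModel):
    """Proportions of non-analyzable molecule classes mixed into a simulation."""

    donor_only: float = 0.0
    acceptor_only: float = 0.0
    aggregate: float = 0.0

    @model_validator(mode="after")
    def _check_total(self) -> "ContaminantFractions":
        total = self.donor_only + self.acceptor_only + self.aggregate
        if not (0.0 <= self.donor_only <= 1.0 and 0.0 <= self.acceptor_only <= 1.0
                and 0.0 <= self.aggregate <= 1.0):
            raise ValueError("contaminant fractions must each lie in [0, 1]")
        if total > 1.0 + 1e-12:
            raise ValueError(f"contaminant_fractions sum to {total} > 1")
        return self


class SimulationConfig(_StrictModel):
    """Ground-truth generator settings.

    Defaults emulate the acquisition this analysis targets: 100 ms frames,
    an 80 s donor-excitation segment followed by 1 s of direct acceptor
    excitation, ~7% donor leakage into the acceptor channel, per-molecule
    detection-imbalance factor gamma in [0.5, 2.5], and photobleaching on
    tens-of-seconds timescales (acceptor dyes bleach faster than donors).
    Intensities are arbitrary linear camera units.
    """

    frame_period: float = 0.1
    n_frames_donor_exc: int = 800
    n_frames_acceptor_exc: int = 10
    state_means: tuple[float, ...] = (0.5, 0.9)
    state_occupancies: tuple[float, ...] = (0.25, 0.75)
    # Per-second rate matrix between states (off-diagonal entries used).
    # None -> built from occupancies with the given exchange rate so the
    # stationary distribution equals state_occupancies exactly.
    transition_rates: Optional[tuple[tuple[float, ...], ...]] = None
    exchange_rate: float = 4.0
    total_intensity: float = 1000.0
    donor_bleach_lifetime: float = 120.0
    acceptor_bleach_lifetime: float = 30.0
    leakage_alpha: float = 0.07
    gamma_range: tuple[float, float] = (0.5, 2.5)
    background_level: float = 100.0
    read_noise_sigma: float = 75.0
    shot_noise: bool = True
    contaminant_fractions: ContaminantFractions = Field(default_factory=ContaminantFractions)
    seed: int = 0

    @field_validator("frame_period", "total_intensity", "exchange_rate")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v

    @field_validator("n_frames_donor_exc", "n_frames_acceptor_exc")
    @classmethod
    def _positive_frames(cls, v: int, info) -> int:
        if v <= 0:
            raise ValueError(f"{info.field_name}: frame counts must be > 0")
        return v

    @field_validator("donor_bleach_lifetime", "acceptor_bleach_lifetime")
    @classmethod
    def _positive_lifetime(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name}: bleach lifetimes must be > 0")
        return v

    @field_validator("leakage_alpha")
    @classmethod
    def _leakage(cls, v: float) -> float:
        if not (0.0 <= v < 1.0):
            raise ValueError("leakage_alpha must lie in [0, 1)")
        return v

    @field_validator("read_noise_sigma", "background_level")
    @classmethod
    def _nonneg(cls, v: float, info) -> float:
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0")
        return v

    @model_validator(mode="after")
    def _check_states(self) -> "SimulationConfig":
        means = np.asarray(self.state_means, dtype=float)
        occ = np.asarray(self.state_occupancies, dtype=float)
        if means.size == 0:
            raise ValueError("state_means: need at least one state")
        if means.size != occ.size:
            raise ValueError("state_occupancies: length must match state_means")
        if np.any(means < 0.0) or np.any(means > 1.0):
            raise ValueError("state_means must lie in [0, 1]")
        if np.any(occ < 0.0):
            raise ValueError("state_occupancies must be non-negative")
        if abs(float(occ.sum()) - 1.0) > 1e-12:
            raise ValueError(f"state_occupancies sum to {occ.sum()}, not 1")
        if self.gamma_range[0] <= 0 or self.gamma_range[0] > self.gamma_range[1]:
            raise ValueError("gamma_range must be positive and non-decreasing")
        if self.transition_rates is not None:
            q = np.asarray(self.transition_rates, dtype=float)
            if q.shape != (means.size, means.size):
                raise ValueError("transition_rates: must be n_states x n_states")
            off = q[~np.eye(means.size, dtype=bool)]
            if np.any(off < 0):
                raise ValueError("transition_rates: off-diagonal rates must be >= 0")
        return self

    def rate_matrix(self) -> np.ndarray:
        """Per-second generator matrix Q (rows sum to zero)."""
        n = len(self.state_means)
        if self.transition_rates is not None:
            q = np.asarray(self.transition_rates, dtype=float).copy()
        else:
            # k_ij = exchange_rate * pi_j for i != j -> stationary dist = pi.
            pi = np.asarray(self.state_occupancies, dtype=float)
            q = self.exchange_rate * np.tile(pi, (n, 1))
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the rate matrix (closed form via nullspace)."""
        q = self.rate_matrix()
        n = q.shape[0]
        if n == 1:
            return np.ones(1)
        a = np.vstack([q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        return np.clip(pi, 0.0, None) / pi.sum()


class MovieConfig(_StrictModel):
    """Rendering settings for synthetic two-channel TIRF stacks."""

    image_shape: tuple[int, int] = (256, 256)
    psf_sigma: float = 1.2
    min_separation: float = 10.0
    edge_margin: float = 22.0
    # Donor->acceptor channel affine as a 3x3 homogeneous matrix acting on
    # (x, y, 1); default is a pure translation.
    channel_transform: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.0, 3.0),
        (0.0, 1.0, -2.0),
        (0.0, 0.0, 1.0),
    )
    noise_free: bool = False
    pixel_read_noise: float = 10.0  # camera read noise per pixel (counts)
    registration_spot_intensity: float = 5000.0

    @field_validator("psf_sigma", "min_separation")
    @classmethod
    def _pos(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v

    def transform_matrix(self) -> np.ndarray:
        m = np.asarray(self.channel_transform, dtype=float)
        if m.shape != (3, 3) or abs(np.linalg.det(m[:2, :2])) < 1e-12:
            raise ValueError("channel_transform must be an invertible 3x3 affine")
        return m


class PatternConfig(_StrictModel):
    """Clustered 2D gold-particle point-pattern generator settings (nm units)."""

    n_clusters: int = 50
    cluster_size_mean: float = 4.0  # sizes ~ 1 + Poisson(mean - 1)
    cluster_sigma: float = 20.0
    field_size: tuple[float, float] = (10000.0, 10000.0)
    background_density: float = 0.0  # points per um^2
    min_center_separation_factor: float = 10.0
    n_images: int = 5

    @field_validator("cluster_sigma")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("cluster_sigma must be > 0")
        return v

    @model_validator(mode="after")
    def _check(self) -> "PatternConfig":
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if self.cluster_size_mean < 1.0:
            raise ValueError("cluster_size_mean must be >= 1 (sizes are 1 + Poisson)")
        return self


class CorrectionParams(_StrictModel):
    """Trace-correction settings: leakage, change-point penalty, gamma windows."""

    leakage_alpha: float = 0.07
    gamma_bounds: tuple[float, float] = (0.5, 2.5)
    gamma_window: int = 50
    step_penalty: float = 3.0  # multiplies sigma^2 * log(n)
    min_step_sigma: float = 3.0  # minimum downward step, in noise sigmas
    step_exclusion: int = 3  # frames dropped around each step in window stats
    snr_threshold: float = 5.0
    snr_median_window: int = 5
    snr_cap: float = 1e6
    anticorrelation_threshold: float = -0.3
    min_prebleach_frames: int = 20

    @field_validator("leakage_alpha")
    @classmethod
    def _leak(cls, v: float) -> float:
        if not (0.0 <= v < 1.0):
            raise ValueError("leakage_alpha must lie in [0, 1)")
        return v

    @model_validator(mode="after")
    def _check(self) -> "CorrectionParams":
        if self.gamma_bounds[0] >= self.gamma_bounds[1]:
            raise ValueError("gamma_bounds must be increasing")
        if self.gamma_bounds[0] <= 0:
            raise ValueError("gamma_bounds must be positive")
        if self.gamma_window < 5:
            raise ValueError("gamma_window must be >= 5 frames")
        if self.step_penalty <= 0 or self.min_step_sigma <= 0:
            raise ValueError("step_penalty and min_step_sigma must be > 0")
        return self


class ImagingParams(_StrictModel):
    """Spot detection / pairing / extraction settings."""

    neighborhood: int = 5
    threshold_sigma: float = 5.0
    max_pair_distance: float = 2.0
    aperture_diameter: float = 7.0
    bg_region_diameter: float = 35.0
    detection_frames: int = 100  # detection image = mean of first N donor-exc frames

    @model_validator(mode="after")
    def _check(self) -> "ImagingParams":
        if self.neighborhood < 3 or self.neighborhood % 2 == 0:
            raise ValueError("neighborhood must be an odd integer >= 3")
        if self.aperture_diameter >= self.bg_region_diameter:
            raise ValueError("aperture_diameter must be < bg_region_diameter")
        return self


class FitParams(_StrictModel):
    """Histogramming and two-Gaussian population-fit settings."""

    n_bins: int = 30
    hist_range: tuple[float, float] = (-0.25, 1.25)
    sigma_bounds: tuple[float, float] = (0.01, 0.2)
    shared_sigma: bool = False
    n_bootstrap: int = 200
    idealize: bool = False

    @model_validator(mode="after")
    def _check(self) -> "FitParams":
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.hist_range[0] >= self.hist_range[1]:
            raise ValueError("hist_range must be increasing")
        if self.n_bootstrap < 0:
            raise ValueError("n_bootstrap must be >= 0")
        if not (0 < self.sigma_bounds[0] < self.sigma_bounds[1]):
            raise ValueError("sigma_bounds must be increasing and positive")
        return self


class ClusterParams(_StrictModel):
    """Nanocluster statistics settings (nm units)."""

    linkage_radius: float = 100.0
    test: str = "mannwhitney"

    @model_validator(mode="after")
    def _check(self) -> "ClusterParams":
        if self.linkage_radius <= 0:
            raise ValueError("linkage_radius must be > 0")
        if self.test not in ("mannwhitney", "ks"):
            raise ValueError("test must be 'mannwhitney' or 'ks'")
        return self


class RunConfig(_StrictModel):
    """Full pipeline configuration (serializable, reproducible)."""

    seed: int = 0
    mode: str = "traces"  # "traces" (simulate trace set) or "movie" (render + extract)
    n_molecules: int = 200
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    movie: MovieConfig = Field(default_factory=MovieConfig)
    correction: CorrectionParams = Field(default_factory=CorrectionParams)
    imaging: ImagingParams = Field(default_factory=ImagingParams)
    fit: FitParams = Field(default_factory=FitParams)
    clusters: Optional[ClusterParams] = None
    # nanocluster branch: one point-pattern generator per condition label
    patterns: Optional[dict[str, PatternConfig]] = None

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.mode not in ("traces", "movie"):
            raise ValueError("mode must be 'traces' or 'movie'")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.correction.gamma_window * 2 >= self.simulation.n_frames_donor_exc:
            raise ValueError(
                "correction.gamma_window too large for the donor-excitation segment"
            )
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(raw: dict | str) -> RunConfig:
    """Build a RunConfig from a dict or YAML/JSON text; unknown keys are errors."""
    if isinstance(raw, str):
        import yaml

        data = yaml.safe_load(raw)
        if data is None:
            data = {}
    else:
        data = raw
    return RunConfig.model_validate(data)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed derived by hashing the stage name (< 2^31)."""
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
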