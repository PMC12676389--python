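"""Shared data containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class SpotPair:
    """A donor-channel spot matched to an acceptor-channel spot.

    ``acceptor_xy`` is the acceptor spot mapped into the donor frame;
    ``acceptor_xy_native`` keeps the original acceptor-channel coordinates
    used for trace extraction. Coordinates are (x, y), 0-based pixel centers.
    """

    donor_xy: tuple[float, float]
    acceptor_xy: Optional[tuple[float, float]]
    acceptor_xy_native: Optional[tuple[float, float]]
    pairing_distance: float
    donor_only: bool


@dataclass
class RawTrace:
    """Per-molecule uncorrected intensities over the donor-excitation segment.

    ``donor_raw``/``acceptor_raw`` are aperture sums (or simulated equivalents)
    including local background; ``bg_donor``/``bg_acceptor`` are the per-frame
    background estimates on the same scale. ``direct_acceptor`` holds the raw
    acceptor intensity during the direct acceptor-excitation segment used to
    confirm fluorophore identity.
    """

    molecule_id: str
    donor_raw: np.ndarray
    acceptor_raw: np.ndarray
    bg_donor: np.ndarray
    bg_acceptor: np.ndarray
    frame_period: float
    direct_acceptor: np.ndarray
    direct_bg_mean: float
    direct_bg_sigma: float
    spot: Optional[SpotPair] = None

    def __post_init__(self) -> None:
        n = len(self.donor_raw)
        if not (len(self.acceptor_raw) == len(self.bg_donor) == len(self.bg_acceptor) == n):
            raise ValueError("trace series must share the donor-excitation length")

    @property
    def n_frames(self) -> int:
        return len(self.donor_raw)

    @property
    def direct_acceptor_signal(self) -> float:
        """Mean background-subtracted acceptor intensity under direct excitation."""
        if len(self.direct_acceptor) == 0:
            return 0.0
        return float(np.mean(self.direct_acceptor) - self.direct_bg_mean)


@dataclass
class CorrectedTrace:
    """Background-, leakage- and bleach-annotated trace ready for QC and FRET."""

    molecule_id: str
    donor: np.ndarray
    acceptor: np.ndarray
    frame_period: float
    gamma: Optional[float]
    gamma_reason: Optional[str]
    acceptor_bleach_frame: Optional[int]
    donor_bleach_frame: Optional[int]
    acceptor_step_count: int
    donor_step_count: int
    snr: Optional[float]
    snr_reason: Optional[str]
    anticorrelation_r: Optional[float]
    is_dynamic: bool
    bleach_steps_anticorrelated: bool
    acceptor_confirmed: Optional[bool]  # None = not applicable (bleach-confirmed)
    corrected: bool = True  # idempotence guard

    @property
    def n_frames(self) -> int:
        return len(self.donor)


@dataclass
class QCReport:
    """Outcome of the five selection criteria plus acceptor-identity check."""

    molecule_id: str
    passed: bool
    criterion_results: dict[str, str]  # values: "pass" | "fail" | "not-applicable"
    reject_reason: Optional[str]


@dataclass
class MoleculeTruth:
    """Generator-side ground truth for one simulated molecule."""

    molecule_id: str
    mclass: str  # good | donor_only | acceptor_only | aggregate
    gamma: float
    acceptor_bleach_frame: Optional[int]
    donor_bleach_frame: Optional[int]
    states: Optional[np.ndarray] = None
    position_donor: Optional[tuple[float, float]] = None
    position_acceptor: Optional[tuple[float, float]] = None


@dataclass
class GroundTruth:
    molecules: list[MoleculeTruth] = field(default_factory=list)
    # point-pattern mode: per-point cluster labels (singleton background points
    # carry unique labels) and the true cluster-size multiset
    point_labels: Optional[np.ndarray] = None
    cluster_sizes: Optional[list[int]] = None

    def by_id(self, molecule_id: str) -> MoleculeTruth:
        for m in self.molecules:
            if m.molecule_id == molecule_id:
                return m
        raise KeyError(molecule_id)


@dataclass
class MovieStack:
    """Two-channel image time series with the excitation schedule."""

    donor: np.ndarray  # (T, H, W)
    acceptor: np.ndarray  # (T, H, W)
    frame_period: float
    donor_exc_range: tuple[int, int]  # half-open frame index range
    acceptor_exc_range: tuple[int, int]
    reg_donor: Optional[np.ndarray] = None
    reg_acceptor: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor stacks must share a shape")
        d0, d1 = self.donor_exc_range
        a0, a1 = self.acceptor_exc_range
        if not (0 == d0 < d1 == a0 < a1 == self.donor.shape[0]):
            raise ValueError(
                "excitation ranges must be disjoint, donor first, covering all frames"
            )


@dataclass
class FretTrace:
    """Frame-wise FRET efficiency with optional two-state idealization."""

    molecule_id: str
    efficiency: np.ndarray
    n_excluded: int  # invalid-denominator frames dropped before histogramming
    idealized_state: Optional[np.ndarray] = None
    dwell_times: Optional[list[tuple[int, float]]] = None
    is_static: bool = False


@dataclass
class EnsembleHistogram:
    bin_edges: np.ndarray  # n_bins + 1 edges
    per_molecule: np.ndarray  # (n_molecules, n_bins), rows sum to 1
    ensemble_mean: np.ndarray
    ensemble_sem: np.ndarray
    n_molecules: int
    n_excluded_values: int
    molecule_ids: list[str] = field(default_factory=list)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class GaussianMixtureFit:
    means: tuple[float, float]  # (mu_low, mu_high)
    sigmas: tuple[float, float]
    areas: tuple[float, float]
    fractions: tuple[float, float]  # areas normalized to sum 1
    fraction_sem: Optional[tuple[float, float]]
    rss: float
    n_molecules: int
    converged: bool
    bootstrap_warning: bool = False


@dataclass
class GoldParticleSet:
    """Labeled 2D point pattern of gold-nanoparticle immunolabels (nm)."""

    points: np.ndarray  # (N, 2) in nm
    image_id: str
    condition_label: str
    field_dimensions: tuple[float, float]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.points = pts
        w, h = self.field_dimensions
        if pts.size and (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
                         or pts[:, 0].max() > w or pts[:, 1].max() > h):
            raise ValueError("points must lie within the field bounds")


@dataclass
class ClusterStats:
    condition_label: str
    cluster_sizes: list[int]
    linkage_radius: float
    n_images: int
    per_image_sizes: dict[str, list[int]]

    @property
    def frequency_distribution(self) -> dict[int, int]:
        freq: dict[int, int] = {}
        for s in self.cluster_sizes:
            freq[s] = freq.get(s, 0) + 1
        return dict(sorted(freq.items()))

    def cumulative_probability(self) -> tuple[np.ndarray, np.ndarray]:
        """Sorted sizes and empirical CDF P(size <= s)."""
        sizes = np.sort(np.asarray(self.cluster_sizes))
        if sizes.size == 0:
            return sizes.astype(float), sizes.astype(float)
        uniq = np.unique(sizes)
        cdf = np.searchsorted(sizes, uniq, side="right") / sizes.size
        return uniq.astype(float), cdf
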