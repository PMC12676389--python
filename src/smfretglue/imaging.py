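"""Channel registration, spot detection/pairing, and trace extraction.

Spots are local intensity maxima within a square neighborhood (default side
5 px) above a robust threshold, refined to sub-pixel precision by local
centroid. The acceptor->donor mapping is an affine fitted by least squares to
fiducial spots matched across the two registration images. Intensities are
aperture sums, background-corrected per frame with the median of a local
circular region (default 35 px diameter) outside the aperture.
Coordinates are (x, y), 0-based pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import maximum_filter
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform

from .config import ImagingParams
from .types import MovieStack, RawTrace, SpotPair


@dataclass
class ChannelRegistration:
    """Affine map from acceptor-channel to donor-channel pixel coordinates."""

    transform: AffineTransform
    rms_residual: float
    n_control_points: int

    def acceptor_to_donor(self, xy: np.ndarray) -> np.ndarray:
        return self.transform(np.atleast_2d(xy))

    def donor_to_acceptor(self, xy: np.ndarray) -> np.ndarray:
        return self.transform.inverse(np.atleast_2d(xy))


class RegistrationError(RuntimeError):
    pass


def detect_spots(
    image: np.ndarray,
    neighborhood: int = 5,
    threshold_sigma: float = 5.0,
    refine: bool = True,
) -> np.ndarray:
    """Local maxima within a ``neighborhood`` x ``neighborhood`` window.

    The intensity threshold is background + ``threshold_sigma`` robust spreads
    (MAD-based); on noise-free images a small fraction of the dynamic range is
    used instead. Returns an (N, 2) array of (x, y) with sub-pixel centroid
    refinement.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    bg = float(np.median(img))
    spread = 1.4826 * float(np.median(np.abs(img - bg)))
    if spread > 0:
        thr = bg + threshold_sigma * spread
    else:
        # noise-free image: any spot is real, but per-molecule brightness
        # spans ~25x (gamma and FRET state), so keep the floor low
        rng_ = img.max() - bg
        if rng_ <= 0:
            return np.empty((0, 2))
        thr = bg + 0.02 * rng_
    footprint = np.ones((neighborhood, neighborhood), dtype=bool)
    maxima = (img == maximum_filter(img, footprint=footprint, mode="nearest")) & (
        img > thr
    )
    ys, xs = np.nonzero(maxima)
    if not refine or xs.size == 0:
        return np.column_stack([xs, ys]).astype(float)
    half = neighborhood // 2
    out = []
    h, w = img.shape
    for x0, y0 in zip(xs, ys):
        # log-parabolic interpolation: exact for a sampled Gaussian peak
        sub = _log_parabola_offset(img, x0, y0, bg)
        if sub is not None:
            out.append((x0 + sub[0], y0 + sub[1]))
            continue
        ylo, yhi = max(0, y0 - half), min(h, y0 + half + 1)
        xlo, xhi = max(0, x0 - half), min(w, x0 + half + 1)
        patch = np.clip(img[ylo:yhi, xlo:xhi] - bg, 0, None)
        total = patch.sum()
        if total <= 0:
            out.append((float(x0), float(y0)))
            continue
        yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
        out.append((float((xx * patch).sum() / total), float((yy * patch).sum() / total)))
    return np.asarray(out)


def _log_parabola_offset(img, x0, y0, bg):
    """Sub-pixel peak offset from a parabola through the log intensities of
    the three pixels bracketing the maximum in each axis."""
    h, w = img.shape
    if not (0 < x0 < w - 1 and 0 < y0 < h - 1):
        return None
    vals = img[y0 - 1:y0 + 2, x0 - 1:x0 + 2] - bg
    if np.any(vals[[0, 1, 2], [1, 1, 1]] <= 0) or np.any(vals[1, :] <= 0):
        return None
    lx = np.log(vals[1, :])
    ly = np.log(vals[:, 1])
    dx_den = lx[0] - 2 * lx[1] + lx[2]
    dy_den = ly[0] - 2 * ly[1] + ly[2]
    if dx_den >= 0 or dy_den >= 0:
        return None
    dx = 0.5 * (lx[0] - lx[2]) / dx_den
    dy = 0.5 * (ly[0] - ly[2]) / dy_den
    if abs(dx) > 1 or abs(dy) > 1:
        return None
    return float(dx), float(dy)


def register_channels(
    registration_image_donor: np.ndarray,
    registration_image_acceptor: np.ndarray,
    params: Optional[ImagingParams] = None,
    match_radius: float = 3.0,
) -> ChannelRegistration:
    """Fit the acceptor->donor affine from matched fiducial spots.

    An initial whole-image translation (phase correlation) seeds the
    nearest-neighbor matching; the affine is then fitted by least squares over
    all matches. Requires >= 3 non-collinear matched fiducials.
    """
    params = params or ImagingParams()
    spots_d = detect_spots(
        registration_image_donor, params.neighborhood, params.threshold_sigma
    )
    spots_a = detect_spots(
        registration_image_acceptor, params.neighborhood, params.threshold_sigma
    )
    if len(spots_d) < 3 or len(spots_a) < 3:
        raise RegistrationError("need at least 3 fiducial spots in both images")
    shift, *_ = phase_cross_correlation(
        np.asarray(registration_image_donor, dtype=float),
        np.asarray(registration_image_acceptor, dtype=float),
        upsample_factor=10,
    )
    # scikit-image returns (row, col) shifts of acceptor relative to donor
    rough = spots_a + np.array([shift[1], shift[0]])
    src, dst = [], []
    used: set[int] = set()
    for i, p in enumerate(rough):
        d2 = np.sum((spots_d - p) ** 2, axis=1)
        j = int(np.argmin(d2))
        if d2[j] <= match_radius**2 and j not in used:
            src.append(spots_a[i])
            dst.append(spots_d[j])
            used.add(j)
    if len(src) < 3:
        raise RegistrationError(
            f"only {len(src)} fiducial matches within {match_radius} px"
        )
    src_a = np.asarray(src)
    dst_a = np.asarray(dst)
    centered = dst_a - dst_a.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-6) < 2:
        raise RegistrationError("control points are collinear")
    tform = AffineTransform.from_estimate(src_a, dst_a)
    if not tform:
        raise RegistrationError("affine estimation failed")
    resid = tform(src_a) - dst_a
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return ChannelRegistration(
        transform=tform, rms_residual=rms, n_control_points=len(src_a)
    )


def pair_spots(
    donor_spots: np.ndarray,
    acceptor_spots: np.ndarray,
    registration: ChannelRegistration,
    max_pair_distance: float = 2.0,
    donor_intensities: Optional[np.ndarray] = None,
) -> list[SpotPair]:
    """Greedy nearest-neighbor pairing in the donor frame.

    Acceptor spots are mapped into the donor frame first; each acceptor spot
    is used at most once. Unmatched donor spots are flagged donor-only (the
    analysis excludes them). Ties in distance go to the brighter donor spot
    when intensities are supplied.
    """
    donor_spots = np.atleast_2d(np.asarray(donor_spots, dtype=float))
    acceptor_spots = np.atleast_2d(np.asarray(acceptor_spots, dtype=float))
    pairs: list[SpotPair] = []
    if donor_spots.size == 0:
        return pairs
    if acceptor_spots.size == 0:
        mapped = np.empty((0, 2))
    else:
        mapped = registration.acceptor_to_donor(acceptor_spots)

    candidates = []
    for i, d in enumerate(donor_spots):
        for j, a in enumerate(mapped):
            dist = float(np.hypot(*(d - a)))
            if dist <= max_pair_distance:
                brightness = (
                    -float(donor_intensities[i]) if donor_intensities is not None else 0.0
                )
                candidates.append((dist, brightness, i, j))
    candidates.sort()
    used_d: set[int] = set()
    used_a: set[int] = set()
    matched: dict[int, tuple[int, float]] = {}
    for dist, _, i, j in candidates:
        if i in used_d or j in used_a:
            continue
        used_d.add(i)
        used_a.add(j)
        matched[i] = (j, dist)
    for i, d in enumerate(donor_spots):
        if i in matched:
            j, dist = matched[i]
            pairs.append(
                SpotPair(
                    donor_xy=(float(d[0]), float(d[1])),
                    acceptor_xy=(float(mapped[j, 0]), float(mapped[j, 1])),
                    acceptor_xy_native=(
                        float(acceptor_spots[j, 0]),
                        float(acceptor_spots[j, 1]),
                    ),
                    pairing_distance=dist,
                    donor_only=False,
                )
            )
        else:
            pairs.append(
                SpotPair(
                    donor_xy=(float(d[0]), float(d[1])),
                    acceptor_xy=None,
                    acceptor_xy_native=None,
                    pairing_distance=float("inf"),
                    donor_only=True,
                )
            )
    return pairs


class TraceSkipped(RuntimeError):
    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def _disk_indices(
    center: tuple[float, float], radius: float, shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    cx, cy = center
    h, w = shape
    r = int(np.ceil(radius))
    ylo, yhi = max(0, int(cy) - r - 1), min(h, int(cy) + r + 2)
    xlo, xhi = max(0, int(cx) - r - 1), min(w, int(cx) + r + 2)
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    return yy[mask], xx[mask]


def extract_trace(
    movie: MovieStack,
    pair: SpotPair,
    params: Optional[ImagingParams] = None,
    other_spots_donor: Optional[np.ndarray] = None,
    molecule_id: str = "mol",
) -> RawTrace:
    """Aperture-sum intensity trace for one spot pair.

    Background per frame is the median pixel value inside the background
    region but outside the aperture (excluding pixels near other detected
    spots), scaled to the aperture pixel count. Raises TraceSkipped("edge")
    when the background region leaves the image and TraceSkipped("crowded")
    when a neighboring spot sits within one aperture diameter.
    """
    params = params or ImagingParams()
    if pair.donor_only or pair.acceptor_xy_native is None:
        raise TraceSkipped("donor_only")
    h, w = movie.donor.shape[1:]
    ap_r = params.aperture_diameter / 2.0
    bg_r = params.bg_region_diameter / 2.0

    for cx, cy in (pair.donor_xy, pair.acceptor_xy_native):
        if cx - bg_r < 0 or cy - bg_r < 0 or cx + bg_r > w - 1 or cy + bg_r > h - 1:
            raise TraceSkipped("edge")
    if other_spots_donor is not None and len(other_spots_donor):
        d = np.hypot(
            other_spots_donor[:, 0] - pair.donor_xy[0],
            other_spots_donor[:, 1] - pair.donor_xy[1],
        )
        d = d[d > 1e-6]
        if d.size and d.min() < params.aperture_diameter:
            raise TraceSkipped("crowded")

    d0, d1 = movie.donor_exc_range
    a0, a1 = movie.acceptor_exc_range

    def channel_series(stack: np.ndarray, center, exclude=None):
        ys_ap, xs_ap = _disk_indices(center, ap_r, (h, w))
        ys_bg, xs_bg = _disk_indices(center, bg_r, (h, w))
        in_ap = (xs_bg - center[0]) ** 2 + (ys_bg - center[1]) ** 2 <= ap_r**2
        keep = ~in_ap
        if exclude is not None and len(exclude):
            for ox, oy in exclude:
                if (ox - center[0]) ** 2 + (oy - center[1]) ** 2 < (2 * bg_r) ** 2:
                    keep &= (xs_bg - ox) ** 2 + (ys_bg - oy) ** 2 > ap_r**2
        ys_bg, xs_bg = ys_bg[keep], xs_bg[keep]
        aperture = stack[:, ys_ap, xs_ap].sum(axis=1)
        bg_median = np.median(stack[:, ys_bg, xs_bg], axis=1)
        return aperture, bg_median * ys_ap.size

    donor_ap, donor_bg = channel_series(
        movie.donor, pair.donor_xy, exclude=other_spots_donor
    )
    acceptor_ap, acceptor_bg = channel_series(movie.acceptor, pair.acceptor_xy_native)

    direct = acceptor_ap[a0:a1] - acceptor_bg[a0:a1]
    direct_bg_sigma = float(np.std(acceptor_ap[d0:d1] - acceptor_bg[d0:d1]))
    # conservative per-frame noise scale for the identity test: reuse the
    # donor-excitation acceptor fluctuation when the direct segment is short
    if len(direct) >= 3:
        direct_bg_sigma = max(direct_bg_sigma, float(np.std(direct - np.mean(direct))))

    return RawTrace(
        molecule_id=molecule_id,
        donor_raw=donor_ap[d0:d1],
        acceptor_raw=acceptor_ap[d0:d1],
        bg_donor=donor_bg[d0:d1],
        bg_acceptor=acceptor_bg[d0:d1],
        frame_period=movie.frame_period,
        direct_acceptor=direct,
        direct_bg_mean=0.0,
        direct_bg_sigma=direct_bg_sigma,
        spot=pair,
    )


def extract_all_traces(
    movie: MovieStack,
    params: Optional[ImagingParams] = None,
) -> tuple[list[RawTrace], dict]:
    """Detect, register, pair and extract every usable molecule in a movie.

    Returns the traces and a per-stage accounting dict (detected counts,
    paired, donor-only, edge/crowded skips).
    """
    params = params or ImagingParams()
    if movie.reg_donor is None or movie.reg_acceptor is None:
        raise ValueError("movie carries no registration images")
    registration = register_channels(movie.reg_donor, movie.reg_acceptor, params)

    d0, d1 = movie.donor_exc_range
    a0, a1 = movie.acceptor_exc_range
    n_det = min(params.detection_frames, d1 - d0)
    detection_donor = movie.donor[d0:d0 + n_det].mean(axis=0)
    detection_acceptor = np.concatenate(
        [movie.acceptor[d0:d0 + n_det], movie.acceptor[a0:a1]], axis=0
    ).mean(axis=0)

    spots_d = detect_spots(detection_donor, params.neighborhood, params.threshold_sigma)
    spots_a = detect_spots(
        detection_acceptor, params.neighborhood, params.threshold_sigma
    )
    pairs = pair_spots(spots_d, spots_a, registration, params.max_pair_distance)

    counts = {
        "detected_donor": int(len(spots_d)),
        "detected_acceptor": int(len(spots_a)),
        "paired": int(sum(not p.donor_only for p in pairs)),
        "donor_only_excluded": int(sum(p.donor_only for p in pairs)),
        "skipped_edge": 0,
        "skipped_crowded": 0,
        "registration_rms": registration.rms_residual,
        "registration_points": registration.n_control_points,
    }
    traces: list[RawTrace] = []
    k = 0
    for p in pairs:
        if p.donor_only:
            continue
        try:
            tr = extract_trace(
                movie, p, params, other_spots_donor=spots_d, molecule_id=f"mol{k:05d}"
            )
        except TraceSkipped as exc:
            key = f"skipped_{exc.reason}"
            counts[key] = counts.get(key, 0) + 1
            continue
        traces.append(tr)
        k += 1
    counts["extracted"] = len(traces)
    return traces, counts
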