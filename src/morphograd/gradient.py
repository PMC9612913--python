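"""Ligand gradient extraction and inter-embryo normalization.

Covers the image-analysis chain for source-injected and clone-transplant
embryos: masking the source region in the far-red tracer channel, maximum
intensity projection, distance-binned profile extraction with artifact
masking, background subtraction against uninjected controls, the
inter-embryo normalization model

    I_n(x) = A_n * c_bar(x) + b_n

(embryo-specific proportionality constant ``A_n`` and non-specific
background ``b_n``, fit by least squares against the mean profile
``c_bar``), origin normalization, punctum detection, and radial clone-edge
profiles.

Distances are continuous micrometers measured from the reference boundary
(source edge or clone edge); bins with no contributing pixel carry NaN,
never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_isodata
from skimage.measure import label, regionprops
from skimage.morphology import h_maxima

__all__ = [
    "IntensityProfile",
    "NormalizationResult",
    "ysl_mask",
    "max_project",
    "extract_profile",
    "subtract_background",
    "fit_profile_normalization",
    "normalize_to_origin",
    "detect_puncta",
    "clone_edge_profile",
]


@dataclass(frozen=True)
class IntensityProfile:
    """A 1-D fluorescence profile vs distance from a reference boundary.

    ``intensity`` entries are per-bin means; bins without contributing
    pixels hold NaN.  ``reference`` tags the boundary the distances are
    measured from: ``"ysl"``, ``"clone_edge"`` or ``"margin"``.
    """

    distance_um: np.ndarray
    intensity: np.ndarray
    n_pixels: np.ndarray | None = None
    embryo_id: str = ""
    reference: str = "ysl"

    def __post_init__(self) -> None:
        d = np.asarray(self.distance_um, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "distance_um", d)
        object.__setattr__(self, "intensity", i)
        if d.shape != i.shape:
            raise ValueError("distance and intensity must have equal length")
        if np.any(np.diff(d) <= 0):
            raise ValueError("distances must be strictly increasing")
        if np.any(d < 0):
            raise ValueError("distances must be >= 0")
        if self.n_pixels is None:
            object.__setattr__(self, "n_pixels", np.ones(len(d), dtype=int))
        else:
            n = np.asarray(self.n_pixels, dtype=int)
            object.__setattr__(self, "n_pixels", n)
            if np.any(n < 0):
                raise ValueError("n_pixels must be >= 0")


@dataclass(frozen=True)
class NormalizationResult:
    """Mean profile and per-embryo (A_n, b_n) least-squares solutions."""

    distance_um: np.ndarray
    mean_profile: np.ndarray
    A: np.ndarray
    b: np.ndarray
    ss_res: np.ndarray
    embryo_ids: tuple[str, ...]


def ysl_mask(farred: np.ndarray) -> np.ndarray:
    """Mask the tracer-filled source region by iterative-intermeans threshold.

    Pixels above the isodata (iterative intermeans) threshold of the far-red
    channel are True; downstream profile extraction excludes them.  A
    constant image yields an empty mask with a warning.
    """
    farred = np.asarray(farred, dtype=float)
    if farred.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if np.ptp(farred) == 0:
        warnings.warn("constant image: no threshold exists, returning empty mask")
        return np.zeros(farred.shape, dtype=bool)
    thr = threshold_isodata(farred)
    return farred > thr


def max_project(stack: np.ndarray, slice_range: tuple[int, int] | None = None) -> np.ndarray:
    """Pixelwise maximum intensity projection over ``slice_range`` (half-open)."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a 3-D (z, y, x) stack")
    if slice_range is None:
        slice_range = (0, stack.shape[0])
    a, b = slice_range
    if not (0 <= a < b <= stack.shape[0]):
        raise ValueError(f"empty or out-of-range slice range [{a}, {b})")
    return stack[a:b].max(axis=0)


def extract_profile(
    projection: np.ndarray,
    pixel_size_um: float,
    mask: np.ndarray | None = None,
    bin_um: float | None = None,
    embryo_id: str = "",
    reference: str = "ysl",
) -> IntensityProfile:
    """Distance-binned mean intensity from the source edge.

    The projection must be oriented with the source edge along the left
    image border (column 0), so distance from the source grows with the
    column index.  ``mask`` marks pixels to exclude (source region, pixels
    outside the embryo, staining artifacts); they are dropped from the bin
    means, not zeroed.  Default bin width is one pixel.
    """
    img = np.asarray(projection, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D projection")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    if mask is None:
        mask = np.zeros(img.shape, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape mismatch")
    if bin_um is None:
        bin_um = pixel_size_um

    cols_um = (np.arange(img.shape[1]) + 0.5) * pixel_size_um
    bin_idx = np.floor(cols_um / bin_um).astype(int)
    n_bins = bin_idx.max() + 1

    vals = np.where(mask, np.nan, img)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for j in range(img.shape[1]):
        col = vals[:, j]
        good = ~np.isnan(col)
        sums[bin_idx[j]] += col[good].sum()
        counts[bin_idx[j]] += int(good.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_um
    return IntensityProfile(
        distance_um=centers,
        intensity=means,
        n_pixels=counts,
        embryo_id=embryo_id,
        reference=reference,
    )


def _interp_onto(profile: IntensityProfile, grid: np.ndarray) -> np.ndarray:
    """Linear interpolation onto ``grid``; outside the profile extent -> NaN."""
    d, y = profile.distance_um, profile.intensity
    good = ~np.isnan(y)
    out = np.interp(grid, d[good], y[good], left=np.nan, right=np.nan)
    out[(grid < d[good].min()) | (grid > d[good].max())] = np.nan
    return out


def _common_grid(profiles: Sequence[IntensityProfile]) -> np.ndarray:
    """Coarsest input grid, spanning the largest shared origin-anchored range."""
    spacings = [np.min(np.diff(p.distance_um)) for p in profiles]
    coarsest = profiles[int(np.argmax(spacings))]
    return coarsest.distance_um.copy()


def subtract_background(
    profiles: Sequence[IntensityProfile],
    control_profiles: Sequence[IntensityProfile],
) -> list[IntensityProfile]:
    """Subtract the per-bin median of uninjected-control profiles.

    Controls are interpolated onto each profile's grid.  Resulting
    intensities may be negative (no clipping: keeps bin means unbiased).
    """
    out = []
    for p in profiles:
        ctrl = np.vstack([_interp_onto(c, p.distance_um) for c in control_profiles])
        if np.all(np.isnan(ctrl)):
            raise ValueError("control profiles do not overlap the profile grid")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(ctrl, axis=0)
        out.append(replace(p, intensity=p.intensity - med))
    return out


def fit_profile_normalization(
    profiles: Sequence[IntensityProfile],
    iterate: int = 0,
) -> NormalizationResult:
    """Fit I_n(x) = A_n c_bar(x) + b_n per embryo by ordinary least squares.

    ``c_bar(x)`` is the pointwise mean of the (background-subtracted) input
    profiles on the common grid, computed once; ``A_n`` and ``b_n`` minimize
    each embryo's sum of squared differences from ``A_n c_bar + b_n`` —
    the closed-form two-parameter least-squares solution with regressor
    ``c_bar``.  (A_n, b_n) are identifiable only relative to the gauge of
    c_bar: ratios of A_n and differences of b_n are meaningful.

    ``iterate > 0`` recomputes c_bar from the normalized profiles that many
    times (optional refinement, off by default).
    """
    if len(profiles) < 2:
        raise ValueError("at least two profiles required")
    grid = _common_grid(profiles)
    Y = np.vstack([_interp_onto(p, grid) for p in profiles])

    def solve(cbar: np.ndarray):
        A = np.empty(len(profiles))
        b = np.empty(len(profiles))
        ss = np.empty(len(profiles))
        for i, y in enumerate(Y):
            good = ~np.isnan(y) & ~np.isnan(cbar)
            cb, yy = cbar[good], y[good]
            var = np.var(cb)
            if var == 0:
                raise ValueError(
                    f"mean profile constant in x: A_n unidentifiable for embryo "
                    f"{profiles[i].embryo_id or i}"
                )
            A[i] = np.cov(cb, yy, bias=True)[0, 1] / var
            b[i] = yy.mean() - A[i] * cb.mean()
            ss[i] = float(np.sum((yy - A[i] * cb - b[i]) ** 2))
        return A, b, ss

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cbar = np.nanmean(Y, axis=0)
    A, b, ss = solve(cbar)
    for _ in range(iterate):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cbar = np.nanmean((Y - b[:, None]) / A[:, None], axis=0)
        A, b, ss = solve(cbar)
    return NormalizationResult(
        distance_um=grid,
        mean_profile=cbar,
        A=A,
        b=b,
        ss_res=ss,
        embryo_ids=tuple(p.embryo_id for p in profiles),
    )


def normalize_to_origin(profile: IntensityProfile, atol_um: float = 1e-6) -> IntensityProfile:
    """Divide by the intensity of the first (distance ~ 0) bin.

    The bin covering distance 0 is the profile's first bin; its value must
    be present and nonzero.
    """
    v0 = profile.intensity[0]
    if np.isnan(v0) or v0 == 0:
        raise ValueError("origin bin value missing or zero")
    return replace(profile, intensity=profile.intensity / v0)


def detect_puncta(
    projection: np.ndarray,
    pixel_size_um: float,
    min_prominence: float,
    min_separation_um: float,
) -> np.ndarray:
    """Find punctate local maxima; returns (x_um, y_um) coordinates.

    Maxima with prominence >= ``min_prominence`` (via h-maxima morphological
    reconstruction) and pairwise separation >= ``min_separation_um`` are
    reported.  A flat image yields an empty array.  The x coordinate doubles
    as the distance from the left-edge reference for distance distributions.
    """
    if min_prominence <= 0 or min_separation_um <= 0:
        raise ValueError("thresholds must be positive")
    img = np.asarray(projection, dtype=float)
    if np.ptp(img) == 0:
        return np.empty((0, 2))
    peaks = h_maxima(img, min_prominence)
    lab = label(peaks)
    props = regionprops(lab, intensity_image=img)
    # a punctum is compact: reject ridge/plateau maxima of smooth structures
    # (e.g. the gradient crest itself), whose reconstructed region is large
    min_sep_px_area = np.pi * (min_separation_um / pixel_size_um) ** 2
    props = [r for r in props if r.area <= min_sep_px_area]
    # centroid per plateau, brightest first for separation enforcement
    cands = sorted(props, key=lambda r: -r.intensity_max)
    coords: list[tuple[float, float]] = []
    min_sep_px = min_separation_um / pixel_size_um
    for r in cands:
        cy, cx = r.centroid
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep_px**2 for y, x in coords):
            coords.append((cy, cx))
    if not coords:
        return np.empty((0, 2))
    arr = np.array(coords)  # (y, x) px
    return np.column_stack([arr[:, 1] * pixel_size_um, arr[:, 0] * pixel_size_um])


def clone_edge_profile(
    ligand: np.ndarray,
    farred: np.ndarray,
    pixel_size_um: float,
    edge_threshold: float = 700.0,
    roi_width_um: float = 70.0,
    control_median: float = 0.0,
    bin_um: float | None = None,
    max_distance_um: float | None = None,
    embryo_id: str = "",
    normalize: bool = True,
) -> IntensityProfile:
    """Radial ligand profile from the edge of a transplanted clone.

    The clone boundary is the outermost contour of far-red tracer above
    ``edge_threshold``.  Linear ROIs of width ``roi_width_um`` are laid out
    radially around the clone (tiling all directions); ligand intensity is
    averaged per ROI per distance-from-edge bin and then across ROIs.  The
    ``control_median`` background (median ligand intensity of tracer-only
    control transplants) is subtracted, and the profile is normalized to its
    value at distance 0 from the clone edge.
    """
    ligand = np.asarray(ligand, dtype=float)
    farred = np.asarray(farred, dtype=float)
    clone = farred >= edge_threshold
    if not clone.any():
        raise ValueError("no clone detected: no far-red pixel above threshold")
    # keep the largest connected component as the clone
    lab = label(clone)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    clone = lab == sizes.argmax()

    if bin_um is None:
        bin_um = pixel_size_um
    # distance from the clone edge for every outside pixel
    dist_px = ndimage.distance_transform_edt(~clone)
    dist_um = dist_px * pixel_size_um
    cy, cx = ndimage.center_of_mass(clone)
    yy, xx = np.mgrid[0 : ligand.shape[0], 0 : ligand.shape[1]]
    theta = np.arctan2(yy - cy, xx - cx) % (2 * np.pi)

    # angular sectors whose arc width at the mean edge radius ~ roi_width_um
    edge_r_um = float(np.mean(np.hypot(yy[clone] - cy, xx[clone] - cx))) * pixel_size_um
    n_rois = max(1, int(round(2 * np.pi * max(edge_r_um, bin_um) / roi_width_um)))
    sector = np.minimum((theta / (2 * np.pi) * n_rois).astype(int), n_rois - 1)

    outside = ~clone
    if max_distance_um is not None:
        outside &= dist_um < max_distance_um
    n_bins = int(np.ceil(dist_um[outside].max() / bin_um))
    bin_of = np.minimum((dist_um / bin_um).astype(int), n_bins - 1)

    # per-sector per-bin means, then mean over sectors with data
    flat = sector[outside] * n_bins + bin_of[outside]
    sums = np.bincount(flat, weights=ligand[outside], minlength=n_rois * n_bins)
    counts = np.bincount(flat, minlength=n_rois * n_bins)
    with np.errstate(invalid="ignore"):
        per_roi = (sums / counts).reshape(n_rois, n_bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        prof = np.nanmean(per_roi, axis=0)
    n_pix = counts.reshape(n_rois, n_bins).sum(axis=0)

    centers = (np.arange(n_bins) + 0.5) * bin_um
    profile = IntensityProfile(
        distance_um=centers,
        intensity=prof - control_median,
        n_pixels=n_pix,
        embryo_id=embryo_id,
        reference="clone_edge",
    )
    return normalize_to_origin(profile) if normalize else profile
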