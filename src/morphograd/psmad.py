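"""Nuclear pSmad2/3 immunofluorescence quantification.

The nuclear phospho-Smad2/3 stain is the direct readout of Nodal signaling
activity.  This module masks nuclei from the DAPI channel, extracts
margin-to-animal-pole intensity profiles, counts contiguous positive nuclei
tiers (the signaling-range unit: one nucleus-wide band parallel to the
margin), quantifies transplant-derived signaling ranges normalized per
transplanted cell, and counts positive nuclei beyond the animal-most
transplanted nucleus.

Conventions: the embryonic margin lies along the left image border
(column 0); "towards the animal pole" is increasing x.  Distances are
continuous um from the margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .gradient import IntensityProfile

__all__ = [
    "NucleusRecord",
    "TransplantQuant",
    "nuclear_mask",
    "margin_profile",
    "positivity_threshold",
    "classify_nuclei",
    "count_tiers",
    "count_cells",
    "transplant_profile",
    "quantify_transplant",
    "count_animal_positive",
]

DEFAULT_NUCLEAR_DIAMETER_UM = 8.0


@dataclass(frozen=True)
class NucleusRecord:
    """One nucleus: position, mean pSmad intensity, positivity and tier."""

    centroid_um: tuple[float, float]  # (x, y)
    mean_psmad_intensity: float
    is_positive: bool
    distance_from_margin_um: float
    tier_index: int  # 1-based from the margin

    def __post_init__(self) -> None:
        if self.tier_index < 1:
            raise ValueError("tier_index is 1-based")


@dataclass(frozen=True)
class TransplantQuant:
    """Quantification of one marginal-cell transplant."""

    cell_count: int
    profile: IntensityProfile  # per-cell-normalized, from the transplant edge
    intensity_in_transplant: float
    animal_positive_count: int

    def __post_init__(self) -> None:
        if self.cell_count < 1:
            raise ValueError("a valid transplant has cell_count >= 1")


def nuclear_mask(
    dapi: np.ndarray, pixel_size_um: float, min_size_um2: float = 10.0
) -> np.ndarray:
    """Otsu-threshold the DAPI projection and drop specks below min_size_um2.

    Downstream quantification reads pSmad intensities only under this mask.
    """
    dapi = np.asarray(dapi, dtype=float)
    if np.ptp(dapi) == 0:
        warnings.warn("blank DAPI channel: empty nuclear mask")
        return np.zeros(dapi.shape, dtype=bool)
    mask = dapi > threshold_otsu(dapi)
    min_px = max(1, int(round(min_size_um2 / pixel_size_um**2)))
    return remove_small_objects(mask, max_size=min_px - 1)


def margin_profile(
    psmad: np.ndarray,
    mask: np.ndarray,
    pixel_size_um: float,
    roi: tuple[slice, slice],
    background_region: tuple[slice, slice],
    normalizer: float,
    bin_um: float | None = None,
    embryo_id: str = "",
) -> IntensityProfile:
    """Margin-to-animal-pole profile of nuclear pSmad intensity.

    ``roi`` is a (rows, cols) rectangle with its base on the margin (left
    border).  Per-distance means use only nuclear-mask pixels.  The
    background — the median intensity of ``background_region`` near the
    animal pole — is subtracted, and the result is divided by
    ``normalizer`` (the average wild-type lateral marginal-zone signal).
    """
    if normalizer <= 0:
        raise ValueError("normalizer must be > 0")
    psmad = np.asarray(psmad, dtype=float)
    if bin_um is None:
        bin_um = pixel_size_um
    bg_vals = psmad[background_region][mask[background_region]]
    if bg_vals.size == 0:
        bg_vals = psmad[background_region].ravel()
    background = float(np.median(bg_vals))

    sub = psmad[roi]
    sub_mask = mask[roi]
    col0 = roi[1].start or 0
    cols_um = (np.arange(col0, col0 + sub.shape[1]) + 0.5) * pixel_size_um
    bin_idx = np.floor(cols_um / bin_um).astype(int)
    n_bins = bin_idx.max() + 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for j in range(sub.shape[1]):
        sel = sub_mask[:, j]
        sums[bin_idx[j]] += sub[sel, j].sum()
        counts[bin_idx[j]] += int(sel.sum())
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    first = bin_idx[0]
    centers = (np.arange(first, n_bins) + 0.5) * bin_um
    return IntensityProfile(
        distance_um=centers - first * bin_um if first else centers,
        intensity=(means[first:] - background) / normalizer,
        n_pixels=counts[first:],
        embryo_id=embryo_id,
        reference="margin",
    )


def positivity_threshold(background_values: np.ndarray) -> float:
    """Default positivity rule: background median + 3 x background MAD."""
    bg = np.asarray(background_values, dtype=float)
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    return med + 3.0 * mad


def classify_nuclei(
    centroids_um: np.ndarray,
    intensities: np.ndarray,
    threshold: float,
    nuclear_diameter_um: float = DEFAULT_NUCLEAR_DIAMETER_UM,
) -> list[NucleusRecord]:
    """Build NucleusRecords from centroids (x from margin) and intensities."""
    recs = []
    for (x, y), inten in zip(np.asarray(centroids_um, float), intensities):
        tier = int(np.floor(x / nuclear_diameter_um)) + 1
        recs.append(
            NucleusRecord(
                centroid_um=(float(x), float(y)),
                mean_psmad_intensity=float(inten),
                is_positive=bool(inten > threshold),
                distance_from_margin_um=float(x),
                tier_index=tier,
            )
        )
    return recs


def count_tiers(
    nuclei: Sequence[NucleusRecord],
    nuclear_diameter_um: float = DEFAULT_NUCLEAR_DIAMETER_UM,
    contiguous: bool = True,
) -> int:
    """Maximum number of positive nuclei tiers from the margin.

    Tier ``i`` spans distances ``[(i-1)*d, i*d)`` from the margin for
    nuclear diameter ``d``.  The default (contiguous) rule returns the
    largest T such that every tier 1..T holds at least one positive nucleus,
    implementing "maximum number of positive tiers from the margin towards
    the animal pole"; ``contiguous=False`` returns the highest occupied
    positive tier instead.
    """
    if nuclear_diameter_um <= 0:
        raise ValueError("nuclear_diameter_um must be > 0")
    pos_tiers = {
        int(np.floor(n.distance_from_margin_um / nuclear_diameter_um)) + 1
        for n in nuclei
        if n.is_positive
    }
    if not pos_tiers:
        return 0
    if not contiguous:
        return max(pos_tiers)
    t = 0
    while (t + 1) in pos_tiers:
        t += 1
    return t


def count_cells(
    stack: np.ndarray,
    pixel_size_um: float,
    z_step_um: float,
    spot_diameter_um: float = 8.0,
    quality_threshold: float = 0.1,
    exclusions_um: Sequence[tuple[float, float, float]] | None = None,
) -> tuple[int, np.ndarray]:
    """Count transplanted nuclei in a 3-D stack by scale-matched blob detection.

    Laplacian-of-Gaussian detection at sigma matched to ``spot_diameter_um``
    (radius = sigma * sqrt(ndim)); responses below ``quality_threshold`` are
    dropped.  ``exclusions_um`` is an explicit list of (z, y, x) um
    coordinates of spurious detections to remove (within one spot radius) —
    the programmatic stand-in for manual curation.

    Returns (count, coordinates) with coordinates as (z, y, x) in um.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a 3-D (z, y, x) stack")
    if stack.size == 0 or np.ptp(stack) == 0:
        return 0, np.empty((0, 3))
    radius_um = spot_diameter_um / 2.0
    # sigma matched to the spot radius (r = sigma*sqrt(ndim)); clamped to
    # >= 0.8 voxel per axis so a coarse z-step does not amplify voxel noise
    sigma_xy = max(radius_um / pixel_size_um / np.sqrt(3), 0.8)
    sigma_z = max(radius_um / z_step_um / np.sqrt(3), 0.8)
    resp = -ndimage.gaussian_laplace(stack, (sigma_z, sigma_xy, sigma_xy)) * sigma_xy**2
    min_dist_px = max(1, int(round(radius_um / pixel_size_um)))
    peaks = peak_local_max(
        resp, min_distance=min_dist_px, threshold_abs=quality_threshold,
        exclude_border=False,
    )
    if peaks.size == 0:
        return 0, np.empty((0, 3))
    coords = peaks.astype(float) * np.array([z_step_um, pixel_size_um, pixel_size_um])
    if exclusions_um:
        keep = np.ones(len(coords), dtype=bool)
        for ex in np.asarray(exclusions_um, float):
            d = np.linalg.norm(coords - ex, axis=1)
            keep &= d > radius_um
        coords = coords[keep]
    return len(coords), coords


def transplant_profile(
    psmad: np.ndarray,
    pixel_size_um: float,
    edge_col_px: int,
    center_row_px: int,
    cell_count: int,
    background_level: float,
    height_um: float = 100.0,
    bin_um: float | None = None,
    embryo_id: str = "",
) -> IntensityProfile:
    """Per-cell-normalized pSmad profile extending from the transplant edge.

    A rectangular ROI of height ``height_um`` centered on ``center_row_px``
    runs from ``edge_col_px`` (the transplant edge) in the direction of
    increasing x.  Per-distance means minus ``background_level`` are divided
    by ``cell_count`` to correct for transplant size.
    """
    if cell_count < 1:
        raise ValueError("cell_count must be >= 1")
    psmad = np.asarray(psmad, dtype=float)
    if bin_um is None:
        bin_um = pixel_size_um
    half_rows = int(round(height_um / pixel_size_um / 2))
    r0 = max(0, center_row_px - half_rows)
    r1 = min(psmad.shape[0], center_row_px + half_rows)
    if r1 <= r0 or edge_col_px >= psmad.shape[1]:
        raise ValueError("empty transplant ROI")
    sub = psmad[r0:r1, edge_col_px:]
    dist_um = (np.arange(sub.shape[1]) + 0.5) * pixel_size_um
    bin_idx = np.floor(dist_um / bin_um).astype(int)
    n_bins = bin_idx.max() + 1
    sums = np.bincount(bin_idx, weights=sub.mean(axis=0), minlength=n_bins)
    counts = np.bincount(bin_idx, minlength=n_bins)
    means = sums / counts
    centers = (np.arange(n_bins) + 0.5) * bin_um
    return IntensityProfile(
        distance_um=centers,
        intensity=(means - background_level) / cell_count,
        n_pixels=counts * (r1 - r0),
        embryo_id=embryo_id,
        reference="clone_edge",
    )


def quantify_transplant(
    psmad: np.ndarray,
    pixel_size_um: float,
    nuclei: Sequence[NucleusRecord],
    transplant_coords_um: np.ndarray,
    background_level: float,
    height_um: float = 100.0,
    measure_radius_um: float = 20.0,
    embryo_id: str = "",
) -> TransplantQuant:
    """Full quantification of one transplant from its detected nuclei.

    Combines the per-cell-normalized range profile (ROI anchored at the
    transplant edge, i.e. its animal-most nucleus), the mean pSmad intensity
    inside a fixed-size circular region at the transplant centroid, and the
    count of positive host nuclei animal of the transplant.
    """
    coords = np.asarray(transplant_coords_um, dtype=float)
    if coords.size == 0:
        raise ValueError("no transplanted nuclei")
    xy = coords[:, -2:][:, ::-1] if coords.shape[1] == 3 else coords  # (x, y)
    cell_count = len(coords)
    edge_col = int(round(xy[:, 0].max() / pixel_size_um))
    center_row = int(round(np.mean(xy[:, 1]) / pixel_size_um))
    profile = transplant_profile(
        psmad, pixel_size_um, edge_col, center_row, cell_count,
        background_level, height_um=height_um, embryo_id=embryo_id,
    )
    h, w = psmad.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = np.mean(xy[:, 0]) / pixel_size_um, np.mean(xy[:, 1]) / pixel_size_um
    disk = ((yy - cy) ** 2 + (xx - cx) ** 2) <= (measure_radius_um / pixel_size_um) ** 2
    intensity = float(psmad[disk].mean()) if disk.any() else float("nan")
    return TransplantQuant(
        cell_count=cell_count,
        profile=profile,
        intensity_in_transplant=intensity,
        animal_positive_count=count_animal_positive(nuclei, xy),
    )


def count_animal_positive(
    nuclei: Sequence[NucleusRecord],
    transplant_coords_um: np.ndarray,
    eps_um: float = 1.0,
) -> int:
    """Positive host nuclei animal of the animal-most transplanted nucleus.

    A line parallel to the margin is drawn one pixel (``eps_um``) above the
    animal-most transplanted nucleus (largest x); positive non-transplant
    nuclei strictly beyond it are counted.  Translation of the whole scene
    leaves the count unchanged.
    """
    coords = np.asarray(transplant_coords_um, dtype=float)
    if coords.size == 0:
        raise ValueError("no transplanted nuclei")
    line_x = float(coords[:, 0].max()) + eps_um
    count = 0
    for n in nuclei:
        if n.is_positive and n.distance_from_margin_um > line_x:
            near_transplant = np.any(
                np.linalg.norm(
                    coords - np.array(n.centroid_um), axis=1
                )
                < eps_um
            )
            if not near_transplant:
                count += 1
    return count
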