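"""Synthetic embryo data with known ground truth.

Stand-ins for the imaging inputs of the analysis chain: exponential-like
ligand gradients emanating from a margin source with embryo-specific
amplitude and background, punctate ligand distributions, far-red tracer
channels (source stripe or clone disk), nuclei lattices with a graded
positive pSmad domain, bleach/photoconversion time series driven by the
synthesis-diffusion-clearance forward model, and two-group measurement
samples.  Every generator is a pure function of (parameters, seed), and the
returned truth objects are sufficient to score each downstream operation
without manual annotation.

Default parameters reflect the measured study conditions: effective
diffusivity ~2 um^2/s for the wild-type ligand, extracellular clearance
~1e-4 /s, gradient length scale ~100 um, nuclear diameter 8 um, ~12
positive nuclei tiers in the wild type.

Noise model: multiplicative Gaussian (relative sd) on fluorescence, which
matches the high-intensity lightsheet regime; a Poisson mode is available
for the image channels.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .fdap import FDAPRecord
from .frap import FRAPRecord, simulate_frap
from .gradient import IntensityProfile
from .rd import Domain1D, RDParams
from .stats import TwoGroupData

__all__ = [
    "SceneTruth",
    "make_profiles",
    "make_embryo_scene",
    "make_frap_dataset",
    "make_fdap_dataset",
    "make_two_group",
    "save_scene",
]

# study-condition defaults
DEFAULT_LAMBDA_UM = 100.0
DEFAULT_D_UM2_S = 2.0
DEFAULT_K_PER_S = 1e-4
DEFAULT_NUCLEAR_DIAMETER_UM = 8.0
DEFAULT_POSITIVE_TIERS = 12
CLONE_FARRED_LEVEL = 1000.0  # above the 700 edge threshold
YSL_FARRED_LEVEL = 200.0


@dataclass
class SceneTruth:
    """Ground truth for a synthetic scene or profile set."""

    seed: int
    pixel_size_um: float = 1.0
    lambda_um: float = DEFAULT_LAMBDA_UM
    amplitude: float = 0.0
    background: float = 0.0
    A: list[float] = field(default_factory=list)
    b: list[float] = field(default_factory=list)
    puncta_xy_um: list[list[float]] = field(default_factory=list)
    nuclei_xy_um: list[list[float]] = field(default_factory=list)
    nuclei_positive: list[bool] = field(default_factory=list)
    true_tier_count: int = 0
    ysl_width_um: float = 0.0
    clone_center_um: list[float] = field(default_factory=list)
    clone_radius_um: float = 0.0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def make_profiles(
    n_embryos: int,
    lambda_um: float = DEFAULT_LAMBDA_UM,
    A_dist: tuple[float, float] = (100.0, 25.0),
    b_dist: tuple[float, float] = (5.0, 2.0),
    noise_sd: float = 0.03,
    grid_um: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[list[IntensityProfile], SceneTruth]:
    """Per-embryo gradient profiles I_n(x) = A_n exp(-x/lambda) + b_n + noise.

    ``A_dist``/``b_dist`` are (mean, sd) of the per-embryo amplitude and
    non-specific background; noise is multiplicative Gaussian with relative
    sd ``noise_sd``.
    """
    if n_embryos < 2:
        raise ValueError("n_embryos must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if grid_um is None:
        grid_um = np.arange(0.5, 250.0, 2.0)
    rng = np.random.default_rng(seed)
    A = np.abs(rng.normal(*A_dist, size=n_embryos))
    b = rng.normal(*b_dist, size=n_embryos)
    profiles = []
    for i in range(n_embryos):
        clean = A[i] * np.exp(-grid_um / lambda_um) + b[i]
        noisy = clean * (1.0 + noise_sd * rng.standard_normal(len(grid_um)))
        profiles.append(
            IntensityProfile(
                distance_um=grid_um.copy(), intensity=noisy, embryo_id=f"embryo{i:02d}"
            )
        )
    truth = SceneTruth(
        seed=seed, lambda_um=lambda_um, A=A.tolist(), b=b.tolist()
    )
    return profiles, truth


def _hex_lattice(
    width_um: float, height_um: float, spacing_um: float, jitter_um: float, rng
) -> np.ndarray:
    """Jittered hexagonal lattice of (x, y) points, um."""
    dy = spacing_um * np.sqrt(3) / 2
    pts = []
    row = 0
    y = spacing_um / 2
    while y < height_um - spacing_um / 4:
        x0 = spacing_um / 2 + (spacing_um / 2 if row % 2 else 0.0)
        x = x0
        while x < width_um - spacing_um / 4:
            pts.append((x, y))
            x += spacing_um
        y += dy
        row += 1
    pts = np.array(pts)
    if jitter_um > 0:
        pts = pts + rng.uniform(-jitter_um, jitter_um, size=pts.shape)
    return pts


def _draw_gaussian_spots(
    img: np.ndarray, centers_px: np.ndarray, sigma_px: float, amplitude: float
) -> None:
    """Accumulate round Gaussian blobs in place."""
    h, w = img.shape
    r = int(np.ceil(4 * sigma_px))
    for cy, cx in centers_px:
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2)
        )


def make_embryo_scene(
    shape_px: tuple[int, int] = (200, 300),
    pixel_size_um: float = 2.0,
    lambda_um: float = DEFAULT_LAMBDA_UM,
    amplitude: float = 100.0,
    background: float = 5.0,
    n_puncta: int = 0,
    puncta_amplitude: float = 50.0,
    nuclear_diameter_um: float = DEFAULT_NUCLEAR_DIAMETER_UM,
    nuclei_spacing_um: float = 12.0,
    nuclei_jitter_um: float = 1.0,
    positive_tiers: int = DEFAULT_POSITIVE_TIERS,
    layout: str = "ysl",  # "ysl" or "clone"
    ysl_width_um: float = 30.0,
    clone_radius_um: float = 40.0,
    n_z: int = 5,
    noise_sd: float = 0.02,
    noise_model: str = "gaussian",  # or "poisson"
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], SceneTruth]:
    """Multi-channel synthetic embryo image with full ground truth.

    Channels (dict keys): ``ligand`` — a (n_z, H, W) stack carrying the
    exponential gradient from the source edge plus optional Gaussian
    puncta; ``farred`` — tracer marking the source (YSL stripe at the left
    border, or a clone disk for the transplant layout); ``dapi`` — nuclei
    as Gaussian blobs on a jittered hexagonal lattice; ``psmad`` — nuclear
    signal graded so exactly ``positive_tiers`` contiguous tiers from the
    margin exceed the positivity rule (background median + 3 MAD).

    The source/margin edge is the left image border; x grows towards the
    animal pole.
    """
    if nuclei_spacing_um < nuclear_diameter_um:
        raise ValueError("nuclei lattice denser than the nuclear diameter")
    rng = np.random.default_rng(seed)
    h, w = shape_px
    width_um = w * pixel_size_um
    height_um = h * pixel_size_um
    x_um = (np.arange(w) + 0.5) * pixel_size_um

    def add_noise(img: np.ndarray) -> np.ndarray:
        if noise_sd <= 0:
            return img
        if noise_model == "poisson":
            scale = 1.0 / max(noise_sd, 1e-9) ** 2
            return rng.poisson(np.clip(img, 0, None) * scale) / scale
        return np.clip(img * (1.0 + noise_sd * rng.standard_normal(img.shape)), 0, None)

    # ligand: gradient measured from the source edge
    if layout == "ysl":
        dist_from_source = np.maximum(x_um - ysl_width_um, 0.0)
    else:
        dist_from_source = x_um  # clone layout uses radial distance below
    grad_1d = amplitude * np.exp(-dist_from_source / lambda_um) + background
    base = np.tile(grad_1d, (h, 1))

    clone_center_um: list[float] = []
    if layout == "clone":
        cy_um, cx_um = height_um / 2, width_um / 4
        clone_center_um = [cx_um, cy_um]
        yy, xx = np.mgrid[0:h, 0:w]
        r_um = np.hypot(
            (yy + 0.5) * pixel_size_um - cy_um, (xx + 0.5) * pixel_size_um - cx_um
        )
        d_edge = np.maximum(r_um - clone_radius_um, 0.0)
        base = amplitude * np.exp(-d_edge / lambda_um) + background

    puncta_xy: list[list[float]] = []
    if n_puncta > 0:
        margin_px = 6.0
        px = rng.uniform(margin_px, w - margin_px, size=n_puncta)
        py = rng.uniform(margin_px, h - margin_px, size=n_puncta)
        sep_px = 8.0  # keep puncta resolvable
        keep_x, keep_y = [], []
        for cx, cy in zip(px, py):
            if all((cx - a) ** 2 + (cy - b2) ** 2 > sep_px**2 for a, b2 in zip(keep_x, keep_y)):
                keep_x.append(cx)
                keep_y.append(cy)
        puncta_xy = [
            [cx * pixel_size_um, cy * pixel_size_um] for cx, cy in zip(keep_x, keep_y)
        ]

    slice_weights = np.linspace(0.6, 1.0, n_z)
    ligand = np.empty((n_z, h, w))
    for iz in range(n_z):
        sl = base * slice_weights[iz]
        if puncta_xy and iz == n_z - 1:
            spots = np.zeros((h, w))
            centers_px = np.array(
                [[cy / pixel_size_um, cx / pixel_size_um] for cx, cy in puncta_xy]
            )
            _draw_gaussian_spots(spots, centers_px, sigma_px=1.5, amplitude=puncta_amplitude)
            sl = sl + spots
        ligand[iz] = add_noise(sl)

    # far-red tracer
    farred = np.full((h, w), 10.0)
    if layout == "ysl":
        farred[:, x_um < ysl_width_um] = YSL_FARRED_LEVEL
    else:
        farred[r_um <= clone_radius_um] = CLONE_FARRED_LEVEL
    farred = add_noise(farred)

    # nuclei lattice + DAPI
    nuclei = _hex_lattice(width_um, height_um, nuclei_spacing_um, nuclei_jitter_um, rng)
    dapi = np.full((h, w), 2.0)
    centers_px = np.column_stack([nuclei[:, 1], nuclei[:, 0]]) / pixel_size_um  # (y, x)
    sigma_px = nuclear_diameter_um / 2 / pixel_size_um / 1.5
    _draw_gaussian_spots(dapi, centers_px, sigma_px=sigma_px, amplitude=100.0)
    dapi = add_noise(dapi)

    # pSmad: graded positive domain over the first `positive_tiers` tiers
    tier = np.floor(nuclei[:, 0] / nuclear_diameter_um).astype(int) + 1
    positive = tier <= positive_tiers
    psmad_bg_level = 10.0
    psmad = np.full((h, w), psmad_bg_level)
    pos_amp = 120.0
    if positive.any():
        # graded but everywhere clear of the positivity rule
        amp_per_nucleus = pos_amp * (
            1.0 - 0.5 * (tier[positive] - 1) / max(positive_tiers, 1)
        )
        for (xy, a) in zip(nuclei[positive], amp_per_nucleus):
            _draw_gaussian_spots(
                psmad,
                np.array([[xy[1] / pixel_size_um, xy[0] / pixel_size_um]]),
                sigma_px=sigma_px,
                amplitude=float(a),
            )
    psmad = add_noise(psmad)

    truth = SceneTruth(
        seed=seed,
        pixel_size_um=pixel_size_um,
        lambda_um=lambda_um,
        amplitude=amplitude,
        background=background,
        puncta_xy_um=puncta_xy,
        nuclei_xy_um=nuclei.tolist(),
        nuclei_positive=positive.tolist(),
        true_tier_count=int(positive_tiers) if positive.any() else 0,
        ysl_width_um=ysl_width_um if layout == "ysl" else 0.0,
        clone_center_um=clone_center_um,
        clone_radius_um=clone_radius_um if layout == "clone" else 0.0,
    )
    channels = {"ligand": ligand, "farred": farred, "dapi": dapi, "psmad": psmad}
    return channels, truth


def save_scene(
    channels: dict[str, np.ndarray], truth: SceneTruth, directory: str | Path
) -> None:
    """Write channels as TIFF with pixel-size metadata plus a truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    res = 1.0 / truth.pixel_size_um  # pixels per um
    for name, img in channels.items():
        tifffile.imwrite(
            directory / f"{name}.tif",
            img.astype(np.float32),
            resolution=(res, res),
            metadata={"unit": "um", "pixel_size_um": truth.pixel_size_um},
        )
    truth.to_json(directory / "truth.json")


def default_frap_frames(D: float, bleach_width_um: float = 40.0, n_frames: int = 60) -> np.ndarray:
    """Frame schedule spanning ~3 ROI recovery times for diffusivity D."""
    tau = bleach_width_um**2 / (8.0 * max(D, 1e-6))
    return np.linspace(0.0, 3.0 * tau, n_frames)


def make_frap_dataset(
    D_grid: Sequence[float] = (1.0, 2.0, 3.0, 40.0),
    n_replicates: int = 5,
    noise_sd: float = 0.01,
    k: float = DEFAULT_K_PER_S,
    steady_level: float = 100.0,
    domain: Domain1D | None = None,
    bleach_interval: tuple[float, float] = (80.0, 120.0),
    bleach_depth: float = 0.8,
    seed: int = 0,
) -> tuple[list[tuple[FRAPRecord, float]], list[dict]]:
    """Seeded FRAP records across a diffusivity grid, with a truth table.

    Returns ``(records, truth_rows)`` where each record is paired with its
    true D and each truth row lists (D, k, p, seed, noise_sd).
    """
    if domain is None:
        domain = Domain1D(length_um=200.0, dx_um=2.0)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(D_grid) * n_replicates) % (2**31)
    records: list[tuple[FRAPRecord, float]] = []
    truth_rows: list[dict] = []
    idx = 0
    for D in D_grid:
        params = RDParams(D=D, p=k * steady_level, k=k)
        times = default_frap_frames(D, bleach_interval[1] - bleach_interval[0])
        for _ in range(n_replicates):
            rec = simulate_frap(
                params,
                domain,
                times,
                bleach_interval,
                bleach_depth=bleach_depth,
                noise_sd=noise_sd,
                seed=int(child_seeds[idx]),
            )
            records.append((rec, D))
            truth_rows.append(
                {
                    "D": D,
                    "k": k,
                    "p": k * steady_level,
                    "seed": int(child_seeds[idx]),
                    "noise_sd": noise_sd,
                }
            )
            idx += 1
    return records, truth_rows


def make_fdap_dataset(
    k_true: float = DEFAULT_K_PER_S,
    c0: float = 100.0,
    offset: float = 5.0,
    n_records: int = 1,
    n_frames: int = 40,
    t_max_s: float | None = None,
    noise_sd: float = 0.02,
    n_saturated: int = 0,
    n_artifacts: int = 0,
    saturation_level: float = 4095.0,
    seed: int = 0,
) -> tuple[list[FDAPRecord], list[dict]]:
    """Exponential-plus-offset decay series with optional corrupted frames.

    Saturated frames are set to ``saturation_level``; artifact frames get a
    10x local-level spike.  Truth rows record k, c0, offset and the
    corrupted frame indices.
    """
    if t_max_s is None:
        t_max_s = 3.0 / max(k_true, 1e-9)  # ~3 decay times
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(n_records) % (2**31)
    records, truth_rows = [], []
    for i in range(n_records):
        rng = np.random.default_rng(int(child[i]))
        t = np.linspace(0.0, t_max_s, n_frames)
        clean = c0 * np.exp(-k_true * t) + offset
        y = clean * (1.0 + noise_sd * rng.standard_normal(n_frames))
        corrupt = rng.choice(
            np.arange(2, n_frames), size=n_saturated + n_artifacts, replace=False
        )
        sat_idx = corrupt[:n_saturated]
        art_idx = corrupt[n_saturated:]
        y[sat_idx] = saturation_level
        y[art_idx] = clean[art_idx] * 10.0
        records.append(FDAPRecord(times=t, intensity=y))
        truth_rows.append(
            {
                "k": k_true,
                "c0": c0,
                "offset": offset,
                "seed": int(child[i]),
                "saturated_frames": sorted(int(j) for j in sat_idx),
                "artifact_frames": sorted(int(j) for j in art_idx),
            }
        )
    return records, truth_rows


def make_two_group(
    n1: int,
    n2: int,
    mean1: float,
    mean2: float,
    sd1: float,
    sd2: float,
    seed: int = 0,
) -> tuple[TwoGroupData, dict]:
    """Two Gaussian samples; truth records the standardized effect size."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    rng = np.random.default_rng(seed)
    ref = rng.normal(mean1, sd1, size=n1)
    cond = rng.normal(mean2, sd2, size=n2)
    pooled_sd = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    truth = {
        "effect_size": (mean2 - mean1) / pooled_sd if pooled_sd > 0 else float("nan"),
        "seed": seed,
    }
    return TwoGroupData(reference_values=ref, condition_values=cond), truth
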