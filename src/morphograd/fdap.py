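"""Fluorescence Decay After Photoconversion: clearance-rate estimation.

A pool of photoconvertible ligand (e.g. a Dendra2 fusion) is converted and
the decay of the converted extracellular signal is followed over time.  The
decay is fit with an exponential-plus-offset model

    c(t) = c0 * exp(-k t) + offset

whose rate constant ``k`` is the extracellular clearance rate constant
(half-life ln 2 / k).  Single frames hit by signal saturation or transient
artifacts (e.g. bubbles during multi-position imaging) can be excluded before
fitting; whole records whose overall R^2 falls below 0.88 fail QC.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FDAPRecord",
    "FDAPFit",
    "exclude_frames",
    "fit_fdap",
    "read_fdap_csv",
    "write_fdap_csv",
]

R_SQUARED_MIN = 0.88  # overall-fit exclusion threshold
MIN_RETAINED_FRAMES = 8
K_BOUNDS = (0.0, 1e-1)  # 1/s


@dataclass(frozen=True)
class FDAPRecord:
    """Post-conversion decay series with per-frame exclusion tags."""

    times: np.ndarray
    intensity: np.ndarray
    excluded_frames: dict[int, str] | None = None  # index -> "saturation"|"artifact"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.excluded_frames is None:
            object.__setattr__(self, "excluded_frames", {})

    def retained(self) -> np.ndarray:
        mask = np.ones(len(self.times), dtype=bool)
        for i in self.excluded_frames:
            mask[i] = False
        return mask


@dataclass(frozen=True)
class FDAPFit:
    """Exponential-decay fit result with QC verdict."""

    k_hat: float  # clearance rate constant, 1/s
    c0_hat: float
    offset_hat: float
    r_squared: float
    qc_pass: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.k_hat < 0:
            raise ValueError("k_hat must be >= 0")

    @property
    def half_life_s(self) -> float:
        return float(np.log(2) / self.k_hat) if self.k_hat > 0 else float("inf")


def exclude_frames(
    record: FDAPRecord,
    saturation_level: float,
    artifact_z: float = 5.0,
    min_rel_deviation: float = 0.05,
) -> FDAPRecord:
    """Tag saturated and artifact frames; returns a new record.

    Frames at or above ``saturation_level`` are tagged ``saturation``.
    Frames whose relative residual from a local median (window 5) exceeds
    ``artifact_z`` robust standard deviations are tagged ``artifact``;
    ``min_rel_deviation`` floors the threshold so that on near-noiseless
    records smooth-curvature residuals are not mistaken for artifacts.
    """
    if saturation_level <= 0 or artifact_z <= 0:
        raise ValueError("thresholds must be positive")
    y = record.intensity
    n = len(y)
    tags: dict[int, str] = dict(record.excluded_frames)

    sat = np.flatnonzero(y >= saturation_level)
    for i in sat:
        tags.setdefault(int(i), "saturation")
    # patch saturated frames by interpolation so they do not pollute the
    # artifact baseline below
    good = np.setdiff1d(np.arange(n), sat)
    if len(sat) and len(good):
        y = y.copy()
        y[sat] = np.interp(record.times[sat], record.times[good], y[good])

    def neighbor_resid(series: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        # local median of the 4 nearest neighbors (window 5 minus the center,
        # so a smooth monotone decay still yields noise-scale residuals)
        # linear-extrapolation padding: on a steeply decaying series,
        # reflect/edge padding biases the first frames' baselines upward
        pad = np.concatenate(
            [
                [2 * series[0] - series[2], 2 * series[0] - series[1]],
                series,
                [2 * series[-1] - series[-2], 2 * series[-1] - series[-3]],
            ]
        )
        med = np.array(
            [np.median([pad[i], pad[i + 1], pad[i + 3], pad[i + 4]]) for i in range(n)]
        )
        # relative residuals: fluorescence noise scales with the signal, so
        # an absolute scale would over-flag the bright early frames
        scale = np.maximum(np.abs(med), 1e-12)
        resid = (series - med) / scale
        mad = np.median(np.abs(resid - np.median(resid)))
        return resid, med, 1.4826 * mad

    # two passes: gross spikes pollute their neighbors' local medians, so
    # re-estimate with first-pass spikes patched out before the final verdict
    resid, med, robust_sd = neighbor_resid(y)
    thr1 = max(artifact_z * robust_sd, min_rel_deviation)
    suspects = np.abs(resid) > thr1
    patched = y.copy()
    patched[suspects] = med[suspects]
    _, med2, robust_sd2 = neighbor_resid(patched)
    resid2 = (y - med2) / np.maximum(np.abs(med2), 1e-12)
    thr2 = max(artifact_z * robust_sd2, min_rel_deviation)
    for i in np.flatnonzero(np.abs(resid2) > thr2):
        tags.setdefault(int(i), "artifact")

    new = replace(record, excluded_frames=tags)
    if new.retained().sum() < MIN_RETAINED_FRAMES:
        raise ValueError(
            f"insufficient data: exclusion leaves {int(new.retained().sum())} "
            f"frames (< {MIN_RETAINED_FRAMES})"
        )
    return new


def fit_fdap(record: FDAPRecord, with_offset: bool = True) -> FDAPFit:
    """Least-squares fit of c(t) = c0 exp(-k t) + offset on retained frames.

    The nonlinear fit is seeded from a log-linear regression on
    ``intensity - min`` for robustness.  An all-equal series yields a
    degenerate fit with ``k_hat = 0``.
    """
    mask = record.retained()
    if mask.sum() < MIN_RETAINED_FRAMES:
        raise ValueError("at least 8 retained frames required")
    t = record.times[mask]
    y = record.intensity[mask]
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")

    if np.ptp(y) == 0:
        return FDAPFit(
            k_hat=0.0,
            c0_hat=0.0,
            offset_hat=float(y[0]),
            r_squared=1.0,
            qc_pass=False,
            degenerate=True,
        )

    # log-linear seed on positive excess over the floor
    floor = y.min()
    excess = y - floor + 1e-9 * max(np.ptp(y), 1.0)
    slope, logc0 = np.polyfit(t, np.log(np.clip(excess, 1e-300, None)), 1)
    k0 = float(np.clip(-slope, 1e-8, K_BOUNDS[1]))
    c00 = float(np.exp(logc0))
    off0 = float(floor) if with_offset else 0.0

    if with_offset:
        def model(theta):
            c0, k, off = theta
            return c0 * np.exp(-k * t) + off

        x0 = np.array([c00, k0, off0])
        lo = np.array([0.0, K_BOUNDS[0], -np.inf])
        hi = np.array([np.inf, K_BOUNDS[1], np.inf])
    else:
        def model(theta):
            c0, k = theta
            return c0 * np.exp(-k * t)

        x0 = np.array([c00 + off0, k0])
        lo = np.array([0.0, K_BOUNDS[0]])
        hi = np.array([np.inf, K_BOUNDS[1]])

    res = least_squares(lambda th: model(th) - y, x0, bounds=(lo, hi), xtol=1e-12)
    yhat = model(res.x)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    c0_hat = float(res.x[0])
    k_hat = float(res.x[1])
    off_hat = float(res.x[2]) if with_offset else 0.0
    return FDAPFit(
        k_hat=k_hat,
        c0_hat=c0_hat,
        offset_hat=off_hat,
        r_squared=float(r2),
        qc_pass=bool(r2 >= R_SQUARED_MIN),
        degenerate=not res.success,
    )


def write_fdap_csv(record: FDAPRecord, path: str | Path) -> None:
    """CSV columns: time_s, intensity, excluded, reason."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "intensity", "excluded", "reason"])
        for i, (t, v) in enumerate(zip(record.times, record.intensity)):
            reason = record.excluded_frames.get(i, "")
            w.writerow([repr(float(t)), repr(float(v)), int(bool(reason)), reason])


def read_fdap_csv(path: str | Path) -> FDAPRecord:
    times, vals, tags = [], [], {}
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            times.append(float(row["time_s"]))
            vals.append(float(row["intensity"]))
            if row.get("reason"):
                tags[i] = row["reason"]
    return FDAPRecord(times=np.array(times), intensity=np.array(vals), excluded_frames=tags)
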