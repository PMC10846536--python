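"""Optical point-spread-function estimation from fluorescent-bead z-stacks.

Sub-diffraction (0.2 μm) beads imaged with the photostimulation beam act as
point sources, so their image is the OPSF itself.  The workflow: register
the stack slice-to-slice to remove mounting tilt, detect bead centroids,
extract 1D intensity profiles through each centroid along the axial and
lateral axes, least-squares fit offset + amplitude·exp(−(x−μ)²/(2σ²)) to
each profile, and summarize the per-bead FWHMs (2√(2 ln 2)·σ) with a mean
and normal-approximation 95% CI per axis.  A fit with R² below a threshold
(default 0.9) is flagged unusable — the automated stand-in for inspecting
each curve by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation

from .model import FWHM_PER_SIGMA

__all__ = [
    "BeadProfile",
    "GaussianFit",
    "OpsfSummary",
    "detect_beads",
    "register_stack",
    "extract_profile",
    "fit_gaussian",
    "summarize_opsf",
]

AXES = ("axial", "lateral_x", "lateral_y")


@dataclass
class BeadProfile:
    """1D intensity profile through a bead centroid along one axis."""

    axis: str
    positions: np.ndarray  # μm, strictly increasing
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.size != self.intensities.size:
            raise ValueError("positions and intensities must have equal length")
        if self.positions.size < 7:
            raise ValueError("a bead profile needs at least 7 samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass
class GaussianFit:
    """Fitted 1D Gaussian: offset + amplitude·exp(−(x−μ)²/(2σ²))."""

    mu: float
    sigma: float
    amplitude: float
    offset: float
    r2: float
    usable: bool

    @property
    def fwhm(self) -> float:
        return self.sigma * FWHM_PER_SIGMA


@dataclass
class OpsfSummary:
    """Per-axis mean FWHM and 95% CI across beads (usable fits only)."""

    per_axis: dict[str, dict] = field(default_factory=dict)
    n_beads: int = 0


def detect_beads(
    stack: np.ndarray,
    min_separation: float,
    intensity_quantile: float = 0.999,
    axial_step: float = 1.0,
    lateral_step: float = 0.1,
) -> list[tuple[float, float, float]]:
    """Sub-voxel bead centroids: local maxima above an intensity quantile.

    ``min_separation`` is a lateral distance in μm; maxima closer than that
    are suppressed (brightest wins).  Centroids are refined by center of
    mass in a local background-subtracted window.  Returns (z, y, x) voxel
    coordinates; an empty list if nothing exceeds the threshold.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValueError("need a 3D stack with at least 3 slices")
    if stack.max() == stack.min():
        return []
    smoothed = ndimage.gaussian_filter(stack, sigma=1.0)
    threshold = float(np.quantile(smoothed, intensity_quantile))
    min_dist_vox = max(int(min_separation / lateral_step), 1)
    peaks = peak_local_max(
        smoothed, min_distance=min_dist_vox, threshold_abs=threshold, exclude_border=False
    )
    centroids = []
    floor = float(np.median(stack))
    for z0, y0, x0 in peaks:
        w = 3
        zs = slice(max(z0 - w, 0), z0 + w + 1)
        ys = slice(max(y0 - w, 0), y0 + w + 1)
        xs = slice(max(x0 - w, 0), x0 + w + 1)
        win = np.clip(stack[zs, ys, xs] - floor, 0, None)
        if win.sum() == 0:
            continue
        com = ndimage.center_of_mass(win)
        centroids.append((zs.start + com[0], ys.start + com[1], xs.start + com[2]))
    return centroids


def register_stack(
    stack: np.ndarray, upsample_factor: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Remove lateral tilt: translate each slice onto the brightest one.

    Shifts are estimated by sub-pixel phase cross-correlation against the
    slice with the highest total intensity and applied with spline
    interpolation.  Returns (registered stack, per-slice (dy, dx) shifts).
    Idempotent on an already-aligned stack up to interpolation error.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a 3D stack with at least 2 slices")
    ref = stack[int(np.argmax(stack.sum(axis=(1, 2))))]
    out = np.empty_like(stack)
    shifts = np.zeros((stack.shape[0], 2))
    for i, sl in enumerate(stack):
        shift, _, _ = phase_cross_correlation(
            ref, sl, upsample_factor=upsample_factor, normalization=None
        )
        shifts[i] = shift
        out[i] = ndimage.shift(sl, shift, order=1, mode="nearest")
    return out, shifts


def extract_profile(
    stack: np.ndarray,
    centroid: tuple[float, float, float],
    axis: str,
    half_window: float,
    axial_step: float = 1.0,
    lateral_step: float = 0.1,
    aperture: int = 3,
) -> BeadProfile:
    """Intensity along one axis through a centroid, other axes averaged.

    Positions are in μm relative to the centroid.  The profile is averaged
    over an ``aperture``-voxel window in the perpendicular directions
    (``aperture=1`` reads single voxels).  Raises if the requested window
    leaves the stack.
    """
    stack = np.asarray(stack, dtype=float)
    cz, cy, cx = (int(round(c)) for c in centroid)
    steps = {"axial": axial_step, "lateral_x": lateral_step, "lateral_y": lateral_step}
    if axis not in steps:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    step = steps[axis]
    half_n = int(round(half_window / step))
    ap = aperture // 2
    axis_dim = {"axial": 0, "lateral_y": 1, "lateral_x": 2}[axis]
    center = (cz, cy, cx)
    lo = center[axis_dim] - half_n
    hi = center[axis_dim] + half_n
    if lo < 0 or hi >= stack.shape[axis_dim]:
        raise ValueError(
            f"{axis} window ±{half_window} μm (voxels {lo}..{hi}) exceeds stack "
            f"extent {stack.shape[axis_dim]} along axis {axis_dim}"
        )
    perp = [d for d in range(3) if d != axis_dim]
    slicer: list[slice] = [slice(None)] * 3
    slicer[axis_dim] = slice(lo, hi + 1)
    for d in perp:
        a, b = center[d] - ap, center[d] + ap
        if a < 0 or b >= stack.shape[d]:
            raise ValueError("perpendicular aperture exceeds stack bounds")
        slicer[d] = slice(a, b + 1)
    window = stack[tuple(slicer)]
    profile = window.mean(axis=tuple(perp))
    positions = (np.arange(lo, hi + 1) - centroid[axis_dim]) * step
    return BeadProfile(axis, positions, profile)


class FitFailure(RuntimeError):
    """Raised when a Gaussian fit cannot be performed at all (as opposed to
    converging onto a poor fit, which is returned with ``usable=False``)."""


def fit_gaussian(profile: BeadProfile, r2_threshold: float = 0.9) -> GaussianFit:
    """Least-squares Gaussian fit with moment-based initialization.

    μ starts at the argmax, σ at the intensity-weighted second moment, and
    σ is bounded to (0.1·spacing, 2·range) for robustness.  The fit is
    flagged unusable when R² < ``r2_threshold``.  A constant profile or a
    non-converging optimizer raises :class:`FitFailure`.
    """
    x = profile.positions
    y = profile.intensities
    if x.size < 5:
        raise FitFailure("need at least 5 samples to fit a Gaussian")
    if y.max() == y.min():
        raise FitFailure("constant profile has no Gaussian component")
    span = x[-1] - x[0]
    offset0 = float(y.min())
    amp0 = float(y.max() - y.min())
    mu0 = float(x[np.argmax(y)])
    w = np.clip(y - offset0, 0, None)
    sigma0 = float(np.sqrt(np.sum(w * (x - mu0) ** 2) / np.sum(w)))
    spacing = float(np.min(np.diff(x)))
    sigma0 = min(max(sigma0, spacing), span)

    def g(xv, mu, sigma, amp, off):
        return off + amp * np.exp(-0.5 * ((xv - mu) / sigma) ** 2)

    try:
        popt, _ = optimize.curve_fit(
            g,
            x,
            y,
            p0=(mu0, sigma0, amp0, offset0),
            bounds=(
                (x[0] - span, 0.1 * spacing, 0.0, -np.inf),
                (x[-1] + span, 2.0 * span, np.inf, np.inf),
            ),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise FitFailure(f"Gaussian fit did not converge: {exc}") from exc
    residuals = y - g(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot
    mu, sigma, amp, off = (float(v) for v in popt)
    return GaussianFit(mu, sigma, amp, off, r2, usable=r2 >= r2_threshold)


def summarize_opsf(fits: dict[str, list[GaussianFit]] | list[GaussianFit]) -> OpsfSummary | None:
    """Mean FWHM and 95% CI per axis across beads.

    ``fits`` maps axis name to per-bead fits (a bare list is treated as
    axial).  Unusable fits are excluded and counted.  Returns None when no
    axis has a usable fit.  The CI is mean ± 1.96·SE and is reported as NaN
    for a single bead.
    """
    if isinstance(fits, list):
        fits = {"axial": fits}
    summary = OpsfSummary()
    max_n = 0
    for axis, axis_fits in fits.items():
        usable = [f for f in axis_fits if f.usable]
        entry: dict = {
            "n": len(usable),
            "n_excluded": len(axis_fits) - len(usable),
        }
        if usable:
            fwhms = np.array([f.fwhm for f in usable])
            entry["mean_fwhm"] = float(fwhms.mean())
            entry["ci95"] = (
                float(1.96 * fwhms.std(ddof=1) / np.sqrt(len(fwhms)))
                if len(fwhms) >= 2
                else float("nan")
            )
            entry["fits"] = usable
            max_n = max(max_n, len(usable))
        else:
            entry["mean_fwhm"] = float("nan")
            entry["ci95"] = float("nan")
            entry["fits"] = []
        summary.per_axis[axis] = entry
    if max_n == 0:
        return None
    summary.n_beads = max_n
    return summary
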