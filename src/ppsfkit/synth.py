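"""Synthetic two-photon optogenetics data with known ground truth.

Emulates the three kinds of raw data the analysis consumes:

* z-stacks of sub-diffraction fluorescent beads imaged with the
  photostimulation beam, for optical-PSF estimation (default geometry:
  0.1 μm lateral / 1 μm axial sampling);
* calcium-imaging movies of photostimulation experiments (default 30 Hz,
  512×512 px at 1.25 μm/px) in which a spiral stimulus is delivered at a
  grid of axial offsets (−60..+60 μm in 15 μm steps, 3 trials each, 250 ms
  stimulation, repeats every 10 s), with GCaMP6s-like transients, a
  stimulation-laser artifact, and frame-clock / stimulation-gate
  synchronization traces;
* curve-level response data (the fast path), skipping movie rendering for
  statistical tests at scale.

The forward model: the excitation dose delivered to a cell at a given
focus offset is the 1D axial convolution of the cell's opsin-weighted area
profile with the axial OPSF Gaussian (the 10 μm spiral covers the soma
laterally, so the lateral dimension drops out).  A saturating Hill law maps
dose to ΔF/F amplitude, and a double-exponential kernel shapes the
transient in time.  All randomness flows through explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import sigma_from_fwhm
from .ppsf import ResponseCurve, TrialWindows, detect_trial_onsets, window_frames

__all__ = [
    "OpsfModel",
    "ResponseParams",
    "CellSpec",
    "StimProtocol",
    "AcquisitionSpec",
    "SyncRecord",
    "SMALL_OPSF",
    "LARGE_OPSF",
    "generate_bead_stack",
    "membrane_area_profile",
    "excitation_dose",
    "amplitude_from_dose",
    "gcamp_kernel",
    "simulate_experiment",
    "simulate_response_curves",
]


@dataclass(frozen=True)
class OpsfModel:
    """Gaussian description of the photostimulation focus (axial + lateral FWHM, μm)."""

    axial_fwhm: float
    lateral_fwhm: float

    def __post_init__(self) -> None:
        if self.axial_fwhm <= 0 or self.lateral_fwhm <= 0:
            raise ValueError("OPSF FWHMs must be strictly positive")

    @property
    def axial_sigma(self) -> float:
        return sigma_from_fwhm(self.axial_fwhm)

    @property
    def lateral_sigma(self) -> float:
        return sigma_from_fwhm(self.lateral_fwhm)


#: The two experimental focus conditions: axial FWHMs of 8.3 and 18.6 μm.
#: Lateral FWHMs are typical two-photon values (the axial extent is what the
#: numerical-aperture manipulation changes).
SMALL_OPSF = OpsfModel(axial_fwhm=8.3, lateral_fwhm=1.0)
LARGE_OPSF = OpsfModel(axial_fwhm=18.6, lateral_fwhm=1.5)


@dataclass(frozen=True)
class ResponseParams:
    """Saturating dose→ΔF/F response law plus GCaMP6s-like transient kinetics.

    The amplitude follows a Hill curve A(dose) = A_max · doseⁿ/(doseⁿ + hⁿ):
    zero at zero dose, monotone, bounded by ``max_amplitude``.  ``half_dose``
    is on the scale of the peak-normalized dose (which lies in (0, 1]), and
    large ``hill_coefficient`` gives threshold-like behaviour.  The transient
    kernel is (1 − e^(−t/τ_rise))·e^(−t/τ_decay), peak-normalized.
    """

    max_amplitude: float = 2.0
    half_dose: float = 0.3
    hill_coefficient: float = 2.0
    tau_rise: float = 0.2
    tau_decay: float = 1.5

    def __post_init__(self) -> None:
        if self.half_dose <= 0:
            raise ValueError("half_dose must be positive")
        if self.hill_coefficient < 1:
            raise ValueError("hill_coefficient must be >= 1")
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("time constants must be positive")


@dataclass(frozen=True)
class CellSpec:
    """Spherical cell: center (x, y, z) in μm, diameter in μm, opsin layout."""

    center: tuple[float, float, float]
    diameter: float
    opsin_distribution: str = "membrane_shell"
    response: ResponseParams = field(default_factory=ResponseParams)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("cell diameter must be positive")
        if self.opsin_distribution not in ("membrane_shell", "uniform_volume", "square_wave"):
            raise ValueError(f"unknown opsin distribution {self.opsin_distribution!r}")


@dataclass(frozen=True)
class StimProtocol:
    """Photostimulation sweep: 9 z offsets (−60..+60 μm), 3 trials each.

    ``direction`` fixes the order in which offsets are visited in the
    acquisition timeline (all trials at one offset before moving on);
    ``standard`` sweeps ascending z, ``reverse`` descending.
    """

    z_offsets: tuple[float, ...] = tuple(np.arange(-60.0, 61.0, 15.0))
    trials_per_z: int = 3
    direction: str = "standard"
    inter_trial: float = 10.0
    stim_duration: float = 0.25
    spiral_diameter: float = 10.0
    spiral_revolutions: int = 5

    def __post_init__(self) -> None:
        if self.direction not in ("standard", "reverse"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.trials_per_z < 1:
            raise ValueError("trials_per_z must be >= 1")
        if self.stim_duration <= 0 or self.inter_trial <= 0:
            raise ValueError("durations must be positive")

    def sweep(self) -> list[float]:
        z = sorted(self.z_offsets)
        return z if self.direction == "standard" else z[::-1]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Imaging parameters and noise model for movie rendering.

    Noise is Poisson-like (Gaussian with variance ``photon_noise_scale`` ×
    signal) plus additive Gaussian read noise.  Set both scales to 0 for a
    noiseless movie.
    """

    frame_rate: float = 30.0
    frame_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 1.25
    photon_noise_scale: float = 1.0
    read_noise_sd: float = 2.0
    baseline_fluorescence: float = 100.0
    rng_seed: int = 0


@dataclass
class SyncRecord:
    """Voltage-style synchronization traces sampled at ``sample_rate`` Hz."""

    sample_rate: float
    frame_clock: np.ndarray
    stim_gate: np.ndarray

    def __post_init__(self) -> None:
        self.frame_clock = np.asarray(self.frame_clock)
        self.stim_gate = np.asarray(self.stim_gate)
        if self.frame_clock.shape != self.stim_gate.shape:
            raise ValueError("frame_clock and stim_gate must have equal length")


# ---------------------------------------------------------------------------
# Bead stacks
# ---------------------------------------------------------------------------

def generate_bead_stack(
    opsf: OpsfModel,
    n_beads: int,
    stack_shape: tuple[int, int, int],
    axial_step: float = 1.0,
    lateral_step: float = 0.1,
    noise: AcquisitionSpec | None = None,
    seed: int = 0,
    amplitude: float = 1000.0,
) -> tuple[np.ndarray, list[tuple[float, float, float]]]:
    """Render sub-diffraction beads as separable 3D Gaussians.

    Beads are placed at random sub-voxel positions, laterally separated by
    at least 3 axial FWHM and axially near the stack center (the physical
    situation: beads dried on a slide, small mounting tilt).  Returns the
    stack (Z, Y, X float array) and the ground-truth (z, y, x) centroids in
    voxel units.  With ``noise=None`` the rendering is exact and noiseless.
    """
    nz, ny, nx = stack_shape
    sz = opsf.axial_sigma / axial_step  # voxels
    sl = opsf.lateral_sigma / lateral_step
    if nz < 2 * 3 * sz + 1:
        raise ValueError(
            f"stack depth {nz} slices cannot contain ±3σ = ±{3 * sz:.1f} slices of a bead"
        )
    if min(ny, nx) < 2 * 3 * sl + 1:
        raise ValueError("stack lateral extent cannot contain ±3σ of a bead")

    rng = np.random.default_rng(seed)
    min_sep_vox = 3.0 * opsf.axial_fwhm / lateral_step
    margin = 3.0 * sl + 1
    centroids: list[tuple[float, float, float]] = []
    for _ in range(10_000):
        if len(centroids) == n_beads:
            break
        y = rng.uniform(margin, ny - 1 - margin)
        x = rng.uniform(margin, nx - 1 - margin)
        if all(math.hypot(y - cy, x - cx) >= min_sep_vox for _, cy, cx in centroids):
            z = (nz - 1) / 2 + rng.uniform(-0.5, 0.5)
            centroids.append((z, y, x))
    if len(centroids) < n_beads:
        raise ValueError(
            f"could not place {n_beads} beads ≥ 3 axial FWHM apart in a "
            f"{ny}×{nx} voxel field"
        )

    stack = np.zeros(stack_shape, dtype=float)
    zi = np.arange(nz, dtype=float)
    yi = np.arange(ny, dtype=float)
    xi = np.arange(nx, dtype=float)
    for cz, cy, cx in centroids:
        gz = np.exp(-0.5 * ((zi - cz) / sz) ** 2)
        gy = np.exp(-0.5 * ((yi - cy) / sl) ** 2)
        gx = np.exp(-0.5 * ((xi - cx) / sl) ** 2)
        stack += amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]

    if noise is not None:
        stack = stack + 0.05 * noise.baseline_fluorescence  # background offset
        if noise.photon_noise_scale > 0:
            stack = stack + rng.normal(
                0.0, np.sqrt(noise.photon_noise_scale * np.clip(stack, 0, None))
            )
        if noise.read_noise_sd > 0:
            stack = stack + rng.normal(0.0, noise.read_noise_sd, size=stack.shape)
    return stack, centroids


# ---------------------------------------------------------------------------
# Dose model
# ---------------------------------------------------------------------------

def membrane_area_profile(cell: CellSpec, z_grid: np.ndarray) -> np.ndarray:
    """Relative opsin-weighted area per unit z, peak-normalized.

    ``membrane_shell``: the area of a spherical zone of thickness dz is
    2πR·dz wherever the slab cuts the sphere, so the profile is a top hat
    across the diameter — the justification for the binary square-wave cell
    model.  ``square_wave`` is that top hat by definition, and the two
    coincide.  ``uniform_volume`` weights by cross-sectional area,
    π(R² − (z − z_c)²), a parabola.
    """
    z = np.asarray(z_grid, dtype=float)
    zc = cell.center[2]
    r = cell.diameter / 2.0
    inside = np.abs(z - zc) <= r
    if cell.opsin_distribution in ("membrane_shell", "square_wave"):
        return inside.astype(float)
    prof = np.where(inside, 1.0 - ((z - zc) / r) ** 2, 0.0)
    return prof


def excitation_dose(opsf: OpsfModel, cell: CellSpec, z_offset: float) -> float:
    """Axial excitation dose at a focus offset, in (0, 1].

    dose(z_offset) = ∫ profile(z) · G_axial(z − z_offset) dz, with the cell
    profile peak-normalized and G the axial OPSF as a unit-area Gaussian
    density, evaluated on a fine grid.  The spiral is assumed to tile the
    soma laterally, so only the axial dimension enters.  Symmetric about the
    cell center and maximal there.
    """
    sigma = opsf.axial_sigma
    zc = cell.center[2]
    half = cell.diameter / 2.0 + 6.0 * sigma
    step = min(sigma, cell.diameter / 2.0) / 100.0
    n = int(math.ceil(half / step))
    # midpoint rule on a grid symmetric about the cell center: the top-hat
    # edges fall between nodes, so the discontinuity costs O(step^2) accuracy
    z = zc + step * (np.arange(-n, n) + 0.5)
    prof = membrane_area_profile(cell, z)
    g = np.exp(-0.5 * ((z - z_offset) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
    return float(np.sum(prof * g) * step)


def amplitude_from_dose(dose: float | np.ndarray, params: ResponseParams) -> float | np.ndarray:
    """Hill response law: A = A_max · doseⁿ / (doseⁿ + half_doseⁿ)."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    n = params.hill_coefficient
    with np.errstate(divide="ignore", invalid="ignore"):
        a = params.max_amplitude * d**n / (d**n + params.half_dose**n)
    a = np.where(d == 0, 0.0, a)
    return float(a) if np.isscalar(dose) else a


def gcamp_kernel(t: np.ndarray, params: ResponseParams) -> np.ndarray:
    """Peak-normalized double-exponential calcium transient, zero for t < 0."""
    t = np.asarray(t, dtype=float)
    tc = np.maximum(t, 0.0)
    k = np.where(t >= 0, (1.0 - np.exp(-tc / params.tau_rise)) * np.exp(-tc / params.tau_decay), 0.0)
    t_peak = params.tau_rise * math.log1p(params.tau_decay / params.tau_rise)
    k_peak = (1.0 - math.exp(-t_peak / params.tau_rise)) * math.exp(-t_peak / params.tau_decay)
    return k / k_peak


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------

def _cell_mask(cell: CellSpec, acq: AcquisitionSpec) -> np.ndarray:
    ny, nx = acq.frame_shape
    cx = cell.center[0] / acq.pixel_size
    cy = cell.center[1] / acq.pixel_size
    r = cell.diameter / 2.0 / acq.pixel_size
    yy, xx = np.mgrid[0:ny, 0:nx]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def cell_masks(cells: list[CellSpec], acq: AcquisitionSpec) -> np.ndarray:
    """Label image (uint16) of the cells' somata; label k = cell index k−1 + 1."""
    labels = np.zeros(acq.frame_shape, dtype=np.uint16)
    for i, cell in enumerate(cells):
        labels[_cell_mask(cell, acq)] = i + 1
    return labels


def simulate_experiment(
    cells: list[CellSpec],
    protocol: StimProtocol,
    acq: AcquisitionSpec,
    opsf: OpsfModel,
    seed: int = 0,
    sync_sample_rate: float = 10_000.0,
    pre_roll: float = 2.0,
    post_roll: float = 2.0,
    artifact_amplitude: float | None = None,
) -> tuple[np.ndarray, SyncRecord, pd.DataFrame]:
    """Render a full photostimulation-experiment movie with ground truth.

    Every cell is targeted on every trial; per trial the transient amplitude
    comes from the dose at that trial's focus offset (relative to the cell's
    own z position).  Stimulation-period frames carry an additive artifact
    in the target pixels.  Returns (movie [T,Y,X float32], SyncRecord,
    ground-truth table).  The table's ``expected_response_dff`` column is
    the exact value the analysis pipeline recovers on a noiseless movie
    (same windows, same frames, including residual fluorescence from
    earlier trials in the baseline).
    """
    if not cells:
        raise ValueError("need at least one targeted cell")
    windows = TrialWindows()
    if protocol.inter_trial < windows.baseline_s + protocol.stim_duration + windows.response_s:
        raise ValueError(
            "inter-trial period shorter than baseline + stimulation + response windows"
        )
    if pre_roll < windows.baseline_s:
        raise ValueError("pre_roll must cover the baseline window of the first trial")

    sweep = protocol.sweep()
    n_events = len(sweep) * protocol.trials_per_z
    duration = pre_roll + n_events * protocol.inter_trial + post_roll
    n_frames = int(round(duration * acq.frame_rate))
    frame_t = np.arange(n_frames) / acq.frame_rate

    events = []  # (z_offset, trial_index, onset_s)
    k = 0
    for z in sweep:
        for trial in range(protocol.trials_per_z):
            events.append((z, trial, pre_roll + k * protocol.inter_trial))
            k += 1

    # synchronization traces
    n_samples = int(round(duration * sync_sample_rate))
    clock = np.zeros(n_samples, dtype=np.int8)
    gate = np.zeros(n_samples, dtype=np.int8)
    half_frame = int(round(sync_sample_rate / acq.frame_rate / 2))
    for j in range(n_frames):
        s = int(round(j / acq.frame_rate * sync_sample_rate))
        clock[s : s + half_frame] = 1
    for _, _, onset in events:
        s0 = int(round(onset * sync_sample_rate))
        s1 = int(round((onset + protocol.stim_duration) * sync_sample_rate))
        gate[s0:s1] = 1
    sync = SyncRecord(sync_sample_rate, clock, gate)
    stim_frames = detect_trial_onsets(sync)

    # per-cell ΔF/F traces and ground truth
    artifact = (
        artifact_amplitude if artifact_amplitude is not None else acq.baseline_fluorescence
    )
    masks = [_cell_mask(c, acq) for c in cells]
    bg = 0.1 * acq.baseline_fluorescence
    movie = np.full((n_frames,) + tuple(acq.frame_shape), bg, dtype=np.float32)
    records = []
    for i, cell in enumerate(cells):
        dff = np.zeros(n_frames)
        amps = []
        for (z, trial, onset) in events:
            dose = excitation_dose(opsf, cell, z)
            amp = amplitude_from_dose(dose, cell.response)
            amps.append((z, trial, onset, dose, amp))
            dff += amp * gcamp_kernel(frame_t - onset, cell.response)
        f = acq.baseline_fluorescence * (1.0 + dff)
        movie[:, masks[i]] += f[:, None] - bg
        for (z, trial, onset, dose, amp), (sf, ef) in zip(amps, stim_frames):
            base, resp = window_frames(sf, ef, acq.frame_rate, n_frames, windows)
            b = dff[base].mean()
            expected = (dff[resp].mean() - b) / (1.0 + b)
            records.append(
                {
                    "neuron_id": i,
                    "z_offset_um": z,
                    "trial": trial,
                    "onset_s": onset,
                    "stim_start_frame": sf,
                    "stim_end_frame": ef,
                    "dose": dose,
                    "amplitude_dff": amp,
                    "expected_response_dff": expected,
                }
            )
        # additive photostimulation artifact in the target pixels
        for sf, ef in stim_frames:
            movie[sf : ef + 1, masks[i]] += artifact

    rng = np.random.default_rng(seed)
    if acq.photon_noise_scale > 0:
        movie = movie + rng.normal(
            0.0, np.sqrt(acq.photon_noise_scale * np.clip(movie, 0, None))
        ).astype(np.float32)
    if acq.read_noise_sd > 0:
        movie = movie + rng.normal(0.0, acq.read_noise_sd, size=movie.shape).astype(
            np.float32
        )
    truth = pd.DataFrame.from_records(records)
    return movie, sync, truth


def simulate_response_curves(
    cells: list[CellSpec],
    protocol: StimProtocol,
    opsf: OpsfModel,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[ResponseCurve]:
    """Fast path: per-neuron response curves without movie rendering.

    Trial responses are amplitude_from_dose(dose(z)) plus i.i.d. Gaussian
    noise of SD ``noise_sd``.  Curves are returned on the ascending z grid;
    the sweep direction labels the curve but does not affect the values.
    """
    rng = np.random.default_rng(seed)
    z_grid = np.array(sorted(protocol.z_offsets), dtype=float)
    curves = []
    for i, cell in enumerate(cells):
        amps = np.array(
            [amplitude_from_dose(excitation_dose(opsf, cell, z), cell.response) for z in z_grid]
        )
        trials = amps[:, None] + (
            rng.normal(0.0, noise_sd, size=(z_grid.size, protocol.trials_per_z))
            if noise_sd > 0
            else 0.0
        )
        curves.append(
            ResponseCurve(
                z_grid.copy(),
                np.broadcast_to(trials, (z_grid.size, protocol.trials_per_z)).copy()
                if noise_sd == 0
                else trials,
                neuron_id=i,
                direction=protocol.direction,
                opsf_condition=f"axial_fwhm_{opsf.axial_fwhm:g}um",
            )
        )
    return curves
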