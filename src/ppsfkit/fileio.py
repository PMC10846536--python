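"""File formats, run configuration, and pipeline orchestration.

Exchange formats are deliberately plain: multi-page TIFF for movies
(T×Y×X) and stacks (Z×Y×X) with a YAML sidecar declaring axis order and
voxel sizes, two-channel CSV for synchronization traces, label TIFF or
JSON polygons for ROIs, CSV/JSON for results.  Every run is deterministic
given (inputs, config, seed), and numeric output columns carry units.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import ppsf as _ppsf
from . import synth as _synth
from .opsf import detect_beads, extract_profile, fit_gaussian, summarize_opsf

__all__ = [
    "RunConfig",
    "load_config",
    "load_movie",
    "load_stack",
    "save_stack",
    "load_rois",
    "save_sync_csv",
    "load_sync_csv",
    "run_pipeline",
    "make_fixtures",
    "SCENARIOS",
]

logger = logging.getLogger("ppsfkit")

__version__ = "0.1.0"


# ---------------------------------------------------------------------------
# Image IO
# ---------------------------------------------------------------------------

def save_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a 3D array as a multi-page 16-bit TIFF (values clipped to uint16)."""
    arr = np.clip(np.asarray(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)


def load_stack(path: str | Path, n_slices: int | None = None) -> np.ndarray:
    """Read a multi-page TIFF as a (Z, Y, X) array, dtype preserved.

    A single-page file becomes shape (1, Y, X).  If ``n_slices`` is given
    and disagrees with the page count, the file is rejected — the guard
    against a sidecar declaring the wrong axis order.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2D/3D TIFF, got shape {arr.shape}")
    if n_slices is not None and arr.shape[0] != n_slices:
        raise ValueError(
            f"{path}: declared {n_slices} pages but file has {arr.shape[0]}"
        )
    return arr


def load_movie(path: str | Path, n_frames: int | None = None) -> np.ndarray:
    """Read a movie TIFF as (T, Y, X); identical mechanics to ``load_stack``."""
    return load_stack(path, n_frames)


def load_rois(path: str | Path, shape: tuple[int, int] | None = None) -> list[np.ndarray]:
    """Load ROI masks from a label TIFF or a JSON polygon file.

    Label TIFF: background 0, ROI k has value k; returns one boolean mask
    per label in ascending label order.  JSON: ``{"shape": [Y, X],
    "rois": [{"points": [[x, y], ...]}, ...]}``; polygons are rasterized by
    pixel-center inclusion (a pixel belongs to the ROI iff its center
    (x+0.5, y+0.5) lies inside the polygon).  Overlapping polygons are
    rejected.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(str(path))
        if labels.ndim != 2:
            raise ValueError(f"{path}: label image must be 2D")
        values = sorted(int(v) for v in np.unique(labels) if v != 0)
        return [labels == v for v in values]
    if path.suffix.lower() == ".json":
        from matplotlib.path import Path as MplPath

        spec = json.loads(path.read_text())
        shp = tuple(spec.get("shape", shape or ()))
        if len(shp) != 2:
            raise ValueError(f"{path}: JSON ROI file must declare a 2D 'shape'")
        yy, xx = np.mgrid[0 : shp[0], 0 : shp[1]]
        centers = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
        masks = []
        occupancy = np.zeros(shp, dtype=bool)
        for roi in spec["rois"]:
            poly = MplPath(np.asarray(roi["points"], dtype=float))
            mask = poly.contains_points(centers).reshape(shp)
            if (mask & occupancy).any():
                raise ValueError(f"{path}: overlapping ROI polygons")
            occupancy |= mask
            masks.append(mask)
        return masks
    raise ValueError(f"{path}: unsupported ROI format {path.suffix!r}")


def save_sync_csv(path: str | Path, sync: _synth.SyncRecord) -> None:
    """Write synchronization traces as CSV (time_s, frame_clock, stim_gate)."""
    t = np.arange(sync.frame_clock.size) / sync.sample_rate
    pd.DataFrame(
        {"time_s": t, "frame_clock": sync.frame_clock, "stim_gate": sync.stim_gate}
    ).to_csv(path, index=False)


def load_sync_csv(path: str | Path) -> _synth.SyncRecord:
    df = pd.read_csv(path)
    for col in ("time_s", "frame_clock", "stim_gate"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise ValueError(f"{path}: sync record too short")
    rate = 1.0 / float(np.median(np.diff(t)))
    return _synth.SyncRecord(rate, df["frame_clock"].to_numpy(), df["stim_gate"].to_numpy())


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one PPSF analysis run needs, loadable from YAML."""

    movie: Path
    sync: Path
    rois: Path
    output_dir: Path
    frame_rate: float = 30.0
    baseline_s: float = 1.5
    response_s: float = 1.5
    inclusion_threshold: float = 0.35
    z_offsets: tuple[float, ...] = tuple(np.arange(-60.0, 61.0, 15.0))
    trials_per_z: int = 3
    direction: str = "standard"
    opsf_condition: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        self.movie, self.sync, self.rois = Path(self.movie), Path(self.sync), Path(self.rois)
        self.output_dir = Path(self.output_dir)
        for p in (self.movie, self.sync, self.rois):
            if not p.exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        if self.inclusion_threshold <= 0:
            raise ValueError("inclusion_threshold must be positive")
        if list(self.z_offsets) != sorted(self.z_offsets):
            raise ValueError("z_offsets must be sorted ascending")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if "z_offsets" in raw:
        raw["z_offsets"] = tuple(float(z) for z in raw["z_offsets"])
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(
        {k: str(v) for k, v in dataclasses.asdict(config).items()}, sort_keys=True
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Movies + sync + ROIs → per-neuron curves, group curve, stats, log.

    Each ROI label is treated as one targeted neuron.  Detected trials are
    assigned to z offsets in sweep order (all repeats at one offset before
    the next, ascending for the standard direction, descending for
    reverse).  Outputs are written under ``config.output_dir``:
    ``curves.csv`` (per neuron and z: trial responses, mean, inclusion,
    applied shift), ``group_curve.csv``, ``stats.json`` and ``run.log``.
    Re-running with identical inputs reproduces identical outputs.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    log_lines = [
        f"ppsfkit {__version__}",
        f"config_hash {_config_hash(config)}",
        f"seed {config.seed}",
    ]

    movie = load_movie(config.movie).astype(float)
    sync = load_sync_csv(config.sync)
    masks = load_rois(config.rois, shape=movie.shape[1:])
    if not masks:
        raise ValueError(f"{config.rois}: no ROIs found")
    windows = _ppsf.TrialWindows(config.baseline_s, config.response_s)

    stim_frames = _ppsf.detect_trial_onsets(sync)
    sweep = list(config.z_offsets)
    if config.direction == "reverse":
        sweep = sweep[::-1]
    expected = len(sweep) * config.trials_per_z
    if len(stim_frames) != expected:
        raise ValueError(
            f"detected {len(stim_frames)} stimulation trials but the protocol "
            f"defines {expected}"
        )
    trials = [
        (z, sf, ef)
        for z, group in zip(
            sweep,
            [stim_frames[i : i + config.trials_per_z] for i in range(0, expected, config.trials_per_z)],
        )
        for sf, ef in group
    ]

    curves, rows = [], []
    for i, mask in enumerate(masks):
        curve = _ppsf.build_response_curve(
            movie, mask, trials, windows, config.frame_rate,
            neuron_id=i, direction=config.direction, opsf_condition=config.opsf_condition,
        )
        included = _ppsf.inclusion_filter(curve, config.inclusion_threshold)
        if not included:
            log_lines.append(
                f"neuron {i}: excluded (max mean response "
                f"{curve.mean_response.max():.3f} ΔF/F < {config.inclusion_threshold})"
            )
        aligned = _ppsf.align_to_max(curve)
        if aligned.direction == "reverse":
            aligned = _ppsf.flip_reverse(aligned)
        for zi, z in enumerate(aligned.z_positions):
            row = {
                "neuron_id": i,
                "z_um": z,
                "mean_dff": aligned.mean_response[zi],
                "included": included,
                "applied_shift_um": aligned.applied_shift,
            }
            for t in range(aligned.trial_responses.shape[1]):
                row[f"trial_{t + 1}_dff"] = aligned.trial_responses[zi, t]
            rows.append(row)
        if included:
            curves.append(aligned)

    pd.DataFrame(rows).to_csv(out / "curves.csv", index=False)

    stats: dict = {
        "n_neurons_total": len(masks),
        "n_neurons_included": len(curves),
        "inclusion_threshold_dff": config.inclusion_threshold,
        "opsf_condition": config.opsf_condition,
        "multiple_testing_correction": "none",
    }
    if curves:
        group = _ppsf.combine_group(curves, normalize=True)
        fwhm = _ppsf.fwhm_half_prominence(group.z_positions, group.mean)
        pd.DataFrame(
            {
                "z_um": group.z_positions,
                "mean_normalized_dff": group.mean,
                "ci95_halfwidth": group.ci95_halfwidth,
            }
        ).to_csv(out / "group_curve.csv", index=False)
        stats["group_fwhm_um"] = None if np.isnan(fwhm) else round(float(fwhm), 3)
        stats["n_group"] = group.n_neurons
    else:
        stats["group_fwhm_um"] = None
        log_lines.append("no neuron passed the inclusion filter; no group curve")

    (out / "stats.json").write_text(json.dumps(stats, indent=2) + "\n")
    log_path.write_text("\n".join(log_lines) + "\n")
    return stats


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

SCENARIOS = ("beads_small", "beads_large", "cohort_null", "cohort_shifted_peak")


def _bead_fixture(out: Path, opsf: _synth.OpsfModel, seed: int) -> None:
    stack, centroids = _synth.generate_bead_stack(
        opsf,
        n_beads=1,
        stack_shape=(int(8 * opsf.axial_sigma) + 9, 64, 64),
        axial_step=1.0,
        lateral_step=0.1,
        noise=_synth.AcquisitionSpec(photon_noise_scale=0.5, read_noise_sd=2.0),
        seed=seed,
    )
    save_stack(out / "beads.tif", stack)
    (out / "beads.yaml").write_text(
        yaml.safe_dump({"axes": "ZYX", "z_step_um": 1.0, "xy_px_um": 0.1})
    )
    pd.DataFrame(centroids, columns=["z_vox", "y_vox", "x_vox"]).to_csv(
        out / "truth_centroids.csv", index=False
    )


def _cohort_null_fixture(out: Path, seed: int) -> None:
    protocol = _synth.StimProtocol()
    rows = []
    for opsf, label in ((_synth.LARGE_OPSF, "large"), (_synth.SMALL_OPSF, "small")):
        cells = [
            _synth.CellSpec((40.0, 40.0, 0.0), 15.0) for _ in range(8)
        ]
        curves = _synth.simulate_response_curves(cells, protocol, opsf, noise_sd=0.1, seed=seed)
        for c in curves:
            for zi, z in enumerate(c.z_positions):
                for t in range(c.trial_responses.shape[1]):
                    rows.append(
                        {
                            "opsf": label,
                            "neuron_id": c.neuron_id,
                            "z_um": z,
                            "trial": t,
                            "response_dff": c.trial_responses[zi, t],
                        }
                    )
    pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)


def _cohort_shifted_fixture(out: Path, seed: int) -> None:
    # one neuron whose soma sits 15 μm below the imaging plane, so its
    # response curve peaks at +15 μm and align_to_max must recentre it
    acq = _synth.AcquisitionSpec(
        frame_shape=(64, 64), photon_noise_scale=0.0, read_noise_sd=0.0
    )
    protocol = _synth.StimProtocol(inter_trial=4.0, trials_per_z=1)
    cells = [_synth.CellSpec((40.0, 40.0, 15.0), 15.0)]
    movie, sync, truth = _synth.simulate_experiment(
        cells, protocol, acq, _synth.LARGE_OPSF, seed=seed
    )
    tifffile.imwrite(str(out / "movie.tif"), (movie * 10).astype(np.uint16))
    save_sync_csv(out / "sync.csv", sync)
    tifffile.imwrite(str(out / "rois.tif"), _synth.cell_masks(cells, acq))
    truth.to_csv(out / "truth.csv", index=False)
    cfg = {
        "movie": str(out / "movie.tif"),
        "sync": str(out / "sync.csv"),
        "rois": str(out / "rois.tif"),
        "output_dir": str(out / "results"),
        "trials_per_z": 1,
        "z_offsets": [float(z) for z in protocol.z_offsets],
        "seed": seed,
    }
    (out / "config.yaml").write_text(yaml.safe_dump(cfg))


def make_fixtures(scenario: str, seed: int, out_dir: str | Path) -> Path:
    """Write a small deterministic test dataset for a named scenario.

    Scenarios: ``beads_small`` / ``beads_large`` (one noisy bead stack in
    the corresponding OPSF condition, with metadata and ground-truth
    centroids), ``cohort_null`` (fast-path response curves for both OPSFs
    on equal-size cells), ``cohort_shifted_peak`` (a noiseless movie whose
    single neuron peaks at +15 μm, plus sync, ROIs and a ready config).
    A SHA-256 manifest of every written file makes determinism checkable.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if scenario == "beads_small":
        _bead_fixture(out, _synth.SMALL_OPSF, seed)
    elif scenario == "beads_large":
        _bead_fixture(out, _synth.LARGE_OPSF, seed)
    elif scenario == "cohort_null":
        _cohort_null_fixture(out, seed)
    else:
        _cohort_shifted_fixture(out, seed)
    manifest = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "MANIFEST.json"
    }
    (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out


def fit_bead_stack(
    stack: np.ndarray,
    axial_step: float = 1.0,
    lateral_step: float = 0.1,
    min_separation: float | None = None,
    half_window_um: float | None = None,
):
    """Convenience: detect beads in a stack and fit all three axes per bead.

    Returns (summary, per-bead fits DataFrame).  ``min_separation`` defaults
    to 5 μm; the profile half-window defaults to 40% of the axial extent.
    """
    stack = np.asarray(stack, dtype=float)
    if min_separation is None:
        min_separation = 5.0
    if half_window_um is None:
        half_window_um = 0.4 * stack.shape[0] * axial_step
    centroids = detect_beads(
        stack, min_separation, axial_step=axial_step, lateral_step=lateral_step
    )
    fits: dict[str, list] = {"axial": [], "lateral_x": [], "lateral_y": []}
    rows = []
    axis_dims = {"axial": 0, "lateral_y": 1, "lateral_x": 2}
    for bead_id, c in enumerate(centroids):
        for axis in fits:
            dim = axis_dims[axis]
            step = axial_step if axis == "axial" else lateral_step
            # largest symmetric window that stays inside the stack
            room = (min(c[dim], stack.shape[dim] - 1 - c[dim]) - 1) * step
            half = min(half_window_um, room)
            try:
                prof = extract_profile(
                    stack, c, axis, half, axial_step=axial_step, lateral_step=lateral_step
                )
                fit = fit_gaussian(prof)
            except Exception as exc:  # noqa: BLE001 - keep going past one bad bead
                logger.warning("bead %d axis %s: %s", bead_id, axis, exc)
                continue
            fits[axis].append(fit)
            rows.append(
                {
                    "bead_id": bead_id,
                    "axis": axis,
                    "mu_um": fit.mu,
                    "sigma_um": fit.sigma,
                    "fwhm_um": fit.fwhm,
                    "r2": fit.r2,
                    "usable": fit.usable,
                }
            )
    return summarize_opsf(fits), pd.DataFrame(rows)
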