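"""Measurement of the axial physiological point spread function (PPSF).

Turns calcium-imaging movies, synchronization traces and ROI masks into
per-neuron response curves (mean post-stimulation ΔF/F versus the axial
offset of the photostimulation focus) and group-level statistics:

1.  trial onsets are located by counting frame-clock rising edges before
    each stimulation-gate edge;
2.  per trial, the ROI-mean raw fluorescence is converted to
    ΔF/F = (F − F0)/F0 with F0 the mean over a 1.5 s pre-stimulation
    baseline, and the trial response is the mean ΔF/F over the 1.5 s
    window after stimulation end (stimulation-artifact frames belong to
    neither window);
3.  trial responses are averaged over repeats at each z offset to give a
    ResponseCurve, which is screened by the 0.35 ΔF/F inclusion filter,
    recentred on its maximum, flipped if acquired in the reverse sweep
    direction, and combined across neurons into a normalized group curve;
4.  the curve width is summarized as the width at half prominence of the
    peak, and conditions are compared with per-offset Welch t-tests.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "TrialWindows",
    "ResponseCurve",
    "GroupCurve",
    "detect_trial_onsets",
    "window_frames",
    "compute_dff",
    "rolling_average",
    "trial_response",
    "build_response_curve",
    "inclusion_filter",
    "align_to_max",
    "flip_reverse",
    "combine_group",
    "fwhm_half_prominence",
    "compare_conditions",
    "register_acquisitions",
]

#: ΔF/F threshold of the inclusion filter: a neuron must reach this mean
#: response at at least one z offset to count as successfully stimulated.
INCLUSION_THRESHOLD_DFF: float = 0.35


@dataclass(frozen=True)
class TrialWindows:
    """Analysis windows around one stimulation trial, in seconds.

    ``baseline_s`` ends at stimulation onset; ``response_s`` starts when the
    stimulation (and its imaging artifact) ends.  Frames overlapping the
    stimulation gate are artifact frames and belong to neither window.
    """

    baseline_s: float = 1.5
    response_s: float = 1.5

    def __post_init__(self) -> None:
        if self.baseline_s <= 0 or self.response_s <= 0:
            raise ValueError("window durations must be positive")


@dataclass
class ResponseCurve:
    """Per-neuron axial response curve: trial ΔF/F responses by z offset."""

    z_positions: np.ndarray
    trial_responses: np.ndarray  # shape (n_z, n_trials)
    neuron_id: int = 0
    direction: str = "standard"
    opsf_condition: str = ""
    applied_shift: float = 0.0  # μm added to z_positions by align_to_max

    def __post_init__(self) -> None:
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        self.trial_responses = np.atleast_2d(np.asarray(self.trial_responses, dtype=float))
        if self.trial_responses.shape[0] != self.z_positions.size:
            raise ValueError("trial_responses must have one row per z position")
        if self.direction not in ("standard", "reverse"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def mean_response(self) -> np.ndarray:
        return self.trial_responses.mean(axis=1)


@dataclass
class GroupCurve:
    """Mean (optionally per-neuron-normalized) response curve across neurons."""

    z_positions: np.ndarray
    per_neuron: np.ndarray  # shape (n_neurons, n_z)
    mean: np.ndarray
    ci95_halfwidth: np.ndarray  # NaN where n < 2
    n_neurons: int
    normalized: bool


# ---------------------------------------------------------------------------
# Synchronization
# ---------------------------------------------------------------------------

def _rising_edges(trace: np.ndarray) -> np.ndarray:
    # a trace that starts high counts as an edge at sample 0 (first frame)
    b = (np.asarray(trace) > 0.5).astype(np.int8)
    return np.flatnonzero(np.diff(np.concatenate(([0], b))) > 0)


def _falling_edges(trace: np.ndarray) -> np.ndarray:
    b = (np.asarray(trace) > 0.5).astype(np.int8)
    return np.flatnonzero(np.diff(b) < 0) + 1


def detect_trial_onsets(sync) -> list[tuple[int, int]]:
    """Map stimulation-gate intervals to (first, last) artifact frame indices.

    ``sync`` is any object with ``sample_rate``, ``frame_clock`` and
    ``stim_gate`` attributes (see :class:`ppsfkit.synth.SyncRecord`).  Frame
    ``i`` spans from its clock rising edge to the next; a frame overlapping
    the gate at all is an artifact frame.
    """
    frame_idx = _rising_edges(sync.frame_clock)
    if frame_idx.size == 0:
        raise ValueError("no frame-clock edges in sync record")
    gate = np.asarray(sync.stim_gate)
    rises = _rising_edges(gate)
    falls = _falling_edges(gate)
    if gate[0] > 0.5 or gate[-1] > 0.5 or rises.size != falls.size:
        raise ValueError("stimulation gate edges are unpaired")
    frame_times = frame_idx / sync.sample_rate
    out: list[tuple[int, int]] = []
    for r, f in zip(rises, falls):
        t0, t1 = r / sync.sample_rate, f / sync.sample_rate
        start = int(np.searchsorted(frame_times, t0, side="right")) - 1
        if start < 0:
            raise ValueError("stimulation begins before the first imaging frame")
        end = int(np.searchsorted(frame_times, t1, side="left")) - 1
        out.append((start, max(end, start)))
    return out


def window_frames(
    stim_start_frame: int,
    stim_end_frame: int,
    frame_rate: float,
    n_frames: int,
    windows: TrialWindows | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame indices of the baseline and response windows for one trial.

    The baseline is the ``baseline_s`` seconds of frames immediately before
    the first artifact frame; the response window is the ``response_s``
    seconds of frames immediately after the last one.
    """
    windows = windows or TrialWindows()
    nb = int(round(windows.baseline_s * frame_rate))
    nr = int(round(windows.response_s * frame_rate))
    baseline = np.arange(stim_start_frame - nb, stim_start_frame)
    response = np.arange(stim_end_frame + 1, stim_end_frame + 1 + nr)
    if baseline.size == 0 or baseline[0] < 0:
        raise ValueError("baseline window extends before the start of the movie")
    if response.size == 0 or response[-1] >= n_frames:
        raise ValueError("response window extends past the end of the movie")
    return baseline, response


# ---------------------------------------------------------------------------
# Trace processing
# ---------------------------------------------------------------------------

def compute_dff(trace: np.ndarray, baseline_frames: np.ndarray) -> np.ndarray:
    """ΔF/F = (F − F0)/F0 with F0 the mean raw fluorescence over the baseline."""
    trace = np.asarray(trace, dtype=float)
    f0 = float(trace[np.asarray(baseline_frames)].mean())
    if f0 <= 0:
        raise ValueError(f"baseline fluorescence F0 = {f0:.3g} is not positive")
    return (trace - f0) / f0


def rolling_average(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average (odd window, shrunken at the edges).

    Used for time-series display; trial statistics are computed on the raw
    ΔF/F values.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def trial_response(dff: np.ndarray, response_frames: np.ndarray) -> float:
    """Mean ΔF/F over the post-stimulation response window."""
    response_frames = np.asarray(response_frames)
    if response_frames.size == 0:
        raise ValueError("response window is empty")
    return float(np.asarray(dff, dtype=float)[response_frames].mean())


def build_response_curve(
    movie: np.ndarray,
    roi_mask: np.ndarray,
    trials: list[tuple[float, int, int]],
    windows: TrialWindows,
    frame_rate: float,
    neuron_id: int = 0,
    direction: str = "standard",
    opsf_condition: str = "",
) -> ResponseCurve:
    """Per-neuron response curve from a movie and a list of trials.

    ``trials`` holds (z_offset_um, stim_start_frame, stim_end_frame) per
    trial; trials are grouped by z offset and the curve rows are ordered by
    ascending z.  Each trial is processed independently: ROI-mean raw F →
    ΔF/F against its own baseline → mean over the response window.
    """
    movie = np.asarray(movie)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != movie.shape[1:]:
        raise ValueError("ROI mask shape does not match movie frames")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    trace = movie[:, roi_mask].mean(axis=1)

    by_z: dict[float, list[float]] = {}
    for z, start, end in trials:
        base, resp = window_frames(start, end, frame_rate, movie.shape[0], windows)
        dff = compute_dff(trace, base)
        by_z.setdefault(float(z), []).append(trial_response(dff, resp))
    z_sorted = sorted(by_z)
    n_trials = {len(v) for v in by_z.values()}
    if len(n_trials) != 1:
        raise ValueError("unequal trial counts across z offsets")
    mat = np.array([by_z[z] for z in z_sorted])
    return ResponseCurve(
        np.array(z_sorted), mat, neuron_id=neuron_id,
        direction=direction, opsf_condition=opsf_condition,
    )


# ---------------------------------------------------------------------------
# Curve-level operations
# ---------------------------------------------------------------------------

def inclusion_filter(curve: ResponseCurve, threshold: float = INCLUSION_THRESHOLD_DFF) -> bool:
    """True if the neuron responded with mean ΔF/F >= threshold at any z offset."""
    return bool(curve.mean_response.max() >= threshold)


def align_to_max(curve: ResponseCurve, max_expected_shift: float = 15.0) -> ResponseCurve:
    """Relabel z so the maximum response sits at 0 μm.

    The soma's true axial position relative to the imaging plane is
    uncertain, so curves are recentred on their peak.  Ties are broken
    toward the smallest-magnitude shift, and toward negative z when two
    candidates tie in magnitude.  A shift larger than ``max_expected_shift``
    (one 15 μm z step) triggers a warning, not an error.
    """
    mean = curve.mean_response
    is_max = mean == mean.max()
    candidates = curve.z_positions[is_max]
    # prefer smallest |z|; on an exact magnitude tie pick the positive z,
    # so the applied shift is the negative one
    order = np.lexsort((-np.sign(candidates), np.abs(candidates)))
    z_max = float(candidates[order[0]])
    shift = -z_max
    if abs(shift) > max_expected_shift:
        warnings.warn(
            f"curve for neuron {curve.neuron_id} shifted by {shift:+.1f} μm "
            f"(> {max_expected_shift} μm)",
            stacklevel=2,
        )
    return dataclasses.replace(
        curve, z_positions=curve.z_positions + shift, applied_shift=shift
    )


def flip_reverse(curve: ResponseCurve) -> ResponseCurve:
    """Negate z and reorder a reverse-direction curve to match the standard one."""
    if curve.direction != "reverse":
        raise ValueError("flip_reverse applies only to reverse-direction curves")
    z = -curve.z_positions
    order = np.argsort(z)
    return dataclasses.replace(
        curve,
        z_positions=z[order],
        trial_responses=curve.trial_responses[order],
        direction="standard",
    )


def combine_group(curves: list[ResponseCurve], normalize: bool = True) -> GroupCurve:
    """Pointwise mean and 95% CI across neurons, on a shared z grid.

    With ``normalize`` each neuron's mean curve is first divided by its own
    maximum, so the group mean peaks at 1.
    """
    if not curves:
        raise ValueError("no curves to combine")
    z = curves[0].z_positions
    rows = []
    for c in curves:
        if not np.array_equal(c.z_positions, z):
            raise ValueError("curves do not share a common z grid")
        m = c.mean_response
        rows.append(m / m.max() if normalize else m)
    per_neuron = np.vstack(rows)
    mean = per_neuron.mean(axis=0)
    n = per_neuron.shape[0]
    if n >= 2:
        ci = 1.96 * per_neuron.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        ci = np.full(z.shape, np.nan)
    return GroupCurve(z.copy(), per_neuron, mean, ci, n, normalize)


def fwhm_half_prominence(z_positions: np.ndarray, values: np.ndarray) -> float:
    """Width of the curve at half the prominence of its highest peak, in μm.

    Prominence measures the peak height above the higher of its two flanking
    bases (the curve boundaries count as bases), and the width is taken
    where a horizontal line at peak − prominence/2 intercepts the signal,
    with linear interpolation between samples.  Returns NaN for flat or
    monotone curves (no interior peak).
    """
    z = np.asarray(z_positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if z.size < 3 or z.size != y.size:
        raise ValueError("need at least 3 matching samples")
    spacing = np.diff(z)
    if spacing.min() <= 0 or not np.allclose(spacing, spacing[0]):
        raise ValueError("z positions must be uniformly increasing")
    peaks, _ = signal.find_peaks(y)
    if peaks.size == 0 or y[peaks].max() < y.max():
        return float("nan")  # flat curve or maximum on the boundary
    peak = peaks[np.argmax(y[peaks])]
    widths, _, _, _ = signal.peak_widths(y, [peak], rel_height=0.5)
    return float(widths[0] * spacing[0])


def compare_conditions(group_a: np.ndarray, group_b: np.ndarray) -> pd.DataFrame:
    """Welch two-sample t-test per z offset between two neuron groups.

    ``group_a`` and ``group_b`` are (n_neurons, n_z) response matrices.
    No multiple-testing correction is applied across the z offsets; the
    output notes this.  Offsets where both groups have zero variance yield
    NaN (test not available).
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must cover the same z offsets")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 neurons per group")
    t = np.full(a.shape[1], np.nan)
    p = np.full(a.shape[1], np.nan)
    for j in range(a.shape[1]):
        if a[:, j].var(ddof=1) == 0 and b[:, j].var(ddof=1) == 0:
            continue
        res = stats.ttest_ind(a[:, j], b[:, j], equal_var=False)
        t[j], p[j] = res.statistic, res.pvalue
    df = pd.DataFrame({"t": t, "p": p})
    df.attrs["multiple_testing_correction"] = "none"
    return df


def register_acquisitions(movies: list[np.ndarray]) -> list[np.ndarray]:
    """Integer-pixel translation of each acquisition onto the first one.

    Cross-correlates each movie's mean image with the first movie's mean
    image and rolls the frames by the integer shift.  Sufficient to remove
    slow drift between acquisitions at different photostimulation z offsets.
    """
    from skimage.registration import phase_cross_correlation

    if not movies:
        return []
    ref = np.asarray(movies[0]).mean(axis=0)
    out = [np.asarray(movies[0])]
    for mov in movies[1:]:
        mov = np.asarray(mov)
        shift, _, _ = phase_cross_correlation(ref, mov.mean(axis=0), normalization=None)
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        out.append(np.roll(mov, (dy, dx), axis=(1, 2)))
    return out
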