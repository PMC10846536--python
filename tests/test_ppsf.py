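"""PPSF pipeline: synchronization, ΔF/F, curves, alignment, width, statistics."""

import dataclasses

import numpy as np
import pytest

from ppsfkit import ppsf, synth
from ppsfkit.ppsf import ResponseCurve, TrialWindows


def _make_sync(gate_intervals, frame_rate=30.0, sample_rate=1000.0, duration=3.0):
    n = int(duration * sample_rate)
    clock = np.zeros(n)
    for j in range(int(duration * frame_rate)):
        s = int(round(j / frame_rate * sample_rate))
        clock[s : s + 2] = 1
    gate = np.zeros(n)
    for t0, t1 in gate_intervals:
        gate[int(round(t0 * sample_rate)) : int(round(t1 * sample_rate))] = 1
    return synth.SyncRecord(sample_rate, clock, gate)


def _curve(values, z=None, trials=None, **kw):
    values = np.asarray(values, dtype=float)
    if z is None:
        z = np.arange(-60.0, 61.0, 15.0)[: len(values)]
    mat = values[:, None] if trials is None else trials
    return ResponseCurve(np.asarray(z, dtype=float), mat, **kw)


# ---------------------------------------------------------------------------
# Synchronization
# ---------------------------------------------------------------------------

def test_trial_onset_frame_arithmetic():
    """Gate high 1.50-1.75 s against a 30 Hz clock spans frames 45..52."""
    sync = _make_sync([(1.50, 1.75)])
    assert ppsf.detect_trial_onsets(sync) == [(45, 52)]


def test_empty_gate_yields_no_trials():
    assert ppsf.detect_trial_onsets(_make_sync([])) == []


def test_unpaired_gate_rejected():
    sync = _make_sync([(1.5, 1.75)])
    gate = sync.stim_gate.copy()
    gate[-1] = 1  # ends high: falling edge missing
    bad = synth.SyncRecord(sync.sample_rate, sync.frame_clock, gate)
    with pytest.raises(ValueError, match="unpaired"):
        ppsf.detect_trial_onsets(bad)


def test_stimulation_before_first_frame_rejected():
    n = 3000
    clock = np.zeros(n)
    clock[500::100] = 1  # imaging starts at 0.5 s
    gate = np.zeros(n)
    gate[100:200] = 1  # stimulation at 0.1 s
    with pytest.raises(ValueError, match="before the first"):
        ppsf.detect_trial_onsets(synth.SyncRecord(1000.0, clock, gate))


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def test_dff_formula():
    dff = ppsf.compute_dff(np.array([10.0, 10, 10, 20]), np.arange(3))
    assert np.allclose(dff, [0, 0, 0, 1])
    assert np.allclose(ppsf.compute_dff(np.full(6, 3.0), np.arange(3)), 0)


def test_dff_rejects_nonpositive_baseline():
    with pytest.raises(ValueError, match="F0"):
        ppsf.compute_dff(np.array([0.0, 0.0, 1.0]), np.arange(2))


def test_rolling_average_behaviour():
    const = np.full(20, 3.7)
    assert np.allclose(ppsf.rolling_average(const, 5), const)
    impulse = np.zeros(11)
    impulse[5] = 1.0
    out = ppsf.rolling_average(impulse, 5)
    assert np.allclose(out[3:8], 0.2)
    x = np.arange(7.0)
    assert np.array_equal(ppsf.rolling_average(x, 1), x)
    with pytest.raises(ValueError):
        ppsf.rolling_average(x, 4)


def test_trial_response_is_window_mean():
    dff = np.array([9.0, 0.4, 0.6, 0.5, 9.0])
    assert ppsf.trial_response(dff, np.arange(1, 4)) == pytest.approx(0.5)
    assert ppsf.trial_response(np.zeros(5), np.arange(5)) == 0.0
    with pytest.raises(ValueError):
        ppsf.trial_response(dff, np.array([], dtype=int))


# ---------------------------------------------------------------------------
# Movie -> curve
# ---------------------------------------------------------------------------

def _trials_from_truth(truth):
    return list(zip(truth.z_offset_um, truth.stim_start_frame, truth.stim_end_frame))


def test_noiseless_round_trip_recovers_ground_truth(noiseless_experiment, small_acq):
    movie, _, truth, mask = noiseless_experiment
    curve = ppsf.build_response_curve(
        movie, mask, _trials_from_truth(truth), TrialWindows(), small_acq.frame_rate
    )
    expected = (
        truth.groupby("z_offset_um").expected_response_dff.mean().sort_index().to_numpy()
    )
    assert np.allclose(curve.mean_response, expected, atol=1e-5)
    # responses fall off monotonically away from the cell plane (small
    # wiggle allowed: residual decay of earlier transients biases baselines)
    m = curve.mean_response
    center = np.argmin(np.abs(curve.z_positions))
    assert np.all(np.diff(m[: center + 1]) >= -0.05)
    assert np.all(np.diff(m[center:]) <= 0.05)


def test_noiseless_repeats_equal_single_trial(small_acq, centered_cell):
    # default 10 s repeat spacing: transients decay fully between trials,
    # so the three noiseless repeats coincide with their mean
    proto = synth.StimProtocol(z_offsets=(-30.0, 0.0, 30.0))
    movie, _, truth = synth.simulate_experiment(
        [centered_cell], proto, small_acq, synth.LARGE_OPSF, seed=13
    )
    mask = synth.cell_masks([centered_cell], small_acq) == 1
    curve = ppsf.build_response_curve(
        movie, mask, _trials_from_truth(truth), TrialWindows(), small_acq.frame_rate
    )
    assert np.allclose(curve.trial_responses, curve.mean_response[:, None], atol=0.01)


def test_control_roi_far_from_target_is_flat(noiseless_experiment, small_acq):
    movie, _, truth, mask = noiseless_experiment
    control = np.zeros_like(mask)
    control[2:8, 2:8] = True  # background-only corner, same area scale
    assert not (control & mask).any()
    curve = ppsf.build_response_curve(
        movie, control, _trials_from_truth(truth), TrialWindows(), small_acq.frame_rate
    )
    assert np.all(np.abs(curve.mean_response) < 1e-6)


def test_curve_scale_invariance(noiseless_experiment, small_acq):
    """Multiplying raw fluorescence by k > 0 leaves ΔF/F curves unchanged."""
    movie, _, truth, mask = noiseless_experiment
    a = ppsf.build_response_curve(
        movie, mask, _trials_from_truth(truth), TrialWindows(), small_acq.frame_rate
    )
    b = ppsf.build_response_curve(
        movie * 3.0, mask, _trials_from_truth(truth), TrialWindows(), small_acq.frame_rate
    )
    assert np.allclose(a.trial_responses, b.trial_responses, atol=2e-6)


def test_empty_roi_rejected(noiseless_experiment, small_acq):
    movie, _, truth, mask = noiseless_experiment
    with pytest.raises(ValueError, match="empty"):
        ppsf.build_response_curve(
            movie, np.zeros_like(mask), _trials_from_truth(truth), TrialWindows(),
            small_acq.frame_rate,
        )


# ---------------------------------------------------------------------------
# Curve operations
# ---------------------------------------------------------------------------

def test_inclusion_filter_boundary():
    assert ppsf.inclusion_filter(_curve([0.0, 0.35, 0.1]))
    assert not ppsf.inclusion_filter(_curve([0.0, 0.349, 0.1]))
    assert not ppsf.inclusion_filter(_curve(np.zeros(9)))


def test_align_to_max_shifts_and_records():
    values = np.array([0, 0.1, 0.2, 0.4, 0.8, 1.0, 0.5, 0.2, 0.1])  # max at +15
    aligned = ppsf.align_to_max(_curve(values))
    assert aligned.applied_shift == -15.0
    assert aligned.z_positions[np.argmax(aligned.mean_response)] == 0.0

    centered = ppsf.align_to_max(_curve(np.array([0, 0, 0, 0.4, 1.0, 0.4, 0, 0, 0])))
    assert centered.applied_shift == 0.0


def test_align_to_max_tie_breaking():
    # ties at -15 and +15: the negative shift (to the +15 peak) is chosen
    values = np.array([0, 0, 0, 1.0, 0.5, 1.0, 0, 0, 0])
    aligned = ppsf.align_to_max(_curve(values))
    assert aligned.applied_shift == -15.0
    # tie at 0 and +15: zero-magnitude shift wins
    values = np.array([0, 0, 0, 0.5, 1.0, 1.0, 0, 0, 0])
    assert ppsf.align_to_max(_curve(values)).applied_shift == 0.0


def test_align_to_max_warns_on_large_shift():
    values = np.array([0, 1.0, 0.2, 0.1, 0, 0, 0, 0, 0])  # max at -45
    with pytest.warns(UserWarning, match="shifted by"):
        ppsf.align_to_max(_curve(values))


def test_flip_reverse_round_trip():
    values = np.arange(9.0)
    curve = _curve(values, direction="reverse")
    flipped = ppsf.flip_reverse(curve)
    assert np.array_equal(flipped.mean_response, values[::-1])
    assert np.array_equal(flipped.z_positions, curve.z_positions)
    twice = ppsf.flip_reverse(dataclasses.replace(flipped, direction="reverse"))
    assert np.array_equal(twice.mean_response, values)

    symmetric = _curve(np.array([0, 1, 2, 3, 4, 3, 2, 1, 0.0]), direction="reverse")
    assert np.array_equal(ppsf.flip_reverse(symmetric).mean_response, symmetric.mean_response)

    with pytest.raises(ValueError):
        ppsf.flip_reverse(_curve(values, direction="standard"))


def test_combine_group_basics():
    c = _curve(np.array([0, 0.2, 1.0, 0.2, 0, 0, 0, 0, 0.0]))
    single = ppsf.combine_group([c])
    assert np.allclose(single.mean, c.mean_response / c.mean_response.max())
    assert np.all(np.isnan(single.ci95_halfwidth))

    pair = ppsf.combine_group([c, c])
    assert np.allclose(pair.mean, single.mean)
    assert np.allclose(pair.ci95_halfwidth, 0.0)

    other = _curve(np.zeros(5), z=np.arange(5.0))
    with pytest.raises(ValueError, match="z grid"):
        ppsf.combine_group([c, other])


def test_combine_group_mean_near_truth_under_noise():
    rng = np.random.default_rng(6)
    z = np.arange(-60.0, 61.0, 15.0)
    shape = np.exp(-0.5 * (z / 18.0) ** 2)
    curves = [_curve(shape + rng.normal(0, 0.05, z.size)) for _ in range(100)]
    group = ppsf.combine_group(curves, normalize=False)
    se = 0.05 / np.sqrt(100)
    assert np.all(np.abs(group.mean - shape) < 4 * se)


# ---------------------------------------------------------------------------
# Half-prominence width
# ---------------------------------------------------------------------------

def test_fwhm_triangle_example():
    z = np.array([-30.0, -15, 0, 15, 30])
    assert ppsf.fwhm_half_prominence(z, np.array([0, 0.5, 1, 0.5, 0.0])) == pytest.approx(30.0)


def test_fwhm_coarse_gaussian_within_interpolation_error():
    z = np.arange(-60.0, 61.0, 15.0)
    sigma = 44.0 / (2 * np.sqrt(2 * np.log(2)))
    width = ppsf.fwhm_half_prominence(z, np.exp(-0.5 * (z / sigma) ** 2))
    assert width == pytest.approx(44.0, abs=1.0)


def test_fwhm_dense_gaussian_closed_form():
    z = np.arange(-120.0, 120.001, 0.01)
    sigma = 44.0 / (2 * np.sqrt(2 * np.log(2)))
    width = ppsf.fwhm_half_prominence(z, np.exp(-0.5 * (z / sigma) ** 2))
    assert width == pytest.approx(44.0, rel=1e-3)


def test_fwhm_failure_values():
    z = np.arange(-60.0, 61.0, 15.0)
    assert np.isnan(ppsf.fwhm_half_prominence(z, np.full(z.size, 2.0)))
    assert np.isnan(ppsf.fwhm_half_prominence(z, np.linspace(0, 1, z.size)))


# ---------------------------------------------------------------------------
# Condition comparison
# ---------------------------------------------------------------------------

def test_compare_identical_groups():
    g = np.tile([[0.1, 0.5, 1.0], [0.2, 0.6, 1.1], [0.3, 0.7, 1.2]], (1, 1))
    out = ppsf.compare_conditions(g, g)
    assert np.allclose(out["t"], 0.0)
    assert np.allclose(out["p"], 1.0)
    assert out.attrs["multiple_testing_correction"] == "none"


def test_compare_zero_variance_not_available():
    a = np.zeros((3, 2))
    b = np.ones((3, 2))
    out = ppsf.compare_conditions(a, b)
    assert out["p"].isna().all()


def test_compare_requires_two_per_group():
    with pytest.raises(ValueError):
        ppsf.compare_conditions(np.zeros((1, 9)), np.zeros((5, 9)))


# ---------------------------------------------------------------------------
# Acquisition registration
# ---------------------------------------------------------------------------

def test_register_acquisitions_undoes_integer_drift(noiseless_experiment):
    movie, _, _, _ = noiseless_experiment
    short = movie[:50]
    drifted = np.roll(short, (3, -2), axis=(1, 2))
    registered = ppsf.register_acquisitions([short, drifted])
    assert np.allclose(registered[1], short, atol=1e-5)
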