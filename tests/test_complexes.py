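"""Complex detection, position folding, bend angles, volumes, QD flag."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afm_dnacomplex import GeneratorConfig, generate_scene
from afm_dnacomplex.complexes import (ComplexDetection, classify_qd,
                                      detect_complexes, fractional_position,
                                      measure_bend_angle, measure_traces,
                                      measure_volume)
from afm_dnacomplex.core import HeightMap
from afm_dnacomplex.synthetic import render_scene
from afm_dnacomplex.tracing import MoleculeTrace, QC_OK, trace_height_map

from conftest import one_complex_frame, straight_chain

L_FULL = 505 * 0.34


def _polyline_trace(points: np.ndarray) -> MoleculeTrace:
    seg = np.hypot(*np.diff(points, axis=0).T)
    arc = np.concatenate(([0.0], np.cumsum(seg)))
    return MoleculeTrace(path=points, arclength=arc,
                         contour_length=float(arc[-1]), qc_status=QC_OK)


def _kinked_polyline(angle_deg: float, arm_nm: float = 40.0,
                     step: float = 0.5) -> MoleculeTrace:
    """Two straight arms meeting at the origin with a given deflection."""
    s = np.arange(step, arm_nm, step)
    up = np.column_stack((-s[::-1], np.zeros_like(s)))
    t = np.deg2rad(angle_deg)
    down = np.column_stack((s * np.cos(t), s * np.sin(t)))
    pts = np.vstack((up, [[0.0, 0.0]], down))
    return _polyline_trace(pts)


def _ok_traces(height_map):
    return [t for t in trace_height_map(height_map,
                                        expected_length_nm=L_FULL)
            if t.qc_status == QC_OK]


def test_bare_dna_has_zero_detections(bare_dna_scene):
    hm = bare_dna_scene.height_map
    for t in _ok_traces(hm):
        assert detect_complexes(t, hm) == []


def test_single_blob_detected_near_site():
    """One complex at fraction 0.498 is found once, near 49.8% folded."""
    cfg = GeneratorConfig(n_molecules=1, noise_sd_nm=0.0)
    scene = render_scene([straight_chain()], one_complex_frame(0.498), cfg,
                         np.random.default_rng(0))
    hm = scene.height_map
    (trace,) = _ok_traces(hm)
    dets = detect_complexes(trace, hm)
    assert len(dets) == 1
    folded = fractional_position(trace, dets[0].arclength_nm)
    assert folded == pytest.approx(49.8, abs=2.0)


def test_two_blobs_30nm_apart_detected_separately():
    import pandas as pd
    frac_gap = 30.0 / L_FULL
    frame = pd.concat([one_complex_frame(0.35),
                       one_complex_frame(0.35 + frac_gap)],
                      ignore_index=True)
    cfg = GeneratorConfig(n_molecules=1, noise_sd_nm=0.0)
    scene = render_scene([straight_chain()], frame, cfg,
                         np.random.default_rng(0))
    hm = scene.height_map
    (trace,) = _ok_traces(hm)
    dets = detect_complexes(trace, hm)
    assert len(dets) == 2
    gap = abs(dets[1].arclength_nm - dets[0].arclength_nm)
    assert gap == pytest.approx(30.0, abs=6.0)


def test_fractional_position_midpoint_and_ends():
    trace = _polyline_trace(np.column_stack((np.linspace(0, 172, 173),
                                             np.zeros(173))))
    assert fractional_position(trace, trace.contour_length / 2) == \
        pytest.approx(50.0)
    assert fractional_position(trace, 0.0) == 0.0
    assert fractional_position(trace, trace.contour_length) == 0.0


@settings(deadline=None, max_examples=50)
@given(st.floats(min_value=0.0, max_value=171.7))
def test_fractional_position_fold_is_orientation_invariant(s):
    """Reversing the trace maps arclength s -> L - s but leaves the
    folded position unchanged (the ends are interchangeable)."""
    pts = np.column_stack((np.linspace(0, 171.7, 400),
                           10 * np.sin(np.linspace(0, 3, 400))))
    trace = _polyline_trace(pts)
    rev = trace.reversed()
    s = min(s, trace.contour_length)
    assert fractional_position(trace, s) == pytest.approx(
        fractional_position(rev, trace.contour_length - s), abs=1e-6)
    assert 0.0 <= fractional_position(trace, s) <= 50.0


def test_bend_angle_straight_polyline_is_zero():
    trace = _polyline_trace(np.column_stack((np.linspace(0, 100, 201),
                                             np.zeros(201))))
    assert measure_bend_angle(trace, 50.0) == pytest.approx(0.0, abs=1e-6)


@pytest.mark.parametrize("angle", [20.0, 35.0, 70.0])
def test_bend_angle_constructed_kink(angle):
    """A polyline with an exact kink measures to within 2 deg."""
    trace = _kinked_polyline(angle)
    s0 = trace.arclength[len(trace.path) // 2]
    measured = measure_bend_angle(trace, s0, arm_length_nm=10.0)
    assert measured == pytest.approx(angle, abs=2.0)


def test_bend_angle_rotation_invariant():
    """The measured kink angle varies < 1 deg under global rotation."""
    vals = []
    for rot in (0.0, 17.0, 45.0, 90.0, 133.0):
        trace = _kinked_polyline(35.0)
        t = np.deg2rad(rot)
        R = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        rotated = _polyline_trace(trace.path @ R.T + np.array([50.0, 30.0]))
        s0 = rotated.arclength[len(rotated.path) // 2]
        vals.append(measure_bend_angle(rotated, s0))
    assert max(vals) - min(vals) < 1.0


def test_bend_angle_undefined_near_ends():
    trace = _polyline_trace(np.column_stack((np.linspace(0, 100, 201),
                                             np.zeros(201))))
    assert measure_bend_angle(trace, 3.0, arm_length_nm=10.0) is None
    assert measure_bend_angle(trace, 99.0, arm_length_nm=10.0) is None


def test_bend_angle_image_ensemble_recovers_35deg_state(bent35_scene):
    """Complexes generated in the 35 deg bend state measure back with an
    ensemble mean within 5 deg of 35."""
    hm = bent35_scene.height_map
    df, _ = measure_traces(hm, trace_height_map(hm, expected_length_nm=L_FULL),
                           measure_volumes=False)
    angles = df.bend_angle_deg.dropna()
    assert len(angles) >= 20
    assert angles.mean() == pytest.approx(35.0, abs=5.0)


def test_volume_of_isolated_blob_accurate():
    """A noiseless unconvolved 100 nm^3 blob measures within 5%."""
    from afm_dnacomplex.synthetic import _protein_blob_shape, _stamp_gaussian
    cfg = GeneratorConfig(tip_sigma_nm=0.0)
    grid = np.zeros((100, 100))
    amp, s0 = _protein_blob_shape(100.0, 1.5, cfg)
    _stamp_gaussian(grid, 101.0, 101.0, amp, s0, 2.0)
    hm = HeightMap(grid, 2.0)
    det = ComplexDetection(0.0, np.array([101.0, 101.0]),
                           float(grid.max()), 0.0)
    res = measure_volume(hm, det)
    assert res.volume_nm3 == pytest.approx(100.0, rel=0.05)
    assert not res.ambiguous


def test_volume_zero_height_region_is_zero():
    hm = HeightMap(np.zeros((60, 60)), 2.0)
    det = ComplexDetection(0.0, np.array([60.0, 60.0]), 0.0, 0.0)
    assert measure_volume(hm, det).volume_nm3 == 0.0


def test_monomer_vs_dimer_modes_ordered_and_separated():
    """Scenes rendered at 100 vs 160 nm^3 give measured volume
    distributions whose medians are separated and correctly ordered."""
    medians = {}
    for v in (100.0, 160.0):
        cfg = GeneratorConfig(n_molecules=12, occupancy_specific=1.0,
                              nonspecific_rate=0.0, protein_volume_nm3=v,
                              volume_sd_nm3=0.0, seed=17)
        scene = generate_scene(cfg)
        hm = scene.height_map
        df, _ = measure_traces(hm,
                               trace_height_map(hm, expected_length_nm=L_FULL))
        medians[v] = df.volume_nm3.median()
    assert medians[160.0] > medians[100.0]
    assert medians[160.0] - medians[100.0] > 30.0


def test_qd_classification_thresholds():
    assert classify_qd(4.5) is True          # QD-containing complex
    assert classify_qd(1.5) is False         # bare protein complex
    assert classify_qd(3.0) is True          # boundary is inclusive
    assert classify_qd(2.999999) is False
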