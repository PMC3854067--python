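import numpy as np
import pytest

from fmposthoc import (
    AcquisitionTiming,
    QualityCriteria,
    RoiSet,
    SimulationConfig,
    TimeLapseStack,
    build_candidate_mask,
    classify_roi_quality,
    remove_edge_rois,
    roi_traces,
    simulate_experiment,
)

from conftest import make_trace_stack
from oracles import brute_roi_traces


def centers_to_labels(rois, truth):
    r = np.round(truth.center_row).astype(int)
    c = np.round(truth.center_col).astype(int)
    return rois.label_image[r, c]


def test_noise_free_field_recovers_every_bouton(clean_experiment):
    config, (stack, _, _, truth) = clean_experiment
    rois = build_candidate_mask(stack)
    assert rois.n_rois == truth.n_boutons
    hits = centers_to_labels(rois, truth)
    assert np.all(hits > 0)
    assert len(np.unique(hits)) == truth.n_boutons  # one ROI per bouton


def test_empty_field_yields_empty_roiset():
    config = SimulationConfig(seed=0, n_boutons=0, noise_model="none",
                              background_gradient=0.0)
    stack, _, _, _ = simulate_experiment(config)
    with pytest.warns(UserWarning, match="empty ROI set"):
        rois = build_candidate_mask(stack)
    assert rois.n_rois == 0


def test_watershed_splits_boutons_at_minimum_separation():
    # two spots exactly 4 sigma apart must come out as two labels
    sigma = 1.5
    shape = (48, 48)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    spot = lambda r, c: np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2))
    profile = 1000.0 * (spot(24.0, 21.0) + spot(24.0, 27.0))
    factor = np.concatenate([np.ones(30), np.full(15, 0.5)])
    frames = factor[:, None, None] * profile[None]
    stack = TimeLapseStack(frames, AcquisitionTiming())
    rois = build_candidate_mask(stack, expected_sigma_px=sigma)
    assert rois.n_rois == 2
    assert rois.label_image[24, 21] != rois.label_image[24, 27]
    assert min(rois.label_image[24, 21], rois.label_image[24, 27]) > 0


def test_roi_traces_match_brute_force(default_experiment):
    _, (stack, _, _, _) = default_experiment
    rois = build_candidate_mask(stack)
    traces = roi_traces(stack, rois)
    brute = brute_roi_traces(stack.frames, rois.label_image, rois.n_rois)
    assert np.allclose(traces, brute, rtol=1e-9)


def step_trace(baseline, post, n_base=30, n_post=15):
    return np.concatenate([np.full(n_base, baseline, float), np.full(n_post, post, float)])


def quality_of(trace, **criteria_kwargs):
    stack = make_trace_stack({(5, 5): trace, (5, 6): trace, (6, 5): trace, (6, 6): trace})
    rois = RoiSet((np.arange(16 * 16).reshape(16, 16) * 0).astype(np.int32))
    labels = np.zeros((16, 16), np.int32)
    labels[5:7, 5:7] = 1
    rois = RoiSet(labels)
    criteria = QualityCriteria(**criteria_kwargs) if criteria_kwargs else None
    return classify_roi_quality(stack, rois, criteria)


def test_clean_step_response_passes_quality():
    v = quality_of(step_trace(100.0, 60.0))
    assert v.baseline_slope[0] == pytest.approx(0.0, abs=1e-12)
    assert v.baseline_cv[0] == pytest.approx(0.0, abs=1e-12)
    assert v.unloading_extent[0] == pytest.approx(0.40, abs=1e-12)
    assert v.passed[0] and v.failure_reasons[0] == frozenset()


def test_flat_trace_fails_on_extent():
    v = quality_of(step_trace(100.0, 100.0))
    assert v.unloading_extent[0] == pytest.approx(0.0, abs=1e-12)
    assert not v.passed[0]
    assert v.failure_reasons[0] == frozenset({"extent"})


def test_baseline_ramp_fails_on_slope_with_closed_form_value():
    # baseline climbs 100 -> 130 over the 30 baseline frames, then unloads
    base = np.linspace(100.0, 130.0, 30)
    trace = np.concatenate([base, np.full(15, 50.0)])
    v = quality_of(trace, max_baseline_cv=10.0)  # isolate the slope criterion
    f0 = base.mean()
    expected_slope = (30.0 / 29.0) / f0  # arithmetic-ramp least-squares slope / F0
    assert v.baseline_slope[0] == pytest.approx(expected_slope, rel=1e-12)
    assert v.failure_reasons[0] == frozenset({"slope"})


def test_quality_statistics_invariant_to_intensity_scale(default_experiment):
    _, (stack, _, _, _) = default_experiment
    rois = build_candidate_mask(stack)
    v1 = classify_roi_quality(stack, rois)
    scaled = TimeLapseStack(stack.frames * 3.7, stack.timing)
    v2 = classify_roi_quality(scaled, rois)
    assert np.allclose(v1.baseline_slope, v2.baseline_slope, rtol=1e-9)
    assert np.allclose(v1.baseline_cv, v2.baseline_cv, rtol=1e-9)
    assert np.allclose(v1.unloading_extent, v2.unloading_extent, rtol=1e-9)
    assert np.array_equal(v1.passed, v2.passed)


def test_remove_edge_rois_geometry():
    labels = np.zeros((20, 30), np.int32)
    labels[0:3, 5:8] = 1      # touches the top border strip
    labels[10:13, 10:13] = 2  # fully interior
    labels[15:18, 27:30] = 3  # touches the right border strip
    rois = RoiSet(labels)

    all_true = np.ones((20, 30), bool)
    assert np.array_equal(remove_edge_rois(rois, all_true).label_image, labels)

    # a shift of (3, -2) invalidates a 3-row top strip and a 2-col right strip
    valid = np.zeros((20, 30), bool)
    valid[3:, :-2] = True
    assert (~valid).sum() == 3 * 30 + 2 * 20 - 6
    kept = remove_edge_rois(rois, valid)
    assert kept.n_rois == 1
    assert np.array_equal(kept.label_image == 1, labels == 2)  # relabeled consecutively


def test_roiset_relabels_to_consecutive_labels():
    labels = np.zeros((10, 10), np.int32)
    labels[1:3, 1:3] = 4
    labels[6:8, 6:8] = 9
    rois = RoiSet(labels)
    assert rois.n_rois == 2
    assert sorted(np.unique(rois.label_image)) == [0, 1, 2]
    assert rois.areas_px.tolist() == [4, 4]
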