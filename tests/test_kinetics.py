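import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmposthoc import (
    RoiSet,
    bonferroni_pairwise,
    build_candidate_mask,
    compute_kinetics,
    nominal_unloaded_fraction,
    one_way_anova,
    summarize_groups,
)

from conftest import make_trace_stack
from oracles import brute_anova


def single_roi_records(trace):
    stack = make_trace_stack({(5, 5): np.asarray(trace, float)})
    labels = np.zeros((16, 16), np.int32)
    labels[5, 5] = 1
    return compute_kinetics(stack, RoiSet(labels), tail_window_frames=10)


def test_step_trace_unloaded_fraction():
    trace = np.concatenate([np.full(30, 100.0), np.full(30, 60.0)])
    rec = single_roi_records(trace)
    assert rec.unloaded_fraction[0] == pytest.approx(0.40, abs=1e-12)
    assert rec.normalized_traces[0, :30].mean() == pytest.approx(1.0, abs=1e-12)


def test_constant_trace_has_zero_unloading():
    rec = single_roi_records(np.full(60, 123.0))
    assert rec.unloaded_fraction[0] == 0.0


def test_noise_free_boutons_match_analytic_fraction(clean_experiment):
    config, (stack, _, _, truth) = clean_experiment
    rois = build_candidate_mask(stack)
    rec = compute_kinetics(stack, rois, tail_window_frames=10)
    # match each ROI to its planted bouton through the truth centers
    r = np.round(truth.center_row).astype(int)
    c = np.round(truth.center_col).astype(int)
    labels = rois.label_image[r, c]
    assert np.all(labels > 0)
    for i, label in enumerate(labels):
        expected = nominal_unloaded_fraction(
            truth.unload_fraction[i],
            config.unload_tau_frames,
            config.timing.stim_start_frame,
            config.n_frames,
            10,
            n_baseline_frames=config.timing.n_baseline_frames,
            bleach_rate_per_frame=config.bleach_rate_per_frame,
        )
        assert rec.unloaded_fraction[label - 1] == pytest.approx(expected, rel=1e-6)


def test_anova_on_frozen_fixture_matches_textbook_value():
    groups = [
        np.array([31.2, 35.0, 33.1, 36.4, 34.0]),
        np.array([38.1, 36.9, 40.2, 37.5, 39.0]),
        np.array([29.5, 30.8, 28.1, 31.0, 30.2]),
    ]
    f, p = one_way_anova(groups)
    # frozen from independent sums-of-squares computation
    assert f == pytest.approx(38.512160, rel=1e-6)
    assert p == pytest.approx(5.998401e-06, rel=1e-4)
    f_ref, p_ref = brute_anova(groups)
    assert f == pytest.approx(f_ref, rel=1e-9)
    assert p == pytest.approx(p_ref, rel=1e-9)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_anova_matches_independent_implementation_on_random_fixtures(seed):
    rng = np.random.default_rng(seed)
    k = rng.integers(2, 5)
    groups = [rng.normal(rng.uniform(-1, 1), 1.0, rng.integers(3, 20)) for _ in range(k)]
    f, p = one_way_anova(groups)
    f_ref, p_ref = brute_anova(groups)
    assert f == pytest.approx(f_ref, rel=1e-9, abs=1e-12)
    assert p == pytest.approx(p_ref, rel=1e-9, abs=1e-12)


def test_anova_degenerate_conventions():
    same = [np.full(5, 3.0), np.full(4, 3.0), np.full(6, 3.0)]
    assert one_way_anova(same) == (0.0, 1.0)
    split = [np.full(5, 1.0), np.full(5, 2.0)]
    f, p = one_way_anova(split)
    assert np.isinf(f) and p == 0.0
    with pytest.raises(ValueError):
        one_way_anova([np.array([1.0]), np.array([1.0, 2.0])])


def test_bonferroni_multiplies_by_number_of_pairs_and_caps():
    rng = np.random.default_rng(0)
    samples = {
        "a": rng.normal(0, 1, 10),
        "b": rng.normal(0.2, 1, 10),
        "c": rng.normal(3, 1, 10),
    }
    table = bonferroni_pairwise(samples)
    assert len(table) == 3
    assert np.all(table["p_bonferroni"] <= 1.0)
    expected = np.minimum(1.0, table["p_raw"] * 3)
    assert np.allclose(table["p_bonferroni"], expected)

    two = bonferroni_pairwise({"a": samples["a"], "b": samples["b"]})
    assert len(two) == 1
    assert two["p_bonferroni"][0] == pytest.approx(min(1.0, two["p_raw"][0]))


def records_from_fractions(u):
    """Minimal KineticRecords carrying the given unloaded fractions."""
    from fmposthoc import KineticRecords

    n = len(u)
    traces = np.ones((n, 40))
    traces[:, 30:] = (1 - np.asarray(u))[:, None]
    f0 = np.ones(n)
    return KineticRecords(traces, f0, traces.copy(), np.asarray(u, float), 10)


def test_summarize_groups_means_sems_and_overlap_counts():
    u = np.array([0.30, 0.35, 0.40, 0.45, 0.20, 0.25])
    groups = np.array(["mid", "high", "high", "high", "low", "low"])
    s = summarize_groups(records_from_fractions(u), groups)
    assert s.group_n == {"whole": 6, "high": 3, "low": 2}
    assert s.group_n["whole"] >= s.group_n["high"] + s.group_n["low"]
    assert s.unloaded_pct_mean["high"] == pytest.approx(100 * u[1:4].mean())
    expected_sem = 100 * u[1:4].std(ddof=1) / np.sqrt(3)
    assert s.unloaded_pct_sem["high"] == pytest.approx(expected_sem)
    assert not s.anova_skipped
    assert np.isfinite(s.disjoint_anova_f)
    # normalized group traces start at 1 over the baseline window
    assert s.trace_mean["whole"][:30].mean() == pytest.approx(1.0, abs=1e-9)


def test_summarize_groups_identical_values_give_null_statistics():
    u = np.full(8, 0.34)
    groups = np.array(["high", "high", "low", "low", "mid", "mid", "mid", "mid"])
    s = summarize_groups(records_from_fractions(u), groups)
    assert s.anova_f == 0.0 and s.anova_p == 1.0
    assert not s.pairwise["significant"].any()


def test_summarize_groups_skips_anova_when_a_group_is_too_small():
    u = np.linspace(0.2, 0.5, 6)
    groups = np.array(["mid"] * 5 + ["high"])
    with pytest.warns(UserWarning, match="ANOVA skipped"):
        s = summarize_groups(records_from_fractions(u), groups)
    assert s.anova_skipped
    assert np.isnan(s.anova_p)
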