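import numpy as np
import pytest

from fmposthoc import (
    SimulationConfig,
    nominal_unloaded_fraction,
    sample_bouton_population,
    simulate_experiment,
)


def test_same_seed_gives_bit_identical_experiments():
    config = SimulationConfig(seed=1, n_boutons=30)
    s1, a1, b1, t1 = simulate_experiment(config)
    s2, a2, b2, t2 = simulate_experiment(config)
    assert np.array_equal(s1.frames, s2.frames)
    assert np.array_equal(a1.pixels, a2.pixels)
    assert np.array_equal(b1.pixels, b2.pixels)
    assert np.array_equal(t1.unload_fraction, t2.unload_fraction)


def test_different_seeds_differ():
    s1 = simulate_experiment(SimulationConfig(seed=1, n_boutons=10))[0]
    s2 = simulate_experiment(SimulationConfig(seed=2, n_boutons=10))[0]
    assert not np.array_equal(s1.frames, s2.frames)


def test_null_slope_and_zero_noise_make_marker_levels_equal():
    config = SimulationConfig(
        seed=3, n_boutons=15, marker_slope=0.0, marker_noise_cv=0.0, marker_log_sd=0.0
    )
    rng = np.random.default_rng(0)
    pop = sample_bouton_population(config, rng)
    assert np.all(pop.marker_a_amplitude == pop.marker_a_amplitude[0])
    # integrated levels additionally carry the (tiny) subpixel sampling factor
    _, _, _, truth = simulate_experiment(config)
    assert np.allclose(truth.marker_a_level, truth.marker_a_level.mean(), rtol=1e-3)


def test_trace_plateau_matches_formula_limit():
    # noise/bleach/background off, u = 0.4, tau = 3: late plateau = 0.6 * baseline
    config = SimulationConfig(
        seed=4,
        n_boutons=8,
        noise_model="none",
        background_level=0.0,
        background_gradient=0.0,
        bleach_rate_per_frame=0.0,
        unload_mean=0.4,
        unload_sd=0.0,
        unload_tau_frames=3.0,
    )
    stack, _, _, _ = simulate_experiment(config)
    baseline_total = stack.frames[:30].mean(axis=0).sum()
    assert stack.frames[-1].sum() == pytest.approx(0.6 * baseline_total, rel=1e-9)


def test_truth_marker_levels_equal_rendered_integrated_intensity(clean_experiment):
    config, (stack, cha, chb, truth) = clean_experiment
    w = int(np.ceil(4 * config.psf_sigma_px))
    for img, levels in ((cha.pixels, truth.marker_a_level), (chb.pixels, truth.marker_b_level)):
        for i in range(truth.n_boutons):
            r, c = int(round(truth.center_row[i])), int(round(truth.center_col[i]))
            rendered = img[r - w : r + w + 1, c - w : c + w + 1].sum()
            assert rendered == pytest.approx(levels[i], rel=1e-6)


def test_functional_and_marker_centroids_coincide_without_shift(clean_experiment):
    config, (stack, cha, _, truth) = clean_experiment
    fm = stack.baseline_mean_image()
    w = int(np.ceil(4 * config.psf_sigma_px))
    for i in range(truth.n_boutons):
        r, c = int(round(truth.center_row[i])), int(round(truth.center_col[i]))
        win = (slice(r - w, r + w + 1), slice(c - w, c + w + 1))
        for img in (fm, cha.pixels):
            patch = img[win]
            yy, xx = np.mgrid[win]
            cr = (patch * yy).sum() / patch.sum()
            cc = (patch * xx).sum() / patch.sum()
            assert abs(cr - truth.center_row[i]) < 0.1
            assert abs(cc - truth.center_col[i]) < 0.1


def test_boutons_respect_margin_and_separation(default_experiment):
    config, (_, _, _, truth) = default_experiment
    sigma = config.psf_sigma_px
    pts = np.stack([truth.center_row, truth.center_col], axis=1)
    assert pts.min() >= 2 * sigma
    assert (np.array(config.image_shape) - pts.max(axis=0)).min() >= 2 * sigma
    d2 = ((pts[:, None] - pts[None]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    assert np.sqrt(d2.min()) >= 4 * sigma


def test_infeasible_placement_raises():
    with pytest.raises((RuntimeError, ValueError)):
        simulate_experiment(SimulationConfig(seed=0, n_boutons=500, image_shape=(64, 64)))


def test_nominal_unloaded_fraction_limits():
    assert nominal_unloaded_fraction(0.0, 4.0, 30, 100, 10) == 0.0
    # instantaneous destaining: the tail plateau is exactly 1 - u
    assert nominal_unloaded_fraction(0.4, 1e-9, 30, 100, 10) == pytest.approx(0.4, abs=1e-12)


def test_nominal_unloaded_fraction_matches_direct_trace_average():
    # frozen independent evaluation: average the closed-form trace by hand
    u, tau, ts, end, tail = 0.4, 5.0, 30, 90, 10
    t = np.arange(end)
    trace = np.where(t < ts, 1.0, (1 - u) + u * np.exp(-(np.maximum(t - ts, 0)) / tau))
    expected = (1.0 - trace[-tail:].mean()) / 1.0
    assert nominal_unloaded_fraction(u, tau, ts, end, tail) == pytest.approx(expected, rel=1e-12)


def test_population_mean_nominal_fraction_increases_with_unload_mean():
    rng = np.random.default_rng(9)
    means = []
    for unload_mean in (0.2, 0.34, 0.5):
        config = SimulationConfig(seed=0, n_boutons=200, unload_mean=unload_mean)
        pop = sample_bouton_population(config, rng)
        means.append(
            np.mean(
                [
                    nominal_unloaded_fraction(u, config.unload_tau_frames, 30, 100, 10)
                    for u in pop.unload_fraction
                ]
            )
        )
    assert means[0] < means[1] < means[2]


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(unload_mean=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(noise_model="salt")
    with pytest.raises(ValueError):
        SimulationConfig(min_separation_sigma=2.0)
    with pytest.raises(ValueError):
        SimulationConfig(n_frames=20)
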