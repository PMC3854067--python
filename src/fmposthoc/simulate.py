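r"""Synthetic FM1-43 experiments with exported ground truth.

The generator emulates the acquisition protocol this package analyses: a
1 Hz destaining movie (30 baseline frames, a 10-frame high-K+ stimulation,
then a post-stimulus plateau) of diffraction-limited boutons, followed by
one or two post-hoc immunofluorescence channels of the same field acquired
with a small, purely translational offset.

Model, per bouton *i* with baseline peak brightness :math:`B_i` and planted
unloading fraction :math:`u_i`:

.. math::

    F_i(t) = B_i\,b(t) \quad (t < t_{stim}), \qquad
    F_i(t) = B_i\,b(t)\,[(1-u_i) + u_i e^{-(t-t_{stim})/\tau}]
    \quad (t \ge t_{stim}),

with multiplicative photobleaching :math:`b(t) = (1-\beta)^t`.  Marker-A
integrated spot intensity is linear in :math:`u_i` (slope 0 plants a null,
Munc13-1-like experiment; positive slope a RIM1α-like one); marker-B is
marker-A times lognormal noise, so normalized B-vs-A has unit slope — the
two-channel linearity control.  Each image gets a background plane (level +
linear gradient) and photon (Poisson) or Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AcquisitionTiming, ChannelImage, TimeLapseStack

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "BoutonPopulation",
    "sample_bouton_population",
    "simulate_experiment",
    "nominal_unloaded_fraction",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic destaining + post-hoc ICC experiment.

    Population defaults echo the printed statistics of the protocol this
    package models: mean unloading fraction 0.34 with bouton-to-bouton
    spread 0.18 (truncated to (0, 1)), and a broad lognormal marker-level
    distribution (sigma 0.6) so that a realistic minority of boutons sits
    beyond the 2x / 0.5x normalized-immunoreactivity thresholds.  The image
    scale defaults to 256x256 with 100 boutons so simulations run in
    seconds; camera-scale fields are just larger configs.
    """

    n_boutons: int = 100
    image_shape: tuple[int, int] = (256, 256)
    psf_sigma_px: float = 1.5
    # lognormal baseline peak brightness (14-bit camera scale)
    brightness_log_mean: float = math.log(2000.0)
    brightness_log_sd: float = 0.4
    # per-bouton unloading fraction, truncated normal on (0, 1)
    unload_mean: float = 0.34
    unload_sd: float = 0.18
    unload_tau_frames: float = 4.0
    # marker model
    marker_slope: float = 1.0
    marker_log_sd: float = 0.6
    marker_noise_cv: float = 0.2
    marker_base_amplitude: float = 1500.0
    # field geometry
    channel_shift_px: tuple[int, int] = (5, -3)
    min_separation_sigma: float = 4.0  # pairwise center separation, in psf sigmas
    # background + noise
    background_level: float = 100.0
    background_gradient: float = 20.0
    noise_model: str = "poisson"  # "poisson" | "gaussian" | "none"
    gaussian_noise_sd: float = 10.0
    bleach_rate_per_frame: float = 0.0005
    # acquisition timing
    n_frames: int = 100
    timing: AcquisitionTiming = field(default_factory=AcquisitionTiming)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boutons < 0:
            raise ValueError("n_boutons must be >= 0")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if not 0 < self.unload_mean < 1:
            raise ValueError("unload_mean must lie in (0, 1)")
        if self.unload_sd < 0 or self.marker_noise_cv < 0 or self.marker_slope < 0:
            raise ValueError("unload_sd, marker_noise_cv and marker_slope must be >= 0")
        if self.unload_tau_frames <= 0:
            raise ValueError("unload_tau_frames must be positive")
        if not 0 <= self.bleach_rate_per_frame < 1:
            raise ValueError("bleach_rate_per_frame must lie in [0, 1)")
        if self.min_separation_sigma < 4.0:
            raise ValueError("min_separation_sigma must be >= 4 (no ground-truth merging)")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError("noise_model must be 'poisson', 'gaussian' or 'none'")
        needed = self.timing.stim_start_frame + self.timing.stim_duration_frames + 1
        if self.n_frames < needed:
            raise ValueError(f"n_frames must be >= {needed}")


@dataclass
class SimulationTruth:
    """Planted per-bouton ground truth of a simulated experiment."""

    center_row: np.ndarray
    center_col: np.ndarray
    baseline_brightness: np.ndarray
    unload_fraction: np.ndarray
    marker_a_level: np.ndarray
    marker_b_level: np.ndarray
    channel_shift_px: tuple[int, int]

    @property
    def n_boutons(self) -> int:
        return len(self.unload_fraction)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bouton_id": np.arange(1, self.n_boutons + 1),
                "center_row": self.center_row,
                "center_col": self.center_col,
                "baseline_brightness": self.baseline_brightness,
                "unload_fraction": self.unload_fraction,
                "marker_a_level": self.marker_a_level,
                "marker_b_level": self.marker_b_level,
            }
        )


@dataclass
class BoutonPopulation:
    """Sampled per-bouton parameters, before any rendering."""

    brightness: np.ndarray
    unload_fraction: np.ndarray
    marker_a_amplitude: np.ndarray
    marker_b_amplitude: np.ndarray


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) truncated to the open interval (0, 1) by resampling."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, n)
    bad = (out <= 0) | (out >= 1)
    tries = 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out <= 0) | (out >= 1)
        tries += 1
        if tries > 1000:
            raise RuntimeError("truncated-normal resampling failed to converge")
    return out


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Lognormal multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(n)
    s = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * s * s, s, n)


def sample_bouton_population(config: SimulationConfig, rng: np.random.Generator) -> BoutonPopulation:
    """Draw the per-bouton brightness, unloading and marker amplitudes.

    Marker-A amplitude is ``base * lognormal(marker_log_sd)`` times the
    planted linear coupling ``1 + marker_slope * (u_i - unload_mean)``
    (floored at 1% of base to keep amplitudes positive for extreme slopes)
    times lognormal measurement noise of the configured CV; marker-B is
    marker-A times another lognormal noise draw.
    """
    n = config.n_boutons
    brightness = rng.lognormal(config.brightness_log_mean, config.brightness_log_sd, n)
    u = _truncated_normal(rng, config.unload_mean, config.unload_sd, n)
    base = config.marker_base_amplitude * (
        rng.lognormal(0.0, config.marker_log_sd, n) if config.marker_log_sd > 0 else np.ones(n)
    )
    coupling = np.maximum(1.0 + config.marker_slope * (u - config.unload_mean), 0.01)
    marker_a = base * coupling * _lognormal_unit_mean(rng, config.marker_noise_cv, n)
    marker_b = marker_a * _lognormal_unit_mean(rng, config.marker_noise_cv, n)
    return BoutonPopulation(brightness, u, marker_a, marker_b)


def _place_boutons(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample bouton centers.

    Centers keep a margin of ``ceil(4*sigma) + max|channel shift| + 1`` from
    every border (so the rendered spot window is never clipped, in the
    functional or the shifted post-hoc images) and a pairwise separation of
    at least ``min_separation_sigma * sigma`` (>= 4 sigma, so spots never
    merge at ground-truth level).
    """
    rows, cols = config.image_shape
    margin = math.ceil(4 * config.psf_sigma_px) + max(
        abs(config.channel_shift_px[0]), abs(config.channel_shift_px[1])
    ) + 1
    min_sep = config.min_separation_sigma * config.psf_sigma_px
    if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
        raise ValueError("image_shape too small for the PSF margin")
    rr = np.empty(config.n_boutons)
    cc = np.empty(config.n_boutons)
    placed = 0
    attempts = 0
    max_attempts = 2000 * max(config.n_boutons, 1)
    while placed < config.n_boutons:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {config.n_boutons} boutons with separation "
                f">= {min_sep:.1f}px in a {rows}x{cols} field"
            )
        attempts += 1
        r = rng.uniform(margin, rows - margin)
        c = rng.uniform(margin, cols - margin)
        if placed:
            d2 = (rr[:placed] - r) ** 2 + (cc[:placed] - c) ** 2
            if d2.min() < min_sep * min_sep:
                continue
        rr[placed], cc[placed] = r, c
        placed += 1
    return rr, cc


def _spot_patches(
    rr: np.ndarray, cc: np.ndarray, sigma: float
) -> list[tuple[slice, slice, np.ndarray]]:
    """Per-bouton Gaussian kernel evaluated on its ±4σ pixel window."""
    w = math.ceil(4 * sigma)
    patches = []
    for r, c in zip(rr, cc):
        r0, c0 = int(round(r)) - w, int(round(c)) - w
        yy = np.arange(r0, r0 + 2 * w + 1)
        xx = np.arange(c0, c0 + 2 * w + 1)
        ky = np.exp(-((yy - r) ** 2) / (2 * sigma * sigma))
        kx = np.exp(-((xx - c) ** 2) / (2 * sigma * sigma))
        patches.append((slice(r0, r0 + 2 * w + 1), slice(c0, c0 + 2 * w + 1), np.outer(ky, kx)))
    return patches


def _background_plane(config: SimulationConfig) -> np.ndarray:
    rows, cols = config.image_shape
    ramp_r = np.linspace(0.0, 1.0, rows)[:, None]
    ramp_c = np.linspace(0.0, 1.0, cols)[None, :]
    return config.background_level + config.background_gradient * 0.5 * (ramp_r + ramp_c)


def _add_noise(image: np.ndarray, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise_model == "poisson":
        return rng.poisson(np.maximum(image, 0.0)).astype(np.float64)
    if config.noise_model == "gaussian":
        return np.maximum(image + rng.normal(0.0, config.gaussian_noise_sd, image.shape), 0.0)
    return image


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[TimeLapseStack, ChannelImage, ChannelImage, SimulationTruth]:
    """Render a complete synthetic experiment.

    Returns the destaining movie, the two post-hoc marker channels
    (translated by ``channel_shift_px``), and the planted ground truth.
    ``SimulationTruth`` marker levels are the exact noise-free integrated
    intensities of the rendered spots (background and pixel noise excluded).
    Identical seeds produce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    rr, cc = _place_boutons(config, rng)
    pop = sample_bouton_population(config, rng)

    timing = config.timing
    t = np.arange(config.n_frames, dtype=np.float64)
    bleach = (1.0 - config.bleach_rate_per_frame) ** t
    # temporal profile per bouton: (n_boutons, n_frames)
    decay = np.ones((config.n_boutons, config.n_frames))
    post = t >= timing.stim_start_frame
    u = pop.unload_fraction[:, None]
    decay[:, post] = (1.0 - u) + u * np.exp(
        -(t[post] - timing.stim_start_frame) / config.unload_tau_frames
    )
    temporal = pop.brightness[:, None] * bleach[None, :] * decay

    patches = _spot_patches(rr, cc, config.psf_sigma_px)
    bg = _background_plane(config)
    frames = np.repeat(bg[None, :, :], config.n_frames, axis=0)
    for i, (sr, sc, kern) in enumerate(patches):
        frames[:, sr, sc] += temporal[i][:, None, None] * kern[None, :, :]
    frames = _add_noise(frames, config, rng)
    stack = TimeLapseStack(frames, timing)

    dr, dc = config.channel_shift_px
    kernel_sum = np.array([kern.sum() for _, _, kern in patches]) if patches else np.empty(0)
    channels = []
    for name, amp in (("marker_a", pop.marker_a_amplitude), ("marker_b", pop.marker_b_amplitude)):
        img = bg.copy()
        for i, (sr, sc, kern) in enumerate(patches):
            sr2 = slice(sr.start + dr, sr.stop + dr)
            sc2 = slice(sc.start + dc, sc.stop + dc)
            img[sr2, sc2] += amp[i] * kern
        img = _add_noise(img, config, rng)
        channels.append(ChannelImage(img, channel_name=name))

    truth = SimulationTruth(
        center_row=rr,
        center_col=cc,
        baseline_brightness=pop.brightness,
        unload_fraction=pop.unload_fraction,
        marker_a_level=pop.marker_a_amplitude * kernel_sum,
        marker_b_level=pop.marker_b_amplitude * kernel_sum,
        channel_shift_px=(dr, dc),
    )
    return stack, channels[0], channels[1], truth


def nominal_unloaded_fraction(
    u: float,
    tau_frames: float,
    stim_start: int,
    trace_end: int,
    tail_window: int,
    n_baseline_frames: int | None = None,
    bleach_rate_per_frame: float = 0.0,
) -> float:
    """Closed-form unloaded fraction of a noise-free simulated trace.

    Evaluates the trace model on frames ``0 .. trace_end-1``, averages the
    first ``n_baseline_frames`` (default: all pre-stimulus frames) for F0
    and the last ``tail_window`` frames for the plateau, and returns
    ``(F0 - tail) / F0`` — exactly what the kinetics stage reports on such a
    trace.  Serves as the analytic oracle for kinetic tests.
    """
    if n_baseline_frames is None:
        n_baseline_frames = stim_start
    t = np.arange(trace_end, dtype=np.float64)
    trace = (1.0 - bleach_rate_per_frame) ** t
    post = t >= stim_start
    trace[post] *= (1.0 - u) + u * np.exp(-(t[post] - stim_start) / tau_frames)
    f0 = trace[:n_baseline_frames].mean()
    tail = trace[trace_end - tail_window :].mean()
    return float((f0 - tail) / f0)
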