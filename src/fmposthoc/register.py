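"""Translation-only registration of post-hoc channels to the FM reference.

The functional (FM) field and the post-hoc immunofluorescence images of the
same field are related by a small translation left over after manual
re-positioning at the microscope.  Registration is integer-pixel and
translation-only: the shift maximizing the normalized cross-correlation
(Pearson correlation over the overlap region) across all integer
displacements within a search window.  The module also provides the
two-channel linearity control: per-ROI normalized intensities of two
co-acquired markers should fall on a line of slope close to 1 with strong
correlation when acquisition and alignment are sound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .io import ChannelImage

__all__ = [
    "AlignmentTransform",
    "LinearityReport",
    "estimate_shift",
    "apply_shift",
    "linearity_qc",
]


@dataclass(frozen=True)
class AlignmentTransform:
    """An estimated integer translation of a moving image vs the reference.

    ``shift_px`` is the (row, col) displacement such that
    ``moving[p] ≈ reference[p - shift]``; applying the transform moves the
    image by ``-shift`` back onto reference coordinates.
    ``low_confidence`` flags a peak correlation below the configured floor
    (e.g. when the true shift exceeds the search window).
    """

    shift_px: tuple[int, int]
    peak_correlation: float
    channel_name: str = "channel"
    low_confidence: bool = False


def _overlap_sums(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross-correlation sums over every displacement, via FFT.

    Returns the full correlation surface ``S[d] = sum_p b[p] * a[p - d]``
    indexed so that displacement d maps to ``S[d + (R-1, C-1)]``.
    """
    return signal.fftconvolve(b, a[::-1, ::-1], mode="full")


def estimate_shift(
    reference: np.ndarray,
    moving: np.ndarray,
    max_shift_px: int = 20,
    min_correlation: float = 0.2,
    channel_name: str = "channel",
) -> AlignmentTransform:
    """Estimate the integer translation of ``moving`` relative to ``reference``.

    Exhaustively evaluates the Pearson correlation over the overlap region
    for every integer displacement within ``±max_shift_px`` (computed in
    closed form from FFT-based sliding sums, identical to the brute-force
    search).  Ties are broken by smaller displacement magnitude, then
    smaller row, then smaller col.  A peak correlation below
    ``min_correlation`` raises a warning and flags the transform.
    """
    reference = np.asarray(reference, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving must share a shape")
    if reference.ndim != 2:
        raise ValueError("images must be 2-D")
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        raise ValueError("cannot register a constant (zero-variance) image")
    rows, cols = reference.shape
    k = int(max_shift_px)
    if k < 0 or k >= rows or k >= cols:
        raise ValueError("max_shift_px must be in [0, min(image shape))")

    ones = np.ones_like(reference)
    n = _overlap_sums(ones, ones)
    s_r = _overlap_sums(reference, ones)
    s_m = _overlap_sums(ones, moving)
    s_rr = _overlap_sums(reference * reference, ones)
    s_mm = _overlap_sums(ones, moving * moving)
    s_rm = _overlap_sums(reference, moving)

    c0, c1 = rows - 1, cols - 1  # index of displacement (0, 0)
    win = (slice(c0 - k, c0 + k + 1), slice(c1 - k, c1 + k + 1))
    n_w = np.maximum(n[win], 1.0)
    cov = s_rm[win] - s_r[win] * s_m[win] / n_w
    var_r = np.maximum(s_rr[win] - s_r[win] ** 2 / n_w, 0.0)
    var_m = np.maximum(s_mm[win] - s_m[win] ** 2 / n_w, 0.0)
    denom = np.sqrt(var_r * var_m)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(denom > 0, cov / np.maximum(denom, 1e-300), -np.inf)

    best = ncc.max()
    cand = np.argwhere(ncc >= best - 1e-9)
    shifts = cand - k  # displacement (row, col)
    order = np.lexsort(
        (shifts[:, 1], shifts[:, 0], shifts[:, 0] ** 2 + shifts[:, 1] ** 2)
    )
    dr, dc = (int(v) for v in shifts[order[0]])
    peak = float(np.clip(ncc[cand[order[0]][0], cand[order[0]][1]], -1.0, 1.0))
    low = peak < min_correlation
    if low:
        warnings.warn(
            f"peak correlation {peak:.3f} below floor {min_correlation} "
            f"for channel {channel_name!r}; alignment may be unreliable",
            stacklevel=2,
        )
    return AlignmentTransform(
        shift_px=(dr, dc), peak_correlation=peak, channel_name=channel_name, low_confidence=low
    )


def apply_shift(image: ChannelImage, transform: AlignmentTransform) -> ChannelImage:
    """Translate a channel image by ``-shift`` onto reference coordinates.

    Output pixel p takes the value of source pixel ``p + shift``; border
    pixels with no source are zeroed and marked invalid in ``valid_mask``
    (no extrapolation).
    """
    dr, dc = transform.shift_px
    src = image.pixels
    rows, cols = src.shape
    out = np.zeros_like(src)
    valid = np.zeros(src.shape, dtype=bool)
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = src[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid[r0:r1, c0:c1] = image.valid_mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return ChannelImage(out, channel_name=image.channel_name, valid_mask=valid)


@dataclass(frozen=True)
class LinearityReport:
    """Two-channel linearity control on per-ROI normalized intensities."""

    slope: float
    intercept: float
    pearson_r: float
    n: int
    passed: bool


def linearity_qc(
    ir_a: np.ndarray,
    ir_b: np.ndarray,
    min_r: float = 0.5,
    slope_band: tuple[float, float] = (0.5, 1.5),
) -> LinearityReport:
    """Regress channel B on channel A and judge experiment validity.

    A slope close to 1 with a strong positive correlation indicates sound
    double labelling and alignment; the default acceptance band is
    deliberately loose and configurable.
    """
    a = np.asarray(ir_a, dtype=np.float64)
    b = np.asarray(ir_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ir_a and ir_b must be equal-length 1-D vectors")
    if a.size < 3:
        raise ValueError("linearity QC needs at least 3 ROIs")
    if np.ptp(a) == 0:
        raise ValueError("channel A has zero variance")
    fit = stats.linregress(a, b)
    passed = (slope_band[0] <= fit.slope <= slope_band[1]) and fit.rvalue >= min_r
    return LinearityReport(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        n=int(a.size),
        passed=bool(passed),
    )
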