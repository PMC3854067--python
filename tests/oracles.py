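"""Independent brute-force oracles used by the test suite.

Each function implements the *definition* of an operation directly, without
touching the library's own code paths, so agreement between the two routes
is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np


def brute_rolling_ball(image: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background by direct grayscale opening.

    Erosion then dilation with the ball height profile, replicated ("edge")
    boundary handling, each computed as an explicit min/max over structuring
    element offsets.
    """
    image = np.asarray(image, dtype=np.float64)
    r = int(np.floor(radius))
    offsets = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            d2 = dy * dy + dx * dx
            if d2 <= radius * radius:
                offsets.append((dy, dx, np.sqrt(radius * radius - d2)))
    padded = np.pad(image, r, mode="edge")
    rows, cols = image.shape
    eroded = np.full_like(image, np.inf)
    for dy, dx, h in offsets:
        eroded = np.minimum(eroded, padded[r + dy : r + dy + rows, r + dx : r + dx + cols] - h)
    padded_e = np.pad(eroded, r, mode="edge")
    dilated = np.full_like(image, -np.inf)
    for dy, dx, h in offsets:
        dilated = np.maximum(dilated, padded_e[r - dy : r - dy + rows, r - dx : r - dx + cols] + h)
    return dilated


def brute_ncc_shift(
    reference: np.ndarray, moving: np.ndarray, max_shift: int
) -> tuple[tuple[int, int], float]:
    """Exhaustive normalized cross-correlation over integer displacements.

    Returns the displacement maximizing the Pearson correlation between
    ``moving[p]`` and ``reference[p - d]`` over the overlap region, with
    ties broken by smaller magnitude, then row, then col.
    """
    rows, cols = reference.shape
    best = None
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            r0, r1 = max(0, dr), min(rows, rows + dr)
            c0, c1 = max(0, dc), min(cols, cols + dc)
            m = moving[r0:r1, c0:c1]
            f = reference[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
            if m.size < 2 or m.std() == 0 or f.std() == 0:
                continue
            cc = np.corrcoef(m.ravel(), f.ravel())[0, 1]
            key = (-cc, dr * dr + dc * dc, dr, dc)
            if best is None or key < best[0]:
                best = (key, (dr, dc), cc)
    return best[1], best[2]


def brute_integrated_density(image: np.ndarray, labels: np.ndarray, n_rois: int) -> np.ndarray:
    """Per-ROI pixel sums by an explicit per-pixel loop."""
    sums = np.zeros(n_rois)
    for r in range(labels.shape[0]):
        for c in range(labels.shape[1]):
            k = labels[r, c]
            if k > 0:
                sums[k - 1] += image[r, c]
    return sums


def brute_roi_traces(frames: np.ndarray, labels: np.ndarray, n_rois: int) -> np.ndarray:
    """Per-ROI mean-intensity traces by explicit pixel-set averaging."""
    traces = np.empty((n_rois, frames.shape[0]))
    for k in range(1, n_rois + 1):
        mask = labels == k
        traces[k - 1] = frames[:, mask].mean(axis=1)
    return traces


def brute_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA via scipy's independent implementation."""
    from scipy import stats

    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
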