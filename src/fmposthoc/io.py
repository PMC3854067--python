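"""Image and table I/O for the destaining/immunofluorescence pipeline.

Conventions shared by every module:

* 0-based indices, ``(row, col)`` axis order, pixel centers at integer
  coordinates.
* TIFF pixel data may be 8/16-bit integer or floating point on disk; it is
  promoted to ``float64`` exactly once, at read time.  The camera bit depth
  (14 bits in the acquisition protocol this package models) is carried as
  metadata only — no clipping is ever applied.
* Acquisition timing (baseline window, stimulation window, frame rate) is
  always explicit metadata, never inferred from pixel content.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AcquisitionTiming",
    "TimeLapseStack",
    "ChannelImage",
    "read_stack",
    "write_stack",
    "read_channel",
    "write_channel",
    "read_label_mask",
    "write_label_mask",
    "write_results",
]


@dataclass(frozen=True)
class AcquisitionTiming:
    """Timing metadata of an FM destaining recording.

    Defaults follow the acquisition protocol modelled here: 1 frame/s,
    a 30-frame baseline, then a 10 s high-K+ stimulation.
    """

    n_baseline_frames: int = 30
    stim_start_frame: int = 30
    stim_duration_frames: int = 10
    frame_rate_hz: float = 1.0
    bit_depth: int = 14

    def __post_init__(self) -> None:
        if self.n_baseline_frames <= 0:
            raise ValueError("n_baseline_frames must be positive")
        if self.stim_duration_frames <= 0:
            raise ValueError("stim_duration_frames must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.stim_start_frame < self.n_baseline_frames:
            raise ValueError(
                "stim_start_frame must be >= n_baseline_frames "
                f"({self.stim_start_frame} < {self.n_baseline_frames})"
            )


@dataclass
class TimeLapseStack:
    """An FM1-43 destaining movie plus its acquisition timing.

    ``frames`` has shape ``(time, rows, cols)`` and is floating point;
    intensities are non-negative and, for integer source data, below
    ``2**bit_depth``.
    """

    frames: np.ndarray
    timing: AcquisitionTiming = field(default_factory=AcquisitionTiming)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (time, rows, cols), got shape {frames.shape}")
        if np.issubdtype(frames.dtype, np.integer):
            if frames.size and frames.max() >= 2 ** self.timing.bit_depth:
                raise ValueError(
                    f"integer intensities must be < 2**{self.timing.bit_depth}"
                )
        frames = frames.astype(np.float64, copy=False)
        if frames.size and frames.min() < 0:
            raise ValueError("intensities must be non-negative")
        needed = self.timing.stim_start_frame + self.timing.stim_duration_frames + 1
        if frames.shape[0] < needed:
            raise ValueError(
                f"stack has {frames.shape[0]} frames; needs at least "
                f"stim_start_frame + stim_duration_frames + 1 = {needed}"
            )
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def baseline_frames(self) -> np.ndarray:
        """View of the pre-stimulus baseline frames."""
        return self.frames[: self.timing.n_baseline_frames]

    def baseline_mean_image(self) -> np.ndarray:
        """Time-average of the baseline frames (the registration reference)."""
        return self.baseline_frames().mean(axis=0)


@dataclass
class ChannelImage:
    """A single post-hoc immunofluorescence channel.

    ``valid_mask`` marks pixels whose value is defined; it is all-true on a
    freshly read image and acquires false borders after translation.
    """

    pixels: np.ndarray
    channel_name: str = "channel"
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=np.float64)
        if pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {pixels.shape}")
        self.pixels = pixels
        if self.valid_mask is None:
            self.valid_mask = np.ones(pixels.shape, dtype=bool)
        else:
            mask = np.asarray(self.valid_mask, dtype=bool)
            if mask.shape != pixels.shape:
                raise ValueError("pixels and valid_mask must share a shape")
            self.valid_mask = mask


def _best_tiff_dtype(data: np.ndarray) -> np.ndarray:
    """Store integral data that fits as uint16, everything else as float32."""
    if np.issubdtype(data.dtype, np.integer):
        if data.size == 0 or (data.min() >= 0 and data.max() < 2 ** 16):
            return data.astype(np.uint16)
        return data.astype(np.float32)
    if data.size and np.all(data == np.round(data)) and data.min() >= 0 and data.max() < 2 ** 16:
        return data.astype(np.uint16)
    return data.astype(np.float32)


def write_stack(stack: TimeLapseStack, path: str | Path) -> Path:
    """Write a time-lapse as a multi-frame grayscale TIFF.

    16-bit integer data round-trips bit exactly; other data is stored as
    float32.
    """
    path = Path(path)
    tifffile.imwrite(path, _best_tiff_dtype(stack.frames))
    return path


def read_stack(path: str | Path, timing: AcquisitionTiming | None = None) -> TimeLapseStack:
    """Read a multi-frame grayscale TIFF destaining movie.

    Timing metadata is supplied by the caller — TIFFs carry none that we
    trust — and validated against the frame count.
    """
    frames = _read_grayscale(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"{path}: expected a multi-frame grayscale TIFF, got array of shape {frames.shape}"
        )
    return TimeLapseStack(frames, timing or AcquisitionTiming())


def _read_grayscale(path: str | Path) -> np.ndarray:
    """Read TIFF pixel data, rejecting RGB/multi-sample files."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        if "S" in series.axes or "C" in series.axes:
            raise ValueError(
                f"{path}: RGB/multi-sample TIFFs are not supported; "
                "provide grayscale single-channel data"
            )
        return series.asarray()


def write_channel(image: ChannelImage | np.ndarray, path: str | Path) -> Path:
    """Write a single-frame grayscale TIFF."""
    pixels = image.pixels if isinstance(image, ChannelImage) else np.asarray(image)
    path = Path(path)
    tifffile.imwrite(path, _best_tiff_dtype(pixels))
    return path


def read_channel(path: str | Path, channel_name: str = "channel") -> ChannelImage:
    """Read a single-frame grayscale TIFF as a :class:`ChannelImage`."""
    pixels = _read_grayscale(path)
    if pixels.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-frame grayscale TIFF, got array of shape {pixels.shape}"
        )
    return ChannelImage(pixels, channel_name=channel_name)


def write_label_mask(label_image: np.ndarray, path: str | Path) -> Path:
    """Write an ROI label mask (0 = background, k = ROI k) as 16-bit TIFF."""
    label_image = np.asarray(label_image)
    if label_image.size and (label_image.min() < 0 or label_image.max() >= 2 ** 16):
        raise ValueError("label values must fit in uint16")
    path = Path(path)
    tifffile.imwrite(path, label_image.astype(np.uint16))
    return path


def read_label_mask(path: str | Path) -> np.ndarray:
    """Read an ROI label mask written by :func:`write_label_mask`."""
    labels = tifffile.imread(Path(path))
    if labels.ndim != 2:
        raise ValueError("label mask must be a single-frame image")
    return labels.astype(np.int32)


class _JsonEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102 - stdlib hook
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def write_results(
    tables: dict[str, "pd.DataFrame | dict"],
    out_dir: str | Path,
) -> dict[str, str]:
    """Write result tables and run metadata, returning a manifest.

    DataFrames become CSV files, dicts become JSON documents; the manifest
    (name -> file path, itself also written as ``manifest.json``) lists every
    file produced.  Values round-trip at full precision (CSV floats use
    ``repr`` formatting).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for name, table in tables.items():
        if isinstance(table, pd.DataFrame):
            dest = out_dir / f"{name}.csv"
            table.to_csv(dest, index=False, float_format=None)
        elif isinstance(table, dict):
            dest = out_dir / f"{name}.json"
            dest.write_text(json.dumps(table, indent=2, cls=_JsonEncoder))
        else:
            raise TypeError(f"unsupported table type for {name!r}: {type(table)}")
        manifest[name] = str(dest)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["manifest"] = str(out_dir / "manifest.json")
    return manifest
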