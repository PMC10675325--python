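"""Color-range segmentation of stained hydrogel discs.

Each time-lapse frame is converted to a binary mask of "stained gel" pixels
by thresholding in HSV space: a pixel is gel iff its hue falls inside a
(possibly wrap-around) red window AND its saturation and value exceed
configurable floors.  The saturation floor is what separates the strongly
stained disc from the dye-tinted perfusion medium, which shares the disc's
hue but at much lower saturation.

Masks are pure functions of the frame and the gate; debris suppression
(:func:`clean_mask`) is a minimum-region-size filter, so the cleaned mask is
always a subset of the thresholded pixels.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from skimage.morphology import remove_small_objects


@dataclasses.dataclass
class FrameImage:
    """One timestamped RGB frame of the chip.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3), uint8
        8-bit RGB image data.
    time_min : float
        Acquisition time in minutes since the start of the experiment.
    source_name : str
        Originating filename, if any.
    """

    pixels: np.ndarray
    time_min: float
    source_name: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"frame must be H x W x 3 RGB, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"frame must be 8-bit per channel, got dtype {px.dtype}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("frame must have at least one pixel")
        if self.time_min < 0:
            raise ValueError(f"frame time must be >= 0, got {self.time_min}")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclasses.dataclass(frozen=True)
class ColorGate:
    """HSV acceptance window for "stained gel" pixels.

    ``hue_lo``/``hue_hi`` are in degrees in [0, 360); the window may wrap
    through 0 (the default red window [340, 20] does).  ``sat_min`` and
    ``val_min`` are floors in [0, 1].  Achromatic pixels have hue 0 by the
    hexcone convention but saturation 0, so any ``sat_min > 0`` rejects them.
    """

    hue_lo: float = 340.0
    hue_hi: float = 20.0
    sat_min: float = 0.35
    val_min: float = 0.15

    def __post_init__(self) -> None:
        for name in ("sat_min", "val_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("hue_lo", "hue_hi"):
            v = getattr(self, name)
            if not 0.0 <= v < 360.0:
                raise ValueError(f"{name} must be in [0, 360), got {v}")


@dataclasses.dataclass
class BinaryMask:
    """Binary gel mask aligned with its source frame."""

    values: np.ndarray  # bool, H x W
    time_min: float = 0.0
    source_name: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {vals.shape}")
        if vals.dtype != bool:
            uniq = np.unique(vals)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be 0/1")
            vals = vals.astype(bool)
        self.values = vals

    @property
    def pixel_count(self) -> int:
        return int(self.values.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def make_mask(frame: FrameImage, gate: ColorGate) -> BinaryMask:
    """Threshold a frame into a binary gel mask.

    A pixel is set iff its hue lies within the gate's window (with
    wraparound through 0) and its saturation and value meet the floors.
    """
    hsv = rgb2hsv(frame.pixels)
    hue = hsv[..., 0] * 360.0
    sat = hsv[..., 1]
    val = hsv[..., 2]
    if gate.hue_lo <= gate.hue_hi:
        in_hue = (hue >= gate.hue_lo) & (hue <= gate.hue_hi)
    else:  # window wraps through 0 degrees (red)
        in_hue = (hue >= gate.hue_lo) | (hue <= gate.hue_hi)
    values = in_hue & (sat >= gate.sat_min) & (val >= gate.val_min)
    return BinaryMask(values=values, time_min=frame.time_min,
                      source_name=frame.source_name)


def clean_mask(mask: BinaryMask, min_region_px: int) -> BinaryMask:
    """Remove 8-connected regions smaller than ``min_region_px`` pixels.

    Regions with at least ``min_region_px`` pixels pass through unchanged,
    so the operation is idempotent and never adds pixels.
    """
    if min_region_px < 0:
        raise ValueError(f"min_region_px must be >= 0, got {min_region_px}")
    if min_region_px <= 1:
        values = mask.values.copy()
    else:
        # remove objects with < min_region_px pixels (i.e. <= min_region_px-1)
        values = remove_small_objects(mask.values, max_size=min_region_px - 1,
                                      connectivity=2)
    return BinaryMask(values=values, time_min=mask.time_min,
                      source_name=mask.source_name)


def load_frames(manifest_path: str | Path,
                frames_dir: str | Path | None = None) -> list[FrameImage]:
    """Load a time-lapse sequence from a ``filename,time_min`` manifest CSV.

    Paths in the manifest are resolved relative to ``frames_dir`` (default:
    the manifest's own directory).  Alpha channels, if present, are dropped.
    """
    manifest_path = Path(manifest_path)
    base = Path(frames_dir) if frames_dir is not None else manifest_path.parent
    df = pd.read_csv(manifest_path)
    frames = []
    for row in df.itertuples(index=False):
        px = iio.imread(base / row.filename)
        if px.ndim == 3 and px.shape[2] == 4:
            px = px[:, :, :3]
        frames.append(FrameImage(pixels=px, time_min=float(row.time_min),
                                 source_name=str(row.filename)))
    return frames


def write_mask_png(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG (0 = background, 255 = gel)."""
    iio.imwrite(Path(path), (mask.values.astype(np.uint8) * 255))


def masks_for_frames(frames: Sequence[FrameImage], gate: ColorGate,
                     min_region_px: int = 0) -> list[BinaryMask]:
    """Threshold and clean every frame of a sequence."""
    return [clean_mask(make_mask(f, gate), min_region_px) for f in frames]
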