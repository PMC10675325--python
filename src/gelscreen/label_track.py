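"""Pixel grouping, well assignment and per-well area tracking.

Mask pixels are grouped into 8-connected regions, each region is assigned to
the chip well whose circular chamber contains its centroid (regions whose
centroid lies in the channel between wells are treated as flowing debris and
discarded), and each well's total assigned pixel area is followed through
the frame sequence as a :class:`DiscTrace`.

Fragments of a disintegrating disc inside one well are summed: the disc,
not the fragment, is the unit of interest.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .segment import BinaryMask, ColorGate, FrameImage, clean_mask, make_mask

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class Well:
    """One circular chamber: center (cy, cx) and radius, in pixels."""

    well_id: str
    cx: float
    cy: float
    r: float

    def contains(self, y: float, x: float) -> bool:
        return (y - self.cy) ** 2 + (x - self.cx) ** 2 <= self.r ** 2


@dataclasses.dataclass
class WellLayout:
    """Chip geometry: pairwise-disjoint well circles."""

    wells: list[Well]

    def __post_init__(self) -> None:
        if len(self.wells) < 1:
            raise ValueError("layout needs at least one well")
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("well ids must be unique")
        for i, a in enumerate(self.wells):
            for b in self.wells[i + 1:]:
                d = np.hypot(a.cx - b.cx, a.cy - b.cy)
                if d < a.r + b.r:
                    raise ValueError(
                        f"wells {a.well_id!r} and {b.well_id!r} overlap")

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    @property
    def well_ids(self) -> list[str]:
        return [w.well_id for w in self.wells]


@dataclasses.dataclass(frozen=True)
class Region:
    label: int
    pixel_count: int
    centroid: tuple[float, float]  # (row, col), fractional pixels
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)


@dataclasses.dataclass
class RegionLabeling:
    """Connected-component labeling of one mask (0 = background)."""

    label_map: np.ndarray
    regions: list[Region]


def label_regions(mask: BinaryMask) -> RegionLabeling:
    """Group mask pixels into 8-connected regions.

    Labels 1..K are assigned in raster-scan order of each region's first
    pixel, so the labeling is deterministic; the region list is sorted by
    label.  An empty mask yields zero regions.
    """
    lab = sk_label(mask.values, background=0, connectivity=2)
    if lab.max() == 0:
        return RegionLabeling(label_map=lab.astype(np.int32), regions=[])
    # relabel so labels follow raster-scan order of first encounter
    uniq, first_idx = np.unique(lab.ravel(), return_index=True)
    nz = uniq != 0
    old = uniq[nz][np.argsort(first_idx[nz])]
    lut = np.zeros(int(lab.max()) + 1, dtype=np.int32)
    lut[old] = np.arange(1, old.size + 1, dtype=np.int32)
    lab = lut[lab]
    regions = [
        Region(label=int(p.label), pixel_count=int(p.area),
               centroid=(float(p.centroid[0]), float(p.centroid[1])),
               bbox=tuple(int(v) for v in p.bbox))
        for p in regionprops(lab)
    ]
    regions.sort(key=lambda r: r.label)
    return RegionLabeling(label_map=lab, regions=regions)


def assign_to_wells(labeling: RegionLabeling,
                    layout: WellLayout) -> dict[str, int]:
    """Sum region areas per well by centroid containment.

    A region contributes to the well whose circle contains its centroid;
    centroids in no well (channel debris) are discarded.  Wells with no
    region get area 0.  Well circles are disjoint, so the assignment is
    unambiguous.
    """
    areas: dict[str, int] = {w.well_id: 0 for w in layout.wells}
    for region in labeling.regions:
        cy, cx = region.centroid
        for well in layout.wells:
            if well.contains(cy, cx):
                areas[well.well_id] += region.pixel_count
                break
    return areas


@dataclasses.dataclass
class DiscTrace:
    """Per-well time series of segmented disc area.

    ``area_pct`` is normalized to the first frame; ``complete_at`` is the
    first time at which the area reaches 0 and stays there, or None.
    """

    well_id: str
    times: np.ndarray  # hours, strictly increasing
    area_px: np.ndarray
    area_pct: np.ndarray
    complete_at: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.area_px = np.asarray(self.area_px, dtype=float)
        self.area_pct = np.asarray(self.area_pct, dtype=float)
        if not (len(self.times) == len(self.area_px) == len(self.area_pct)):
            raise ValueError("times/area_px/area_pct lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trace times must be strictly increasing")


def build_traces(
    samples: Sequence[tuple[float, Mapping[str, int]]],
) -> list[DiscTrace]:
    """Assemble per-well traces from (time_h, well -> pixel area) samples.

    Requires at least two frames with strictly increasing times and a
    positive initial area for every tracked well (normalization frame is
    frame 0).  A disc whose area returns above zero after reaching zero is
    flagged as an anomaly in the log and keeps ``complete_at`` unset.
    """
    if len(samples) < 2:
        raise ValueError("need at least two frames to build traces")
    times = np.array([t for t, _ in samples], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    well_ids = list(samples[0][1].keys())
    traces = []
    for wid in well_ids:
        areas = np.array([float(areas_t.get(wid, 0)) for _, areas_t in samples])
        if areas[0] <= 0:
            raise ValueError(
                f"well {wid!r} has zero initial area; cannot normalize")
        pct = 100.0 * areas / areas[0]
        complete_at = None
        zero = areas == 0
        if zero.any():
            i0 = int(np.argmax(zero))
            if zero[i0:].all():
                complete_at = float(times[i0])
            else:
                logger.warning(
                    "well %s: area recovered after reaching zero at t=%.3g h;"
                    " treating as anomaly (complete_at unset)",
                    wid, times[i0])
        traces.append(DiscTrace(well_id=wid, times=times, area_px=areas,
                                area_pct=pct, complete_at=complete_at))
    return traces


def measure_frames(frames: Sequence[FrameImage], gate: ColorGate,
                   layout: WellLayout,
                   min_region_px: int = 0) -> list[DiscTrace]:
    """Segment, label and track a whole frame sequence into disc traces."""
    samples = []
    for frame in frames:
        mask = clean_mask(make_mask(frame, gate), min_region_px)
        labeling = label_regions(mask)
        samples.append((frame.time_min / 60.0, assign_to_wells(labeling, layout)))
    return build_traces(samples)


# ---------------------------------------------------------------------------
# CSV interfaces

def read_layout(path: str | Path) -> WellLayout:
    """Read a well-layout CSV with header ``well_id,cx_px,cy_px,r_px``."""
    df = pd.read_csv(path)
    wells = [Well(well_id=str(r.well_id), cx=float(r.cx_px),
                  cy=float(r.cy_px), r=float(r.r_px))
             for r in df.itertuples(index=False)]
    return WellLayout(wells=wells)


def write_layout(layout: WellLayout, path: str | Path) -> None:
    pd.DataFrame(
        {"well_id": [w.well_id for w in layout.wells],
         "cx_px": [w.cx for w in layout.wells],
         "cy_px": [w.cy for w in layout.wells],
         "r_px": [w.r for w in layout.wells]}
    ).to_csv(path, index=False)


def traces_to_frame(traces: Sequence[DiscTrace]) -> pd.DataFrame:
    """Tidy per-well traces: ``well_id,time_h,area_px,area_pct``."""
    parts = [
        pd.DataFrame({"well_id": t.well_id, "time_h": t.times,
                      "area_px": t.area_px.astype(int),
                      "area_pct": t.area_pct})
        for t in traces
    ]
    return pd.concat(parts, ignore_index=True)


def write_traces(traces: Sequence[DiscTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[DiscTrace]:
    df = pd.read_csv(path)
    traces = []
    for wid, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("time_h")
        areas = grp["area_px"].to_numpy(dtype=float)
        times = grp["time_h"].to_numpy(dtype=float)
        complete_at = None
        zero = areas == 0
        if zero.any() and zero[int(np.argmax(zero)):].all():
            complete_at = float(times[int(np.argmax(zero))])
        traces.append(DiscTrace(well_id=str(wid), times=times, area_px=areas,
                                area_pct=grp["area_pct"].to_numpy(dtype=float),
                                complete_at=complete_at))
    return traces
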