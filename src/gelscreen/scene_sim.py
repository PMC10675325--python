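"""Ground-truthed synthetic degradation experiments.

This module simulates enzyme-driven surface erosion of dye-stained hydrogel
discs sitting in the wells of a perfused millifluidic chip, and renders the
corresponding top-down time-lapse frames, so that every downstream stage
(segmentation, tracking, rate estimation, eluate assays, validation
statistics) can be exercised against exact ground truth.

Kinetics model
--------------
* Erosion acts on the disc radius only; the thickness stays constant, as
  observed for discs degrading under tangential flow.  The radius decays
  linearly at speed ``erode_coeff * enzyme_conc`` (mm/h) until it reaches
  zero::

      r(t) = max(0, r0 - erode_coeff * enzyme_conc * t)

* Disintegration is an all-or-nothing event mimicking the abrupt collapse
  seen at high enzyme concentrations: once the remaining area fraction
  ``(r/r0)^2`` falls below ``disintegrate_frac``, each subsequent step
  collapses the disc (radius -> 0) with probability ``disintegrate_prob``.
* Mass is ``pi * r(t)^2 * h0 * density_scale`` (top-view area times constant
  thickness); degraded-gel release is the mass lost so far.
* Entrapped-compound (PVA) release is an early diffusive burst plus a
  degradation-coupled term proportional to the eroded area fraction::

      cum_pva(t) = load * [ f_b (1 - exp(-t/tau))
                            + (1 - f_b) (1 - r(t)^2 / r0^2) ]

All randomness flows from explicit integer seeds; repeated calls with the
same inputs are bit-identical.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .label_track import Well, WellLayout
from .segment import FrameImage

#: Default radial erosion speed per unit enzyme concentration,
#: mm/h per (ug/mL).  With r0 = 2 mm this puts complete degradation of the
#: 100 ug/mL condition at 12 h, the time scale observed on the chip.
DEFAULT_ERODE_COEFF = 1.0 / 600.0

RGB = tuple[int, int, int]


def _check_unit(name: str, v: float) -> None:
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclasses.dataclass(frozen=True)
class WellCondition:
    """Enzyme exposure and disintegration behavior of one well.

    ``enzyme_conc`` is the protease concentration (ug/mL, MMP9 analog);
    ``erode_coeff`` converts it to a radial erosion speed.  Disintegration
    may trigger only once the remaining area fraction drops below
    ``disintegrate_frac``, with per-step probability ``disintegrate_prob``.
    """

    well_id: str
    enzyme_conc: float
    erode_coeff: float = DEFAULT_ERODE_COEFF
    disintegrate_frac: float = 0.2
    disintegrate_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.enzyme_conc < 0:
            raise ValueError(f"enzyme_conc must be >= 0, got {self.enzyme_conc}")
        if self.erode_coeff < 0:
            raise ValueError(f"erode_coeff must be >= 0, got {self.erode_coeff}")
        _check_unit("disintegrate_frac", self.disintegrate_frac)
        _check_unit("disintegrate_prob", self.disintegrate_prob)


@dataclasses.dataclass(frozen=True)
class DiscSpec:
    """Geometry and payload of a cast hydrogel disc.

    Defaults correspond to a 2 mm radius x 1 mm thick disc of 10% w/v gel
    (density_scale 100 ug/mm^3) loaded with 7.5% w/v PVA (942 ug total).
    """

    radius0: float = 2.0       # mm
    thickness0: float = 1.0    # mm
    density_scale: float = 100.0  # mass units (ug) per mm^3
    pva_load: float = 942.0    # ug releasable
    burst_frac: float = 0.3    # fraction released by passive diffusion
    burst_tau: float = 1.0     # h, burst time constant

    def __post_init__(self) -> None:
        if self.radius0 <= 0:
            raise ValueError(f"radius0 must be > 0, got {self.radius0}")
        if self.thickness0 <= 0:
            raise ValueError(f"thickness0 must be > 0, got {self.thickness0}")
        if self.burst_tau <= 0:
            raise ValueError(f"burst_tau must be > 0, got {self.burst_tau}")
        if self.pva_load < 0:
            raise ValueError(f"pva_load must be >= 0, got {self.pva_load}")
        _check_unit("burst_frac", self.burst_frac)


@dataclasses.dataclass
class SimTruth:
    """Ground-truth kinetics for a set of wells on a common time grid.

    Arrays are shaped (T, W): one row per sample time (hours, starting at
    0), one column per well in ``well_ids`` order.
    """

    times: np.ndarray
    well_ids: list[str]
    radius: np.ndarray     # mm
    area_mm2: np.ndarray
    mass: np.ndarray       # ug (area * thickness * density_scale)
    cum_pva: np.ndarray    # ug released
    cum_gel: np.ndarray    # ug degraded gel released
    t_complete: dict[str, float | None]
    disintegrated_at: dict[str, float | None]
    seed: int
    disc: DiscSpec
    wells: list[WellCondition]

    def column(self, well_id: str) -> int:
        return self.well_ids.index(well_id)


@dataclasses.dataclass(frozen=True)
class RenderConfig:
    """Camera/raster parameters for synthetic frames.

    ``frame_interval`` is in minutes (the time-lapse default is one frame
    per 60 s).  Colors are 8-bit RGB: the disc is strongly red-stained, the
    perfusion medium is dye-tinted (reddish but far less saturated) and the
    chip body is neutral gray.  ``noise_sd`` is additive Gaussian sensor
    noise in 8-bit intensity units; debris specks of disc-colored pixels
    appear at Poisson(``debris_rate``) per frame at random non-well
    locations.
    """

    px_per_mm: float = 20.0
    frame_interval: float = 1.0  # minutes
    image_size: tuple[int, int] | None = None  # (width, height); None = auto
    disc_color: RGB = (200, 30, 40)
    media_color: RGB = (235, 185, 185)
    background_color: RGB = (120, 120, 120)
    noise_sd: float = 5.0
    debris_rate: float = 1.0
    debris_size_px: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError(f"px_per_mm must be > 0, got {self.px_per_mm}")
        if self.frame_interval <= 0:
            raise ValueError(
                f"frame_interval must be > 0, got {self.frame_interval}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.debris_rate < 0:
            raise ValueError(f"debris_rate must be >= 0, got {self.debris_rate}")
        for name in ("disc_color", "media_color", "background_color"):
            c = getattr(self, name)
            if len(c) != 3 or not all(0 <= v <= 255 for v in c):
                raise ValueError(f"{name} must be an RGB triple in [0,255]^3")


def simulate_kinetics(wells: Sequence[WellCondition], disc: DiscSpec,
                      duration: float, step: float, seed: int) -> SimTruth:
    """Simulate radial surface-erosion kinetics for a set of wells.

    Parameters
    ----------
    duration, step : float
        Total simulated time and sample spacing, hours.  Samples are at
        ``0, step, 2*step, ..., duration``.
    seed : int
        Seeds the per-well disintegration draws; the kinetics are otherwise
        deterministic.

    Returns
    -------
    SimTruth
        Radii, areas, masses and cumulative releases per time and well,
        with per-well completion and disintegration times.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    n_steps = int(round(duration / step))
    times = np.arange(n_steps + 1, dtype=float) * step
    W = len(wells)
    radius = np.zeros((len(times), W))
    t_complete: dict[str, float | None] = {}
    disintegrated_at: dict[str, float | None] = {}
    children = np.random.SeedSequence(seed).spawn(W)
    for j, (well, child) in enumerate(zip(wells, children)):
        r = np.maximum(0.0, disc.radius0
                       - well.erode_coeff * well.enzyme_conc * times)
        disintegrated_at[well.well_id] = None
        if well.disintegrate_prob > 0:
            rng = np.random.default_rng(child)
            for i in range(1, len(times)):
                if r[i] <= 0:
                    break
                frac = (r[i] / disc.radius0) ** 2
                if frac < well.disintegrate_frac and \
                        rng.random() < well.disintegrate_prob:
                    r[i:] = 0.0
                    disintegrated_at[well.well_id] = float(times[i])
                    break
        radius[:, j] = r
        zero = r == 0
        t_complete[well.well_id] = (
            float(times[int(np.argmax(zero))]) if zero.any() else None)

    area = math.pi * radius ** 2
    mass = area * disc.thickness0 * disc.density_scale
    cum_gel = mass[0:1, :] - mass
    eroded_frac = 1.0 - (radius / disc.radius0) ** 2
    burst = disc.burst_frac * (1.0 - np.exp(-times / disc.burst_tau))
    cum_pva = disc.pva_load * (burst[:, None]
                               + (1.0 - disc.burst_frac) * eroded_frac)
    return SimTruth(times=times, well_ids=[w.well_id for w in wells],
                    radius=radius, area_mm2=area, mass=mass,
                    cum_pva=cum_pva, cum_gel=cum_gel,
                    t_complete=t_complete, disintegrated_at=disintegrated_at,
                    seed=seed, disc=disc, wells=list(wells))


def truth_to_frame(truth: SimTruth) -> pd.DataFrame:
    """Long-format ground truth table, one row per (well, time)."""
    rows = []
    for j, wid in enumerate(truth.well_ids):
        rows.append(pd.DataFrame({
            "well_id": wid,
            "time_h": truth.times,
            "radius_mm": truth.radius[:, j],
            "area_mm2": truth.area_mm2[:, j],
            "mass": truth.mass[:, j],
            "cum_pva_ug": truth.cum_pva[:, j],
            "cum_gel": truth.cum_gel[:, j],
        }))
    return pd.concat(rows, ignore_index=True)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    truth_to_frame(truth).to_csv(path, index=False)


def row_layout(well_ids: Sequence[str], px_per_mm: float,
               well_radius_mm: float = 5.0, pitch_mm: float = 12.0,
               margin_mm: float = 1.0) -> tuple[WellLayout, tuple[int, int]]:
    """Lay wells out in a single row, as on the physical chip.

    Returns the layout (pixel coordinates) and the (width, height) of the
    smallest image that contains it.  Well centers sit at half-integer
    pixel coordinates so that no pixel center coincides exactly with a
    disc center.
    """
    r_px = well_radius_mm * px_per_mm
    cy = (margin_mm + well_radius_mm) * px_per_mm + 0.5
    wells = []
    for i, wid in enumerate(well_ids):
        cx = (margin_mm + well_radius_mm + i * pitch_mm) * px_per_mm + 0.5
        wells.append(Well(well_id=str(wid), cx=cx, cy=cy, r=r_px))
    width = int(math.ceil(wells[-1].cx + r_px + margin_mm * px_per_mm)) + 1
    height = int(math.ceil(cy + r_px + margin_mm * px_per_mm)) + 1
    return WellLayout(wells=wells), (width, height)


def rasterize_disc(shape: tuple[int, int], cy: float, cx: float,
                   radius: float) -> np.ndarray:
    """Boolean mask of pixels whose center lies within the circle.

    The rasterization rule is: pixel (row r, col c) — whose center is the
    point (r, c) — belongs to the disc iff (r-cy)^2 + (c-cx)^2 <= radius^2.
    The renderer and the area oracle share this exact rule.
    """
    H, W = shape
    yy, xx = np.ogrid[:H, :W]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius


def _grow_debris(rng: np.random.Generator, start: tuple[int, int], size: int,
                 shape: tuple[int, int], forbidden: np.ndarray) -> list[tuple[int, int]]:
    """Grow a connected speck of up to `size` pixels by a random walk."""
    H, W = shape
    speck = [start]
    seen = {start}
    for _ in range(size - 1):
        y0, x0 = speck[rng.integers(0, len(speck))]
        dy, dx = rng.integers(-1, 2, size=2)
        y, x = int(y0 + dy), int(x0 + dx)
        if 0 <= y < H and 0 <= x < W and (y, x) not in seen \
                and not forbidden[y, x]:
            speck.append((y, x))
            seen.add((y, x))
    return speck


def render_frames(truth: SimTruth, layout: WellLayout, cfg: RenderConfig,
                  outdir: str | Path | None = None
                  ) -> tuple[list[FrameImage], pd.DataFrame]:
    """Render one frame per simulated sample time.

    Each live disc is drawn as a filled circle of its true radius in
    ``disc_color`` at its well center; well interiors are ``media_color``
    on a ``background_color`` chip body.  Debris specks and Gaussian noise
    are added per the config.  Deterministic given ``cfg.seed``.

    If ``outdir`` is given, frames are written as 8-bit RGB PNGs alongside a
    ``manifest.csv`` with header ``filename,time_min``.

    Raises
    ------
    ValueError
        If the layout does not fit in the image, a truth well is missing
        from the layout, or a disc radius exceeds its well radius.
    """
    if cfg.image_size is not None:
        width, height = cfg.image_size
    else:
        width = int(math.ceil(max(w.cx + w.r for w in layout.wells))) + 2
        height = int(math.ceil(max(w.cy + w.r for w in layout.wells))) + 2
    for w in layout.wells:
        if w.cx - w.r < 0 or w.cy - w.r < 0 or w.cx + w.r > width - 1 \
                or w.cy + w.r > height - 1:
            raise ValueError(
                f"well {w.well_id!r} does not fit inside a "
                f"{width}x{height} image")
    by_id = {w.well_id: w for w in layout.wells}
    missing = [wid for wid in truth.well_ids if wid not in by_id]
    if missing:
        raise ValueError(f"layout lacks wells for {missing}")
    max_r_px = float(truth.radius.max()) * cfg.px_per_mm
    for wid in truth.well_ids:
        r_disc = float(truth.radius[:, truth.column(wid)].max()) * cfg.px_per_mm
        if r_disc > by_id[wid].r:
            raise ValueError(
                f"disc radius {r_disc:.1f} px exceeds well radius "
                f"{by_id[wid].r:.1f} px in well {wid!r}")
    del max_r_px

    shape = (height, width)
    base = np.empty((height, width, 3), dtype=np.uint8)
    base[:] = cfg.background_color
    well_mask = np.zeros(shape, dtype=bool)
    for w in layout.wells:
        m = rasterize_disc(shape, w.cy, w.cx, w.r)
        well_mask |= m
        base[m] = cfg.media_color

    rng = np.random.default_rng(cfg.seed)
    frames: list[FrameImage] = []
    records = []
    outdir_path = Path(outdir) if outdir is not None else None
    if outdir_path is not None:
        outdir_path.mkdir(parents=True, exist_ok=True)
    for i, t_h in enumerate(truth.times):
        img = base.copy()
        for wid in truth.well_ids:
            r_px = float(truth.radius[i, truth.column(wid)]) * cfg.px_per_mm
            if r_px > 0:
                w = by_id[wid]
                img[rasterize_disc(shape, w.cy, w.cx, r_px)] = cfg.disc_color
        n_debris = rng.poisson(cfg.debris_rate) if cfg.debris_rate > 0 else 0
        for _ in range(n_debris):
            for _attempt in range(100):
                y = int(rng.integers(0, height))
                x = int(rng.integers(0, width))
                if not well_mask[y, x]:
                    break
            else:
                continue
            size = int(rng.integers(1, cfg.debris_size_px + 1))
            for (yy, xx) in _grow_debris(rng, (y, x), size, shape, well_mask):
                img[yy, xx] = cfg.disc_color
        if cfg.noise_sd > 0:
            noisy = img.astype(np.float64) + rng.normal(
                0.0, cfg.noise_sd, size=img.shape)
            img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
        name = f"frame_{i:04d}.png"
        time_min = float(t_h) * 60.0
        frame = FrameImage(pixels=img, time_min=time_min, source_name=name)
        frames.append(frame)
        records.append({"filename": name, "time_min": time_min})
        if outdir_path is not None:
            iio.imwrite(outdir_path / name, img)
    manifest = pd.DataFrame(records, columns=["filename", "time_min"])
    if outdir_path is not None:
        manifest.to_csv(outdir_path / "manifest.csv", index=False)
    return frames, manifest


def sample_eluates(truth: SimTruth, sample_times: Sequence[float],
                   slope: float, intercept: float, reservoir_vol_ml: float,
                   noise_sd: float, seed: int,
                   analyte: str = "pva") -> pd.DataFrame:
    """Simulate eluate absorbance readings at a sampling schedule.

    The reservoir is closed and recirculating, so the analyte concentration
    at time t is the cumulative released amount divided by the reservoir
    volume; absorbance follows the linear standard curve plus Gaussian
    read noise.  Returns ``well_id,time_h,absorbance``.
    """
    if analyte == "pva":
        cum = truth.cum_pva
    elif analyte == "gel":
        cum = truth.cum_gel
    else:
        raise ValueError(f"unknown analyte {analyte!r}")
    if reservoir_vol_ml <= 0:
        raise ValueError("reservoir_vol_ml must be positive")
    rng = np.random.default_rng(seed)
    ts = np.asarray(sample_times, dtype=float)
    rows = []
    for j, wid in enumerate(truth.well_ids):
        conc = np.interp(ts, truth.times, cum[:, j]) / reservoir_vol_ml
        absorbance = slope * conc + intercept \
            + rng.normal(0.0, noise_sd, size=ts.size)
        rows.append(pd.DataFrame({"well_id": wid, "time_h": ts,
                                  "absorbance": absorbance}))
    return pd.concat(rows, ignore_index=True)


def sample_masses(truth: SimTruth, sample_times: Sequence[float],
                  noise_frac: float, seed: int) -> pd.DataFrame:
    """Simulate dry-mass measurements (``well_id,time_h,dry_mass``).

    Multiplicative Gaussian weighing noise of relative SD ``noise_frac``;
    masses are clipped at zero.
    """
    rng = np.random.default_rng(seed)
    ts = np.asarray(sample_times, dtype=float)
    rows = []
    for j, wid in enumerate(truth.well_ids):
        m = np.interp(ts, truth.times, truth.mass[:, j])
        m = np.maximum(0.0, m * (1.0 + rng.normal(0.0, noise_frac, ts.size)))
        rows.append(pd.DataFrame({"well_id": wid, "time_h": ts,
                                  "dry_mass": m}))
    return pd.concat(rows, ignore_index=True)
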