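"""Eluate quantification via a linear absorbance standard curve.

Released compounds (the PVA payload, detected colorimetrically at 630 nm by
the iodine-borate reaction, and degraded gel as a second analyte) are
quantified by fitting an ordinary-least-squares line through standards of
known concentration and inverting it on unknown absorbances.  The chip's
reservoir is closed and recirculating, so cumulative released mass is
concentration times reservoir volume; the small sampled withdrawals are
treated as negligible.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class StandardCurve:
    """Linear absorbance <-> concentration calibration.

    ``absorbance = slope * conc + intercept`` over ``valid_range`` (the
    span of the standard concentrations, ug/mL).
    """

    slope: float
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]

    def predict(self, conc):
        return self.slope * np.asarray(conc, dtype=float) + self.intercept


@dataclasses.dataclass
class EluateSeries:
    """Per-well eluate sampling series (times in hours)."""

    well_id: str
    times: np.ndarray
    absorbance: np.ndarray
    conc: np.ndarray | None = None  # ug/mL, filled by inversion
    volume_note: float = 50.0  # uL withdrawn per sample

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if len(self.times) != len(self.absorbance):
            raise ValueError("times and absorbance lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sampling times must be strictly increasing")


def fit_standard_curve(
    standards: Iterable[tuple[float, float]] | pd.DataFrame,
) -> StandardCurve:
    """Fit an OLS line through (concentration, absorbance) standards.

    Accepts an iterable of (conc, absorbance) pairs or a DataFrame with
    columns ``conc_ug_ml`` and ``absorbance``.  Requires at least two
    standards at two distinct concentrations; with exactly two the line
    passes through both points.  ``r_squared`` is the squared Pearson
    correlation of the fit.
    """
    if isinstance(standards, pd.DataFrame):
        conc = standards["conc_ug_ml"].to_numpy(dtype=float)
        ab = standards["absorbance"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(standards), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("standards must be (conc, absorbance) pairs")
        conc, ab = arr[:, 0], arr[:, 1]
    if conc.size < 2:
        raise ValueError("need at least two standards")
    if np.unique(conc).size < 2:
        raise ValueError(
            "all standard concentrations identical; degenerate design")
    res = stats.linregress(conc, ab)
    r2 = float(res.rvalue) ** 2 if np.isfinite(res.rvalue) else 0.0
    return StandardCurve(slope=float(res.slope),
                         intercept=float(res.intercept),
                         r_squared=min(1.0, r2),
                         valid_range=(float(conc.min()), float(conc.max())))


def invert_curve(curve: StandardCurve, absorbance):
    """Map absorbance back to concentration (ug/mL).

    Returns ``(conc, extrapolated)``: concentration clamped below at zero
    and a flag set when the unclamped value falls outside the curve's
    calibrated range.  Works elementwise on arrays.
    """
    if curve.slope == 0:
        raise ValueError("standard curve slope is zero; non-identifiable")
    a = np.asarray(absorbance, dtype=float)
    raw = (a - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    # tolerance absorbs round-off so an absorbance exactly at a calibration
    # endpoint is not flagged as extrapolated
    tol = 1e-9 * max(1.0, hi - lo)
    flag = (raw < lo - tol) | (raw > hi + tol)
    conc = np.maximum(raw, 0.0)
    if np.isscalar(absorbance) or a.ndim == 0:
        return float(conc), bool(flag)
    return conc, flag


def release_profile(series: EluateSeries, curve: StandardCurve,
                    reservoir_vol: float) -> pd.DataFrame:
    """Cumulative released mass (ug) over the sampling schedule.

    Concentrations come from :func:`invert_curve`; mass is concentration
    times the closed recirculating reservoir volume (mL).  Monotonicity is
    not enforced — measurement noise can produce small decreases — but a
    non-monotone profile is logged as a warning.

    Returns ``well_id,time_h,conc_ug_ml,cum_mass_ug,extrapolated``.
    """
    if reservoir_vol <= 0:
        raise ValueError(f"reservoir_vol must be > 0, got {reservoir_vol}")
    conc, flags = invert_curve(curve, series.absorbance)
    conc = np.atleast_1d(conc)
    flags = np.atleast_1d(flags)
    series.conc = conc
    cum_mass = conc * reservoir_vol
    if np.any(np.diff(cum_mass) < 0):
        logger.warning("well %s: non-monotone cumulative release "
                       "(measurement noise?)", series.well_id)
    return pd.DataFrame({"well_id": series.well_id, "time_h": series.times,
                         "conc_ug_ml": conc, "cum_mass_ug": cum_mass,
                         "extrapolated": flags})


# ---------------------------------------------------------------------------
# CSV interfaces

def read_standards(path: str | Path) -> pd.DataFrame:
    """Read a standards CSV with header ``conc_ug_ml,absorbance``."""
    return pd.read_csv(path)


def read_eluates(path: str | Path) -> list[EluateSeries]:
    """Read an eluates CSV (``well_id,time_h,absorbance``) into series."""
    df = pd.read_csv(path)
    series = []
    for wid, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("time_h")
        series.append(EluateSeries(
            well_id=str(wid), times=grp["time_h"].to_numpy(dtype=float),
            absorbance=grp["absorbance"].to_numpy(dtype=float)))
    return series


def release_profiles(series_list: Sequence[EluateSeries],
                     curve: StandardCurve,
                     reservoir_vol: float) -> pd.DataFrame:
    """Concatenated release profiles for several wells."""
    return pd.concat(
        [release_profile(s, curve, reservoir_vol) for s in series_list],
        ignore_index=True)
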