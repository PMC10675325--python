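"""Degradation pseudorates and disintegration-event detection.

The pseudorate is an endpoint-based average rate in %/h, computed under a
linear-degradation assumption: for a disc that fully degrades it is
``100 / t_complete``; otherwise it is the percent of initial area lost over
the whole run divided by the run duration.  A least-squares-slope variant is
provided as an explicitly non-default alternative.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .label_track import DiscTrace


@dataclasses.dataclass
class RateEstimate:
    """Endpoint pseudorate for one well.

    ``basis`` records the endpoint pair used: (t_start, t_end, A_start,
    A_end) in hours and pixels.  ``events`` lists flagged disintegration
    events as (time_h, single-frame drop as a fraction of initial area).
    """

    well_id: str
    rate: float  # %/h
    basis: tuple[float, float, float, float]
    complete: bool
    t_complete: float | None = None
    events: list[tuple[float, float]] = dataclasses.field(default_factory=list)


def pseudorate(trace: DiscTrace) -> RateEstimate:
    """Endpoint average degradation rate of one trace, in %/h.

    If the disc fully degraded, the rate is 100% divided by the time to
    complete degradation; otherwise it is the percent change between the
    first and last frames divided by the elapsed time, floored at zero if
    the disc apparently grew.
    """
    if len(trace.times) < 2:
        raise ValueError(
            f"well {trace.well_id!r}: single-frame trace has no elapsed time")
    a0 = trace.area_px[0]
    if a0 <= 0:
        raise ValueError(f"well {trace.well_id!r}: zero initial area")
    if trace.complete_at is not None:
        rate = 100.0 / trace.complete_at
        basis = (float(trace.times[0]), float(trace.complete_at),
                 float(a0), 0.0)
        return RateEstimate(well_id=trace.well_id, rate=rate, basis=basis,
                            complete=True, t_complete=float(trace.complete_at))
    t_end = float(trace.times[-1])
    a_end = float(trace.area_px[-1])
    elapsed = t_end - float(trace.times[0])
    rate = max(0.0, 100.0 * (a0 - a_end) / a0 / elapsed)
    return RateEstimate(well_id=trace.well_id, rate=rate,
                        basis=(float(trace.times[0]), t_end, float(a0), a_end),
                        complete=False, t_complete=None)


def pseudorate_regression(trace: DiscTrace) -> float:
    """Least-squares-slope rate variant (%/h), NOT the endpoint definition.

    Fits area_pct against time by ordinary least squares and returns the
    negated slope floored at zero.  Provided as an opt-in alternative; the
    endpoint :func:`pseudorate` is the canonical estimator.
    """
    if len(trace.times) < 2:
        raise ValueError("need at least two frames for a slope")
    slope = np.polyfit(trace.times, trace.area_pct, 1)[0]
    return max(0.0, -float(slope))


def flag_disintegration(trace: DiscTrace,
                        drop_frac: float = 0.3) -> list[tuple[float, float]]:
    """Flag abrupt single-frame area drops as disintegration events.

    An event is recorded at frame i when the drop from the previous frame,
    as a fraction of the *initial* area, reaches ``drop_frac``.  Returns
    (time_h, drop fraction) pairs sorted by time.
    """
    if not 0.0 < drop_frac <= 1.0:
        raise ValueError(f"drop_frac must be in (0, 1], got {drop_frac}")
    a0 = trace.area_px[0]
    drops = (trace.area_px[:-1] - trace.area_px[1:]) / a0
    events = [(float(trace.times[i + 1]), float(d))
              for i, d in enumerate(drops) if d >= drop_frac]
    return events


def estimate_rates(traces: Sequence[DiscTrace],
                   drop_frac: float = 0.3) -> list[RateEstimate]:
    """Pseudorate plus disintegration flags for every trace."""
    estimates = []
    for trace in traces:
        est = pseudorate(trace)
        est.events = flag_disintegration(trace, drop_frac)
        estimates.append(est)
    return estimates


def rates_to_frame(rates: Sequence[RateEstimate]) -> pd.DataFrame:
    """Tidy rates table: ``well_id,rate_pct_per_h,complete,t_complete_h,n_events``."""
    return pd.DataFrame({
        "well_id": [r.well_id for r in rates],
        "rate_pct_per_h": [r.rate for r in rates],
        "complete": [r.complete for r in rates],
        "t_complete_h": [r.t_complete if r.t_complete is not None else np.nan
                         for r in rates],
        "n_events": [len(r.events) for r in rates],
    })


def write_rates(rates: Sequence[RateEstimate], path: str | Path) -> None:
    rates_to_frame(rates).to_csv(path, index=False)
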