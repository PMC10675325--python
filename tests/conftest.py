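"""Shared fixtures: in-memory synthetic experiments at desk scale.

The "study" runs reproduce the reference experiment (8 wells, four enzyme
concentrations 0/50/100/200 µg/mL in duplicate, 20 h) at a 15-min frame
interval so a whole rendered run stays inexpensive.
"""

from __future__ import annotations

import dataclasses

import pytest

from gelscreen import (ColorGate, estimate_rates, measure_frames,
                       render_frames, row_layout, simulate_kinetics)
from gelscreen.config import (disc_from_config, load_config,
                              render_from_config, wells_from_config)


@dataclasses.dataclass
class SyntheticRun:
    cfg: dict
    wells: list
    disc: object
    truth: object
    layout: object
    frames: list
    traces: list
    rates: list
    conditions: dict


def _make_run(noisy: bool, seed: int) -> SyntheticRun:
    cfg = load_config()
    cfg["simulate"]["duration_h"] = 20.0
    cfg["simulate"]["render"]["frame_interval_min"] = 15.0
    if not noisy:
        cfg["simulate"]["render"]["noise_sd"] = 0.0
        cfg["simulate"]["render"]["debris_rate"] = 0.0
        cfg["simulate"]["erode_jitter_frac"] = 0.0
    wells = wells_from_config(cfg, seed=seed + 1)
    disc = disc_from_config(cfg)
    rcfg = render_from_config(cfg, seed=seed + 2)
    truth = simulate_kinetics(wells, disc, duration=20.0,
                              step=rcfg.frame_interval / 60.0, seed=seed)
    layout, _ = row_layout(truth.well_ids, rcfg.px_per_mm)
    frames, _ = render_frames(truth, layout, rcfg)
    traces = measure_frames(frames, ColorGate(), layout,
                            min_region_px=int(cfg["segment"]["min_region_px"]))
    rates = estimate_rates(traces, drop_frac=float(cfg["quantify"]["drop_frac"]))
    conditions = {w.well_id: w.enzyme_conc for w in wells}
    return SyntheticRun(cfg=cfg, wells=wells, disc=disc, truth=truth,
                        layout=layout, frames=frames, traces=traces,
                        rates=rates, conditions=conditions)


@pytest.fixture(scope="session")
def study_run() -> SyntheticRun:
    """Noisy study-condition run: sensor noise, debris, replicate jitter."""
    return _make_run(noisy=True, seed=11)


@pytest.fixture(scope="session")
def noiseless_run() -> SyntheticRun:
    """Same experiment with noise, debris and replicate jitter disabled."""
    return _make_run(noisy=False, seed=11)
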