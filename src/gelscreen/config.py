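"""YAML run configuration with study-condition defaults.

The default configuration encodes the reference experiment: eight wells
(four MMP9-analog concentrations 0/50/100/200 µg/mL, two replicates each),
2 mm x 1 mm discs, a 20 h time course imaged at one frame per minute,
eluate sampling at 0/1/2/3/17 h from a 20 mL closed reservoir, and dry-mass
reference sampling every 4 h.  A user YAML file is deep-merged over these
defaults, so a config need only state what it changes.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from .scene_sim import (DEFAULT_ERODE_COEFF, DiscSpec, RenderConfig,
                        WellCondition)
from .segment import ColorGate

DEFAULTS: dict[str, Any] = {
    "simulate": {
        "duration_h": 20.0,
        "enzyme_concs": [0.0, 50.0, 100.0, 200.0],
        "replicates": 2,
        "erode_coeff": DEFAULT_ERODE_COEFF,
        "erode_jitter_frac": 0.05,
        "disintegrate_frac": 0.2,
        "disintegrate_prob": 0.0,
        "disc": {
            "radius0_mm": 2.0,
            "thickness0_mm": 1.0,
            "density_scale": 100.0,
            "pva_load_ug": 942.0,
            "burst_frac": 0.3,
            "burst_tau_h": 1.0,
        },
        "render": {
            "px_per_mm": 20.0,
            "frame_interval_min": 1.0,
            "noise_sd": 5.0,
            "debris_rate": 1.0,
            "debris_size_px": 20,
            "disc_color": [200, 30, 40],
            "media_color": [235, 185, 185],
            "background_color": [120, 120, 120],
        },
        "layout": {
            "well_radius_mm": 5.0,
            "pitch_mm": 12.0,
            "margin_mm": 1.0,
        },
    },
    "segment": {
        "hue_lo": 340.0,
        "hue_hi": 20.0,
        "sat_min": 0.35,
        "val_min": 0.15,
        "min_region_px": 5,
    },
    "quantify": {
        "drop_frac": 0.3,
    },
    "assay": {
        "reservoir_vol_ml": 20.0,
        "sample_times_h": [0.0, 1.0, 2.0, 3.0, 17.0],
        "mass_times_h": [0.0, 4.0, 8.0, 12.0, 16.0, 20.0],
        "standard_concs": [0.0, 10.0, 20.0, 40.0, 60.0, 80.0, 100.0],
        "curve_slope": 0.02,
        "curve_intercept": 0.05,
        "standard_noise_sd": 0.002,
        "eluate_noise_sd": 0.005,
        "mass_noise_frac": 0.02,
    },
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config merged over the package defaults."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    return cfg


def wells_from_config(cfg: dict, seed: int | None = None) -> list[WellCondition]:
    """Build well conditions from a config.

    A config may either enumerate ``simulate.wells`` explicitly (a list of
    WellCondition field dicts) or give ``enzyme_concs`` x ``replicates``,
    in which case wells are named ``W1..Wn`` in concentration-major order.

    ``erode_jitter_frac`` models disc-to-disc replicate variability as a
    multiplicative Gaussian perturbation of the erosion coefficient; it is
    applied only when a ``seed`` is given.
    """
    import numpy as np

    sim = cfg["simulate"]
    if "wells" in sim:
        return [WellCondition(**w) for w in sim["wells"]]
    jitter = float(sim.get("erode_jitter_frac", 0.0))
    rng = np.random.default_rng(seed) if seed is not None else None
    wells = []
    k = 1
    for conc in sim["enzyme_concs"]:
        for _ in range(int(sim["replicates"])):
            coeff = float(sim["erode_coeff"])
            if rng is not None and jitter > 0:
                coeff = max(0.0, coeff * (1.0 + jitter * rng.standard_normal()))
            wells.append(WellCondition(
                well_id=f"W{k}", enzyme_conc=float(conc),
                erode_coeff=coeff,
                disintegrate_frac=float(sim["disintegrate_frac"]),
                disintegrate_prob=float(sim["disintegrate_prob"])))
            k += 1
    return wells


def disc_from_config(cfg: dict) -> DiscSpec:
    d = cfg["simulate"]["disc"]
    return DiscSpec(radius0=float(d["radius0_mm"]),
                    thickness0=float(d["thickness0_mm"]),
                    density_scale=float(d["density_scale"]),
                    pva_load=float(d["pva_load_ug"]),
                    burst_frac=float(d["burst_frac"]),
                    burst_tau=float(d["burst_tau_h"]))


def render_from_config(cfg: dict, seed: int) -> RenderConfig:
    r = cfg["simulate"]["render"]
    return RenderConfig(px_per_mm=float(r["px_per_mm"]),
                        frame_interval=float(r["frame_interval_min"]),
                        disc_color=tuple(r["disc_color"]),
                        media_color=tuple(r["media_color"]),
                        background_color=tuple(r["background_color"]),
                        noise_sd=float(r["noise_sd"]),
                        debris_rate=float(r["debris_rate"]),
                        debris_size_px=int(r["debris_size_px"]),
                        seed=seed)


def gate_from_config(cfg: dict) -> ColorGate:
    s = cfg["segment"]
    return ColorGate(hue_lo=float(s["hue_lo"]), hue_hi=float(s["hue_hi"]),
                     sat_min=float(s["sat_min"]),
                     val_min=float(s["val_min"]))
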