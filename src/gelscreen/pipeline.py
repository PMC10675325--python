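"""Stage orchestration: simulate -> segment -> quantify -> assay -> report.

Each ``run_*`` function is a thin file-level wrapper over the library
modules so the CLI subcommands and the ``run-all`` chain share one code
path.  All randomness within a run derives from a single integer seed via
``numpy.random.SeedSequence`` spawning, so a whole chained run is
reproducible bit for bit.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assay, config, label_track, quantify, scene_sim, segment, stats_report

logger = logging.getLogger(__name__)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    return [int(c.generate_state(1)[0] % (2 ** 31))
            for c in np.random.SeedSequence(seed).spawn(n)]


def run_simulate(cfg: dict, outdir: str | Path, seed: int):
    """Simulate kinetics, render the time lapse, and write all artifacts.

    Writes ``frames/`` (PNG + manifest.csv), ``truth.csv`` and
    ``layout.csv`` under ``outdir``.  Returns (truth, layout, frames).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_kin, seed_render, seed_wells = _child_seeds(seed, 3)
    wells = config.wells_from_config(cfg, seed=seed_wells)
    disc = config.disc_from_config(cfg)
    rcfg = config.render_from_config(cfg, seed_render)
    step_h = rcfg.frame_interval / 60.0
    logger.info("simulate: %d wells, %.3g h at %.3g-min frames",
                len(wells), cfg["simulate"]["duration_h"], rcfg.frame_interval)
    truth = scene_sim.simulate_kinetics(
        wells, disc, duration=float(cfg["simulate"]["duration_h"]),
        step=step_h, seed=seed_kin)
    lay = cfg["simulate"]["layout"]
    layout, _ = scene_sim.row_layout(
        truth.well_ids, rcfg.px_per_mm,
        well_radius_mm=float(lay["well_radius_mm"]),
        pitch_mm=float(lay["pitch_mm"]), margin_mm=float(lay["margin_mm"]))
    frames, _ = scene_sim.render_frames(truth, layout, rcfg,
                                        outdir=outdir / "frames")
    scene_sim.write_truth(truth, outdir / "truth.csv")
    label_track.write_layout(layout, outdir / "layout.csv")
    return truth, layout, frames


def run_segment(manifest: str | Path, layout_csv: str | Path, cfg: dict,
                out_traces: str | Path) -> list[label_track.DiscTrace]:
    """Frames + layout -> tidy traces CSV."""
    frames = segment.load_frames(manifest)
    layout = label_track.read_layout(layout_csv)
    gate = config.gate_from_config(cfg)
    logger.info("segment: %d frames, %d wells", len(frames), layout.n_wells)
    traces = label_track.measure_frames(
        frames, gate, layout, min_region_px=int(cfg["segment"]["min_region_px"]))
    label_track.write_traces(traces, out_traces)
    return traces


def run_quantify(traces_csv: str | Path, out_rates: str | Path,
                 drop_frac: float = 0.3) -> list[quantify.RateEstimate]:
    """Traces CSV -> rates CSV."""
    traces = label_track.read_traces(traces_csv)
    rates = quantify.estimate_rates(traces, drop_frac=drop_frac)
    quantify.write_rates(rates, out_rates)
    return rates


def run_assay(standards_csv: str | Path, eluates_csv: str | Path,
              out_release: str | Path,
              reservoir_vol_ml: float = 20.0) -> pd.DataFrame:
    """Standards + eluates CSVs -> release-profile CSV."""
    curve = assay.fit_standard_curve(assay.read_standards(standards_csv))
    logger.info("assay: curve slope=%.4g intercept=%.4g R2=%.4f",
                curve.slope, curve.intercept, curve.r_squared)
    series = assay.read_eluates(eluates_csv)
    release = assay.release_profiles(series, curve, reservoir_vol_ml)
    release.to_csv(out_release, index=False)
    return release


def run_all(cfg: dict, outdir: str | Path, seed: int) -> dict:
    """Chain the whole pipeline from one config and seed.

    Simulates the experiment (kinetics + frames + eluates + masses),
    re-measures it through segmentation/tracking/quantification/assay, and
    writes the validation report under ``outdir/report``.  Returns the
    report summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (seed_sim, seed_std, seed_pva, seed_gel, seed_mass) = _child_seeds(seed, 5)

    truth, layout, frames = run_simulate(cfg, outdir, seed_sim)

    gate = config.gate_from_config(cfg)
    traces = label_track.measure_frames(
        frames, gate, layout, min_region_px=int(cfg["segment"]["min_region_px"]))
    label_track.write_traces(traces, outdir / "traces.csv")

    rates = quantify.estimate_rates(
        traces, drop_frac=float(cfg["quantify"]["drop_frac"]))
    quantify.write_rates(rates, outdir / "rates.csv")

    acfg = cfg["assay"]
    rng = np.random.default_rng(seed_std)
    concs = np.asarray(acfg["standard_concs"], dtype=float)
    standards = pd.DataFrame({
        "conc_ug_ml": concs,
        "absorbance": float(acfg["curve_slope"]) * concs
        + float(acfg["curve_intercept"])
        + rng.normal(0.0, float(acfg["standard_noise_sd"]), concs.size),
    })
    standards.to_csv(outdir / "standards.csv", index=False)
    curve = assay.fit_standard_curve(standards)

    sample_times = [t for t in acfg["sample_times_h"]
                    if t <= float(cfg["simulate"]["duration_h"])]
    eluates_pva = scene_sim.sample_eluates(
        truth, sample_times, float(acfg["curve_slope"]),
        float(acfg["curve_intercept"]), float(acfg["reservoir_vol_ml"]),
        float(acfg["eluate_noise_sd"]), seed_pva, analyte="pva")
    eluates_pva.to_csv(outdir / "eluates_pva.csv", index=False)
    eluates_gel = scene_sim.sample_eluates(
        truth, sample_times, float(acfg["curve_slope"]),
        float(acfg["curve_intercept"]), float(acfg["reservoir_vol_ml"]),
        float(acfg["eluate_noise_sd"]), seed_gel, analyte="gel")
    eluates_gel.to_csv(outdir / "eluates_gel.csv", index=False)

    release_pva = assay.release_profiles(
        assay.read_eluates(outdir / "eluates_pva.csv"), curve,
        float(acfg["reservoir_vol_ml"]))
    release_pva.to_csv(outdir / "release_pva.csv", index=False)
    release_gel = assay.release_profiles(
        assay.read_eluates(outdir / "eluates_gel.csv"), curve,
        float(acfg["reservoir_vol_ml"]))
    release_gel.to_csv(outdir / "release_gel.csv", index=False)

    mass_times = [t for t in acfg["mass_times_h"]
                  if t <= float(cfg["simulate"]["duration_h"])]
    masses = scene_sim.sample_masses(
        truth, mass_times, float(acfg["mass_noise_frac"]), seed_mass)
    masses.to_csv(outdir / "mass.csv", index=False)

    mass_pairs = stats_report.pair_with_reference(traces, masses, "dry_mass")
    # eluate validation: remaining gel inferred from eluate (initial mass
    # minus cumulative eluted) varies positively with the visual area
    initial_mass = float(truth.mass[0, 0])
    gel_remaining = release_gel.rename(columns={"cum_mass_ug": "value"})[
        ["well_id", "time_h", "value"]].copy()
    gel_remaining["value"] = initial_mass - gel_remaining["value"]
    gel_pairs = stats_report.pair_with_reference(traces, gel_remaining, "value")

    conditions = {w.well_id: w.enzyme_conc for w in truth.wells}
    rate_by_id = {r.well_id: r.rate for r in rates}
    group_values: dict[float, list[float]] = {}
    for wid, conc in conditions.items():
        group_values.setdefault(conc, []).append(rate_by_id[wid])
    comparison = None
    if len(group_values) >= 2 and all(len(v) >= 2
                                      for v in group_values.values()):
        try:
            comparison = stats_report.compare_groups(
                [(f"{conc:g}", vals)
                 for conc, vals in sorted(group_values.items())])
        except ValueError as exc:
            logger.info("group comparison skipped: %s", exc)

    summary = stats_report.build_report(
        traces, rates, outdir / "report", conditions=conditions,
        comparison=comparison, release=release_pva,
        mass_pairs=mass_pairs if len(mass_pairs) >= 3 else None,
        gel_pairs=gel_pairs if len(gel_pairs) >= 3 else None)
    logger.info("run-all complete: %d wells, report at %s",
                len(truth.well_ids), outdir / "report")
    return summary
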