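"""Validation statistics and report generation.

Correlates the visual (pixel-area) degradation measure against reference
measures (dry mass, eluate-quantified gel), compares pseudorates across
enzyme conditions by one-way ANOVA with Tukey HSD multiple comparisons, and
emits figures plus machine-readable summaries.

Significance stars follow the convention * p < 0.05, ** p < 0.005.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .label_track import DiscTrace
from .quantify import RateEstimate, rates_to_frame


@dataclasses.dataclass
class PairedMeasurements:
    """Paired (visual measure, reference measure) observations."""

    x: np.ndarray
    y: np.ndarray
    wells: list[str]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.wells)
                == len(self.times)):
            raise ValueError("paired-measurement fields must align")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("pairs must not contain missing values")

    def __len__(self) -> int:
        return len(self.x)


@dataclasses.dataclass
class GroupComparison:
    """One-way ANOVA with Tukey-HSD pairwise comparisons across conditions."""

    groups: list[tuple[str, np.ndarray]]
    anova_F: float
    anova_p: float
    pairwise: list[tuple[str, str, float, str]]  # (A, B, adjusted p, stars)


def significance_stars(p: float) -> str:
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (0 and non-finite pass through)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient with a two-sided p-value.

    Requires at least three pairs and nonzero variance in both margins;
    the p-value comes from the t-transform with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least three pairs for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a margin; r undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    groups: Sequence[tuple[str, Sequence[float]]],
) -> GroupComparison:
    """One-way fixed-effects ANOVA plus Tukey HSD across condition groups.

    ``groups`` is a list of (condition label, replicate values).  Each
    group needs at least two replicates.  Adjusted pairwise p-values come
    from the studentized-range distribution (Tukey-Kramer for unequal n).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    labels = []
    for label, values in groups:
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(
                f"group {label!r} has {v.size} replicate(s); need >= 2")
        arrays.append(v)
        labels.append(str(label))
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError(
            "all observations identical; ANOVA undefined (zero variance)")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError(
            "zero within-group variance in every group; F undefined")
    F, p = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    pairwise = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            p_adj = float(tukey.pvalue[i, j])
            pairwise.append((labels[i], labels[j], p_adj,
                             significance_stars(p_adj)))
    return GroupComparison(groups=[(l, a) for l, a in zip(labels, arrays)],
                           anova_F=float(F), anova_p=float(p),
                           pairwise=pairwise)


def pair_with_reference(traces: Sequence[DiscTrace], ref: pd.DataFrame,
                        value_col: str,
                        max_dt_h: float = 0.5) -> PairedMeasurements:
    """Pair trace area_pct with a reference table at matching times.

    ``ref`` has columns ``well_id,time_h,<value_col>``.  Each reference row
    is paired with the trace sample nearest in time (within ``max_dt_h``);
    rows for untracked wells or off-schedule times are skipped.
    """
    by_id = {t.well_id: t for t in traces}
    xs, ys, wells, times = [], [], [], []
    for row in ref.itertuples(index=False):
        trace = by_id.get(str(row.well_id))
        if trace is None:
            continue
        i = int(np.argmin(np.abs(trace.times - float(row.time_h))))
        if abs(trace.times[i] - float(row.time_h)) > max_dt_h:
            continue
        xs.append(float(trace.area_pct[i]))
        ys.append(float(getattr(row, value_col)))
        wells.append(str(row.well_id))
        times.append(float(row.time_h))
    return PairedMeasurements(x=np.array(xs), y=np.array(ys), wells=wells,
                              times=np.array(times))


# ---------------------------------------------------------------------------
# Report bundle

def _plot_traces(traces, path) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for t in traces:
        ax.plot(t.times, t.area_pct, label=t.well_id, lw=1.2)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("disc area (% of initial)")
    ax.set_ylim(bottom=0)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_rates(rates, conditions, comparison, path) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    xs = [conditions[r.well_id] for r in rates]
    ys = [r.rate for r in rates]
    ax.plot(xs, ys, "o", alpha=0.7)
    ax.set_xlabel("enzyme concentration (µg/mL)")
    ax.set_ylabel("pseudorate (%/h)")
    if comparison is not None:
        note = "; ".join(f"{a} vs {b}: {s}"
                         for a, b, _, s in comparison.pairwise)
        ax.set_title(f"ANOVA p = {round_sig(comparison.anova_p)}\n{note}",
                     fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_scatter(pairs, xlabel, ylabel, path) -> tuple[float, float]:
    import matplotlib.pyplot as plt

    r, p = pearson_r(pairs.x, pairs.y)
    coeffs = np.polyfit(pairs.x, pairs.y, 1)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(pairs.x, pairs.y, "o", alpha=0.7)
    xfit = np.linspace(pairs.x.min(), pairs.x.max(), 50)
    ax.plot(xfit, np.polyval(coeffs, xfit), "r--", lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"Pearson R = {r:.2f}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return r, p


def build_report(traces: Sequence[DiscTrace],
                 rates: Sequence[RateEstimate],
                 outdir: str | Path, *,
                 conditions: Mapping[str, float] | None = None,
                 comparison: GroupComparison | None = None,
                 release: pd.DataFrame | None = None,
                 mass_pairs: PairedMeasurements | None = None,
                 gel_pairs: PairedMeasurements | None = None) -> dict:
    """Emit figures plus ``summary.json`` and ``summary.csv``.

    Sections for release profiles and validation correlations appear only
    when the corresponding inputs are provided; the output is a pure
    function of its inputs (no timestamps), so identical inputs give
    byte-identical summaries.

    Returns the summary dict (also written as JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"wells": {}}
    for r in rates:
        summary["wells"][r.well_id] = {
            "rate_pct_per_h": round_sig(r.rate, 6),
            "complete": r.complete,
            "t_complete_h": r.t_complete,
            "n_events": len(r.events),
        }
    _plot_traces(traces, outdir / "area_vs_time.png")
    if conditions is not None:
        _plot_rates(rates, conditions, comparison,
                    outdir / "rates_vs_concentration.png")
    if comparison is not None:
        summary["anova"] = {
            "F": round_sig(comparison.anova_F, 6),
            "p": round_sig(comparison.anova_p),
            "pairwise": [
                {"a": a, "b": b, "p_adj": round_sig(p), "stars": s}
                for a, b, p, s in comparison.pairwise
            ],
        }
    correlations = {}
    if mass_pairs is not None and len(mass_pairs) >= 3:
        r, p = _plot_scatter(mass_pairs, "disc area (% of initial)",
                             "dry mass", outdir / "area_vs_mass.png")
        correlations["area_vs_mass"] = {"r": round_sig(r, 4),
                                        "p": round_sig(p),
                                        "n": len(mass_pairs)}
    if gel_pairs is not None and len(gel_pairs) >= 3:
        r, p = _plot_scatter(gel_pairs, "disc area (% of initial)",
                             "eluate-inferred remaining gel (µg)",
                             outdir / "area_vs_eluate_gel.png")
        correlations["area_vs_eluate_gel"] = {"r": round_sig(r, 4),
                                              "p": round_sig(p),
                                              "n": len(gel_pairs)}
    if correlations:
        summary["correlations"] = correlations
    if release is not None and len(release):
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5.5, 4))
        for wid, grp in release.groupby("well_id", sort=False):
            ax.plot(grp["time_h"], grp["cum_mass_ug"], "o-", label=str(wid))
        ax.set_xlabel("time (h)")
        ax.set_ylabel("cumulative released mass (µg)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "release_profiles.png", dpi=120)
        plt.close(fig)
        summary["release_final_ug"] = {
            str(wid): round_sig(float(grp["cum_mass_ug"].iloc[-1]), 6)
            for wid, grp in release.groupby("well_id", sort=False)
        }
    rates_to_frame(list(rates)).to_csv(outdir / "summary.csv", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
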