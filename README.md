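# gelscreen

Image-based screening of hydrogel biodegradation and therapeutic release on
a millifluidic chip.

Biodegradable hydrogels such as gelatin methacrylate (GelMA) release
entrapped therapeutics as they degrade, but the conventional way to measure
degradation — drying and weighing gels at discrete time points — is slow,
destructive, and blind to fast events such as sudden disintegration.
`gelscreen` implements the computational side of a visual screening
platform: dye-stained hydrogel discs sit in the wells of a perfused
millifluidic chip, a camera takes time-lapse images, and the degradation of
every disc is quantified continuously from the images while the circulating
eluate is assayed for released compounds. The package is aimed at
drug-delivery and biomaterials researchers who want a non-destructive,
high-throughput degradation readout validated against mass loss.

## What it computes

**Visual degradation.** Each RGB frame is thresholded in HSV space (a red
hue window plus saturation/value floors separates the strongly stained disc
from the dye-tinted medium), mask pixels are grouped into 8-connected
regions, regions are assigned to chip wells by centroid containment, and
each well's pixel area A(t) is tracked over time, normalized to the first
frame.

**Pseudorate.** Under a linear-degradation assumption the endpoint average
rate in %/h is

- complete degradation at time t_c:  rate = 100 / t_c,
- otherwise over a run of length T:  rate = 100 · (A(0) − A(T)) / A(0) / T,

with abrupt single-frame drops ≥ a configurable fraction of A(0) flagged as
disintegration events.

**Eluate assay.** A linear standard curve `absorbance = m·c + b` (e.g. the
iodine–borate PVA assay read at 630 nm) is fit by ordinary least squares
and inverted to concentrations; cumulative released mass is concentration
times the closed recirculating reservoir volume.

**Validation statistics.** Pearson correlation of the visual measure
against dry mass and against eluate-quantified gel; one-way ANOVA with
Tukey HSD across enzyme concentrations (stars: `*` p < 0.05, `**`
p < 0.005).

**Synthetic experiments.** Because the method targets live imaging rigs, a
ground-truthed simulator generates complete experiments: discs of initial
radius r₀ erode radially at speed proportional to the enzyme (MMP9 analog)
concentration, r(t) = max(0, r₀ − k·C·t), may disintegrate abruptly once
their area fraction falls below a threshold, and release their payload as
an early diffusive burst plus a degradation-coupled term. A renderer turns
the kinetics into noisy time-lapse PNG frames with flowing debris, so every
stage of the pipeline can be benchmarked against exact ground truth.

## Worked example

```python
from gelscreen import (WellCondition, DiscSpec, RenderConfig, ColorGate,
                       simulate_kinetics, row_layout, render_frames,
                       measure_frames, estimate_rates)

wells = [WellCondition("control", 0.0), WellCondition("mmp9_100", 100.0),
         WellCondition("mmp9_200", 200.0)]            # enzyme, µg/mL
truth = simulate_kinetics(wells, DiscSpec(), duration=20.0, step=0.25, seed=1)
layout, _ = row_layout(truth.well_ids, px_per_mm=20.0)
frames, manifest = render_frames(
    truth, layout, RenderConfig(px_per_mm=20.0, frame_interval=15.0,
                                noise_sd=5.0, debris_rate=1.0, seed=1))
traces = measure_frames(frames, ColorGate(), layout, min_region_px=5)
for est in estimate_rates(traces):
    print(f"{est.well_id}: {est.rate:.2f} %/h"
          + (f", complete at {est.t_complete:g} h" if est.complete else ""))
```

prints

```
control: 0.00 %/h
mmp9_100: 8.51 %/h, complete at 11.75 h
mmp9_200: 16.67 %/h, complete at 6 h
```

The control disc (no enzyme) does not degrade; at 100 µg/mL the disc
vanishes from the images a quarter-frame before its true completion time of
12 h, giving 8.51 %/h against a ground-truth 8.33 %/h; at 200 µg/mL the
disc completes at exactly 6 h for 16.67 %/h. Rates rise monotonically with
enzyme concentration.

The same pipeline is available from the shell:

```
gelscreen run-all -c config.yaml -o outdir --seed 1
```

which chains simulate → segment → quantify → assay → report from one YAML
config (any omitted setting takes the study defaults) and writes frames,
tidy CSVs (traces, rates, release profiles, standards, masses) and a report
directory with figures, `summary.json` and `summary.csv`. The
subcommands `simulate`, `segment`, `quantify`, `assay` and `report` expose
the individual stages for real image sequences.

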