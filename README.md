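# tirfpuncta

Quantitative analysis of vesicle puncta in single-cell TIRF time-lapse
movies, built for comparing the exocytosis of multivesicular bodies
(CD63⁺ compartments, which release exosomes) with insulin secretory
granules in pancreatic β-cells — and for any similar punctum-resolved
membrane-trafficking experiment.

The package measures, from a calibrated `(T, Y, X)` movie:

* **puncta density** — prominence-thresholded local maxima (h-maxima
  transform), counted inside a segmented cell footprint and normalized to
  its area (puncta/µm²);
* **ΔF fluorometry** — per-ROI background-subtracted fluorescence,
  ΔF = mean(3-px circle) − mean(5-px annulus), exactly offset-invariant;
* **exocytosis kinetics** — fusion events as abrupt, permanent losses of a
  stably docked punctum's fluorescence, with release duration measured from
  the pre-drop bright point (time 0) to the return of ΔF to the background
  level; sub-second (granule-like) and multi-second (MVB-like) phenotypes
  are handled uniformly by a plateau→ramp→background changepoint fit;
* **residence behaviour** — docking / undocking / docking-and-undocking /
  visiting, classified from linked tracks by a 40-frame (≙ 5.92 s)
  residence threshold, a 0.59 s minimum visit, and 0.3 µm confinement;
* **release-site zoning** — peripheral vs non-peripheral by a 1.6 µm
  (10 px at 0.16 µm/px) Euclidean band inside the cell border;
* **object colocalization** — two-channel yes/no centering within one pixel
  (Chebyshev), with a uniform-permutation chance control;
* **statistics** — one-tailed unpaired Student's t (pooled by default,
  Welch optional), mean ± SEM, star thresholds at 0.05/0.01/0.001.

Because such experiments rarely ship reusable raw movies, the package
includes a first-class synthetic movie generator
(`tirfpuncta.synthetic_data`) that renders a single elliptical cell with
Gaussian puncta that dock, undock, visit, and fuse — fast single-frame
content loss or slow multi-second linear ramps — and emits an exact
ground-truth event log. Every analysis stage is validated by parameter
recovery against that log.

## Worked example

Simulate a β-cell-like movie (SNR 10, 0.16 µm/px, 0.1 s/frame) with a
static punctum population plus fast fusion, docking and visiting events,
then run the analysis:

```python
import numpy as np
from tirfpuncta import synthetic_data as sd, detection, event_kinetics as ek, spatial

cfg = sd.SimulationConfig(n_frames=200, noise_sd=10.0, static_density=0.65, seed=42)
cfg.events = sd.schedule_random_events(
    cfg, {"fusion_fast": 5, "docking": 4, "visiting": 6}, seed=43)
movie, mask, truth = sd.render_movie(cfg)

density = detection.puncta_density(movie, mask, frame=0)
print(f"cell area: {density.area_um2:.1f} um^2")
print(f"puncta density on frame 0: {density.density_per_um2:.3f} /um^2 "
      f"({density.n_puncta} puncta)")

dets = detection.detect_movie(movie)
fusions = ek.detect_fusion_events(movie, dets, mask, ek.KineticThresholds(),
                                  stimulation_frame=0)
durations = [e.release_duration_s for e in fusions]
print(f"fusion events detected: {len(fusions)}")
print(f"mean release duration: {np.mean(durations):.2f} s")

zones = spatial.zone_summary([e.roi.center_x_px for e in fusions],
                             [e.roi.center_y_px for e in fusions], mask)
print(f"peripheral fraction of release sites: {zones.fraction_peripheral:.2f}")
```

Output:

```
cell area: 603.1 um^2
puncta density on frame 0: 0.632 /um^2 (381 puncta)
fusion events detected: 5
mean release duration: 0.50 s
peripheral fraction of release sites: 0.20
```

The density estimate (0.632/µm²) recovers the generated 0.65/µm² within
3%; all five scheduled fusion events are found and their mean estimated
release duration (0.50 s) matches the generated sub-second phenotype
(true mean 0.62 s); one of the five release sites lies in the 1.6 µm
peripheral band.

A command-line interface wraps the same functions:

```sh
tirfpuncta simulate --config sim.yaml --out run/ --seed 1
tirfpuncta density  --movie run/movie.tif --pixel-size 0.16 --mask run/mask.tif
tirfpuncta events   --movie run/movie.tif --pixel-size 0.16 --out events.csv
tirfpuncta coloc    --ref chA.csv --other chB.csv --tolerance 1 --reference A
tirfpuncta pipeline --config run.yaml --out results/
```

`tirfpuncta.pipeline.run_pipeline` executes the whole chain with a single
seed and serializes every parameter next to its outputs; reruns with the
same config reproduce all CSVs byte-for-byte.

## Layout

```
src/tirfpuncta/
  synthetic_data.py   movie generator + ground-truth logs + presets
  image_io.py         calibrated movies, masks, segmentation, CSV/YAML
  detection.py        h-maxima spot detection, densities, spot intensity
  fluorometry.py      circle/annulus ΔF traces
  event_kinetics.py   linking, fusion detection, release duration, taxonomy
  spatial.py          peripheral-band zoning
  colocalization.py   centering colocalization + permutation control
  stats_report.py     one-tailed unpaired t, stars, per-cell summaries
  pipeline.py, cli.py orchestration and command-line interface
docs/methods.md       model, assumptions, numerical choices, limitations
```
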