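# conetrack

Multiscale quantification of microtubule plus-end dynamics in migrating
neuronal growth cones.

Growing microtubule plus ends recruit end-binding proteins (EB1/EB3),
which appear as short, bright "comets" in fluorescence time-lapse movies
of neurons expressing a tagged EB3. The motion of these comets reports
the rate, duration and location of microtubule polymerization — the
machinery that growth cones, the motile tips of extending neurites, use
to migrate and steer. `conetrack` implements the full analysis chain
for such movies, acquired as short rapid bursts (e.g. 33 frames at 2-s
intervals, to resolve comet motion) repeated at long intervals (every
10 min, to score net growth-cone displacement):

1. **Growth-cone segmentation** from the diffuse cytoplasmic signal of
   the EB3 fusion protein (Sobel edge detection + morphological
   cleanup + half-maximum boundary refinement), with per-frame
   morphology from the second-moment equivalent ellipse (area,
   perimeter, length, width, eccentricity).
2. **Landmark geometry**: the midline as the ridge of the interior
   distance transform (longest skeleton path), and the leading-edge
   "front" arc via a 1:1.7 front:rear division of the midline.
3. **Comet detection and tracking**: band-pass spot detection with
   sub-pixel centroids, then gap-closing trajectory linking under
   plus-end tracking constraints (search radius 1.5–6 px, minimum
   track length 3 frames, maximum gap 3 frames, shrinkage factor 1.4,
   forward/backward angular cones 35°/15°, fluctuation radius 1.25 px).
4. **Spatial mapping**: minimal Euclidean distances of each comet to
   the front and midline; anterograde / retrograde / lateral
   classification of net comet paths against the local midline tangent.
5. **Behavior scoring**: extension vs retraction per 10-min interval
   from signed tip displacement along the proximal→tip axis.
6. **Size-stratified statistics**: notch-style median confidence
   intervals (q₂ ± 1.57·IQR/√n), Wilcoxon rank-sum and bootstrap
   median-difference tests with Holm–Bonferroni correction,
   stratification into 20-μm² growth-cone-area bins (10–170 μm²), a
   sliding-window bootstrap (window 300, overlap 220) as a
   binning-artifact check, differential probability distributions
   (common histograms up to the pooled 97th percentile, bootstrap 5/95
   envelopes), and PCA of the growth-cone feature space.

Because public raw data for this kind of experiment is scarce, the
package ships a **synthetic time-lapse generator** that renders a
migrating growth-cone-shaped fluorescent blob containing moving
anisotropic comet spots, with exact ground truth for every comet
position, mask and behavior label. Every stage of the pipeline is
validated against this ground truth.

## Worked example

```python
import numpy as np
from conetrack import (SimulationConfig, make_schedule,
                       simulate_sequence, analyze_stack)

# canonical protocol: 33 frames / 2 s per burst, every 10 min, 30 min
schedule = make_schedule(33, 2.0, 600.0, 4, 0.211)
config = SimulationConfig(seed=1, migration_velocity_um_min=0.25)
stack, truth = simulate_sequence(config, schedule)

result = analyze_stack(stack, schedule)
tracks, behavior = result["tracks"], result["behavior"]
print(f"median comet speed: {tracks.median_speed_um_s.median():.3f} um/s "
      f"(truth {np.nanmedian(truth.comets.step_speed_um_s):.3f})")
for r in behavior.itertuples():
    print(f"bursts {r.burst_a}->{r.burst_b}: "
          f"tip {r.tip_displacement_um:+.2f} um -> {r.label}")
print(f"migration rate: {behavior.tip_displacement_um.mean()/10:.3f} um/min")
```

prints

```
median comet speed: 0.097 um/s (truth 0.089)
bursts 0->1: tip +2.53 um -> extension
bursts 1->2: tip +2.53 um -> extension
bursts 2->3: tip +2.11 um -> extension
migration rate: 0.239 um/min
```

The measured median speed sits a few percent above the ground-truth
median (localization noise inflates per-step displacements slightly;
see `docs/methods.md`), and the tip-displacement scoring recovers the
configured 0.25 μm/min extension within 5%, labeling every 10-min
interval as extension.

A command-line interface wraps the same stages:

```
conetrack simulate --n-bursts 4 --velocity 0.25 --seed 1 --out run/sim
conetrack analyze run/sim --n-bursts 4 --out run/analysis
conetrack all config.yaml          # full pipeline from a YAML RunConfig
```

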