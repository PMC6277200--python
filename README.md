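# midgut4d

Quantitative analysis of long-term 4D live-imaging movies of the adult
*Drosophila* midgut.

The adult fly midgut renews itself through stem-cell divisions, Notch-driven
enteroblast differentiation, and apical extrusion of spent enterocytes.
Extended live imaging of the organ inside the living animal produces
multi-hour, multichannel volumetric movies in which every nucleus can be
tracked; `midgut4d` implements the measurements that turn those tracked
movies into biology:

* **Cell typing** from combinatorial nuclear reporters: a ubiquitous RFP on
  all nuclei, a progenitor CFP (stem cells + enteroblasts), and a
  Notch-reporter GFP (enteroblasts).  Channel-mask arithmetic
  (stem = CFP ∧ ¬GFP, enteroblast = GFP, mature = RFP ∧ ¬CFP) plus a
  nuclear-volume filter (≤ 113 µm³ → enteroendocrine, > 113 µm³ →
  enterocyte) assigns each nucleus one of four types.
* **Extrusion morphometry**: the junctional ring outlining an extruding
  enterocyte is measured over time — cross-sectional area by centroid-fan
  triangulation (Σ ‖(vᵢ−c)×(vᵢ₊₁−c)‖/2), footprint projection onto the
  basal plane, signed centroid-to-plane distance — and the area series is
  decomposed into alternating constriction and relaxation/stabilization
  pulses (the *ratchet*), alongside onset/peak/recoil kinetics of apical
  nuclear travel.
* **Division orientation** in three reference frames: horizontal–vertical
  (spindle vs. basal plane, 0° = in-plane), longitudinal–circumferential
  (daughter axis vs. the tube's long axis), and enteroblast-relative
  (daughter axis vs. the axis to a flanking enteroblast).  Plus mitotic
  durations (condensation → decondensation) and the mitotic index
  T_M/T_SC — summed mitosis time over summed stem-cell screen time.
* **Notch-fate dynamics**: the normalized GFP:RFP metric (each channel
  divided by its per-movie maximum, then ratioed per cell per frame), the
  bimodal pooled distribution whose between-mode density minimum defines
  the stem/enteroblast fate threshold, benchmark validation against known
  (pre-mitotic) stem cells, persistent-crossing transition calling, and
  sibling-contact inference from inter-nuclear distance (< 6 µm contact,
  > 15.5 µm separated).
* **A synthetic-movie generator** that produces tracked-nuclei tables,
  annotation tables and rendered image volumes with all of the above
  structure and complete ground truth, so every stage of the pipeline is
  testable without any imaging data.

## Worked example

```python
import numpy as np
from midgut4d.synthetic import SimConfig, ExtrusionSpec, generate_extrusion_event
from midgut4d.extrusion import detect_pulses, ring_area
from midgut4d.divisions import mitotic_index, reorientation_events

cfg = SimConfig(rng_seed=2, frame_interval=5.0, n_frames=200)
ring, plane, nucleus, truth = generate_extrusion_event(cfg, ExtrusionSpec(0.0, 360.0, 6))
areas = [ring_area(ring["points"][i]) for i in range(len(ring["frames"]))]
dec = detect_pulses(ring["t_min"], areas)
print(dec.n_constrictions, round(areas[-1] / areas[0], 3))
print(round(mitotic_index([30.0], [{"stem_count_t0": 10, "duration_min": 600.0}]), 4))
print(reorientation_events([24, 60, 62, 2], threshold_deg=30))
```

prints

```
6 0.02
0.005
2
```

— the six scheduled constriction pulses are recovered from the ring-vertex
series and the ring closes to 2% of its initial area; a single 30-minute
mitosis among ten stem cells watched for 600 minutes gives a mitotic index
of 0.005 (0.5%); and the horizontal-vertical angle series 24°→60°→62°→2°
contains two re-orientations of at least 30°.

A full synthetic pipeline run (tracks, annotations, analyses, JSON report):

```bash
midgut4d run --seed 1 --out-dir out/
```

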