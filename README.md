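# cordmetrics

Quantitative analysis pipeline for rat spinal-cord lesion studies that
combine trichrome histology, antidromic electrophysiology, fluorescence
morphometry and postural video measurements — together with synthetic-data
generators that produce every input with programmed ground truth.

The package is aimed at labs quantifying how an implant (here a porous
reduced-graphene-oxide scaffold placed in a complete thoracic transection)
changes the lesion environment: how compact the collagen scar is, how
homogeneously regrowing neurites colonize the lesion, whether brainstem
neurons can be driven antidromically from below the injury, and how
whole-body posture changes.

## What it computes

**Histology** (`cordmetrics.histology`). Masson's-trichrome RGB sections
are reduced to *k* = 16 colours by k-means in RGB space; each cluster is
mapped to {background, collagen (blue), tissue (red-purple), scaffold
(black)} by a colour-family rule. Class areas and the blue/purple ratio
(collagen area / tissue area, background excluded) follow directly. The
collagen *compactness* of a blue pixel *p* is

```
C(p) = Σ_{q ∈ N_r(p)} I(q),   I(q) = (255 − gray(q)) / 255
```

the stain intensity (grey-scale complement; 255 = white = no stain) summed
over the (2r+1)² neighbourhood of *p*, with non-collagen intensities taken
as zero; the map is reported as collagen-area fractions in four levels
(0–25, 25–50, 50–75, 75–100 % of the per-image maximum). Spatial
homogeneity of a colonization mask is scored by a distributional
homogeneity index: for macropixel sizes *s* in a dyadic ladder,

```
H_s = RMS(c_b − c̄) / c̄ ,    DHI = 100 · mean_s H_s
```

where *c_b* are *s*×*s* block coverages and *c̄* the global coverage —
0 for exactly uniform coverage, high for border-concentrated layouts.

**Electrophysiology** (`cordmetrics.ephys`). Raw traces are band-passed
500–5000 Hz (zero phase), spikes detected at a baseline mean + 3 SD
threshold, and per-stimulus first-spike responses tabulated.
Peri-stimulus time histograms use 1 ms bins normalized to % of stimuli;
response efficiency is 100 · responses / stimuli. A unit is classified
**antidromic** when it meets at least two of: (1) constant latency and
amplitude, (2) reliable following of >100 Hz stimulation, (3) a positive
collision test (a spontaneous orthodromic spike just before the expected
antidromic arrival blocks the antidromic spike). Responsive units failing
the criteria are **synaptic**; units whose "responses" are only uniformly
scattered chance crossings are **unresponsive**. Conduction velocity is
path length / latency (mm/ms ≡ m/s).

**Morphometry** (`cordmetrics.morphometry`). Binary vessel/neurite masks
are measured per 8-connected component: skeleton-based neurite length,
tube-model vessel width and centreline length, rostro-caudal extent, and
total length per image.

**Posture** (`cordmetrics.posture`). From eye/shoulder/hip landmarks: the
cervico-thoraco-lumbar angle (interior angle at the shoulder between the
shoulder–eye and shoulder–hip lines) and the trunk alignment angle
(unsigned angle between the shoulder–hip line and the ground direction),
plus per-animal movement ranges and categorical prevalence summaries.

**Synthetic data** (`cordmetrics.simulate`). Seeded generators for
trichrome images with exact class fractions and controllable collagen
layout, recordings with a stimulus-locked unit (programmable latency,
jitter, response probability, collision blocking) plus spontaneous
spikes, disjoint neurite/vessel masks with known lengths and diameters,
and landmark scenes with exact programmed angles.

## Worked example

```python
import numpy as np
from cordmetrics import (
    SynthHistologyParams, gen_trichrome_image, cluster_colors,
    classify_clusters, quantify_areas, blue_intensity, compactness,
    bin_compactness, conduction_velocity,
)
from cordmetrics.histology import TissueClass
from cordmetrics import scenarios

params = SynthHistologyParams(width=256, height=256,
                              collagen_layout="clustered", seed=7)
image, truth = gen_trichrome_image(params)
model = cluster_colors(image, k=16, seed=7)
classmap = classify_clusters(model)
report = quantify_areas(classmap, pixel_size=params.pixel_size)
print(f"blue/purple ratio: {report.blue_purple_ratio:.3f} "
      f"(true {params.frac_collagen / params.frac_tissue:.3f})")

intensity = blue_intensity(image, classmap)
cmap = compactness(intensity, radius=1,
                   mask=classmap.classes == TissueClass.COLLAGEN)
hist = bin_compactness(cmap, pixel_size=params.pixel_size)
print("compactness level fractions:", np.round(hist.level_fractions, 3))

for kind in ("antidromic", "synaptic", "unresponsive"):
    label = scenarios.classify_unit(kind, seed=0, noise_sd=20.0)
    print(f"simulated {kind:12s} unit -> classified {label}")

print(f"57.3 mm / 3.0 ms -> {conduction_velocity(57.3, 3.0):.1f} m/s")
```

prints

```
blue/purple ratio: 1.200 (true 1.200)
compactness level fractions: [0.   0.   0.04 0.96]
simulated antidromic   unit -> classified antidromic
simulated synaptic     unit -> classified synaptic
simulated unresponsive unit -> classified unresponsive
57.3 mm / 3.0 ms -> 19.1 m/s
```

The synthetic section is recovered with its programmed collagen/tissue
ratio; nearly all collagen area sits in the top compactness level because
the clustered layout packs stained pixels together; the three simulated
unit archetypes are classified correctly at signal-to-noise 5; and a
3 ms antidromic latency over a 57.3 mm spinal path corresponds to a
19.1 m/s conduction velocity.

A `cordmetrics` console script exposes the stages
(`simulate`, `histology`, `ephys`, `morpho`, `angles`, `report`); the
`report` subcommand runs the whole simulate-then-analyze pipeline from a
YAML config and writes a manifest whose hash is reproducible under a
fixed seed.

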