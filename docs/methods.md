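# Methods

This note documents the models, conventions and numerical choices behind
cordmetrics, in the spirit of the methods documentation of packages like
statsmodels or scanpy: what each procedure assumes, which parameters
matter, and what the synthetic-data tests do and do not demonstrate.

## Trichrome colour segmentation

Sections are clustered in raw RGB with k-means (k = 16 by default,
seeded; the clustering is per image, never pooled across images). Pixel
labels are re-derived as nearest-centroid assignments with ties broken
toward the lowest cluster index, so the nearest-centroid invariant holds
exactly even if the k-means iteration stops early. Clustering operates on
the distinct colours weighted by abundance, which is exact and much
faster on palette-like images.

Centroids map to tissue classes by colour families: background when all
channels ≥ 220 (near white); scaffold when all channels ≤ 60 (near
black) — or, in a no-scaffold configuration, such dark centroids go to
tissue and are flagged for review; collagen (blue) when B is the dominant
channel and B − R ≥ δ (δ = 20 by default); tissue (red-purple) when both
R and B exceed G by δ. A centroid matching no family falls back to the
nearest of four prototype colours and is recorded in an audit table.
Areas are pixel counts × (pixel size)²; the blue/purple ratio is collagen
area over tissue area after excluding background, flagged undefined when
no tissue pixels exist.

## Collagen compactness

Stain intensity of a collagen pixel is the complement of its luminance,
(255 − gray)/255, because in grey scale 255 is white (no stain).
Luminance uses the 0.299/0.587/0.114 weights. Compactness sums the
intensity over a square (2r+1)² window centred on the pixel (own value
included; r = 1, the 8-neighbourhood, by default; diagonals included).
Border pixels use the in-image part of the window. Non-collagen
intensities count as zero, and non-collagen pixels carry no compactness.

*Numerical contract.* Intensities are quantized on an exact 1/255 000
grid (integer per-mil luminance weights 299/587/114 over a 0–255 000
range), and window sums are accumulated in 64-bit integers with one
float division at the end. Sums are therefore exact and independent of
summation order — the implementation (an integer convolution) agrees
bit-for-bit with a brute-force double loop, which the tests exercise on
random maps up to 64×64. The quantization (resolution ≈ 4·10⁻⁶) is far
below any meaningful stain-intensity difference.

The compactness histogram uses four bins at quarters of the per-image
maximum compactness; fractions are of collagen area and sum to 1. A map
whose maximum is 0 (all-white collagen) puts all area in the lowest
level. An image with no collagen yields an empty-histogram flag.

## Distributional homogeneity index

For each macropixel size *s* the mask is tiled with non-overlapping
*s*×*s* blocks (edge remainders trimmed) and the per-scale heterogeneity
is the RMS deviation of block coverage from the trimmed-region global
coverage, divided by that coverage. The index is the mean over scales
× 100. This convention satisfies the properties that matter for
interpretation: it is 0 only when every block equals the global coverage,
invariant to permuting block positions at a fixed scale, and strictly
higher for border-concentrated than for uniform layouts at matched
density. The default ladder is dyadic from 4 px up to a quarter of the
short image side: single-pixel-scale blocks carry no layout information
for sparse colonization masks and would only dilute the contrast between
layouts. Absolute DHI values depend on image size, coverage and the
ladder, so only comparisons under a fixed convention are meaningful;
cross-study absolute values are not.

## Spike detection and response bookkeeping

Traces are band-passed 500–5000 Hz with a 4th-order zero-phase
Butterworth filter (`sosfiltfilt`), preserving latencies. The detection
threshold is baseline mean + 3 SD on the polarity-adjusted signal
(negative deflections by default, per extracellular convention), over a
baseline window that must contain no stimuli. Supra-threshold runs
closer than the refractory period (1 ms) merge, and each group reports
its peak sample. Note that a mean + 3 SD threshold intrinsically yields
chance crossings on pure noise (the one-sided 3σ tail); downstream logic
is designed around that fact rather than pretending detection is clean.

The response table records the first spike in a per-stimulus window
(default 0.5–10 ms; the start doubles as stimulus-artifact blanking).
Windows are truncated at the next stimulus onset so consecutive windows
never overlap — this is what makes mixed low/high-frequency protocols
analysable, since a 200 Hz train leaves only 5 ms per stimulus. A window
start that leaves no room before the next stimulus is rejected.

PSTHs use half-open 1 ms bins with time 0 at stimulus onset, normalized
to % of stimuli. Efficiency is 100 · responded/stimuli.

## Antidromic criteria and classification

1. **Constant latency and amplitude**: sample SD of response latencies
   ≤ 0.3 ms and amplitude CV ≤ 0.3 (defaults; at least 5 responses,
   otherwise indeterminate). Trials whose first-window spike deviates
   from the median latency by more than max(5 × MAD, 0.5 ms) are excluded
   first — the automated stand-in for trial-by-trial waveform
   verification, which rejects coincident spontaneous events without
   masking genuinely jittered units (for jitter ≥ ~1 ms the MAD window
   keeps the spread and the criterion still fails, as it should).
2. **High-frequency following**: efficiency ≥ 90 % among trials at
   ≥ 100 Hz; indeterminate without high-frequency trials.
3. **Collision test**: a trial is a collision trial when a spontaneous
   spike (a detected spike outside every response window) falls within
   the critical window before the expected antidromic arrival (default:
   expected latency + 1 ms refractory). The test passes when the
   antidromic response (a response within ±0.5 ms of the expected
   latency) is absent in 100 % of collision trials (configurable) and
   present in at least 50 % of non-collision trials; with no collision
   trials it is indeterminate.

A unit is antidromic when ≥ 2 criteria are met (indeterminate counts as
not met). Otherwise it is synaptic if its responses are *time-locked*,
else unresponsive. Time-locking is a chi-square test of the first-spike
latency histogram (1 ms bins over the response window) against
uniformity at α = 10⁻³: chance crossings scatter uniformly, genuine
evoked responses — even jittered synaptic ones — concentrate. This
replaces a naive "any responses → responsive" rule, which the 3σ
threshold's chance crossings would render useless on noisy recordings.

Caudal responsiveness follows the weaker screening rule: any
post-stimulus PSTH bin exceeding the mean + SD of the pre-stimulus bins.
Its null false-positive rate is high by construction (an any-bin rule
with a 1σ margin); the test suite measures this on rate-matched Poisson
nulls and bounds it loosely rather than claiming specificity the rule
does not have.

Conduction velocity divides the stimulation-to-recording path length
(mm) by the response latency (ms), which is numerically identical to
m/s. Cohort summaries aggregate per-animal unit counts into per-group
totals, means and caudal-respondent percentages.

## Morphometry

Components are 8-connected; specks below `min_size` (10 px) are removed
at segmentation. Neurite length is measured on the skeleton: orthogonal
and diagonal step counts (with redundant corner diagonals skipped) are
recombined as `hypot(n_orth + n_diag, n_diag) + 1` px. This is exact for
digital straight segments at any orientation — a plain 1/√2 step sum
overestimates shallow-angle lines by up to 8 % — and the +1 makes an
axis-aligned n-pixel segment measure exactly n pixels (pixel-extent
convention, matched by the generator's ground truth). For curved
skeletons the estimator assumes local monotonicity; strongly zigzagging
paths would be underestimated.

Vessels use a tube (capsule) model: with extent *E* along the
component's principal (PCA) axis and pixel area *A*,
`A = (E − d)·d + (π/4)·d²` is solved for the width *d*, and the
centreline length is `E − d` (+1 px). This is orientation-independent,
unlike the raster distance transform, which reads a diagonal 10 px tube
as ~11.3 px (the nearest background pixel lies on a diagonal lattice
step). Both estimators recover generator truth within ±5 % (lengths)
and ±10 % (diameters) on the synthetic masks; on real images, branching
or strongly curved vessels violate the capsule assumption and the
numbers should be read as effective widths/lengths.

Rostro-caudal extent is the bounding extent along the declared image
axis (rows or columns), in µm.

## Postural angles

Coordinates are image pixels with y increasing downward; the ground
direction is supplied per scene (rather than assumed horizontal) so
camera tilt can be corrected. The cervico-thoraco-lumbar angle is the
interior angle at the shoulder between the shoulder→eye and
shoulder→hip vectors, in (0°, 180°]; the trunk angle is the unsigned
angle between the shoulder–hip line and the ground, in [0°, 90°] — it is
reported as an alignment magnitude, not a signed deviation. Both are
invariant under translation, rotation (ground co-rotated) and uniform
scaling; coincident landmarks or a zero ground vector raise geometry
errors. Movement ranges need at least 3 frames per animal. Prevalence
summaries export a 2×k contingency table for external χ² testing; the
test itself is deliberately out of scope.

## Synthetic-data generators

All generators draw every random quantity from a single seeded
`numpy.random.Generator`; identical parameters and seed give
bit-identical outputs.

*Trichrome images.* Class pixel counts are apportioned by largest
remainder, so realized fractions are exact to one pixel. Collagen
placement is uniform, clustered (pixels nearest to random blob centres),
or border (pixels nearest to the image edge); other classes fill the
remainder uniformly. Colours are per-class palette RGB plus Gaussian
noise (SD 6), clipped to 8 bits. The default palette keeps the four
colour families separable under the default rule thresholds.

*Recordings.* Spikes are a biphasic 1 ms template (dominant negative
lobe; spike times refer to the negative peak) — sampled waveforms, not
membrane models — which requires ≥ 8 samples/ms, hence a minimum 8 kHz
rate. Stimulus trains are blocks of (frequency, count) separated by
0.5 s, after a 1 s stimulus-free baseline. Responses are Bernoulli per
stimulus (optionally different at ≥ 100 Hz), with Gaussian latency
jitter. Spontaneous spikes are Poisson with a 2 ms refractory, or
planted at explicit times. Collision semantics: when a spontaneous spike
falls within the collision window (default latency + 1 ms) before the
expected antidromic arrival, the antidromic spike is omitted and the
trial flagged collided. The stimulus artifact (a square transient of
configurable amplitude and width) defaults off, since analysis windows
begin after a blanking interval anyway.

*Structure masks.* Structures are straight segments — 1 px lines for
neurites, capsules (pixels within d/2 of the segment) for vessels —
drawn without anti-aliasing so truth is exactly countable, placed
disjointly with ≥ 2 px separation by rejection sampling (a capacity
error after 300·n attempts). Truth records the pixel-extent length
(endpoint distance + 1 px), the requested diameter and the
rostro-caudal extent.

*Landmark scenes.* The shoulder is placed randomly, the hip along a
direction making exactly the requested trunk angle with the ground, and
the eye along the hip direction rotated by exactly the requested
interior angle, so recomputed angles match to machine precision.

## What the synthetic tests do and do not show

The generators emulate the *structure* of the real data — stimulus-locked
units with collision blocking, colour-separable stain classes, disjoint
tubular structures, exact landmark geometry — not its texture: real
sections have stain gradients, out-of-focus blur and touching structures;
real recordings have drifting baselines, stimulus artifacts and
overlapping units; real landmarks carry digitization error. Passing the
recovery tests therefore demonstrates correctness of the computations
and their conventions under known ground truth, not robustness to every
real-world artifact. Problem sizes in the tests (256² images, ~10²
stimuli per protocol, ≤ 25 structures per mask) were chosen as the
smallest scales at which the statistical contrasts of interest are
stable.

## Degenerate inputs and tie-breaks

Fractions must sum to 1 (±10⁻⁹); an all-background image yields zero
areas and an undefined ratio flag; an empty mask yields zero morphometry
and an undefined DHI flag; k-means ties go to the lowest cluster index;
`argmin`/`argmax` resolve remaining ties to the first occurrence;
responses are indeterminate (None) — never silently false — when a
criterion's preconditions fail (too few responses, no high-frequency
trials, no collision trials).
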