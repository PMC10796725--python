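# Methods

## Micrograph morphometry

### Model of the image

A 5000X FESEM field of a longitudinally cut rice grain shows bright
compound-starch-granule matter separated by dark inter-granular gaps. A
gap pixel is either a *pore* (true empty space) or a *shadow* (partial
occlusion by a raised granule edge on the side facing away from the
implicit illumination). Porosity is the percentage of the analysed area
that is true pore; shadows belong to the denominator but never the
numerator. Calibration (µm/px) is a required input, supplied per image by
a metadata sidecar — it is never inferred from nominal magnification,
because the physical pixel size depends on the acquisition settings, not
on the magnification label alone.

### Segmentation

Intensities are smoothed with a small Gaussian (default σ = 0.7 px — wide
enough to suppress single-pixel noise, narrow enough not to close the
2–4 px gaps typical at the porosity levels of interest) and thresholded
with Otsu's method (a percentile threshold is available for pathological
histograms). Two guards wrap the threshold:

* a constant image raises a "no structure detected" error;
* if the two threshold classes differ by fewer than 3.5 granule-class
  standard deviations, the field is treated as uniform granule matter
  with no voids (splitting unimodal noise at its Otsu threshold yields a
  class separation of about 2.7 within-class sds, well below real
  granule/void contrast, which is > 5 in all our synthetic conditions).

Granule regions smaller than a minimum area (default 1 µm²) are merged
into the surrounding void and void specks below a separate, much smaller
minimum (default 0.02 µm²) are filled: granules have a physical minimum
size, but gaps can legitimately be thin. Touching granule matter is
optionally split into compound-granule wedges by a marker-based watershed
on the Euclidean distance transform (markers from distance-transform
peaks at a minimum separation, default 2 µm). Watershed occasionally
leaves diagonal-neck pixels unlabelled; these are assigned to the nearest
labelled pixel so that granule + pore + shadow + background exactly
partition every image — an invariant enforced by the label container
itself.

### Pore versus shadow

The decision uses two rules with configurable thresholds:

a. **brightness** — a void pixel above the *pore ceiling* (midpoint
   between the pore mode and the granule mode of the intensity
   histogram) is shadow: partial occlusion still returns signal, true
   empty space returns almost none. Because the dark tail of a shadow
   ramp dips below the ceiling while remaining well above pore grey, the
   supra-ceiling seed is grown by hysteresis into connected void pixels
   above a floor halfway between the pore mode and the ceiling.
b. **ramp** — a connected sub-ceiling void region whose intensities rise
   monotonically with distance from the nearest granule edge (Spearman
   rank correlation > 0.6, at least 12 pixels) is shadow: a cast shadow
   is darkest against the occluding edge and fades outward. Regions whose
   median absolute deviation is zero (flat grey with a few boundary
   outliers) are never ramps.

Rule (a) is evaluated per pixel rather than per connected component. In a
packed section the gap network is a single connected component containing
both pores and shadows, so a component-level vote would assign the whole
network to one class; pixel-level brightness with hysteresis and
region-level ramp detection keeps the two rules' semantics while staying
well-defined on connected networks. A consequence is that bright
granule-boundary pixels mis-assigned to the void by the threshold end up
in the shadow class — which is exactly where they do no harm, since
porosity counts them in the denominator either way.

### Shape descriptors and aggregation

Per-granule area is the pixel count times the pixel area; perimeter,
moment-ellipse eccentricity and centroid come from standard region
properties; circularity is 4πA/P², clipped at 1 (coarse rasterisation
can push the estimate slightly above the analytic bound); the equivalent
diameter 2√(A/π) is reported half-up to 2 decimals, matching report-table
precision. Granules touching the field border are flagged and excluded
from shape statistics but their pixels count toward porosity: truncation
biases shape, not area fractions.

Field summaries average within grain, grain means average within
endosperm region, and the variety value mixes the chalky and crystalline
region means as w·chalky + (1 − w)·crystalline with w the externally
supplied chalky volume fraction (a visual estimate; estimating it from
images is out of scope). The weighting applies to porosity and all shape
means alike and can be switched off. Across-grain standard deviations are
propagated through the fixed-weight combination. A field whose granule
matter is one unsplittable region filling > 95 % of the non-void area
*and* > 90 % of the whole analysed area is flagged *compact* — the waxy /
very compact endosperm case where granules are indistinguishable — and
its shape features are reported missing while porosity remains valid.
(The second condition keeps a lone granule in a sparse field from being
mislabelled compact.)

## Glycemic Index

Baseline is the mean of the fasting samples (−5 and 0 min). IAUC is the
trapezoidal area of max(G(t) − baseline, 0) over t ≥ 0, with segments
that cross the baseline split at the linearly interpolated crossing time
— the standard incremental-AUC convention that makes the result exact
for piecewise-linear curves. Per subject GI = 100 · IAUC(test) / mean
IAUC(reference repetitions); a subject with non-positive mean reference
IAUC is a non-responder, excluded and recorded. The study GI is the
arithmetic subject mean with sample (n − 1) sd (undefined and flagged for
a single subject). Class cut-offs: ≤ 55 low, ≥ 70 high, otherwise medium
— the conventional printed cut-offs leave (55, 56) formally unassigned;
we close the gap on the medium side. Curves with missing grid points are
rejected rather than imputed: an 8-point grid is too short to impute
defensibly.

## Correlations and PCA

Correlations are pairwise-complete Pearson r with the n used always
reported; a constant column or fewer than 3 complete pairs yields an
explicitly undefined result, never a silent number. PCA drops rows with
any missing retained variable (recording which), autoscales the remainder
(zero mean, unit sample sd per column), and decomposes by SVD. Loadings
are orthonormal; explained variance percentages are non-increasing and
sum to 100 at full rank; component signs are fixed so each component's
largest-magnitude loading is positive (signs are otherwise arbitrary).
The censored amylose entry of the waxy variety ("< 5 %") is imputed at
the interval midpoint 2.5 % by default, with exclude/0/5 alternatives
behind a switch; the correlation of amylose with GI is negative under
every policy.

One reported correlation — ashes against granule eccentricity over the
full GI panel — cannot be confirmed from the packaged tables: the
eccentricity column spans only 0.69–0.74 at two printed decimals, so
cell-rounding noise alone moves that r over roughly ±0.09, far beyond the
±0.02 agreement the other pairs achieve. The recomputed value (0.48 on
the 21 varieties with printed eccentricity) is reported as-is next to the
published one; the variant excluding the high-ash outlier variety does
agree within ±0.02.

## Synthetic data

### Micrographs

Granules are the cells of an anisotropic Voronoi tessellation: each of
n seeded centres carries an orientation and a lognormal aspect ratio
(median 1.5), and a pixel joins the cell with the smallest area-preserving
elliptic distance, which yields the polygonal, moderately elongated
wedges seen in real sections (moment eccentricity around 0.7). A pixel is
void when the difference of its two smallest centre distances falls below
a gap width, bisected until the pore fraction matches the programmed
porosity — the achieved value is recorded in the ground truth and matches
the programme to well under 0.5 points. Gap segments whose boundary
normal is within 40° of the illumination azimuth (default 35°) are
shadows, rendered as a monotone ramp from 35 % of the pore→granule span
at the occluding edge to full granule brightness at the far edge.
Interiors are flat granule grey (0.75) with small per-granule jitter,
pores are dark (0.15), and Gaussian noise (sd 0.05) is added after the
ground truth is frozen. Defaults: 384 px square at 0.05 µm/px (a 19.2 µm
window) with 60 granules, i.e. wedges of roughly 2–3 µm — the
single-granule scale; the porosity defaults span the 0.4–6.7 % range
observed across varieties. Everything is a pure function of seed and
parameters (bit-reproducible).

What the generator does *not* emulate: real FESEM surface texture,
membrane films over granules, protein bodies, charging artefacts, or cut
damage. Passing recovery tests therefore demonstrates the pipeline's
correctness on images with the assumed two-mode intensity structure and
geometric shadow model, not robustness to every real-world artefact.

### Glycemic curves

Each subject draws a fasting baseline (normal, mean 4.8, sd 0.3 mmol/L,
clipped to the healthy 3.5–5.4 range), a reference peak height (normal,
mean 3.3, sd 0.6 mmol/L above baseline) and a peak time (30 or 45 min).
The excursion rises piecewise-linearly to the peak and decays
exponentially with the time constant set so it has fallen to ~5 % of the
peak by 120 min. All reference repetitions share the subject's noise-free
profile; each test food's excursion is that profile scaled by programmed
GI / 100, so the noise-free per-subject GI equals the programmed GI
exactly and any recovery error is attributable to noise. Measurement
noise is additive Gaussian, sd 0.15 mmol/L — about a 3 % CV at the
fasting level, matching glucometer quality-control figures. Under the
default 10-subject, 3-repetition conditions this produces per-subject GI
spreads of roughly 8–10 GI units (comparable to reported inter-subject
variability) and a study-level bias below 1 GI unit across 200 replicate
trials.

## Problem sizes and numerical choices

Synthetic fields are 384 px square (recovery experiments use 20 fields;
unit tests use 192–256 px); trials use 10 subjects × 3 repetitions with
200 replicates for bias estimates — sizes chosen to make every
experiment reproducible in seconds to minutes on a single core while
keeping estimator spreads small against the tolerances tested.
Rounding for report output is half-up to 2 decimals. Porosity bisection
runs 60 iterations (resolution far below one pixel of gap width). The
watershed marker separation, intensity thresholds, ramp correlation
cut-off and hysteresis floor are all exposed in the parameter
dataclasses and echoed by the CLI log.

## Known limitations

* The segmentation is a declared replacement for the study's undisclosed
  MATLAB pipeline, not a reconstruction of it; agreement is established
  against synthetic ground truth, not against the original tool.
* Whether the porosity denominator of the original analysis included
  shadow pixels is unknown; we include them (excluding them would raise
  porosity by the shadow fraction of the analysed area).
* Protein bodies and small granules are not distinguished.
* Sub-pixel gaps (porosity well below ~1 % at the default packing) are at
  the resolution limit and are recovered as near-zero porosity.
* How the printed per-variety standard deviations combine grain-level and
  field-level variation is not documented; we report across-grain sds of
  grain means.
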