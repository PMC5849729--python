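# Methods

`eggcount` automates egg counting for Drosophila fecundity assays in which
flies lay on Petri dishes of dark, charcoal-containing ("high-contrast")
medium photographed from above against a white background. The pale eggs are
bright ellipses on a nearly black disk, which reduces counting to particle
analysis: find the dish, binarize its interior, measure each bright connected
component, and separate eggs from dust and from clusters of touching eggs by
particle area.

## Per-image chain

1. **Grayscale.** Color frames are reduced to 8-bit gray as a rounded
   weighted channel sum. Default weights are equal (an unweighted RGB mean);
   Rec. 601 luma weights (0.299, 0.587, 0.114) are available. The choice is
   immaterial for the high-contrast scene as long as it is held constant
   across a batch.
2. **Plate ROI.** The frame histogram of such scenes is strongly bimodal
   (white background vs dark medium). The dark threshold defaults to the
   midpoint between the two highest modes of the smoothed (σ = 3 gray
   levels) histogram, with a fixed-value override. A seed-free global split
   was chosen over wand-style region growing because it needs no seed point
   or tolerance and is fully deterministic. Among dark connected components,
   the largest one that covers ≥ 10% of the frame and has circularity
   4π·area/perimeter² ≥ 0.8 (perimeter via the weighted boundary estimator,
   which is close to the true contour length for smooth shapes) is accepted;
   its holes are filled **before** the centroid/radius fit — eggs are bright
   holes in the dark disk and belong to the dish interior. Fitted center =
   mask centroid; fitted radius = √(area/π). If no candidate passes, the
   error reports the best candidate's circularity and area.
3. **Binarization.** Foreground = pixels strictly above a threshold AND
   inside the ROI. The default policy is Otsu's between-class variance
   maximization computed over ROI pixels only (background pixels would
   otherwise dominate the histogram); ties are broken toward the smallest
   maximizing threshold for determinism. A fixed threshold is available for
   reproducing legacy settings.
4. **Particle measurement.** Connected components (8-connectivity default,
   so thin diagonal contours do not fragment; 4 available) are measured
   with: area = pixel count; centroid = mean pixel coordinates (x = column,
   y = row, origin top-left); perimeter = crack length, i.e. the count of
   foreground pixel edges exposed to the exterior — simple, exactly
   testable, and monotone under dilation (corner-weighted perimeters are a
   deliberate non-goal since nothing downstream consumes perimeter); and an
   area-preserving moment ellipse: second central moments with a +1/12
   per-pixel variance term (the variance of a unit square about its center),
   axis *ratio* √(λ₁/λ₂) from the eigenvalues, axes rescaled so
   π·(major/2)·(minor/2) equals the pixel area exactly, orientation
   ½·atan2(2μ₁₁, μ₂₀−μ₀₂) reported in [0°, 180°). Single-pixel particles
   degenerate to the unit-area circle equivalent (major = minor = 2/√π,
   angle 0) and carry a flag.
5. **Area filter.** Particle areas on a plate are bimodal on a log scale:
   a dust mode well below one egg, and an egg mode. A Gaussian KDE
   (Silverman bandwidth) is evaluated on a 512-point grid over the log-areas
   padded by three bandwidths; the two highest local maxima are the modes
   and the density minimum between them, back-transformed, is the dust/egg
   cutoff. The valley must fall below half the lower mode's density,
   otherwise the distribution is declared unimodal — this prominence rule
   stops shallow KDE ripples inside a pure dust cloud (an egg-free plate)
   from being read as bimodality. Anything above cluster_factor × egg-mode
   area (default 1.75; two touching eggs have roughly twice one egg's area,
   so a cutoff below 2× and above single-egg variation separates singles
   from pairs) is a cluster; ties at the dust cutoff count as dust
   (conservative against dust false positives). Clusters are *excluded*,
   not apportioned, so counts are deliberately biased downward at very high
   laying densities — the documented behavior of this class of pipeline.
   Fitting is per image by default; a pooling option fits once across a
   batch, which low-count images (fewer than 10 particles) cannot support
   alone. When the fit fails (too few particles or no second mode), fixed
   cutoffs from configuration take over; `FilterConfig.from_nominal_egg_area`
   derives them from a nominal egg area by the same 0.25×/cluster_factor×
   rule the fitted partition applies to its estimated mode.

## Batch processing and validation

Directory trees are traversed depth-first in lexicographic order; a
case-insensitive extension filter (default ".JPG", camera firmware vs OS
case conventions) selects inputs, and ancestor directory names are mapped
onto a user-declared metadata schema (e.g. population/transfer/treatment).
Each image yields a particle CSV named by joining its relative path
components with underscores (name collisions abort before processing); a
combined summary CSV carries metadata plus counts and fitted cutoffs.
Per-image failures are recorded and never abort the batch. Outputs are
byte-reproducible; timestamps are confined to the run log.
Manual-vs-automated concordance uses Spearman's ρ with average ranks for
ties, requiring ≥ 3 pairs and non-degenerate variance.

## Synthetic plates

The generator emulates the assay scene so that every stage has ground
truth: a dark disk (default radius 420 px in a 1024×1024 frame — a
desk-scale stand-in for >15 MP frames; all algorithms are
resolution-agnostic) on a white background, eggs as bright filled ellipses,
dust as small bright specks, plus medium texture, a linear horizontal
illumination gradient (±2.5% at defaults) and additive Gaussian pixel noise
clipped to [0, 255]. Egg geometry defaults to major 24 px and aspect ratio
2.5, a plausible rendering of a ~0.5 mm egg at ~30 cm camera distance
scaled to the test frame; the exact values are assumptions, not measured
facts, and correctness never depends on them because the planted parameters
are recorded. Size and aspect draws are truncated at ±2σ: real eggs of one
species are close to uniform in size, and untruncated tails would let rare
single eggs cross the cluster cutoff, which would misrepresent the filter
rather than the biology.

Placement rejection-samples centers uniformly over the disk and tests the
candidate's rendered pixel footprint against a 1-px-dilated occupancy mask,
which guarantees that separately planted objects never touch at
8-connectivity (each non-clumped egg is one maximal component by
construction) while permitting realistic densities; 5000 attempts per
object before a placement error. Clump members are placed within
0.45·minor of a common anchor: any two members then sit closer than one
minor axis apart, so their pixel sets always overlap and the clump renders
as a single oversized particle. Dust areas (2–12 px²) sit strictly below
the smallest egg (~120 px² at defaults), so the filter's bimodal assumption
holds by construction. A single global seed with per-image sub-seeds
(seed + index) makes series reproducible without coupling images.

What the generator does *not* model: yeast paste, bubbles, reflections,
lens distortion, perspective, or real sensor noise statistics. Passing
tests therefore demonstrate the correctness of the algorithmic chain under
the scene model's assumptions (dark circular dish, bright well-separated
eggs, small dust, bimodal areas), not performance on arbitrary real
photographs, where thresholds and cutoffs may need the provided
configuration hooks.

## Numerical choices and limitations

- Foreground is *strictly above* the threshold; ROI darkness is *strictly
  below*; the dust rule is inclusive at the cutoff. All ties are resolved
  deterministically (smallest Otsu maximizer, first-listed KDE modes).
- Problem sizes in the test suite and the reproduction script (30–50 plates
  at 1024×1024, series of 20) were chosen as the smallest sets that
  exercise the density range 0–600 eggs per plate; results are insensitive
  to the exact counts.
- Clusters are never decomposed into estimated egg numbers
  (cluster_area / egg_mode would be an obvious extension); the pipeline
  reproduces the exclude-clusters behavior by design, hence the downward
  bias at >500 eggs that the validation quantities document.
- Scale calibration from a visual mark is optional and off by default; the
  mark's pixel length is user-supplied, not auto-detected.
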