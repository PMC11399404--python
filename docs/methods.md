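# Methods

## The quantification model

`tmaquant` counts marker-positive cells on dearrayed tissue-microarray
(TMA) core images from single-plex chromogenic immunohistochemistry:
hematoxylin counterstain plus a DAB-labelled antibody (CD3, CD8, PD-L1,
p53, ...). Per core the pipeline is:

1. **Core disk detection.** The ~1 mm tissue disk is located by a Hough
   circle transform over a Canny edge map. The search runs on a 4x
   downscaled image over radii spanning a configurable fraction range
   (default 0.55–0.98 of half the image's short side) and is refined at
   full resolution in a narrow radius window, with voting restricted to
   an annulus around the coarse circle so the refinement cost scales
   with the rim length, not the tissue content. The accumulator is
   perimeter-normalised, so the peak value is the fraction of the circle
   supported by edges; peaks below 0.3 mean "no circle" and the core is
   flagged rather than quantified. The detected centre and radius define
   the coordinate frame used by every later stage (0-based pixel
   indices, x rightward, y downward, points at pixel centres).

2. **Colour deconvolution.** Chromogenic stains attenuate light
   multiplicatively, so stain contributions add in optical density,
   OD_c = −log10((I_c + 1)/256) per 8-bit channel (the +1 guard keeps
   black finite at OD ≈ 2.408 and maps pure white to exactly 0).
   Per-pixel stain concentrations solve OD = M·c where the columns of M
   are the unit OD vectors of hematoxylin (0.650, 0.704, 0.286), DAB
   (0.269, 0.568, 0.778) and their normalised cross product as the
   residual axis — the standard H-DAB matrix of Ruifrok & Johnston,
   overridable per marker. Negative concentrations are clipped to zero.

3. **Triangle thresholding of the DAB layer.** A per-image threshold
   accommodates staining intensity differences between cores and TMA
   blocks. The histogram (256 bins over [0, max]) is thresholded at the
   bin of maximal perpendicular distance to the line from the histogram
   peak to the furthest non-empty bin on the longer-tailed side (ties to
   the high-OD side, where DAB signal lives); distances are computed in
   coordinates normalised so the peak-to-tail span is 1 on both axes,
   making the construction scale-equivariant: multiplying the channel by
   k scales the threshold by k and leaves the mask unchanged. The
   histogram is restricted to pixels inside the detected disk (the white
   background would otherwise dominate the peak); the mask covers the
   whole image. A degenerate single-bin histogram yields an empty mask
   with a warning.

   One guard sits in front of the thresholder inside `quantify_core`: if
   the 99.99th percentile of in-disk DAB OD is below 0.15 (configurable
   `min_dab_signal`), the layer is treated as signal-free and the mask
   is empty. A triangle threshold on a pure-noise channel necessarily
   lands inside the noise distribution and would call noise pixels
   positive; a genuinely stained core (even a single positive cell of
   ~100 px at the default geometry) clears the percentile easily.

4. **Nuclei segmentation.** Cell detection runs on the hematoxylin
   concentration channel through a pluggable backend contract (same
   input ⇒ same ordered cell list, always). Three backends ship:
   * `log` (default): multi-scale Laplacian-of-Gaussian blob detection
     (scales spanning the configured nucleus radius range, default 5–10
     px; scale-normalised response cut 0.15 OD above the median
     hematoxylin level; overlap-based non-maximum suppression). Blobs
     within 12 px of the detected rim are discarded — the disk boundary
     is a step edge whose LoG ridge would otherwise read as a line of
     nuclei.
   * `ground_truth`: injects the synthetic generator's exact cell list
     (from memory or a sidecar file). This is the test oracle mode that
     isolates the calling rule from segmentation error.
   * `register_backend()`: the adapter point for external pretrained
     segmenters (e.g. star-convex polygon models) satisfying the same
     contract.

5. **Positive-cell calling.** Every cell is placed at the centre of a
   16 × 16 px window on the thresholded DAB layer and called positive
   iff strictly more than 10% of the window pixels are DAB-positive.
   Conventions the rule needs but that are otherwise open: the centroid
   is rounded half-up to integer pixels; the window spans [c−8, c+8)
   per axis; windows are clipped at the image border and the clipped
   pixel count is the denominator (a fixed 256 would penalise edge
   cells). Cells outside 1.05 × the detected radius are excluded from
   counts (the 5% margin absorbs detection error). The cutoff grid
   0.05–0.25 can be re-evaluated from stored per-cell window fractions
   without re-segmentation (`cutoff_sensitivity`); counts are
   non-increasing in the cutoff by construction.

## Quality flags

A core is flagged, never silently dropped: `no_circle` (no acceptable
Hough peak — blank positions, destroyed tissue), `low_tissue` (tissue
covers < 85% of the disk), `suspected_fold` (> 10% of disk pixels with
summed RGB OD above 2.5, the signature of doubly-absorbing folded
tissue). Tissue pixels are those at least 0.08 grey units (of 1.0)
darker than the background level, estimated as the median grey outside
the disk. A global two-class (Otsu) cut was rejected here: on
light-tissue cores the grey histogram is trimodal
(background/tissue/nuclei) and Otsu can lock onto the nuclei–tissue
valley, misreporting coverage by a factor of seven. The 85% coverage
default is deliberately strict so that cores missing a ≥ 25% wedge of
tissue are always caught; it is a parameter, not a claim about any
particular scanner.

## Stack registration and composites

Serial sections of one core stained for different markers are merged by
pure circle geometry: each layer's cell centroids are translated so its
detected centre is the origin and scaled by reference_radius/radius
(reference = first layer's radius by default). No rotation or elastic
warping is applied; residual shifts between sections are measured (by
gated nearest-neighbour matching, 10 px gate) and reported, not
corrected. `render_composite` draws each layer's cells in a per-marker
colour over the reference circle outline, later layers on top.

## Count analytics

Raw per-core counts are aggregated to one value per tumour as the mean
of available (unflagged) cores, *then* log2(x + 1) transformed — the
order is fixed, enforced by a transform-state flag, and configurable;
the pseudocount handles zero counts. Agreement between count series
uses Spearman rank correlation (average ranks on ties; NaN with a
warning on constant input). Marker co-expression is explored by
complete-linkage hierarchical clustering on Euclidean distances, cut
into exactly two clusters (immune-high / immune-low). Survival-ready
group labels come from a median split with ties assigned to "low" (a
fixed, reproducible convention). Survival estimation itself
(Kaplan–Meier, log-rank, Cox) is out of scope by design; the module
emits tidy label tables for standard survival tooling.

## The synthetic-core generator

No scanned cohort images are desk-scale inputs, so all tests run on a
seeded generator that emulates a dearrayed core at 20X: a circular disk
(default radius 400 px in a 1024 px image) carrying a light tissue wash,
nuclei as Gaussian-softened (σ = 1 px) filled ellipses placed by
rejection sampling with a minimum centre spacing (2.2 × max nucleus
radius for well-separated fixtures, halved for the overlapping preset),
and an exactly assigned round(fraction × n) subset carrying DAB.
Composition happens in concentration space — hematoxylin field times the
H vector plus DAB field times the DAB vector — and converts to RGB by
I = round(256·10^(−OD)) − 1, the exact inverse of the OD transform (the
naive 255·10^(−OD) paired with the (I+1)/256 inverse carries a
systematic ~0.02 OD bias near OD 1, which would swamp the quantisation
budget). The background is an extremely light hematoxylin tint whose
mean grey equals `background_intensity` (default 245), so ground-truth
concentration fields stay non-negative everywhere and deconvolution
recovers them exactly up to quantisation. Seeded Gaussian pixel noise
(σ = 2 grey levels) is added after quantisation.

Default OD ranges — nucleus hematoxylin 0.35–0.75 over a 0.15 wash, DAB
0.25–0.65 — were chosen by a worst-corner error analysis: with maximum
total hematoxylin 0.9 and DAB 0.65 the darkest channel stays near
intensity 29, where one grey level is ≈ 0.015 OD, and propagating
simultaneous worst-case rounding in all three channels through the
matrix inverse bounds the concentration error at ≈ 0.016 OD, inside the
0.02 round-trip budget. Round-trip checks therefore disable pixel noise
(σ = 0): noise is physical signal degradation, not quantisation.

Artifact variants mimic the failure modes real batches contain: `blank`
(background only — no Hough votes), `gap` (a missing angular wedge,
default 25% of the disk; the circle is still recovered from the
remaining arc), `fold` (a dark band through the disk, ≥ 35% of its area
at OD 1.9, far above any nucleus).

What the generator does *not* model — chromatin texture, stromal
structure, stain-batch drift, non-circular or off-centre damaged disks,
uneven illumination — bounds what passing tests show: they validate the
algorithmic contracts (exact inversion, exact counting rules, geometric
registration) rather than robustness to real-world histology variation.
In particular the default LoG backend's exact recovery on well-separated
synthetic nuclei says nothing about touching-nuclei performance on real
tissue; that is what the pluggable pretrained-model adapter is for.

## Numerical and determinism choices

All randomness flows through `numpy.random.default_rng` with explicit
seed streams, so the same spec + seed yields byte-identical images and
ground truth across runs and platforms. Quantification contains no
randomness at all. Output tables are TSV with a schema-version comment
line, counts as integers and reals at 6 significant digits, so identical
batches produce byte-identical files. Ground-truth sidecars store
coordinates at 10 significant digits so reloaded cells land in the same
calling window. Tie-breaks are fixed everywhere: triangle ties to the
high-OD tail and, within equal distances, to the bin nearest the peak;
median ties to "low"; cluster ties by scipy's deterministic row order;
cell lists sorted by (y, x).

## Problem sizes used in verification

The acceptance checks run 20 injection-backend cores (50–400 cells,
positive fractions 0–1), 10 default-backend cores, 20 circle-recovery
cores spanning radii 290–480 px, 6 artifact cores, 1000 random
cell/mask pairs against brute-force window counting, 100 random
histograms against the exhaustive triangle construction, a two-marker
jittered stack (translation up to 20 px, scale ±5%), and the
count-analytics fixtures. These sizes give every rule a full sweep of
its input range while keeping a complete verification run in the
low minutes on one CPU.

## Known limitations

* The classical LoG backend assumes roughly blob-like nuclei within a
  known radius range; heavily overlapping or irregular nuclei need an
  external learned backend via the adapter.
* Registration is translation + isotropic scale only; rotated or
  deformed serial sections will leave residuals that are reported but
  not corrected.
* The positive/negative call is binary; partially stained cells are not
  distinguished.
* Inputs are per-core images; whole-slide dearraying is upstream and out
  of scope.
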