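# Methods

## Problem and model

Colonies of *S. cerevisiae* carrying the Sup35 prion report their prion
state as color: prion-containing [PSI+] colonies are white, prion-free
[psi-] colonies are red, and colonies in which prion loss occurred during
growth show red wedge-shaped *sectors* inside an otherwise white disk. The
package quantifies plate photographs of such colonies in four steps:
semantic segmentation of the plate image into background / red-colony /
white-colony pixels, circle-Hough localization of individual colonies,
geometric decomposition of each colony into idealized sectors scored by a
purity metric, and phenotype classification with a sector count.

### Idealized sectors and the purity metric

Each colony is assumed circular, centered in its crop, with every red or
white patch growing radially from the center with straight edges. The colony
boundary (colony pixels with a background 8-neighbor, thinned to a 1-px
skeleton that keeps its red/white labels) is decomposed into maximal
monochrome arcs; an arc's two endpoints, joined to the center, close an
idealized sector. With `a` red regions R_1..R_a and `b` white regions
W_1..W_b, and N(X, c) the count of pixels of color c inside region X:

    p(R_i, red)    = N(R_i, red)  / (N(R_i, red) + N(R_i, white))
    p(W_j, white)  = N(W_j, white)/ (N(W_j, red) + N(W_j, white))

Region weights mu(X) = |X| / (N_R + N_W) normalize to 1 over the colony, and
the colony purity p_w is the weighted mean of region purities, identically
equal to the pooled matching-pixel fraction. Both forms are implemented and
the identity is verified numerically in the tests.

### Purity correction

Segmentation errors can produce regions whose boundary color disagrees with
their interior. Every region with p < 0.5 has its boundary-arc pixels
flipped to the opposite color; adjacent same-color arcs then merge
(connected components are recomputed on the recolored skeleton), regions are
rebuilt and rescored, and the pass repeats until all regions satisfy
p >= 0.5. The mediant inequality — the pooled fraction of several fractions
lies between their minimum and maximum — guarantees that merging regions
that each satisfy the constraint cannot break it. A cap of 20 passes guards
against oscillation (never observed on synthetic data; a capped colony is
reported unquantifiable(non_convergent) rather than mis-scored).

### Classification

a = 0, b >= 1 -> [PSI+];  a >= 1, b = 0 -> [psi-];  a >= 1 and b >= 1 ->
sectored with sector count a (red and white arcs alternate on a closed
boundary, so a = b). Sectored colonies carry a secondary label S1, S2, ...;
summary tables bin S3 and above as "S3+".

## Design choices where the design was open

- **Connectivity.** 8-connectivity throughout (components, adjacency,
  skeleton traversal); 4-connectivity fragments diagonal arcs.
- **Endpoint detection.** Union of a hit-or-miss pass and a brute-force scan
  for pixels with exactly one component neighbor. The hit-or-miss templates
  are the eight degree-1 patterns (one required neighbor, seven required
  background): looser "near-corner" templates fire on legitimate degree-2
  corner pixels of jagged skeletons and would spuriously flag colonies as
  branched. More than two endpoints on one arc marks the colony
  unquantifiable(branched_boundary); an arc with a single endpoint (corner
  artifact) is closed against its farthest pixel.
- **Pixel-to-region assignment.** By polar angle about the crop center.
  Each arc's angular interval is the complement of the largest gap in its
  pixel angles; the cut between adjacent regions is the midpoint of the gap
  between their facing endpoints, and intervals are half-open so pixels on a
  dividing line deterministically join the region counterclockwise of it.
  This is equivalent to the Bresenham-radius construction up to
  rasterization slack and guarantees that the regions exactly partition the
  colony's pixels (the partition invariant is asserted in tests).
- **Crop hygiene.** A crop centered on one colony may clip fragments of
  neighbors in its corners; only the connected colony component containing
  (or nearest to) the crop center is annotated. Without this step,
  neighbor arcs corrupt the boundary decomposition and many colonies become
  unquantifiable.
- **Flip order.** All sub-threshold regions are flipped simultaneously in a
  pass, then components are recomputed; a per-region sequential order would
  bias the merge toward the iteration order.

## Segmentation network

A U-Net-pattern fully convolutional network: double 3x3 convolution blocks
with ReLU, 2x2 max-pooling contractions, nearest-neighbor 2x upsampling with
skip concatenations, and a 1x1 output convolution with three channels. All
convolutions are same-padded, so the output segmentation has exactly the
input's spatial resolution; per-pixel softmax + argmax yields the label
mask. Training minimizes mean pixelwise cross-entropy with Adam under a
cosine learning-rate schedule annealed to zero; the weights of the epoch
with the lowest validation loss are kept. Inputs are scaled to [-1, 1]:
the informative color differences are small relative to the common
brightness offset, and centering keeps first-layer units sensitive to them.
No class weighting and no augmentation are used (the synthetic generator
already supplies the variation). The network, its backpropagation and the
optimizer are implemented directly on NumPy arrays (im2col-style
convolutions; the full-network gradient is verified against float64 finite
differences in the tests).

Two configuration profiles are provided:

| profile | image | colonies/plate | radius (px) | depth | base ch. | epochs | images (train/val) |
|---------|-------|----------------|-------------|-------|----------|--------|--------------------|
| full    | 1024  | 100            | 18-28       | 4     | 64       | 24     | 200 (150/50)       |
| desk    | 128   | 6              | 10-14       | 2     | 8        | 100    | 30 (24/6)          |

The desk profile is the package's reduced-scale configuration used by the
tests and the acceptance script; it keeps the colony-to-image scale of the
full-size setting (radius about 1/10 of the image side) while shrinking
everything else. At this scale a training run takes a few CPU-minutes and
reaches ~0.992 validation pixel accuracy; the residual errors sit almost
entirely in the 1-2 px band around colony boundaries, where the true label
is genuinely ambiguous under shot noise.

## Synthetic plate generator

Each plate scene is built from five representative colors — white colony
(235, 225, 210), red sector (185, 60, 55), plate (250, 245, 235), table
(60, 60, 60), border (plate darkened ~20%) — with small darker blotches on
the border ring as aberrations. Colonies are disks placed by uniform
rejection sampling inside the plate interior with a minimum inter-center gap
of r_i + r_j + 2 px; radii are uniform in the configured range, and each
colony carries the configured number of disjoint angular sectors with widths
uniform in 20-120 degrees. The class mask is produced by exact color
identity against the two colony colors on the clean render; the count mask
places a 5-px disk at each colony center with intensity 40 x (sectors + 1).
Poisson shot noise (each channel value replaced by a Poisson draw with that
mean) is applied after mask creation, so the masks are pixel-exact.

Default colony geometry: 100 colonies of radius 18-28 px per 1024-px plate.
One hundred colonies of radius 35-55 px cannot be placed — their disk area
alone would exceed the random-packing limit of the plate interior — so the
radius default is chosen as the largest band that places 100 disjoint
colonies reliably (~24% interior coverage). Colony count and radius are
independently configurable, including a degenerate range for equal-size
colonies.

What the generator does *not* emulate: lighting gradients, 3-D colony
texture, off-circular or touching colonies, the pink intermediate
phenotypes of partial prion loss, and camera effects beyond shot noise.
Tests passing on this data therefore certify the geometry and algebra of
the pipeline and the trainability of the network on color-separable
classes; they do not certify performance on real plate photographs, which
additionally need the color-transfer preprocessing and tolerate only
visually judged segmentation quality.

## Numerical details and degenerate inputs

- Angles are measured as atan2(row - center_row, col - center_col) mod 360,
  identically in the generator and the annotator.
- A colony with no pixels, or an empty boundary skeleton, is
  unquantifiable(empty); a closed boundary loop coexisting with other arcs,
  an empty region after assignment, or overlapping arc intervals is
  unquantifiable(ill_defined_regions).
- A single closed monochrome boundary loop yields one region covering the
  whole colony (purity 1 on clean data).
- Detection: the edge map is the morphological gradient of the binarized
  mask; Hough radii are searched at 1-px steps over the configured range,
  peaks below 0.4 of the accumulator maximum are dropped, and peaks closer
  than 1.5 x min-radius are suppressed. The border-exclusion margin is
  150 px at 1024 px, scaled proportionally at other sizes.
- Crops are square with side ceil(2 x radius x 1.5), bumped to odd so the
  detected center is the unique central pixel.
- Color transfer matches channel means and standard deviations in the
  log-opponent l-alpha-beta space and rejects references with a
  zero-variance channel.

## Known limitations

- Sector counts are reliable only for sectors covering at least ~5% of the
  colony; smaller regions are absorbed by purity correction (by design).
- Touching colonies are not split; the central-component selection keeps
  the annotation well-defined but a merged blob may still fail detection.
- The full-scale profile training run (200 plates at 1024 px, 24 epochs) is
  supported but impractical without substantial compute; all quantitative
  checks in this repository run the desk profile.
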