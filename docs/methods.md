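# Methods

`cmekymo` quantifies clathrin-mediated endocytosis (CME) dynamics
separately on the mother and the daughter (bud) cortex of budded yeast
cells imaged by 2D wide-field time-lapse microscopy at the equatorial
focal plane. Because each endocytic event is an immobile, diffraction-
limited cortical patch that appears, accumulates and disappears over tens
of seconds, unrolling the cell outline into a *circumferential kymograph*
(cortex position x time) turns every event into a vertical streak whose
length is the tagged protein's lifetime at that site. This note records
the model, the parameters that matter, the numerical choices, and what
the synthetic validation does and does not establish.

## Pipeline model and assumptions

1. **Segmentation.** A label mask assigns each cell lobe an integer
   label. External masks (e.g. from a deep-learning segmenter) are
   first-class input; a built-in fallback (median blur + grayscale
   erosion, Otsu threshold, hole filling, distance-transform watershed)
   exists so the pipeline is testable end to end without external tools.
   Cells are not tracked over time: one mask serves the whole short
   movie, which assumes negligible cell motion over ~3 min.
2. **Pairing.** Labels whose boundaries touch (8-adjacency) form a
   budded cell; within a pair the larger lobe is the mother. This area
   rule replaces the study's visual assignment and is overridable. A
   label touching two or more partners is reported as an error rather
   than guessed.
3. **Contours.** Each lobe's boundary is traced at the 0.5 iso-level of
   its indicator image after light Gaussian smoothing (sigma 1 px). The
   smoothing suppresses the pixel staircase, whose jagged polygon would
   overestimate perimeter by ~7%; with it, a radius-20 px disk's
   circumference is recovered to ~0.3%. Contours are oriented
   counter-clockwise and resampled to uniform spacing (default 1 px;
   three refinement passes make chord spacing uniform to ~1e-4 px).
   Arclength is converted to micrometres with the pixel size (default
   65 nm; frame interval default 1 s).
4. **Bud-neck exclusion.** Contour samples within a margin (default
   5 px, equal to the band width so the two compartments' bands cannot
   overlap) of any neck pixel — a boundary pixel of one lobe 8-adjacent
   to the other lobe — are excluded. CME sites at the neck are too
   crowded to resolve. Retained + excluded arclength equals the closed
   arclength exactly.
5. **Kymographs.** For each retained contour sample, intensities are
   bilinearly interpolated at `width` points spaced 1 px along the local
   normal (central-difference normals) and reduced by `max` (default;
   robust to sub-pixel contour placement) or `mean` (photometry). The
   band width can be set from the movie's maximum intensity projection:
   the smallest odd width capturing >= 95% of above-background cortical
   signal within 3 PSF sigmas of the contour. Rows flanking an excluded
   gap are marked non-adjacent; the closed-contour seam stays adjacent.
6. **Trace detection.** Per-row baseline = temporal median; noise =
   1.4826 x pooled MAD. Pixels above `baseline + k_sigma * noise`
   (default k_sigma 4) are grouped by 8-connectivity in (row, frame),
   wrapping across the seam but never across excluded gaps; components
   shorter than 3 frames or thinner than 1 row are discarded. Lifetime =
   (t_end - t_start + 1) x frame interval; a trace touching the first or
   last frame is censored. The temporal-median baseline tolerates up to
   50% event occupancy per row; events that outlive half the movie (as
   mother-cell Ede1/Sla2-like patches do in 3-min movies) contaminate
   it, which is the same regime in which the study could only report
   lower bounds on lifetimes.
7. **Statistics.** Mean, SD and CV of lifetimes exclude censored traces
   by default (an `include-flagged` policy is provided); frequency =
   events per retained micrometre of cortex per minute, counting
   censored traces, which corrects for the different surface distance
   sampled in mother vs daughter. Mann-Whitney comparisons use exact
   enumeration for n1+n2 <= 12 without ties, otherwise the normal
   approximation with mid-rank tie correction and no continuity
   correction (identical samples give p = 1).
8. **Two-stage traces.** Proteins recruited in a low- then
   high-abundance stage (Pan1-like) are split by the interior change
   point minimising the two-segment piecewise-constant residual sum of
   squares; the step is significant when the stage means differ by more
   than twice the noise scale. A piecewise-constant model applied to a
   monotone ramp places the change near the midpoint — a documented
   model mismatch, not a failure mode the detector can flag.
9. **Two-colour analysis.** Kymographs built on the same contour are
   paired; channel-A traces match channel-B traces when row extents come
   within `row_tol` (default 1) and time intervals overlap after
   dilation by `frame_tol` (default 5 frames), assigned greedily
   one-to-one by overlap area.
10. **Projection statistics.** Cytoplasmic puncta: Laplacian-of-Gaussian
    response at the PSF scale, restricted to the cell mask eroded by a
    cortex margin (default 8 px ~ band width + 2 PSF sigma, so cortical
    patches are never counted), thresholded at baseline + 5 robust sigma
    of the interior response; a cell with >= 1 spot is puncta-positive.
    The study classified by eye; this threshold is the documented
    operational stand-in. Pearson colocalization is the plain correlation
    over a cell mask; it errors on constant channels and small masks.
    The daughter/mother cortical intensity ratio averages
    above-background band intensity along each retained contour; on
    time-lapse data the recommended input is the time-mean image minus
    the temporal-median image, which cancels cytoplasmic background and
    avoids the noise-maximum bias a MIP would add to both compartments.

## Synthetic movies

The study's raw movies are not deposited, so validation uses a generator
that reproduces the statistical structure the analysis assumes:

* **Geometry**: two overlapping disks (mother radius 30 px, daughter
  15 px at 65 nm/px; the neck chord half-width 6 px fixes the centre
  distance). Disks keep contour-length oracles analytic; the pipeline
  must not depend on cell shape.
* **Events**: births are a homogeneous Poisson process per unit retained
  cortex length and time, extended before t = 0 so events already in
  progress at the movie start occur and are censored. Default rates
  1.0 (daughter) and 0.2 (mother) events/um/min encode the roughly
  five-fold higher initiation frequency on the bud cortex. Lifetimes:
  daughter Gaussian mean 30 s, CV 20% (short and regular, Ede1-like);
  mother lognormal mean 90 s, CV 50% (long and irregular); both
  truncated at 2 frame intervals. Events are immobile in arclength, so
  streaks are vertical; patch motility is out of scope.
* **Rendering**: isotropic Gaussian spots (PSF sigma 1.4 px, the
  diffraction limit for GFP at 65 nm pixels), amplitude 60 photons/frame
  at peak (photon-limited peak SNR ~6 over the cytoplasm), plateau or
  triangular temporal profile, optional low/high two-stage profile and a
  birth/death-shifted second channel. Expected photons (field background
  10, cytoplasmic autofluorescence 30, softened cell edge) are bleached
  by exp(-kt), Poisson-sampled, and Gaussian read noise (SD 1) is
  added. Interior puncta (amplitude 30, >= 12 px from the cortex) and
  immobile mother-cortex eisosome analogues are available.
* **Determinism**: all randomness flows from one seed through named
  substreams; the ground-truth event table is bit-identical across runs.

Not emulated: 3D structure, vacuole/autofluorescence texture, patch
drift and inward movement, cell growth, segmentation errors of real
cells. Passing the validation therefore shows the *analysis* recovers
truth under the stated image-formation model, not that segmentation of
difficult real images is solved.

## Validation scene sizes

Replicate counts and rates in `cmekymo.validation` are chosen once so
each check is statistically meaningful on one CPU within minutes:

* **Lifetime recovery**: daughter rate 0.1 events/um/min, 140 replicate
  180-s single-cell movies pooled to >= 150 uncensored events. The rate
  keeps simultaneous row-overlapping events rare: threshold detection
  merges traces that overlap in both cortex position and time (a human
  reading the kymograph cannot separate these either), and at this
  density ~2% of events merge, leaving mean/CV errors well inside the
  2 s / 5-point bands. The published kymographs show comparably
  resolvable traces.
* **Frequency ratios**: larger lobes (38/20 px) and replicates scaled
  with the ratio (>= 100, up to 175) keep the mother-side Poisson error
  of the recovered ratio under ~10%; lifetime laws are identical in the
  two compartments so rate is the only asymmetry.
* **Censoring**: 20 replicates with the regular 30-s lifetime law in
  both compartments (see the median-baseline occupancy limit above);
  flags are scored at the trace level because a trace occasionally spans
  two overlapping truth events.
* **Puncta classifier**: 100 cells, half with 1-3 interior puncta at
  spot SNR ~5.5; sensitivity and specificity both hit >= 95%.
* **Intensity ratio**: 12 cells, equal rates (3/um/min), daughter
  amplitude 2x; cohort mean recovers the ratio within a few percent.

## Known limitations

* Overlapping events merge into one trace; lifetime statistics are
  reliable only while kymograph traces are visually resolvable.
* The temporal-median baseline fails for rows occupied by signal more
  than half the movie; lifetimes in that regime are lower bounds.
* The two-stage split assumes piecewise-constant stages.
* The built-in segmenter expects bright-cytoplasm images with clear
  lobes; real data should use a dedicated segmenter's masks.
* Frequency normalisation uses retained arclength at the equatorial
  plane, a proxy for sampled surface distance, as in the source
  workflow; no 3D correction is attempted.
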