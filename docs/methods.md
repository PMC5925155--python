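# Methods

## The measurement problem

Quantitative phase microscopy (QPM) measures the optical path delay a
transparent specimen imposes on transmitted light.  The phase at an image
point couples two unknowns — refractive index and physical thickness —

    phi(x, y) = (2 pi / lambda) * (n_c(x, y) - n_m) * h(x, y),

so a phase map alone cannot separate a thick low-index structure from a
thin high-index one, and in particular cannot delineate the nucleus of a
nucleated cell directly.  What *is* directly observable is where the phase
changes its rate of growth: every refractive-index boundary crossed by the
illumination produces a localized spike ("jump") in the lateral phase
gradient.  This package implements that gradient analysis: it renders
nested-sphere cell phantoms, computes forward-difference gradient maps and
their modulus square, detects and pairs gradient jumps along 1D
traversals, and converts jump-pair separations into physical sizes.

## Phantom model

A cell is modelled as a large sphere (cytoplasm, index `n1`, radius `R1`)
containing zero or more inner spheres (nucleus/organelles, index `n2`,
radius `R2`), all immersed in medium `n_m`.  With plane illumination along
z, each sphere contributes its contrast times the axial chord length

    phi(x, y) = (2 pi / lambda) * [ (n1 - n_m) * 2 sqrt(R1^2 - d1^2)
                                  + (n2 - n1)  * 2 sqrt(R2^2 - d2^2) ],

with `d_k` the in-plane distance from sphere `k`'s centre, and each chord
zero outside its disc.  The additive decomposition requires every
inclusion's projected disc to lie inside the body's disc; the model
validator enforces this.  The closed-form lateral derivative used as the
discretization oracle is

    d phi/dx = sum_k C_k * ( -(x - cx_k) / sqrt(R_k^2 - d_k^2) ),
    C_k = (4 pi / lambda) * contrast_k,

which diverges on each boundary; evaluation exactly on a boundary raises
`BoundaryGradientError` rather than returning a sentinel.

### Reference phantom and raster

The default nucleated-cell phantom has `R1 = 6.0` um at the origin,
`R2 = 2.5` um centred at (3, 0, 0), `n1 = 1.37`, `n2 = 1.45`,
`n_m = 1.33`, `lambda = 0.6328` um (He-Ne), rendered on a 15 x 15 um^2
field of 255 x 255 pixels (pitch 15/255 ~ 0.0588 um).  The synthetic bead
preset is a single 25 um-radius sphere of index 1.59 in water on a
60 um / 255 px field, emulating a polystyrene calibration bead.

Pixel centres follow `x_i = -width/2 + (i + 1/2) dx` with 0-based
indices; the implementation computes this as `(i + 1/2 - nx/2) * dx`,
which is the same expression but makes mirrored indices exactly negated
floats, so the rendered map of a mirror-symmetric phantom is bitwise
mirror-symmetric.  Squared in-plane distances are summed before
subtracting from `R^2` so pixel centres that lie exactly on a sphere
(they exist: rational grids meet rational circles) get a radicand of
exactly zero and a phase of exactly zero.

## Gradients

The lateral gradient is the plain forward difference
`g[c] = (phi[c+1] - phi[c]) / dx`, the final index padded with zero so
gradient maps stay aligned with the source raster (the padded index is
excluded from jump candidacy).  No smoothing or higher-order stencils are
used.  At interior points at least 3 px from any boundary the forward
difference matches the closed form within the first-order truncation
bound `sup |phi''| * dx / 2`, and refining the grid 4x shrinks the worst
interior error by more than 3x (both are tested).  Gradient units are
rad/um everywhere so thresholds are grid-independent.

Squaring the gradient (optionally `gx^2 + gy^2`) removes the sign
reversal across edges ("shadow artifact") and gives an all-positive
edge-strength map with extrema at the same pixels.

Profiles are extracted along rows, columns, or oblique lines
(nearest-pixel sampling at unit steps of the dominant axis — integer
pixel positions localize spikes better than interpolation).  A traversal
uses the gradient component *along* the traversal: rows read the
x-gradient, columns the y-gradient.  A vertical traversal through the
centre of a concentric sphere then shows exactly two spikes,
antisymmetric up to the one-pixel forward-difference offset.

## Jump detection

The detector works on the two-pixel slope `T[i] = (s[i] + s[i+1]) / 2`
of the profile rather than on single forward differences:

1. candidates: `|T| >= threshold_fraction * max |T|` (default 0.5);
2. contiguous same-sign candidate runs; same-sign runs separated by at
   most `merge_gap` (default 3) subthreshold samples are merged;
3. one jump per run at `argmax |T| + 1` (the difference the statistic
   straddles), ties to the lowest index;
4. on a modulus-squared profile the square root of the samples is taken
   first (restoring the magnitude scale so the relative threshold means
   the same thing), with polarity from the companion signed profile.

The aggregation in `T` is deliberate.  A sphere boundary generically
falls between two pixel centres, splitting the spike energy across two
adjacent differences, and phase noise is amplified by `1/dx` in each
difference.  For the reference phantom at 35 dB SNR the per-difference
noise sigma is ~1.2 rad/um while adjacent boundary differences differ by
only ~2-3 rad/um, so any single-difference argmax flips indices in a
large fraction of realizations.  Thresholding and localizing on `T`
halves the noise variance and compares samples two pixels apart; the
detected index set is then identical to the noiseless run in ~99% of
noise realizations, with no smoothing of the gradient itself.  The
defaults assume boundaries of interest are separated by more than
`merge_gap + 2` pixels and that paired edges have spike magnitudes within
a factor ~2 of each other (true for nucleus/cytoplasm contrasts of this
kind); outside that regime the threshold can be set per run.

## Pairing, distances, error statistics

For a phase hill traversed left to right, jumps must arrive as `m` rising
then `m` falling spikes; the k-th from the left pairs with the k-th from
the right, giving strictly nested intervals (body outline outermost).
Any other signature raises `PairingError` — it signals overlapping,
non-nested media outside the model class.

Physical separations are exactly `pixel separation x pixel pitch`; they
are kept in exact pixel arithmetic internally and rounded to three
decimals only on serialization.  A report contains one diameter row per
pair plus left/right edge gaps for each adjacent nesting level.  Error
statistics against set values report the absolute and relative error per
row, the maximum absolute error over the *diameter* rows, and the mean
relative error over *all* rows with truth, expressed in percent (the only
combination consistent with the reference table's summary figures).

## Noise model

`add_gaussian_noise` adds i.i.d. zero-mean Gaussian noise with variance
`P_signal / 10^(snr_db/10)`, where `P_signal` is the mean squared phase
over the full image including the zero background — the common white-
Gaussian SNR convention; defining it over the cell's support only would
raise sigma by ~35% here and change no conclusion.  The seed fixes the
realization bitwise.  The robustness study uses 35 dB.

## What the generator does and does not emulate

The simulator produces exactly the study conditions: piecewise-constant
refractive indices, perfect plane illumination, no diffraction, no
partial-volume averaging, and noise that is white, Gaussian and
stationary.  Real QPM rasters additionally contain speckle, halo and
shade-off artifacts, reflection-induced centre depressions in high-index
beads, unwrapping residues, and spatially correlated background — none of
which are modelled.  Passing tests therefore demonstrate correctness of
the geometry-to-distance chain and its behaviour under the stated noise
model, not robustness to instrument-specific artifacts; external
instrument maps are accepted as already-computed phase rasters with an
explicit pixel calibration and analysed with the same pipeline.

The "phase centre" used for default profile placement on external maps is
the argmax of the 3x3 median-filtered phase map (ties to the lowest
row-major index); the median filter keeps single hot pixels from steering
the traversals.

## Numerical and design choices

- Chord evaluation at pixel centres, no anti-aliasing: matches direct
  per-pixel evaluation of the model and keeps boundaries crisp for the
  jump detector.
- Forward-difference padding with zero instead of shrinking the raster.
- Detected indices are conventions, not estimates of sub-pixel boundary
  location: each reported edge is within one pixel of the true boundary,
  so pair diameters are accurate to ~2 px (0.12 um on the reference
  raster) and may shift by up to one pixel per edge across resolutions.
- Tie-breaks everywhere go to the lowest index, making runs bitwise
  reproducible.
- Degenerate inputs: all-zero or constant profiles yield no jumps;
  single-pixel profiles yield none; an all-zero map has no definable SNR
  and is rejected.

## Problem sizes

All simulations run on the 255 x 255 reference raster (1023 x 1023 for
the one grid-refinement check, 510 x 510 for the resolution-stability
check); the noise study uses 10 independent realizations.  The full test
suite and the acceptance script each complete in a few seconds on one
CPU.
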