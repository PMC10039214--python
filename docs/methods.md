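# Methods

`pelvreg` couples two components: a simulator of inter-fraction pelvic
organ deformation that manufactures fixed/moving CT slice pairs with
known ground-truth displacement fields, and an unsupervised
convolutional registration network family trained on those pairs. This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Deformation simulation

### Correlated Gaussian offset field

The background deformation is a stationary Gaussian random field (GRF)
per displacement axis. Marginally each pixel value is Gaussian with
mean `y_c` (default 0) and dispersion `sigma`; jointly the field is
governed by a covariance function `xi` with `xi(0) = sigma^2`. We use
the squared-exponential covariance

    xi(r) = sigma^2 exp(-r^2 / (2 ell^2)),

with length scale `ell` a free parameter (default 20 px, chosen to
produce smooth, organ-scale deformation; the covariance family and
scale are design choices of this package). Sampling is by convolution:
white Gaussian noise on a padded grid is filtered with a Gaussian
kernel of width `ell / sqrt(2)` normalized to unit L2 norm, then
cropped. This realizes the prescribed covariance exactly in expectation
without forming the dense N x N correlation matrix; the dense
matrix + Cholesky construction is retained (`grf_covariance_matrix`) as
a brute-force oracle on small grids and is cross-checked in the tests.
The padding (4 kernel sigmas) removes boundary variance loss, so the
marginal SD is exact.

### Anatomy-aware modulation

A multiplicative correction map suppresses the offset field where
anatomy is rigid or absent: it is ~1 in unconstrained soft tissue,
`bone_sigma / offset_sigma` (default 3/10) inside bone, and 0 outside
the body, smoothed with a Gaussian of width `correction_smoothing`
(default 6 mm) so the field strength has no spatial discontinuity.

### Organ expansions

Rectal and bladder filling are modelled as radial expansion fields
about each organ's centroid. The magnitude profile ramps from zero at
the centroid to its peak at the organ boundary and decays with a
Gaussian taper (default width 24 px) outside it — the taper is what
deforms neighbouring structures, notably the cervix, reproducing the
clinically observed cross-organ effect of rectal filling. The profile
is normalized so the organ-mean displacement is proportional to the
drawn amplitude independent of organ shape; for a conical ramp the
boundary peak then equals the amplitude times the calibration constant.

### Units and calibration

All stochastic strengths live in one internal unit system: offset
dispersion 10 (3 in bone) and per-organ amplitude ranges 100–1000
(rectum) and 100–500 (bladder). A single calibration constant
`displacement_per_unit` (default 0.02 px/unit, configurable) converts
the composed field to pixels, chosen so the maximum rectum amplitude
maps to a ~20 px peak boundary displacement (~17 mm at 0.84 mm
spacing, the magnitude of reported cervix motion). Under this
single-unit reading the organ expansions dominate the sub-pixel
background offset, so the composed field has maximal amplitude in the
rectum, moderate amplitude in the bladder, and minimal amplitude in
bone — the simulator's design guarantee. To make that guarantee hold
per field and not merely in expectation, the two amplitude draws share
one uniform severity deviate per pair (each amplitude remains
marginally uniform over its configured range, and the rectum draw is
never below the bladder draw). Treating the dispersions and amplitudes
as commensurable quantities in one unit system, rather than reading
the offset sigma as a pixel displacement outright, is the
interpretation this package adopts; the calibration constant exposes
the conversion.

### Warping conventions

Displacement fields use the backward-warp convention
`output(p) = input(p + d(p))` with clamp-to-edge sampling. Simulated
image warps are bilinear (4-neighbour); masks are warped bilinearly and
thresholded at 0.5 (ties map to 1), keeping outputs strictly binary
with smooth boundaries. Because the warp is backward, a physically
*outward* organ expansion is stored as a field pointing *toward* the
centroid; the warped organ then grows. A training pair is
(fixed = original slice, moving = warped slice + masks), with the
composed field returned for oracle testing. The network's target — the
field that undoes the simulated deformation — is the inverse of the
simulation field, which the tests approximate by its negation where a
reference field is needed.

## Preprocessing

Fixed order: couch elimination, bone extraction, body crop.

- **Couch**: connected components with median HU inside (-405, -340)
  that are disjoint from the body mask are replaced by air. The
  replacement value (-1000 HU) is this package's choice. The body mask
  is HU > -300, largest component, hole-filled. The step is idempotent
  and never touches body pixels.
- **Bone**: strictly HU > 150; components under 20 px are dropped as an
  automatable surrogate for visual verification of the segmentation.
- **Crop**: to a fixed matrix (256 x 512 of a 512 x 512 slice),
  centred on the body bounding box along the anterior-posterior axis; a
  body that does not fit raises rather than silently truncating.

## Registration network

The regressor takes the channel-concatenated pair — by default 10
channels: image + bladder/cervix/rectum/bone masks for each of fixed
and moving (an image-only 2-channel mode exists) — with HU clipped to
[-1000, 2000] and scaled to [0, 1]. Each conv layer has sixteen 3 x 3
kernels, batch normalization (momentum 0.9), and ELU; with pooling,
four 2 x 2 average-pooling stages downsample by 16. The final layer is
a linear 3 x 3 conv to 2 channels, zero-initialized so training starts
at the identity transform; batch normalization is applied to the hidden
layers only, since normalizing the zero-initialized linear output would
be degenerate. Four variants are configured: (1) 4 conv layers, NCC
loss, pooling; (2) as 1 with MSE; (3) as 1 without pooling; (4) 8 conv
layers (pooling after every second). The no-pooling variant regresses a
full-resolution parameter map strided every 16 px onto the shared
control-grid geometry, so all variants drive one transformer; how that
variant forms control points is not otherwise constrained, and striding
is this package's choice.

The spatial transformer is a cubic B-spline: control displacements at
16 px spacing (configurable; no canonical value exists) are
interpolated by the tensor-product cubic basis, each pixel depending on
its 4 x 4 control neighbourhood — C2-smooth with local support. Edge
control indices are clamped, preserving the partition of unity, so a
constant grid yields an exactly constant field. The pixel/control map
is linear; its transpose backpropagates field gradients.

The resampler warps the moving image bicubically (Keys kernel,
a = -0.5) and the moving masks bilinearly; during training the mask
warps stay soft (pre-threshold) so the loss is differentiable. The loss
is the image dissimilarity — negative *global* zero-mean NCC (windowed
NCC is not used; zero-variance inputs define NCC as 0 with a warning)
or MSE per variant — plus `lambda_mask` (default 1.0, no canonical
value) times the mean soft-Dice dissimilarity over the four organ
masks. Gradients flow through the resampler analytically (cubic/linear
kernel derivatives; clamped border samples contribute zero gradient),
through the B-spline transpose, and through hand-written conv/BN/ELU/
pool backward passes; every layer's gradient is verified against
central differences in the tests. Optimization is mini-batch Adam
(batch 4, learning rate 1e-4). The network stack is implemented
directly on numpy arrays; training at the desk scales below runs in
minutes on one CPU.

## Evaluation

Dice and Jaccard by exact pixel counting (both-empty pairs score 1;
reference-nonempty/result-empty score 0 and are skipped for ASSD, all
logged). ASSD uses boundary pixels (mask pixels with a 4-neighbour
outside), exact Euclidean distance transforms, and anisotropic mm
spacing. Contours come from marching squares at level 0.5 on a
zero-padded mask so frame-touching components close. Per-organ
aggregation reports mean ± SD over evaluated slices with the
*population* SD (divide by n; fixed for reproducibility). Slices whose
reference organ mask is empty are excluded for that organ; an organ
with no evaluable slices is reported as missing, never as zero.

## Scaled-down experiment

The desk-scale experiment trains on 8 synthetic patients and evaluates
on 3 held-out patients (6 slices each) at 128 x 256 — half the
reference in-plane resolution, with the phantom pixel spacing scaled to
keep body anatomy the same physical size — for 500 Adam iterations
instead of 10,000. These sizes are the package's defaults for
single-CPU runs; the full 256 x 512 geometry and iteration count remain
available through `TrainConfig`. Variant comparisons share byte-exact
batch sequences (the batch stream is seeded independently of weight
initialization), and the full pipeline is deterministic under its seed.

## What the phantoms do and do not show

The phantom reproduces the *structural* features the pipeline depends
on: HU-separable tissue classes (air, couch window, soft tissue, bone),
curved organ boundaries, slice-to-slice anatomical coherence, and
CT-like additive noise (SD 10 HU). It does not model scanner physics
(beam hardening, partial volume, streaks), true anatomical shape
statistics, applicator geometry, or inter-patient HU variability.
Passing the synthetic experiments therefore demonstrates that the
simulation, the differentiable registration machinery, and the
evaluation stack are correct and that training improves alignment under
controlled deformations; it does not certify clinical registration
accuracy, and the absolute metric values are functions of the simulated
deformation magnitudes, not of patient data.

## Known limitations

- 2D slice-wise only; no 3D fields or multi-resolution pyramids.
- No diffeomorphism or fold-over guarantee for simulated or predicted
  fields (none is claimed by the method).
- The conventional iterative baseline (Elastix-style) is out of scope;
  comparisons are between network variants and the unregistered state.
- Parameter counts differ between the 4- and 8-layer variants exactly
  as the architecture implies; no external count is matched.
- RTSTRUCT reading assumes planar, closed contours matched to slices by
  z position and requires a user-supplied ROI-name map for
  institution-specific naming.
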