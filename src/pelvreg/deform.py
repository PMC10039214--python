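"""Anatomy-aware stochastic deformation simulation.

Inter-fraction organ motion is emulated by a correlated Gaussian random
field (GRF) "offset" deformation, modulated by a smoothed correction map
that suppresses displacement inside bone and outside the body, plus
random radial expansions of the rectum and bladder.  Warping a
preprocessed CT slice (and its masks) with the composed field yields a
fixed/moving training pair with a known ground-truth field.

Units
-----
All stochastic strengths (offset sigma, per-organ expansion amplitudes)
live in one internal strength-unit system, exactly as configured; a
single calibration constant ``displacement_per_unit`` (pixels per unit)
converts the composed field to pixels.  The default 0.02 px/unit maps
the maximum rectum amplitude (1000) to a 20-pixel peak boundary
displacement, about 17 mm at 0.84 mm spacing — the magnitude of
clinically reported cervix motion.  The background offset field
(sigma = 10) is then a sub-pixel perturbation, so organ expansions
dominate by construction: the composed field has maximal amplitude in
the rectum, moderate amplitude in the bladder, and minimal amplitude in
bone (sigma = 3 before the additional 3/10 correction-map suppression).

The displacement convention is the backward warp used everywhere in the
package: ``output(p) = input(p + d(p))``.  Physical outward organ
expansion therefore appears as a field pointing *toward* the organ
centroid (sampling positions are pulled inward, so the warped organ
grows).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from ._warp import warp_bilinear, warp_bicubic, warp_mask_binary
from .io import ImageSlice, OrganMaskSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GRFParams:
    """Marginal and covariance parameters of a stationary Gaussian field.

    ``mean``/``sigma`` are the marginal mean and SD; ``correlation_length``
    is the length scale (pixels) of the squared-exponential covariance
    ``xi(r) = sigma^2 exp(-r^2 / (2 ell^2))``, the only covariance kind
    currently implemented.
    """

    mean: float = 0.0
    sigma: float = 10.0
    correlation_length: float = 20.0
    covariance_kind: str = "squared-exponential"

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")
        if self.covariance_kind != "squared-exponential":
            raise ValueError(
                f"unknown covariance kind: {self.covariance_kind!r}")


@dataclass(frozen=True)
class DeformationConfig:
    """Stochastic-field and per-organ amplitude parameters.

    ``offset_sigma``/``bone_sigma`` are the offset-field dispersions in
    unconstrained tissue and inside bone (their ratio sets the bone
    suppression of the correction map).  Amplitude ranges are in internal
    strength units (see module docstring); draws for the two organs share
    one severity deviate so that the rectum amplitude is never smaller
    than the bladder amplitude, the simulator's per-field guarantee.
    """

    offset_sigma: float = 10.0
    bone_sigma: float = 3.0
    rectum_amplitude_range: tuple[float, float] = (100.0, 1000.0)
    bladder_amplitude_range: tuple[float, float] = (100.0, 500.0)
    correlation_length: float = 20.0
    correction_smoothing: float = 6.0          # mm
    displacement_per_unit: float = 0.02        # px per strength unit
    expansion_band_px: float = 24.0            # taper width outside organs
    seed: int = 0

    def __post_init__(self):
        for rng_ in (self.rectum_amplitude_range, self.bladder_amplitude_range):
            if rng_[0] > rng_[1]:
                raise ValueError("amplitude range must be ordered low <= high")
        if self.offset_sigma < 0 or self.bone_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if self.bone_sigma > self.offset_sigma:
            raise ValueError("bone_sigma must not exceed offset_sigma")


@dataclass
class DisplacementField:
    """Dense per-pixel backward-warp offsets in pixel units."""

    dy: np.ndarray
    dx: np.ndarray

    def __post_init__(self):
        self.dy = np.asarray(self.dy, dtype=np.float64)
        self.dx = np.asarray(self.dx, dtype=np.float64)
        if self.dy.shape != self.dx.shape:
            raise ValueError("dy and dx must share a shape")
        if not (np.all(np.isfinite(self.dy)) and np.all(np.isfinite(self.dx))):
            raise ValueError("displacement field must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.dy.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dy, self.dx)

    @classmethod
    def zeros(cls, shape) -> "DisplacementField":
        return cls(np.zeros(shape), np.zeros(shape))

    def __add__(self, other: "DisplacementField") -> "DisplacementField":
        return DisplacementField(self.dy + other.dy, self.dx + other.dx)

    def scaled(self, factor) -> "DisplacementField":
        return DisplacementField(self.dy * factor, self.dx * factor)


# ---------------------------------------------------------------------------
# Gaussian random field
# ---------------------------------------------------------------------------

def _se_kernel_1d(ell: float) -> np.ndarray:
    """1-D Gaussian smoothing kernel whose self-convolution realizes the
    squared-exponential covariance with length scale ``ell``."""
    sk = ell / np.sqrt(2.0)
    radius = max(1, int(np.ceil(4.0 * sk)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sk) ** 2)
    return k / np.sqrt(np.sum(k * k))          # unit L2 norm


def sample_grf(shape: tuple[int, int], params: GRFParams,
               seed: int | np.random.Generator = 0) -> np.ndarray:
    """Sample a stationary GRF with exact marginal mean/SD.

    White Gaussian noise on a padded grid is convolved with an
    L2-normalized Gaussian kernel (realizing the squared-exponential
    covariance without forming the dense N x N correlation matrix), then
    cropped to ``shape``; the padding removes boundary variance loss so
    the marginal SD equals ``params.sigma`` exactly in expectation.
    Deterministic under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if params.sigma == 0.0:
        return np.full(shape, params.mean)
    k = _se_kernel_1d(params.correlation_length)
    pad = len(k) // 2
    H, W = shape
    noise = rng.standard_normal((H + 2 * pad, W + 2 * pad))
    sm = signal.fftconvolve(noise, np.outer(k, k), mode="valid")
    return params.mean + params.sigma * sm


def grf_covariance_matrix(shape: tuple[int, int],
                          params: GRFParams) -> np.ndarray:
    """Dense correlation matrix M of the field on a small grid.

    ``M[i, j] = xi(|p_i - p_j|)`` with ``xi(0) = sigma^2``.  Brute-force
    oracle for grids up to ~32 x 32: sampling by Cholesky factorization
    of this matrix is the reference the convolution synthesis is checked
    against.
    """
    H, W = shape
    if H * W > 4096:
        raise ValueError("dense covariance restricted to grids <= 64*64")
    yy, xx = np.mgrid[0:H, 0:W]
    pts = np.column_stack([yy.ravel(), xx.ravel()]).astype(np.float64)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return params.sigma ** 2 * np.exp(-0.5 * d2 / params.correlation_length ** 2)


# ---------------------------------------------------------------------------
# Anatomy-aware modulation
# ---------------------------------------------------------------------------

def build_correction_map(masks: OrganMaskSet, config: DeformationConfig,
                         spacing_mm: float = 0.84) -> np.ndarray:
    """Multiplicative field-strength map in [0, 1].

    Approximately ``bone_sigma / offset_sigma`` deep inside bone, 0 well
    outside the body, 1 in unconstrained soft tissue, Gaussian-smoothed
    so the transition has no spatial discontinuity.
    """
    if "bone" not in masks or "body" not in masks:
        raise ValueError("correction map requires bone and body masks")
    bone = masks["bone"].astype(bool)
    body = masks["body"].astype(bool)
    ratio = (config.bone_sigma / config.offset_sigma
             if config.offset_sigma > 0 else 0.0)
    raw = np.zeros(masks.shape, dtype=np.float64)
    raw[body] = 1.0
    raw[bone] = ratio
    sigma_px = config.correction_smoothing / spacing_mm
    return ndimage.gaussian_filter(raw, sigma=sigma_px, mode="constant")


def sample_organ_expansion(mask: np.ndarray,
                           amplitude_range: tuple[float, float],
                           seed: int | np.random.Generator = 0,
                           *,
                           displacement_per_unit: float = 0.02,
                           band_px: float = 24.0,
                           amplitude: float | None = None,
                           ) -> DisplacementField:
    """Random radial expansion of one organ.

    The field is radial about the mask centroid: magnitude ramps from 0
    at the centroid to the peak at the organ boundary, then tapers to 0
    over a Gaussian band of width ``band_px`` outside the mask (this
    spill-over is what deforms neighbouring structures, e.g. rectal
    filling displacing the cervix).  The peak equals the amplitude
    (uniform draw from ``amplitude_range`` unless ``amplitude`` is given)
    times the pixel calibration.  The returned backward field points
    toward the centroid so the *warped* organ expands.

    An empty mask yields a zero field with a warning, not an error.
    """
    mask = np.asarray(mask).astype(bool)
    shape = mask.shape
    if not mask.any():
        log.warning("organ expansion requested on empty mask; zero field")
        return DisplacementField.zeros(shape)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if amplitude is None:
        amplitude = rng.uniform(*amplitude_range)
    peak_px = amplitude * displacement_per_unit

    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = ndimage.center_of_mass(mask)
    ry = yy - cy
    rx = xx - cx
    r = np.hypot(ry, rx)
    with np.errstate(invalid="ignore", divide="ignore"):
        uy = np.where(r > 0, ry / r, 0.0)
        ux = np.where(r > 0, rx / r, 0.0)

    # radial ramp inside (0 at centroid -> 1 at boundary), Gaussian taper out
    dist_in = ndimage.distance_transform_edt(mask)      # depth inside organ
    dist_out = ndimage.distance_transform_edt(~mask)    # distance outside
    profile = np.where(mask, r / np.maximum(r + dist_in, 1e-9),
                       np.exp(-0.5 * (2.0 * dist_out / band_px) ** 2))
    profile = ndimage.gaussian_filter(profile, sigma=2.0)
    # normalize so the organ-mean displacement is amplitude-proportional
    # independent of organ shape (an ideal conical ramp has mean 2/3, so
    # the boundary peak stays ~= amplitude * displacement_per_unit)
    profile *= (2.0 / 3.0) / max(profile[mask].mean(), 1e-9)

    mag = peak_px * profile
    # backward-warp convention: inward-pointing vectors expand the organ
    return DisplacementField(-mag * uy, -mag * ux)


def compose_deformation(shape: tuple[int, int], masks: OrganMaskSet,
                        config: DeformationConfig | None = None,
                        seed: int | None = None,
                        spacing_mm: float = 0.84) -> DisplacementField:
    """Compose the full simulated deformation field (pixels).

    ``field = k * [correction_map x GRF offset (per axis)] + rectum
    expansion + bladder expansion`` with ``k`` the pixel calibration.
    The per-pair severity deviate couples the two amplitude draws
    (marginally uniform over their configured ranges) so that the mean
    displacement ordering rectum > bladder > bone holds per field.
    Deterministic under the seed.
    """
    config = config or DeformationConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    k = config.displacement_per_unit

    grf_params = GRFParams(mean=0.0, sigma=config.offset_sigma,
                           correlation_length=config.correlation_length)
    corr = build_correction_map(masks, config, spacing_mm)
    dy = k * corr * sample_grf(shape, grf_params, rng)
    dx = k * corr * sample_grf(shape, grf_params, rng)
    total = DisplacementField(dy, dx)

    severity = rng.uniform()
    for organ, amp_range in (("rectum", config.rectum_amplitude_range),
                             ("bladder", config.bladder_amplitude_range)):
        if organ not in masks or not masks[organ].any():
            continue
        lo, hi = amp_range
        total = total + sample_organ_expansion(
            masks[organ], amp_range, rng,
            displacement_per_unit=k, band_px=config.expansion_band_px,
            amplitude=lo + (hi - lo) * severity)
    return total


# ---------------------------------------------------------------------------
# Warping
# ---------------------------------------------------------------------------

def warp_image(image: ImageSlice, field: DisplacementField,
               interpolation: str = "bilinear") -> ImageSlice:
    """Backward-warp an HU image under the field (clamp-to-edge border)."""
    if image.shape != field.shape:
        raise ValueError(
            f"image shape {image.shape} != field shape {field.shape}")
    if interpolation == "bilinear":
        out = warp_bilinear(image.pixels, field.dy, field.dx)
    elif interpolation == "bicubic":
        out = warp_bicubic(image.pixels, field.dy, field.dx)
    else:
        raise ValueError(f"unknown interpolation: {interpolation!r}")
    return image.with_pixels(out)


def warp_mask(mask: np.ndarray, field: DisplacementField) -> np.ndarray:
    """Bilinear warp of a binary mask, thresholded at 0.5 (uint8 {0,1})."""
    mask = np.asarray(mask)
    if mask.shape != field.shape:
        raise ValueError(
            f"mask shape {mask.shape} != field shape {field.shape}")
    return warp_mask_binary(mask, field.dy, field.dx)


@dataclass
class TrainingPair:
    """A fixed/moving pair with its ground-truth simulated field."""

    fixed: ImageSlice
    fixed_masks: OrganMaskSet
    moving: ImageSlice
    moving_masks: OrganMaskSet
    field: DisplacementField
    seed: int = 0


def make_training_pair(slice_: ImageSlice, masks: OrganMaskSet,
                       config: DeformationConfig | None = None,
                       seed: int | None = None) -> TrainingPair:
    """Build a training pair: fixed = original, moving = deformed copy.

    The image and every mask are warped under one composed field, which
    is returned for oracle testing.  Reproducible under the seed.
    """
    config = config or DeformationConfig()
    seed = config.seed if seed is None else seed
    fld = compose_deformation(slice_.shape, masks, config, seed,
                              spacing_mm=slice_.spacing_y)
    moving = warp_image(slice_, fld, interpolation="bilinear")
    moving_masks = masks.map(lambda m: warp_mask(m, fld))
    return TrainingPair(fixed=slice_, fixed_masks=masks, moving=moving,
                        moving_masks=moving_masks, field=fld, seed=seed)
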