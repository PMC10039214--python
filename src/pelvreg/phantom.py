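"""Synthetic pelvic CT phantom generator.

Produces 2D HU slices that structurally emulate a female-pelvis planning
CT: an elliptical soft-tissue body on an air background, a posterior
couch bar, two lateral bony regions, and three non-overlapping
soft-tissue organs (bladder anterior, cervix central, rectum posterior)
with randomized smooth blob boundaries.  Every other module in the
package is testable against these phantoms because the ground-truth
masks are known by construction.

The generator is deterministic under its seed (bit-identical arrays).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .io import ImageSlice, OrganMaskSet

#: Soft-tissue organs that receive their own mask, with plausible mean HU.
DEFAULT_ORGAN_HU = {"bladder": 10.0, "cervix": 45.0, "rectum": -30.0}


class PhantomPlacementError(RuntimeError):
    """Raised when organ regions cannot be placed without overlap."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity parameters of the synthetic pelvis.

    Defaults mimic a 512 x 512 planning-CT slice at 0.84 mm spacing
    before body cropping.  All soft-tissue HU must lie in (-100, 150),
    the couch mean inside (-405, -340), bone above 150 HU; air is -1000.
    ``organ_scale`` uniformly scales organ radii (used to exercise the
    overlap-failure contract).
    """

    image_height: int = 512
    image_width: int = 512
    pixel_spacing: float = 0.84
    organ_hu: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_HU))
    body_hu: float = 35.0
    bone_hu: float = 500.0
    couch_hu: float = -372.0
    noise_sd: float = 10.0
    organ_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if not (-405.0 < self.couch_hu < -340.0):
            raise ValueError("couch_hu must lie strictly inside (-405, -340)")
        for name, hu in self.organ_hu.items():
            if not (-100.0 < hu < 150.0):
                raise ValueError(
                    f"soft-tissue HU for {name!r} must lie inside (-100, 150)")
        if not (-100.0 < self.body_hu < 150.0):
            raise ValueError("body_hu must lie inside (-100, 150)")
        if self.bone_hu <= 150.0:
            raise ValueError("bone_hu must exceed 150")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _blob_mask(shape, center, ry, rx, rng, wobble=0.06, n_harmonics=4):
    """Smoothly-perturbed superellipse: radius r(theta) modulated by a
    low-order random Fourier series, giving realistic curved contours."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    dy = (yy - center[0]) / ry
    dx = (xx - center[1]) / rx
    theta = np.arctan2(dy, dx)
    pert = np.zeros_like(theta)
    for k in range(1, n_harmonics + 1):
        a, b = rng.normal(0.0, wobble / np.sqrt(k), size=2)
        pert += a * np.cos(k * theta) + b * np.sin(k * theta)
    pert = np.clip(pert, -0.15, 0.15)
    r = np.hypot(dy, dx)
    return (r <= 1.0 + pert).astype(np.uint8)


def _ellipse_mask(shape, center, ry, rx):
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    return ((((yy - center[0]) / ry) ** 2 +
             ((xx - center[1]) / rx) ** 2) <= 1.0).astype(np.uint8)


def _layout(config: PhantomConfig, rng: np.random.Generator,
            organ_size_factor: Mapping[str, float] | None = None):
    """Sample the geometric layout (centers and radii) for one slice."""
    H, W = config.image_height, config.image_width
    bc_y, bc_x = 0.46 * H, 0.50 * W          # body center, anterior-up
    body_ry, body_rx = 0.215 * H, 0.42 * W   # height fits a H/2 crop
    s = config.organ_scale
    f = dict(organ_size_factor or {})
    jitter = lambda a: rng.uniform(-0.005, 0.005) * min(H, W) + a
    geo = {
        "body": ((bc_y, bc_x), body_ry, body_rx),
        "bone_left": ((jitter(bc_y + 0.04 * body_ry),
                       jitter(bc_x - 0.58 * body_rx)),
                      0.34 * body_ry, 0.17 * body_rx),
        "bone_right": ((jitter(bc_y + 0.04 * body_ry),
                        jitter(bc_x + 0.58 * body_rx)),
                       0.34 * body_ry, 0.17 * body_rx),
        "bladder": ((jitter(bc_y - 0.50 * body_ry), jitter(bc_x)),
                    s * f.get("bladder", 1.0) * 0.24 * body_ry,
                    s * f.get("bladder", 1.0) * 0.21 * body_rx),
        "cervix": ((jitter(bc_y + 0.04 * body_ry), jitter(bc_x)),
                   s * f.get("cervix", 1.0) * 0.16 * body_ry,
                   s * f.get("cervix", 1.0) * 0.13 * body_rx),
        "rectum": ((jitter(bc_y + 0.54 * body_ry), jitter(bc_x)),
                   s * f.get("rectum", 1.0) * 0.18 * body_ry,
                   s * f.get("rectum", 1.0) * 0.12 * body_rx),
    }
    return geo


def _draw_regions(config, rng_shape, shape, organ_size_factor):
    """One attempt at drawing body/bone/organ regions; raises on overlap."""
    geo = _layout(config, rng_shape, organ_size_factor)
    body = _ellipse_mask(shape, *geo["body"])
    bone = np.zeros(shape, np.uint8)
    for key in ("bone_left", "bone_right"):
        c, ry, rx = geo[key]
        bone |= _blob_mask(shape, c, ry, rx, rng_shape, wobble=0.05)
    organs = {}
    for name in ("bladder", "cervix", "rectum"):
        c, ry, rx = geo[name]
        if ry < 0.5 or rx < 0.5:
            organs[name] = np.zeros(shape, np.uint8)
        else:
            organs[name] = _blob_mask(shape, c, ry, rx, rng_shape)

    # containment and disjointness: explicit failure, not silent shrinkage
    regions = dict(organs, bone=bone)
    for name, m in regions.items():
        if np.any(m & ~body):
            raise PhantomPlacementError(
                f"{name} region extends outside the body at the requested size")
    names = list(regions)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.any(regions[a] & regions[b]):
                raise PhantomPlacementError(
                    f"{a} and {b} regions overlap at the requested sizes")
    return body, bone, organs


def generate_phantom_slice(config: PhantomConfig | None = None,
                           seed: int | None = None,
                           organ_size_factor: Mapping[str, float] | None = None,
                           shape_seed: int | None = None,
                           ) -> tuple[ImageSlice, OrganMaskSet]:
    """Generate one phantom slice with ground-truth masks.

    Returns an HU image plus pairwise-disjoint binary masks for bladder,
    cervix, rectum and bone, all strictly inside the body mask.  Organ
    placements that would overlap at the requested sizes raise
    :class:`PhantomPlacementError` rather than silently shrinking.

    ``organ_size_factor`` scales individual organ radii and ``shape_seed``
    pins the geometry (centers and boundary wobble) independently of the
    noise seed; :func:`generate_patient` uses both so that one patient's
    slices share an anatomy while CT noise stays independent per slice.
    A size factor of 0 yields an empty mask for that organ.
    """
    config = config or PhantomConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    rng_shape = rng if shape_seed is None else np.random.default_rng(shape_seed)
    H, W = config.image_height, config.image_width
    shape = (H, W)

    # a random boundary-wobble draw can occasionally make neighbouring
    # regions touch; redraw a bounded number of times (deterministic
    # under the seed) before declaring the requested sizes infeasible
    last_error = None
    for _ in range(5):
        try:
            body, bone, organs = _draw_regions(config, rng_shape, shape,
                                               organ_size_factor)
            last_error = None
            break
        except PhantomPlacementError as exc:
            last_error = exc
    if last_error is not None:
        raise last_error

    image = np.full(shape, -1000.0)
    image[body == 1] = config.body_hu
    image[bone == 1] = config.bone_hu
    for name, m in organs.items():
        image[m == 1] = config.organ_hu[name]

    # posterior couch bar, disjoint from the body
    couch = np.zeros(shape, np.uint8)
    y0, y1 = int(0.93 * H), int(0.965 * H)
    x0, x1 = int(0.15 * W), int(0.85 * W)
    couch[y0:y1, x0:x1] = 1
    if np.any(couch & body):  # pragma: no cover - geometry guards this
        raise PhantomPlacementError("couch bar intersects the body")
    image[couch == 1] = config.couch_hu

    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=shape)
    # keep the structural HU contracts exact despite the additive noise
    image[couch == 1] = np.clip(image[couch == 1], -404.0, -341.0)
    image[bone == 1] = np.maximum(image[bone == 1], 151.0)

    sl = ImageSlice(pixels=image, spacing_y=config.pixel_spacing,
                    spacing_x=config.pixel_spacing)
    masks = OrganMaskSet({**organs, "bone": bone, "body": body,
                          "couch": couch})
    return sl, masks


def generate_patient(config: PhantomConfig | None = None,
                     n_slices: int = 10,
                     seed: int | None = None,
                     ) -> list[tuple[ImageSlice, OrganMaskSet]]:
    """Generate a coherent slice stack for one synthetic patient.

    Organ sizes vary smoothly across slices through a low-frequency
    random walk on per-organ radius factors, tapered toward the stack
    ends (an organ may vanish there, yielding empty masks downstream
    consumers must tolerate).  Adjacent slices keep a consecutive-slice
    organ Dice of at least ~0.5 by bounding the walk's step size.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    config = config or PhantomConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    # smooth per-organ size profiles: tapered base + bounded random walk
    t = np.linspace(0.0, 1.0, n_slices) if n_slices > 1 else np.array([0.5])
    taper = np.clip(np.sin(np.pi * np.clip(t, 0.03, 0.97)) ** 0.4, 0.0, 1.0)
    profiles = {}
    for organ in ("bladder", "cervix", "rectum"):
        steps = rng.normal(0.0, 0.04, size=n_slices)
        walk = np.cumsum(steps) - np.linspace(0, steps.sum(), n_slices)
        profiles[organ] = np.clip(taper * (1.0 + walk), 0.0, 1.1)

    stack = []
    shape_seed = int(rng.integers(0, 2**31 - 1))
    slice_seeds = rng.integers(0, 2**31 - 1, size=n_slices)
    for i in range(n_slices):
        factors = {o: float(profiles[o][i]) for o in profiles}
        stack.append(generate_phantom_slice(
            config, seed=int(slice_seeds[i]), organ_size_factor=factors,
            shape_seed=shape_seed))
    return stack
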