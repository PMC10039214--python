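"""CT preprocessing chain: couch elimination, bone extraction, body crop.

The fixed pipeline order is couch removal -> bone extraction -> crop.
Bone is segmented by a strict HU threshold (> 150); the treatment couch
is detected as connected components whose median HU falls in the couch
window (-405, -340) and that are disjoint from the body, then replaced
by air (-1000 HU).  Slices are finally cropped to a fixed matrix
(256 x 512 by default) that must contain the whole body.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .io import ImageSlice, OrganMaskSet

BONE_HU_THRESHOLD = 150.0
COUCH_HU_RANGE = (-405.0, -340.0)
CROP_TARGET = (256, 512)
AIR_HU = -1000.0
_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def body_mask(slice_: ImageSlice, hu_threshold: float = -300.0) -> np.ndarray:
    """Binary body mask: threshold, largest connected component, hole fill."""
    rough = slice_.pixels > hu_threshold
    labels, n = ndimage.label(rough, structure=_CROSS)
    if n == 0:
        return np.zeros(slice_.shape, dtype=np.uint8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    largest = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(largest).astype(np.uint8)


def extract_bone_mask(slice_: ImageSlice,
                      hu_threshold: float = BONE_HU_THRESHOLD,
                      min_component_px: int = 20) -> np.ndarray:
    """Bone mask: pixels with HU strictly above ``hu_threshold``.

    Components smaller than ``min_component_px`` are removed, as an
    automatable surrogate for visual verification of the segmentation.
    Couch pixels fall far below the threshold and are never included.
    """
    raw = slice_.pixels > hu_threshold
    labels, n = ndimage.label(raw, structure=_CROSS)
    if n == 0:
        return raw.astype(np.uint8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    keep = np.flatnonzero(sizes >= min_component_px) + 1
    return np.isin(labels, keep).astype(np.uint8)


def remove_couch(slice_: ImageSlice,
                 hu_range: tuple[float, float] = COUCH_HU_RANGE,
                 ) -> ImageSlice:
    """Replace couch components by air.

    A connected component counts as couch when its median HU lies inside
    ``hu_range`` *and* it is disjoint from the body mask; body pixels are
    never modified.  Idempotent; a couch-free slice is returned unchanged.
    """
    lo, hi = hu_range
    body = body_mask(slice_).astype(bool)
    candidate = (slice_.pixels > lo) & (slice_.pixels < hi) & ~body
    labels, n = ndimage.label(candidate, structure=_CROSS)
    if n == 0:
        return slice_
    out = slice_.pixels.copy()
    changed = False
    for lab in range(1, n + 1):
        comp = labels == lab
        med = np.median(slice_.pixels[comp])
        if lo < med < hi and not np.any(comp & body):
            out[comp] = AIR_HU
            changed = True
    return slice_.with_pixels(out) if changed else slice_


def crop_to_body(slice_: ImageSlice, masks: OrganMaskSet | None = None,
                 target: tuple[int, int] = CROP_TARGET,
                 ) -> tuple[ImageSlice, OrganMaskSet | None]:
    """Crop image (and masks identically) to a fixed ``target`` matrix.

    The crop window is centred on the body bounding box along the
    anterior-posterior (row) axis and must contain the full body; a body
    taller or wider than the target is an explicit error, never a silent
    truncation of anatomy.
    """
    th, tw = target
    H, W = slice_.shape
    if th > H or tw > W:
        raise ValueError(f"target {target} exceeds image shape {slice_.shape}")
    body = body_mask(slice_)
    if not body.any():
        raise ValueError("no body found to crop around")
    rows = np.flatnonzero(body.any(axis=1))
    cols = np.flatnonzero(body.any(axis=0))
    bh = rows[-1] - rows[0] + 1
    bw = cols[-1] - cols[0] + 1
    if bh > th:
        raise ValueError(f"body height {bh} exceeds crop target {th}")
    if bw > tw:
        raise ValueError(f"body width {bw} exceeds crop target {tw}")
    y0 = int(np.clip((rows[0] + rows[-1] + 1 - th) // 2, 0, H - th))
    x0 = int(np.clip((cols[0] + cols[-1] + 1 - tw) // 2, 0, W - tw))

    win = (slice(y0, y0 + th), slice(x0, x0 + tw))
    oy, ox = slice_.origin
    cropped = ImageSlice(
        pixels=slice_.pixels[win],
        spacing_y=slice_.spacing_y, spacing_x=slice_.spacing_x,
        origin=(oy + y0 * slice_.spacing_y, ox + x0 * slice_.spacing_x))
    cropped_masks = masks.map(lambda m: m[win]) if masks is not None else None
    return cropped, cropped_masks


def preprocess_slice(slice_: ImageSlice, masks: OrganMaskSet | None = None,
                     target: tuple[int, int] = CROP_TARGET,
                     bone_threshold: float = BONE_HU_THRESHOLD,
                     couch_range: tuple[float, float] = COUCH_HU_RANGE,
                     ) -> tuple[ImageSlice, OrganMaskSet]:
    """Full chain: remove couch, extract bone, crop to the target matrix.

    If ``masks`` lacks a bone or body mask, they are derived from the
    image; user-provided organ masks are passed through the crop.
    """
    decouched = remove_couch(slice_, couch_range)
    out_masks = dict(masks.masks) if masks is not None else {}
    if "bone" not in out_masks:
        out_masks["bone"] = extract_bone_mask(decouched, bone_threshold)
    if "body" not in out_masks:
        out_masks["body"] = body_mask(decouched)
    out_masks.pop("couch", None)
    cropped, cropped_masks = crop_to_body(
        decouched, OrganMaskSet(out_masks), target)
    return cropped, cropped_masks
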