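"""Dense backward warping primitives with analytic field gradients.

Convention (fixed package-wide): a displacement field ``(dy, dx)`` in
pixel units defines the backward warp ``output(p) = input(p + d(p))``.
Sample positions outside the image are clamped to the border
(clamp-to-edge), so border values extend outward.

Bilinear and bicubic (Keys, a = -0.5) interpolation are provided, each
with the partial derivatives of the warped output with respect to the
field components needed to backpropagate through a spatial transformer.
"""

from __future__ import annotations

import numpy as np


def _gather(img: np.ndarray, yi: np.ndarray, xi: np.ndarray) -> np.ndarray:
    """img[..., yi, xi] with indices clamped to the image bounds."""
    H, W = img.shape[-2:]
    yi = np.clip(yi, 0, H - 1)
    xi = np.clip(xi, 0, W - 1)
    return img[..., yi, xi]


def warp_bilinear(img: np.ndarray, dy: np.ndarray, dx: np.ndarray,
                  ) -> np.ndarray:
    """Backward bilinear warp of ``img`` (leading axes broadcast over)."""
    H, W = img.shape[-2:]
    yy, xx = np.mgrid[0:H, 0:W]
    sy = np.clip(yy + dy, 0.0, H - 1.0)
    sx = np.clip(xx + dx, 0.0, W - 1.0)
    y0 = np.floor(sy).astype(np.intp)
    x0 = np.floor(sx).astype(np.intp)
    fy = sy - y0
    fx = sx - x0
    i00 = _gather(img, y0, x0)
    i01 = _gather(img, y0, x0 + 1)
    i10 = _gather(img, y0 + 1, x0)
    i11 = _gather(img, y0 + 1, x0 + 1)
    top = i00 * (1 - fx) + i01 * fx
    bot = i10 * (1 - fx) + i11 * fx
    return top * (1 - fy) + bot * fy


def warp_bilinear_with_grad(img, dy, dx):
    """Bilinear warp plus d(out)/d(dy), d(out)/d(dx).

    Where the sample position is clamped at the border, the clamped
    coordinate no longer depends on the field, so the corresponding
    gradient is exactly zero.
    """
    H, W = img.shape[-2:]
    yy, xx = np.mgrid[0:H, 0:W]
    ry = yy + dy
    rx = xx + dx
    sy = np.clip(ry, 0.0, H - 1.0)
    sx = np.clip(rx, 0.0, W - 1.0)
    y0 = np.floor(sy).astype(np.intp)
    x0 = np.floor(sx).astype(np.intp)
    fy = sy - y0
    fx = sx - x0
    i00 = _gather(img, y0, x0)
    i01 = _gather(img, y0, x0 + 1)
    i10 = _gather(img, y0 + 1, x0)
    i11 = _gather(img, y0 + 1, x0 + 1)
    out = (i00 * (1 - fx) + i01 * fx) * (1 - fy) \
        + (i10 * (1 - fx) + i11 * fx) * fy
    free_y = (ry > 0.0) & (ry < H - 1.0)
    free_x = (rx > 0.0) & (rx < W - 1.0)
    d_dy = ((i10 - i00) * (1 - fx) + (i11 - i01) * fx) * free_y
    d_dx = ((i01 - i00) * (1 - fy) + (i11 - i10) * fy) * free_x
    return out, d_dy, d_dx


# Keys cubic-convolution kernel, a = -0.5 (the common "bicubic")
_A = -0.5


def _cubic_weights(f: np.ndarray):
    """Weights for the 4 taps at offsets (-1, 0, 1, 2) given fraction f."""
    t0 = 1.0 + f   # distance to tap -1, in [1, 2)
    t1 = f         # distance to tap 0, in [0, 1)
    t2 = 1.0 - f
    t3 = 2.0 - f
    w0 = _A * t0 ** 3 - 5 * _A * t0 ** 2 + 8 * _A * t0 - 4 * _A
    w1 = (_A + 2) * t1 ** 3 - (_A + 3) * t1 ** 2 + 1.0
    w2 = (_A + 2) * t2 ** 3 - (_A + 3) * t2 ** 2 + 1.0
    w3 = _A * t3 ** 3 - 5 * _A * t3 ** 2 + 8 * _A * t3 - 4 * _A
    return (w0, w1, w2, w3)


def _cubic_dweights(f: np.ndarray):
    """d/df of the 4 tap weights (chain rule: d/d(tap distance) * sign)."""
    t0 = 1.0 + f
    t1 = f
    t2 = 1.0 - f
    t3 = 2.0 - f
    d0 = 3 * _A * t0 ** 2 - 10 * _A * t0 + 8 * _A          # * d t0/df = +1
    d1 = 3 * (_A + 2) * t1 ** 2 - 2 * (_A + 3) * t1        # * +1
    d2 = -(3 * (_A + 2) * t2 ** 2 - 2 * (_A + 3) * t2)     # * -1
    d3 = -(3 * _A * t3 ** 2 - 10 * _A * t3 + 8 * _A)       # * -1
    return (d0, d1, d2, d3)


def warp_bicubic(img, dy, dx, with_grad: bool = False):
    """Backward bicubic warp; optionally also field gradients.

    Returns ``out`` or ``(out, d_dy, d_dx)``.  Exact identity for a zero
    field (weights evaluate to exactly (0, 1, 0, 0) at zero fraction).
    """
    H, W = img.shape[-2:]
    yy, xx = np.mgrid[0:H, 0:W]
    ry = yy + dy
    rx = xx + dx
    sy = np.clip(ry, 0.0, H - 1.0)
    sx = np.clip(rx, 0.0, W - 1.0)
    y0 = np.floor(sy).astype(np.intp)
    x0 = np.floor(sx).astype(np.intp)
    fy = sy - y0
    fx = sx - x0
    wy = _cubic_weights(fy)
    wx = _cubic_weights(fx)
    rows = [sum(wx[j] * _gather(img, y0 + i - 1, x0 + j - 1)
                for j in range(4)) for i in range(4)]
    out = sum(wy[i] * rows[i] for i in range(4))
    if not with_grad:
        return out
    dwy = _cubic_dweights(fy)
    dwx = _cubic_dweights(fx)
    drows = [sum(dwx[j] * _gather(img, y0 + i - 1, x0 + j - 1)
                 for j in range(4)) for i in range(4)]
    # clamped samples do not move with the field -> zero gradient there
    free_y = (ry > 0.0) & (ry < H - 1.0)
    free_x = (rx > 0.0) & (rx < W - 1.0)
    d_dy = sum(dwy[i] * rows[i] for i in range(4)) * free_y
    d_dx = sum(wy[i] * drows[i] for i in range(4)) * free_x
    return out, d_dy, d_dx


def warp_mask_binary(mask: np.ndarray, dy: np.ndarray, dx: np.ndarray,
                     ) -> np.ndarray:
    """Bilinear warp of a {0,1} mask followed by thresholding at 0.5.

    The >= 0.5 tie-break is deterministic; output is uint8 {0,1}.
    """
    soft = warp_bilinear(mask.astype(np.float64), dy, dx)
    return (soft >= 0.5).astype(np.uint8)
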