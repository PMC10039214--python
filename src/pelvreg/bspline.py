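"""Cubic B-spline spatial transformer: control grid -> dense field.

A coarse grid of 2D control-point displacements, spaced ``grid_spacing``
pixels apart (control point ``(i, j)`` sits at pixel ``(i*s, j*s)``),
parameterizes a dense displacement field.  Each pixel's displacement is
the tensor-product cubic B-spline interpolation of the 4 x 4 surrounding
control displacements,

    f(x) = sum_i alpha_i * B3(x/s - i),

which is C^2-smooth and has local support.  Control indices outside the
stored grid are clamped (edge replication), which preserves the
partition of unity everywhere, so a constant control grid produces an
exactly constant dense field.

The pixel -> control-point map is linear; its transpose backpropagates
dense-field gradients to the control grid during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .deform import DisplacementField


def cubic_bspline(t: np.ndarray) -> np.ndarray:
    """The cubic B-spline basis B3(t), support |t| < 2, unit integral."""
    t = np.abs(np.asarray(t, dtype=np.float64))
    out = np.zeros_like(t)
    m1 = t < 1
    m2 = (t >= 1) & (t < 2)
    out[m1] = (4.0 - 6.0 * t[m1] ** 2 + 3.0 * t[m1] ** 3) / 6.0
    out[m2] = (2.0 - t[m2]) ** 3 / 6.0
    return out


@dataclass
class ControlPointGrid:
    """Displacements (2, Gh, Gw) on a coarse control grid (pixels)."""

    displacements: np.ndarray
    grid_spacing: int = 16

    def __post_init__(self):
        d = np.asarray(self.displacements, dtype=np.float64)
        if d.ndim != 3 or d.shape[0] != 2:
            raise ValueError("displacements must have shape (2, Gh, Gw)")
        if not np.all(np.isfinite(d)):
            raise ValueError("control displacements must be finite")
        if self.grid_spacing < 1:
            raise ValueError("grid_spacing must be >= 1")
        self.displacements = d

    @property
    def shape(self) -> tuple[int, int]:
        return self.displacements.shape[1:]


def _basis_matrix(n_pixels: int, n_ctrl: int, spacing: int) -> np.ndarray:
    """(n_pixels, n_ctrl) matrix of clamped cubic B-spline weights.

    Row p holds B3(p/s - i) accumulated onto clamped control index i for
    the four supporting control points; rows sum to exactly 1.
    """
    if n_ctrl < 2:
        raise ValueError("need at least 2 control points per axis")
    B = np.zeros((n_pixels, n_ctrl))
    u = np.arange(n_pixels, dtype=np.float64) / spacing
    base = np.floor(u).astype(int)
    frac = u - base
    for m in range(-1, 3):
        w = cubic_bspline(frac - m)
        idx = np.clip(base + m, 0, n_ctrl - 1)
        np.add.at(B, (np.arange(n_pixels), idx), w)
    return B


def basis_matrices(output_shape: tuple[int, int], grid_shape: tuple[int, int],
                   spacing: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis basis matrices (By, Bx) for a given output/grid geometry."""
    H, W = output_shape
    Gh, Gw = grid_shape
    if (Gh - 1) * spacing < H - spacing or (Gw - 1) * spacing < W - spacing:
        # clamping covers a one-cell shortfall; anything more is an error
        raise ValueError(
            f"control grid {grid_shape} at spacing {spacing} cannot cover "
            f"output {output_shape}")
    return _basis_matrix(H, Gh, spacing), _basis_matrix(W, Gw, spacing)


def bspline_to_dense(grid: ControlPointGrid,
                     output_shape: tuple[int, int]) -> DisplacementField:
    """Interpolate the control grid to a dense displacement field."""
    By, Bx = basis_matrices(output_shape, grid.shape, grid.grid_spacing)
    dy = By @ grid.displacements[0] @ Bx.T
    dx = By @ grid.displacements[1] @ Bx.T
    return DisplacementField(dy, dx)


def dense_batch(cp: np.ndarray, By: np.ndarray, Bx: np.ndarray) -> np.ndarray:
    """Batched control grids (B, 2, Gh, Gw) -> dense fields (B, 2, H, W)."""
    return np.einsum("hg,bcgk,wk->bchw", By, cp, Bx, optimize=True)


def dense_batch_grad(grad_dense: np.ndarray, By: np.ndarray,
                     Bx: np.ndarray) -> np.ndarray:
    """Transpose of :func:`dense_batch`: dense grads -> control-grid grads."""
    return np.einsum("hg,bchw,wk->bcgk", By, grad_dense, Bx, optimize=True)


def evaluate_direct(grid: ControlPointGrid, points_yx: np.ndarray,
                    ) -> np.ndarray:
    """Brute-force spline evaluation at arbitrary pixel points.

    Sums alpha_i * B3 over *all* control points for each query point —
    the independent oracle the separable fast path is tested against.
    Returns (N, 2) displacements.
    """
    s = grid.grid_spacing
    Gh, Gw = grid.shape
    pts = np.asarray(points_yx, dtype=np.float64)
    out = np.zeros((len(pts), 2))
    for n, (py, px) in enumerate(pts):
        uy = py / s
        ux = px / s
        for c in range(2):
            acc = 0.0
            for i in range(Gh):
                # replicate the edge-clamped accumulation of the fast path
                wy = _clamped_weight(uy, i, Gh)
                if wy == 0.0:
                    continue
                for j in range(Gw):
                    wx = _clamped_weight(ux, j, Gw)
                    if wx != 0.0:
                        acc += wy * wx * grid.displacements[c, i, j]
            out[n, c] = acc
    return out


def _clamped_weight(u: float, i: int, n_ctrl: int) -> float:
    """Weight of clamped control index i at spline coordinate u."""
    base = int(np.floor(u))
    w = 0.0
    for m in range(-1, 3):
        if int(np.clip(base + m, 0, n_ctrl - 1)) == i:
            w += float(cubic_bspline(np.array(u - base - m)))
    return w
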