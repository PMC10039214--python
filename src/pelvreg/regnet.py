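"""The DIRNet-style registration network family.

A convolutional regressor maps a channel-concatenated fixed/moving pair
to a coarse grid of 2D control-point displacements; a cubic B-spline
spatial transformer interpolates the grid to a dense displacement field;
a resampler backward-warps the moving image (bicubic) and its organ
masks (bilinear, kept soft for the loss) to the fixed frame.  Training
minimizes an image dissimilarity (negative global NCC, or MSE) plus a
soft-Dice dissimilarity between warped and fixed organ masks —
incorporating the masks into the backpropagation flow.

Four variants are supported, differing in conv depth, loss and pooling:

======= ======== ===== ========
variant n_conv   loss  pooling
======= ======== ===== ========
1       4        NCC   2x2 avg
2       4        MSE   2x2 avg
3       4        NCC   none
4       8        NCC   2x2 avg
======= ======== ===== ========

Each conv layer has sixteen 3 x 3 kernels, ELU activations and batch
normalization (momentum 0.9); the final layer is a linear 3 x 3 conv to
2 channels, zero-initialized so an untrained network realizes the
identity transform.  With pooling, the four 2 x 2 average-pooling stages
downsample by 16, so the regressor's output resolution *is* the control
grid (spacing 16 px); the no-pooling variant regresses a full-resolution
parameter map that is strided every ``grid_spacing`` pixels onto the
same control-grid geometry, so all variants share one transformer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from ._warp import warp_bicubic, warp_bilinear_with_grad, warp_mask_binary
from .bspline import (ControlPointGrid, basis_matrices, dense_batch,
                      dense_batch_grad)
from .deform import DisplacementField
from .io import ImageSlice, OrganMaskSet

#: Mask channels fed to the network and used in the loss, in order.
INPUT_MASKS = ("bladder", "cervix", "rectum", "bone")

HU_CLIP = (-1000.0, 2000.0)


def normalize_hu(pixels: np.ndarray) -> np.ndarray:
    """Clip HU to [-1000, 2000] and scale to [0, 1] for the network."""
    lo, hi = HU_CLIP
    return (np.clip(pixels, lo, hi) - lo) / (hi - lo)


@dataclass(frozen=True)
class ModelVariantConfig:
    """One network variant (a row of the variant table above)."""

    variant_id: int = 1
    n_conv_layers: int = 4
    kernel_size: int = 3
    kernels_per_layer: int = 16
    pooling: bool = True
    loss: str = "NCC"
    input_channels_per_image: int = 5   # image + 4 organ masks

    def __post_init__(self):
        if self.loss not in ("NCC", "MSE"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.input_channels_per_image not in (1, 5):
            raise ValueError("input_channels_per_image must be 1 or 5")

    @property
    def input_channels(self) -> int:
        return 2 * self.input_channels_per_image

    @property
    def uses_masks(self) -> bool:
        return self.input_channels_per_image == 5


_VARIANTS = {
    1: dict(n_conv_layers=4, loss="NCC", pooling=True),
    2: dict(n_conv_layers=4, loss="MSE", pooling=True),
    3: dict(n_conv_layers=4, loss="NCC", pooling=False),
    4: dict(n_conv_layers=8, loss="NCC", pooling=True),
}


def variant_config(variant_id: int, **overrides) -> ModelVariantConfig:
    """The canonical configuration of variant 1-4 (plus overrides)."""
    if variant_id not in _VARIANTS:
        raise ValueError(f"unknown variant {variant_id}; expected 1-4")
    kw = dict(_VARIANTS[variant_id], variant_id=variant_id)
    kw.update(overrides)
    return ModelVariantConfig(**kw)


# ---------------------------------------------------------------------------
# Regressor
# ---------------------------------------------------------------------------

N_POOL_STAGES = 4  # fixed: downsample-by-16 = control-grid spacing 16


class Regressor:
    """ConvNet regressor: input pair -> control-point displacement grid."""

    def __init__(self, config: ModelVariantConfig, grid_spacing: int = 16,
                 seed: int | np.random.Generator = 0):
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        self.config = config
        self.grid_spacing = grid_spacing
        layers: list[nn.Layer] = []
        n_conv = config.n_conv_layers
        pool_after = set()
        if config.pooling:
            step = n_conv // N_POOL_STAGES
            if step < 1:
                raise ValueError("need >= 4 conv layers with pooling")
            pool_after = {step * (k + 1) - 1 for k in range(N_POOL_STAGES)}
        ch = config.input_channels
        for i in range(n_conv):
            layers.append(nn.Conv2d(ch, config.kernels_per_layer,
                                    config.kernel_size, rng=rng))
            layers.append(nn.BatchNorm2d(config.kernels_per_layer,
                                         momentum=0.9))
            layers.append(nn.ELU())
            if i in pool_after:
                layers.append(nn.AvgPool2d())
            ch = config.kernels_per_layer
        # final linear layer: 2 output channels, zero-init -> identity start
        layers.append(nn.Conv2d(ch, 2, config.kernel_size, zero_init=True))
        self.net = nn.Sequential(*layers)

    def grid_shape(self, image_shape: tuple[int, int]) -> tuple[int, int]:
        H, W = image_shape
        s = self.grid_spacing
        if H % s or W % s:
            raise ValueError(
                f"image shape {image_shape} not divisible by spacing {s}")
        return (H // s, W // s)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, C, H, W) input -> (B, 2, Gh, Gw) control displacements."""
        out = self.net.forward(x)
        if not self.config.pooling:
            s = self.grid_spacing
            self._full_shape = out.shape
            out = out[:, :, ::s, ::s]
        return out

    def backward(self, grad_cp: np.ndarray) -> np.ndarray:
        if not self.config.pooling:
            s = self.grid_spacing
            full = np.zeros(self._full_shape)
            full[:, :, ::s, ::s] = grad_cp
            grad_cp = full
        return self.net.backward(grad_cp)

    def n_parameters(self) -> int:
        return self.net.n_parameters()


def build_regressor(config: ModelVariantConfig | int,
                    grid_spacing: int = 16,
                    seed: int | np.random.Generator = 0) -> Regressor:
    """Build the trainable control-grid predictor for a variant."""
    if isinstance(config, int):
        config = variant_config(config)
    return Regressor(config, grid_spacing=grid_spacing, seed=seed)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def ncc(fixed: np.ndarray, warped: np.ndarray) -> float:
    """Global zero-mean normalized cross-correlation in [-1, 1].

    Defined as 0 (with a warning) when either input has zero variance.
    """
    value, _ = _ncc_with_grad(np.asarray(fixed, float),
                              np.asarray(warped, float))
    return value


def _ncc_with_grad(a: np.ndarray, b: np.ndarray):
    if a.shape != b.shape:
        raise ValueError("ncc inputs must share a shape")
    a0 = a - a.mean()
    b0 = b - b.mean()
    sa = float((a0 * a0).sum())
    sb = float((b0 * b0).sum())
    if sa <= 0.0 or sb <= 0.0:
        warnings.warn("zero-variance input to NCC; similarity defined as 0",
                      stacklevel=3)
        return 0.0, np.zeros_like(b)
    sab = float((a0 * b0).sum())
    denom = np.sqrt(sa * sb)
    value = sab / denom
    # d ncc / d b (mean-removal terms vanish because sum(a0) = 0)
    grad = (a0 - value * np.sqrt(sa / sb) * b0) / denom
    return value, grad


def mse(fixed: np.ndarray, warped: np.ndarray) -> float:
    """Mean squared difference (symmetric in its arguments)."""
    fixed = np.asarray(fixed, float)
    warped = np.asarray(warped, float)
    if fixed.shape != warped.shape:
        raise ValueError("mse inputs must share a shape")
    return float(np.mean((fixed - warped) ** 2))


def _mse_with_grad(a: np.ndarray, b: np.ndarray):
    diff = b - a
    return float(np.mean(diff * diff)), 2.0 * diff / diff.size


def soft_dice(fixed_mask: np.ndarray, warped_soft: np.ndarray,
              eps: float = 1e-6) -> float:
    """Differentiable Dice between a binary mask and a soft [0,1] mask."""
    value, _ = _soft_dice_with_grad(np.asarray(fixed_mask, float),
                                    np.asarray(warped_soft, float), eps)
    return value


def _soft_dice_with_grad(f: np.ndarray, w: np.ndarray, eps: float = 1e-6):
    num = 2.0 * float((f * w).sum()) + eps
    den = float(f.sum() + w.sum()) + eps
    value = num / den
    grad = (2.0 * f * den - num) / den ** 2
    return value, grad


def image_loss(kind: str, fixed: np.ndarray, warped: np.ndarray):
    """(loss, d loss / d warped) for the configured image term."""
    if kind == "NCC":
        v, g = _ncc_with_grad(fixed, warped)
        return -v, -g
    v, g = _mse_with_grad(fixed, warped)
    return v, g


def combined_loss(fixed_image: np.ndarray, warped_image: np.ndarray,
                  fixed_masks: dict[str, np.ndarray],
                  warped_masks: dict[str, np.ndarray],
                  config: ModelVariantConfig,
                  lambda_mask: float = 1.0) -> float:
    """Image dissimilarity plus mask dissimilarity.

    ``loss = L_img + lambda_mask * mean_organs(1 - softDice(fixed_m,
    warped_m))`` where the warped masks are the *pre-threshold* bilinear
    warps.  With an NCC variant and identical inputs the minimum is -1.
    """
    if set(fixed_masks) != set(warped_masks):
        raise ValueError("fixed and warped mask channels differ")
    v, _ = image_loss(config.loss, np.asarray(fixed_image, float),
                      np.asarray(warped_image, float))
    total = v
    if lambda_mask != 0.0 and fixed_masks:
        mask_term = np.mean([1.0 - soft_dice(fixed_masks[k], warped_masks[k])
                             for k in fixed_masks])
        total += lambda_mask * float(mask_term)
    return float(total)


# ---------------------------------------------------------------------------
# Full registration network
# ---------------------------------------------------------------------------

@dataclass
class PairBatch:
    """Pre-assembled arrays for a batch of registration pairs.

    ``fixed_img``/``moving_img`` are (B, H, W) normalized intensities;
    ``fixed_masks``/``moving_masks`` are (B, n_organs, H, W) float
    {0,1} arrays ordered as :data:`INPUT_MASKS`.
    """

    fixed_img: np.ndarray
    moving_img: np.ndarray
    fixed_masks: np.ndarray
    moving_masks: np.ndarray

    @property
    def batch_size(self) -> int:
        return self.fixed_img.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.fixed_img.shape[1:]


def assemble_batch(pairs, indices=None) -> PairBatch:
    """Stack :class:`~pelvreg.deform.TrainingPair` objects into arrays."""
    if indices is None:
        indices = range(len(pairs))
    fi, mi, fm, mm = [], [], [], []
    for i in indices:
        p = pairs[i]
        fi.append(normalize_hu(p.fixed.pixels))
        mi.append(normalize_hu(p.moving.pixels))
        fm.append(np.stack([p.fixed_masks[o].astype(float)
                            for o in INPUT_MASKS]))
        mm.append(np.stack([p.moving_masks[o].astype(float)
                            for o in INPUT_MASKS]))
    return PairBatch(np.stack(fi), np.stack(mi), np.stack(fm), np.stack(mm))


class RegistrationNetwork:
    """Regressor + B-spline transformer + resampler, with training step.

    The public inference surface is :meth:`register`; training uses
    :meth:`loss_and_grad` (forward plus full manual backward pass).
    """

    def __init__(self, config: ModelVariantConfig | int = 1,
                 image_shape: tuple[int, int] = (256, 512),
                 grid_spacing: int = 16, lambda_mask: float = 1.0,
                 seed: int | np.random.Generator = 0):
        if isinstance(config, int):
            config = variant_config(config)
        self.config = config
        self.image_shape = tuple(image_shape)
        self.grid_spacing = grid_spacing
        self.lambda_mask = lambda_mask
        self.regressor = Regressor(config, grid_spacing, seed)
        gh, gw = self.regressor.grid_shape(self.image_shape)
        self.By, self.Bx = basis_matrices(self.image_shape, (gh, gw),
                                          grid_spacing)

    # -- forward ---------------------------------------------------------

    def _input_tensor(self, batch: PairBatch) -> np.ndarray:
        if self.config.uses_masks:
            per_image = [batch.fixed_img[:, None], batch.fixed_masks,
                         batch.moving_img[:, None], batch.moving_masks]
        else:
            per_image = [batch.fixed_img[:, None], batch.moving_img[:, None]]
        return np.concatenate(per_image, axis=1)

    def predict_field(self, batch: PairBatch) -> np.ndarray:
        """(B, 2, H, W) dense displacement fields for a batch."""
        if batch.image_shape != self.image_shape:
            raise ValueError(
                f"batch shape {batch.image_shape} != model shape "
                f"{self.image_shape}")
        cp = self.regressor.forward(self._input_tensor(batch))
        self._cp = cp
        return dense_batch(cp, self.By, self.Bx)

    def register(self, fixed: ImageSlice, moving: ImageSlice,
                 moving_masks: OrganMaskSet | None = None,
                 fixed_masks: OrganMaskSet | None = None,
                 ) -> tuple[DisplacementField, ImageSlice, OrganMaskSet | None]:
        """One deterministic inference pass on a single pair.

        Returns the dense field, the bicubic-warped moving image, and
        (when given) the warped moving masks (bilinear + 0.5 threshold).
        """
        was_training = self.regressor.net.training
        self.regressor.net.eval()
        try:
            zeros = np.zeros((1, len(INPUT_MASKS)) + self.image_shape)
            fm = zeros if fixed_masks is None else np.stack(
                [[fixed_masks[o].astype(float) for o in INPUT_MASKS]])
            mm = zeros if moving_masks is None else np.stack(
                [[moving_masks[o].astype(float) for o in INPUT_MASKS]])
            batch = PairBatch(normalize_hu(fixed.pixels)[None],
                              normalize_hu(moving.pixels)[None], fm, mm)
            dense = self.predict_field(batch)[0]
        finally:
            self.regressor.net.train(was_training)
        fld = DisplacementField(dense[0], dense[1])
        warped_img = moving.with_pixels(
            warp_bicubic(moving.pixels, fld.dy, fld.dx))
        warped_masks = None
        if moving_masks is not None:
            warped_masks = moving_masks.map(
                lambda m: warp_mask_binary(m, fld.dy, fld.dx))
        return fld, warped_img, warped_masks

    def control_grid(self, fixed: ImageSlice, moving: ImageSlice,
                     **mask_kw) -> ControlPointGrid:
        """Inference returning the raw control grid of a single pair."""
        self.register(fixed, moving, **mask_kw)
        return ControlPointGrid(self._cp[0], self.grid_spacing)

    # -- training --------------------------------------------------------

    def loss_and_grad(self, batch: PairBatch) -> float:
        """Forward + backward over a batch; accumulates parameter grads.

        The loss averages, over the batch, the image dissimilarity of
        the bicubic-warped moving image against the fixed image plus
        ``lambda_mask`` times the mean soft-Dice dissimilarity of the
        bilinear-warped (soft) moving masks against the fixed masks.
        """
        B = batch.batch_size
        dense = self.predict_field(batch)
        grad_dense = np.zeros_like(dense)
        total = 0.0
        n_org = batch.fixed_masks.shape[1]
        for b in range(B):
            dy, dx = dense[b, 0], dense[b, 1]
            wimg, gdy_img, gdx_img = warp_bicubic(
                batch.moving_img[b], dy, dx, with_grad=True)
            li, gimg = image_loss(self.config.loss, batch.fixed_img[b], wimg)
            total += li
            grad_dense[b, 0] += gimg * gdy_img
            grad_dense[b, 1] += gimg * gdx_img
            if self.lambda_mask != 0.0 and n_org:
                for o in range(n_org):
                    wsoft, gdy_m, gdx_m = warp_bilinear_with_grad(
                        batch.moving_masks[b, o], dy, dx)
                    dval, ddice_dw = _soft_dice_with_grad(
                        batch.fixed_masks[b, o], wsoft)
                    total += self.lambda_mask * (1.0 - dval) / n_org
                    coeff = -self.lambda_mask / n_org
                    grad_dense[b, 0] += coeff * ddice_dw * gdy_m
                    grad_dense[b, 1] += coeff * ddice_dw * gdx_m
        total /= B
        grad_dense /= B
        grad_cp = dense_batch_grad(grad_dense, self.By, self.Bx)
        self.regressor.backward(grad_cp)
        return float(total)

    def evaluate_loss(self, batch: PairBatch) -> float:
        """Loss only (no gradient accumulation), in inference mode."""
        was_training = self.regressor.net.training
        self.regressor.net.eval()
        try:
            dense = self.predict_field(batch)
            total = 0.0
            n_org = batch.fixed_masks.shape[1]
            for b in range(batch.batch_size):
                dy, dx = dense[b, 0], dense[b, 1]
                wimg = warp_bicubic(batch.moving_img[b], dy, dx)
                total += combined_loss(
                    batch.fixed_img[b], wimg,
                    {str(o): batch.fixed_masks[b, o] for o in range(n_org)},
                    {str(o): warp_bilinear_with_grad(
                        batch.moving_masks[b, o], dy, dx)[0]
                     for o in range(n_org)},
                    self.config, self.lambda_mask)
        finally:
            self.regressor.net.train(was_training)
        return float(total / batch.batch_size)

    # -- persistence -----------------------------------------------------

    def state_dict(self) -> dict:
        params = self.regressor.net.params()
        bn_state = {}
        for i, layer in enumerate(self.regressor.net.layers):
            if isinstance(layer, nn.BatchNorm2d):
                bn_state[i] = (layer.running_mean.copy(),
                               layer.running_var.copy())
        return {"params": [p.copy() for p in params], "bn": bn_state,
                "config": self.config, "grid_spacing": self.grid_spacing,
                "lambda_mask": self.lambda_mask,
                "image_shape": self.image_shape}

    def load_state_dict(self, state: dict) -> None:
        for p, saved in zip(self.regressor.net.params(), state["params"]):
            p[...] = saved
        for i, (rm, rv) in state["bn"].items():
            layer = self.regressor.net.layers[i]
            layer.running_mean[...] = rm
            layer.running_var[...] = rv


def register_pair(model: RegistrationNetwork, fixed, moving,
                  moving_masks=None, fixed_masks=None):
    """Functional alias for :meth:`RegistrationNetwork.register`."""
    return model.register(fixed, moving, moving_masks=moving_masks,
                          fixed_masks=fixed_masks)


def bspline_to_dense_field(cp: ControlPointGrid, output_shape):
    """Re-export of the transformer for the network namespace."""
    from .bspline import bspline_to_dense
    return bspline_to_dense(cp, output_shape)


def resample(moving: np.ndarray, fld: DisplacementField,
             kind: str = "image") -> np.ndarray:
    """Resampler: bicubic for images, bilinear+threshold for masks."""
    if moving.shape != fld.shape:
        raise ValueError("resample shape mismatch")
    if kind == "image":
        return warp_bicubic(np.asarray(moving, float), fld.dy, fld.dx)
    if kind == "mask":
        return warp_mask_binary(np.asarray(moving), fld.dy, fld.dx)
    raise ValueError(f"unknown resample kind {kind!r}")
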