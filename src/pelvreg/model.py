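"""Model/Results interface to the registration experiment.

:class:`DeformableRegistration` is the model object: it is constructed
from a dataset of fixed/moving slice pairs (real or simulated) plus a
network-variant configuration, and :meth:`~DeformableRegistration.fit`
runs the optimization and returns a :class:`RegistrationResults` object
carrying the trained network, the loss history, and evaluation /
summary / plotting methods.

Example
-------
>>> from pelvreg import DeformableRegistration, experiment
>>> pairs = experiment.make_synthetic_dataset(2, 3, seed=0)
>>> model = DeformableRegistration(pairs, variant=1)
>>> res = model.fit(iterations=50, seed=0)
>>> print(res.summary())                        # doctest: +SKIP
"""

from __future__ import annotations

import pickle
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import experiment, metrics
from .deform import TrainingPair
from .regnet import ModelVariantConfig, RegistrationNetwork, variant_config


class DeformableRegistration:
    """Unsupervised deformable-registration model over a pair dataset.

    Parameters
    ----------
    pairs : list of TrainingPair
        Fixed/moving slice pairs with organ masks (e.g. from
        :func:`pelvreg.experiment.make_synthetic_dataset` or built from
        clinical data via :mod:`pelvreg.io`).
    variant : int or ModelVariantConfig
        Which network variant to fit (1-4).
    lambda_mask : float
        Weight of the mask term in the combined loss.
    grid_spacing : int
        B-spline control-point spacing in pixels.
    """

    def __init__(self, pairs: list[TrainingPair],
                 variant: int | ModelVariantConfig = 1,
                 lambda_mask: float = 1.0, grid_spacing: int = 16):
        if not pairs:
            raise ValueError("need at least one training pair")
        self.pairs = pairs
        self.variant = (variant_config(variant) if isinstance(variant, int)
                        else variant)
        self.lambda_mask = lambda_mask
        self.grid_spacing = grid_spacing
        self.image_shape = pairs[0].fixed.shape

    @classmethod
    def from_synthetic(cls, n_patients: int = 8, n_slices: int = 6,
                       image_shape=(128, 256), variant=1, seed: int = 0,
                       **kw) -> "DeformableRegistration":
        """Convenience constructor over the built-in phantom pipeline."""
        pairs = experiment.make_synthetic_dataset(
            n_patients, n_slices, image_shape=image_shape, seed=seed)
        return cls(pairs, variant=variant, **kw)

    def fit(self, iterations: int = 500, batch_size: int = 4,
            learning_rate: float = 1e-4, seed: int = 0,
            checkpoint_every: int = 100) -> "RegistrationResults":
        """Run mini-batch Adam training; returns the results object."""
        tc = experiment.TrainConfig(
            iterations=iterations, batch_size=batch_size,
            learning_rate=learning_rate, checkpoint_every=checkpoint_every,
            seed=seed, image_shape=self.image_shape)
        cfg = self.variant
        net, history = experiment.train(cfg, tc, self.pairs, seed=seed)
        net.lambda_mask = self.lambda_mask
        return RegistrationResults(self, net, history, tc)


class RegistrationResults:
    """Fitted registration network plus its training record."""

    def __init__(self, model: DeformableRegistration,
                 network: RegistrationNetwork, loss_history: pd.DataFrame,
                 train_config: experiment.TrainConfig):
        self.model = model
        self.network = network
        self.loss_history = loss_history
        self.train_config = train_config

    # -- use -------------------------------------------------------------

    def register(self, fixed, moving, moving_masks=None, fixed_masks=None):
        """Register one pair; see :meth:`RegistrationNetwork.register`."""
        return self.network.register(fixed, moving,
                                     moving_masks=moving_masks,
                                     fixed_masks=fixed_masks)

    def evaluate(self, test_pairs: list[TrainingPair]
                 ) -> tuple[metrics.MetricReport, metrics.MetricReport]:
        """(before, after) registration metric reports on held-out pairs."""
        return experiment.before_after_report(self.network, test_pairs)

    # -- reporting ---------------------------------------------------------

    def summary(self, test_pairs: list[TrainingPair] | None = None) -> str:
        """Text summary: configuration, parameters, loss, optional metrics."""
        cfg = self.network.config
        lines = [
            "Deformable registration results",
            "=" * 46,
            f"variant:              DIRNet {cfg.variant_id}",
            f"conv layers:          {cfg.n_conv_layers}"
            f" ({'avg-pool 2x2' if cfg.pooling else 'no pooling'})",
            f"image loss:           {cfg.loss}",
            f"lambda_mask:          {self.network.lambda_mask}",
            f"trainable parameters: {self.network.regressor.n_parameters()}",
            f"image shape:          {self.network.image_shape}",
            f"control grid:         "
            f"{self.network.regressor.grid_shape(self.network.image_shape)}"
            f" @ {self.network.grid_spacing} px spacing",
            f"iterations:           {self.train_config.iterations}"
            f" (batch {self.train_config.batch_size},"
            f" lr {self.train_config.learning_rate})",
            f"seed:                 {self.train_config.seed}",
            f"initial loss:         {self.loss_history['loss'].iloc[0]:.4f}",
            f"final loss:           {self.loss_history['loss'].iloc[-1]:.4f}",
        ]
        if test_pairs is not None:
            before, after = self.evaluate(test_pairs)
            lines += ["", "Before registration:", str(before),
                      "", "After registration:", str(after)]
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Loss-history curve (matplotlib axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.loss_history["iteration"], self.loss_history["loss"])
        ax.set_xlabel("iteration")
        ax.set_ylabel("combined loss")
        ax.set_title(f"DIRNet {self.network.config.variant_id} training loss")
        return ax

    def plot_pair(self, pair: TrainingPair, ax=None):
        """Fixed / moving / registered triptych for one test pair."""
        import matplotlib.pyplot as plt

        _, warped, _ = self.register(pair.fixed, pair.moving,
                                     moving_masks=pair.moving_masks,
                                     fixed_masks=pair.fixed_masks)
        if ax is None:
            _, ax = plt.subplots(1, 3, figsize=(12, 4))
        for a, img, title in zip(
                ax, (pair.fixed, pair.moving, warped),
                ("fixed", "moving", "registered")):
            a.imshow(img.pixels, cmap="gray", vmin=-200, vmax=200)
            a.set_title(title)
            a.axis("off")
        return ax

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: config + weights + seed + loss history."""
        state = {"network": self.network.state_dict(),
                 "train_config": self.train_config,
                 "loss_history": self.loss_history}
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path, model: DeformableRegistration | None = None
             ) -> "RegistrationResults":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        ns = state["network"]
        net = RegistrationNetwork(
            ns["config"], image_shape=ns["image_shape"],
            grid_spacing=ns["grid_spacing"], lambda_mask=ns["lambda_mask"])
        net.load_state_dict(ns)
        net.regressor.net.eval()
        if model is None:
            model = DeformableRegistration.__new__(DeformableRegistration)
            model.pairs = []
            model.variant = ns["config"]
            model.lambda_mask = ns["lambda_mask"]
            model.grid_spacing = ns["grid_spacing"]
            model.image_shape = ns["image_shape"]
        return cls(model, net, state["loss_history"], state["train_config"])
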