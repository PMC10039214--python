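"""Segmentation-agreement metrics: Jaccard, Dice, ASSD, contours.

Dice = 2|A n B| / (|A| + |B|) and Jaccard = |A n B| / |A u B| are
computed by exact pixel counting (both-empty convention: 1).  The
average symmetric surface distance

    ASSD = ( sum_{x in B_P} d(x, B_G) + sum_{y in B_G} d(y, B_P) )
           / (|B_P| + |B_G|)

uses boundary pixel sets (mask pixels with a 4-neighbour outside the
mask) and exact Euclidean pixel-center distances in mm via the distance
transform.  Per-organ per-slice values aggregate to mean +/- SD
(population SD) in a :class:`MetricReport`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .io import ORGANS, OrganMaskSet

log = logging.getLogger(__name__)

_CROSS = ndimage.generate_binary_structure(2, 1)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient; 1.0 when both masks are empty."""
    a = _as_bool(a)
    b = _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    sa = int(a.sum())
    sb = int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index (intersection over union); 1.0 when both empty."""
    a = _as_bool(a)
    b = _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one 4-neighbour outside the mask."""
    m = _as_bool(mask)
    if not m.any():
        return np.zeros_like(m)
    eroded = ndimage.binary_erosion(m, structure=_CROSS, border_value=0)
    return m & ~eroded


def assd(a: np.ndarray, b: np.ndarray,
         spacing: float | tuple[float, float] = 0.84) -> float:
    """Average symmetric surface distance between two nonempty masks (mm).

    Distances are pixel-center to pixel-center, exact Euclidean,
    honouring anisotropic spacing ``(sy, sx)``.
    """
    a = _as_bool(a)
    b = _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("ASSD is undefined for an empty mask")
    if np.isscalar(spacing):
        spacing = (float(spacing), float(spacing))
    ba = boundary_pixels(a)
    bb = boundary_pixels(b)
    # distance from every pixel to the nearest boundary pixel of the other
    dist_to_bb = ndimage.distance_transform_edt(~bb, sampling=spacing)
    dist_to_ba = ndimage.distance_transform_edt(~ba, sampling=spacing)
    total = dist_to_bb[ba].sum() + dist_to_ba[bb].sum()
    return float(total / (ba.sum() + bb.sum()))


def assd_bruteforce(a: np.ndarray, b: np.ndarray,
                    spacing: float | tuple[float, float] = 0.84) -> float:
    """O(n^2) all-pairs oracle for :func:`assd` on small masks."""
    if np.isscalar(spacing):
        spacing = (float(spacing), float(spacing))
    pa = np.argwhere(boundary_pixels(a)).astype(float) * np.asarray(spacing)
    pb = np.argwhere(boundary_pixels(b)).astype(float) * np.asarray(spacing)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("ASSD is undefined for an empty mask")
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return float((d.min(axis=1).sum() + d.min(axis=0).sum())
                 / (len(pa) + len(pb)))


def extract_contours(mask: np.ndarray) -> list[np.ndarray]:
    """Marching-squares iso-contours of a binary mask at level 0.5.

    The mask is zero-padded before extraction so that components touching
    the frame still close; coordinates are shifted back to mask pixel
    space.  Each contour is an (N, 2) closed polyline in (y, x).
    """
    m = _as_bool(mask).astype(float)
    if not m.any():
        return []
    padded = np.pad(m, 1)
    contours = measure.find_contours(padded, 0.5)
    return [c - 1.0 for c in contours]


def contour_area(contour: np.ndarray) -> float:
    """Enclosed (shoelace) area of a closed polyline."""
    y = contour[:, 0]
    x = contour[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) -
                           np.dot(y, np.roll(x, -1))))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class OrganStats:
    dice_mean: float
    dice_sd: float
    jaccard_mean: float
    jaccard_sd: float
    assd_mean_mm: float
    assd_sd_mm: float
    n_slices_evaluated: int
    n_slices_assd: int


@dataclass
class MetricReport:
    """Per-organ mean +/- SD of Dice/Jaccard/ASSD over evaluated slices."""

    organs: dict[str, OrganStats] = field(default_factory=dict)

    def __getitem__(self, organ: str) -> OrganStats:
        return self.organs[organ]

    def __contains__(self, organ: str) -> bool:
        return organ in self.organs

    def to_frame(self) -> pd.DataFrame:
        """Delimited-table layout: one row per organ/metric."""
        rows = []
        for organ, s in self.organs.items():
            rows += [
                (organ, "dice", s.dice_mean, s.dice_sd, s.n_slices_evaluated),
                (organ, "jaccard", s.jaccard_mean, s.jaccard_sd,
                 s.n_slices_evaluated),
                (organ, "assd_mm", s.assd_mean_mm, s.assd_sd_mm,
                 s.n_slices_assd),
            ]
        return pd.DataFrame(rows,
                            columns=["organ", "metric", "mean", "sd", "n"])

    def __str__(self) -> str:
        return self.to_frame().to_string(index=False,
                                         float_format=lambda v: f"{v:.4f}")


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    # population SD (divide by n), fixed for reproducibility
    return float(arr.mean()), float(arr.std())


def evaluate(pairs: list[tuple[OrganMaskSet, OrganMaskSet]],
             spacing: float | tuple[float, float] = 0.84,
             organs: tuple[str, ...] = ORGANS) -> MetricReport:
    """Aggregate per-slice metrics over (reference, result) mask pairs.

    Slices whose *reference* organ mask is empty are excluded for that
    organ; a reference-nonempty/result-empty slice scores 0 overlap and
    is skipped for ASSD (logged).  An organ with zero evaluable slices is
    absent from the report rather than reported as zero.
    """
    per_organ: dict[str, dict[str, list[float]]] = {
        o: {"dice": [], "jaccard": [], "assd": []} for o in organs}
    for ref_masks, res_masks in pairs:
        for organ in organs:
            if organ not in ref_masks or organ not in res_masks:
                continue
            ref = ref_masks[organ]
            res = res_masks[organ]
            if not ref.any():
                continue  # not evaluable on this slice
            per_organ[organ]["dice"].append(dice(ref, res))
            per_organ[organ]["jaccard"].append(jaccard(ref, res))
            if res.any():
                per_organ[organ]["assd"].append(assd(ref, res, spacing))
            else:
                log.info("empty result mask for %s; slice skipped for ASSD",
                         organ)
    report = MetricReport()
    for organ, vals in per_organ.items():
        if not vals["dice"]:
            log.info("organ %s had no evaluable slices; omitted", organ)
            continue
        dm, ds = _mean_sd(vals["dice"])
        jm, js = _mean_sd(vals["jaccard"])
        if vals["assd"]:
            am, asd = _mean_sd(vals["assd"])
        else:
            am, asd = float("nan"), float("nan")
        report.organs[organ] = OrganStats(
            dice_mean=dm, dice_sd=ds, jaccard_mean=jm, jaccard_sd=js,
            assd_mean_mm=am, assd_sd_mm=asd,
            n_slices_evaluated=len(vals["dice"]),
            n_slices_assd=len(vals["assd"]))
    return report
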