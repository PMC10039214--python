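"""Reading and writing the formats the tool touches.

Supported inputs are DICOM CT series, NIfTI volumes, DICOM RT-structure
contour polygons (rasterized to binary masks), and the package's own
``.npz`` fixture archives.  All in-memory images are HU-valued 2D slices.

Coordinate convention (used everywhere in the package): arrays are
row-major ``(y, x)``, 0-based, with pixel centers at integer coordinates.
Millimetre coordinates relate to pixel indices through the slice's
``spacing`` and ``origin``: ``mm = origin + index * spacing`` per axis.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

#: Canonical organ names, in reporting order.
ORGANS = ("bladder", "cervix", "rectum")
#: All mask names a full set may carry.
MASK_NAMES = ("bladder", "cervix", "rectum", "bone", "body")


@dataclass(frozen=True)
class ImageSlice:
    """One trans-axial CT slice in Hounsfield units.

    Parameters
    ----------
    pixels : (H, W) float ndarray
        HU values; must be finite.
    spacing_y, spacing_x : float
        Pixel spacing in mm/pixel (> 0).
    origin : (float, float)
        Millimetre position of pixel (0, 0), ``(y, x)`` order.
    """

    pixels: np.ndarray
    spacing_y: float = 0.84
    spacing_x: float = 0.84
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite HU values")
        if self.spacing_y <= 0 or self.spacing_x <= 0:
            raise ValueError("pixel spacing must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def spacing(self) -> tuple[float, float]:
        return (self.spacing_y, self.spacing_x)

    def with_pixels(self, pixels: np.ndarray) -> "ImageSlice":
        return replace(self, pixels=pixels)


@dataclass
class OrganMaskSet:
    """Aligned binary masks for one slice.

    ``masks`` maps organ name (subset of :data:`MASK_NAMES`) to a
    ``uint8`` array of {0, 1} sharing a single shape.
    """

    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        shape = None
        for name, m in self.masks.items():
            m = np.asarray(m)
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"mask {name!r} has values outside {{0,1}}")
            m = m.astype(np.uint8)
            if shape is None:
                shape = m.shape
            elif m.shape != shape:
                raise ValueError("all masks must share one shape")
            clean[name] = m
        self.masks = clean

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> tuple[str, ...]:
        return tuple(self.masks)

    @property
    def shape(self) -> tuple[int, int]:
        if not self.masks:
            raise ValueError("empty mask set has no shape")
        return next(iter(self.masks.values())).shape

    def map(self, fn) -> "OrganMaskSet":
        """Apply ``fn`` to every mask, returning a new set."""
        return OrganMaskSet({k: fn(v) for k, v in self.masks.items()})


# ---------------------------------------------------------------------------
# CT volume reading
# ---------------------------------------------------------------------------

def read_ct_volume(path: str | os.PathLike) -> list[ImageSlice]:
    """Read a CT volume as a list of HU slices, ordered by axial position.

    ``path`` may be a DICOM series directory or a NIfTI file
    (``.nii``/``.nii.gz``).  DICOM pixel data are converted to HU via
    RescaleSlope/RescaleIntercept; missing rescale metadata is an error
    naming the file, as is a series with mixed image orientations.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if path.suffixes and path.suffixes[-1] in (".nii", ".gz"):
        return _read_nifti(path)
    raise ValueError(f"unsupported CT input: {path}")


def _read_dicom_series(directory: Path) -> list[ImageSlice]:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append((f, ds))
    if not datasets:
        raise ValueError(f"no DICOM images found in {directory}")

    orient = None
    slices = []
    for f, ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise ValueError(f"missing rescale metadata in {f}")
        this_orient = tuple(float(v) for v in getattr(
            ds, "ImageOrientationPatient", (1, 0, 0, 0, 1, 0)))
        if orient is None:
            orient = this_orient
        elif not np.allclose(this_orient, orient):
            raise ValueError(f"mixed image orientations in series ({f})")
        hu = ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope) \
            + float(ds.RescaleIntercept)
        sp = getattr(ds, "PixelSpacing", [0.84, 0.84])
        pos = getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])
        z = float(pos[2])
        slices.append((z, ImageSlice(
            pixels=hu,
            spacing_y=float(sp[0]), spacing_x=float(sp[1]),
            origin=(float(pos[1]), float(pos[0])))))
    slices.sort(key=lambda t: t[0])
    return [s for _, s in slices]


def _read_nifti(path: Path) -> list[ImageSlice]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    zooms = img.header.get_zooms()
    if data.ndim == 2:
        data = data[..., None]
    if data.ndim != 3:
        raise ValueError(f"expected 2D/3D NIfTI, got shape {data.shape}: {path}")
    # nibabel axes are (x, y, z); package convention is (y, x) per slice.
    sx, sy = float(zooms[0]), float(zooms[1])
    out = []
    for k in range(data.shape[2]):
        out.append(ImageSlice(pixels=data[:, :, k].T,
                              spacing_y=sy, spacing_x=sx))
    return out


def write_nifti(path: str | os.PathLike, slices: Sequence[ImageSlice],
                slice_thickness: float = 5.0) -> None:
    """Write a slice stack as a NIfTI volume (inverse of :func:`_read_nifti`)."""
    import nibabel as nib

    ref = slices[0]
    vol = np.stack([s.pixels.T for s in slices], axis=2)
    aff = np.diag([ref.spacing_x, ref.spacing_y, slice_thickness, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), aff), str(path))


# ---------------------------------------------------------------------------
# RT-structure rasterization
# ---------------------------------------------------------------------------

def points_in_polygons(points_yx: np.ndarray,
                       polygons: Sequence[np.ndarray]) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test.

    ``points_yx`` is (N, 2) in mm; each polygon is (M, 2) closed loop in mm
    (``(y, x)`` order, last vertex may but need not repeat the first).
    A point on the union of loop interiors under the even-odd rule maps to
    True.  Crossings are counted on rays toward +x.
    """
    pts = np.asarray(points_yx, dtype=np.float64)
    inside = np.zeros(len(pts), dtype=bool)
    for poly in polygons:
        poly = np.asarray(poly, dtype=np.float64)
        if len(poly) >= 2 and np.allclose(poly[0], poly[-1]):
            poly = poly[:-1]
        if len(poly) < 3:
            continue
        y0, x0 = poly[:, 0], poly[:, 1]
        y1, x1 = np.roll(y0, -1), np.roll(x0, -1)
        py = pts[:, 0][:, None]
        px = pts[:, 1][:, None]
        # Edge straddles the horizontal ray through the point (half-open).
        straddle = (y0[None, :] > py) != (y1[None, :] > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xcross = x0[None, :] + (py - y0[None, :]) * \
                (x1 - x0)[None, :] / (y1 - y0)[None, :]
        hits = straddle & (px < xcross)
        inside ^= (hits.sum(axis=1) % 2).astype(bool)
    return inside


def rasterize_polygons(polygons: Sequence[np.ndarray],
                       reference: ImageSlice) -> np.ndarray:
    """Fill closed mm-space polygons onto the reference pixel grid.

    A pixel belongs to the mask iff its *center* lies inside the polygons
    under the even-odd rule.  Geometry outside the image is clipped with a
    warning (never an error).
    """
    H, W = reference.shape
    oy, ox = reference.origin
    mask = np.zeros((H, W), dtype=np.uint8)
    if not polygons:
        return mask
    polys = [np.asarray(p, dtype=np.float64) for p in polygons]
    ymin = min(p[:, 0].min() for p in polys)
    ymax = max(p[:, 0].max() for p in polys)
    xmin = min(p[:, 1].min() for p in polys)
    xmax = max(p[:, 1].max() for p in polys)
    img_ylo, img_yhi = oy, oy + (H - 1) * reference.spacing_y
    img_xlo, img_xhi = ox, ox + (W - 1) * reference.spacing_x
    if ymin < img_ylo or ymax > img_yhi or xmin < img_xlo or xmax > img_xhi:
        log.warning("contour extends outside image bounds; clipping")
    yy, xx = np.mgrid[0:H, 0:W]
    centers = np.column_stack([
        oy + yy.ravel() * reference.spacing_y,
        ox + xx.ravel() * reference.spacing_x,
    ])
    mask.ravel()[:] = points_in_polygons(centers, polys).astype(np.uint8)
    return mask


def rasterize_rtstruct(contours: Mapping[str, Sequence[np.ndarray]],
                       reference: ImageSlice,
                       organ_names: Iterable[str] | None = None,
                       ) -> OrganMaskSet:
    """Rasterize per-organ contour polygons (mm) to an :class:`OrganMaskSet`.

    ``contours`` maps organ name to a list of closed polygon loops on this
    slice.  Organs listed in ``organ_names`` but absent from ``contours``
    get all-zero masks.
    """
    names = list(organ_names) if organ_names is not None else list(contours)
    masks = {}
    for name in names:
        polys = list(contours.get(name, []))
        masks[name] = rasterize_polygons(polys, reference)
    return OrganMaskSet(masks)


def read_rtstruct_contours(path: str | os.PathLike,
                           name_map: Mapping[str, str] | None = None,
                           ) -> dict[str, dict[float, list[np.ndarray]]]:
    """Read a DICOM RTSTRUCT into per-organ, per-z contour polygons (mm).

    RT structures carry institution-specific ROI names; ``name_map``
    translates stored ROI names to the canonical organ names.  Returns
    ``{organ: {z_mm: [poly (M,2) in (y,x) mm, ...]}}``.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    roi_names = {int(r.ROINumber): str(r.ROIName)
                 for r in ds.StructureSetROISequence}
    out: dict[str, dict[float, list[np.ndarray]]] = {}
    for rc in ds.ROIContourSequence:
        raw = roi_names.get(int(rc.ReferencedROINumber), "")
        name = (name_map or {}).get(raw, raw).lower()
        organ = out.setdefault(name, {})
        for c in getattr(rc, "ContourSequence", []):
            pts = np.asarray(c.ContourData, dtype=np.float64).reshape(-1, 3)
            z = round(float(pts[0, 2]), 3)
            organ.setdefault(z, []).append(pts[:, [1, 0]])  # (y, x) mm
    return out


# ---------------------------------------------------------------------------
# Fixture archives
# ---------------------------------------------------------------------------

def save_fixture(path: str | os.PathLike, image: ImageSlice,
                 masks: OrganMaskSet, seed: int | None = None) -> None:
    """Save one slice + masks as a compressed ``.npz`` fixture archive."""
    arrays = {"image": image.pixels,
              "spacing": np.array(image.spacing, dtype=np.float64),
              "origin": np.array(image.origin, dtype=np.float64),
              "seed": np.array(-1 if seed is None else seed)}
    for name, m in masks.masks.items():
        arrays[f"mask_{name}"] = m
    np.savez_compressed(str(path), **arrays)


def load_fixture(path: str | os.PathLike) -> tuple[ImageSlice, OrganMaskSet, int]:
    """Inverse of :func:`save_fixture`; returns (image, masks, seed)."""
    with np.load(str(path)) as z:
        sp = z["spacing"]
        image = ImageSlice(pixels=z["image"], spacing_y=float(sp[0]),
                           spacing_x=float(sp[1]),
                           origin=tuple(z["origin"]))
        masks = OrganMaskSet({k[5:]: z[k] for k in z.files
                              if k.startswith("mask_")})
        seed = int(z["seed"])
    return image, masks, seed
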