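"""Volumetric image / ROI mask data model, standard-format I/O and polygon
rasterisation.

Coordinate convention
---------------------
Arrays are indexed ``(i, j, k)`` mapping to the physical ``(x, y, z)`` axes in
that order.  Indices are 0-based and the centre of voxel ``(i, j, k)`` sits at
``origin + index * spacing`` (mm).  All geometric parameters elsewhere in the
library (rotation angles, translation fractions, volume fractions) are
expressed in physical units — degrees, mm, or fractions of the voxel spacing —
never in raw indices, because spacing is anisotropic before interpolation.

CT intensities are Hounsfield units throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateMaskError, FormatError, GeometryError

__all__ = [
    "VolumetricImage",
    "RoiMask",
    "FractionalMask",
    "read_image",
    "write_nifti",
    "rasterise_contours",
]

AXIS_ORDER = ("x", "y", "z")


def _as_triplet(v: Sequence[float]) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class VolumetricImage:
    """A 3D scalar image on a regular anisotropic grid.

    Parameters
    ----------
    voxels:
        3D array of intensities (HU for CT), axes ``(x, y, z)``.
    spacing:
        Per-axis physical voxel size in mm; strictly positive.
    origin:
        Physical coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: tuple[str, str, str] = field(default=AXIS_ORDER, repr=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise GeometryError("image must be a non-empty 3D array")
        self.spacing = _as_triplet(self.spacing)
        self.origin = _as_triplet(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise GeometryError("image intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def voxel_centres(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis physical coordinates (mm) of voxel centres."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )  # type: ignore[return-value]

    def copy(self, voxels: np.ndarray | None = None) -> "VolumetricImage":
        return replace(self, voxels=np.array(self.voxels if voxels is None else voxels))

    def same_grid(self, other: "VolumetricImage | RoiMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class RoiMask:
    """A binary ROI mask aligned voxel-for-voxel to a parent image.

    ``kind`` distinguishes the original delineation from its two processed
    descendants: the *morphological* mask (full geometric ROI, used for shape
    features) and the *intensity* mask (its re-segmented subset, used for
    intensity and texture features).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "original"

    _KINDS = ("original", "morphological", "intensity")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(bool)
        if self.labels.ndim != 3 or self.labels.size == 0:
            raise GeometryError("mask must be a non-empty 3D array")
        self.spacing = _as_triplet(self.spacing)
        self.origin = _as_triplet(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.labels.sum())

    def require_nonempty(self, context: str = "mask") -> None:
        if self.voxel_count == 0:
            raise DegenerateMaskError(f"{context}: mask has no foreground voxels")

    def as_fractional(self) -> "FractionalMask":
        return FractionalMask(self.labels.astype(np.float64), self.spacing, self.origin)

    def copy(self, labels: np.ndarray | None = None, kind: str | None = None) -> "RoiMask":
        return RoiMask(
            np.array(self.labels if labels is None else labels),
            self.spacing,
            self.origin,
            self.kind if kind is None else kind,
        )

    def voxel_centres(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )  # type: ignore[return-value]


@dataclass
class FractionalMask:
    """Fractional voxel occupancy in [0, 1].

    Produced when a binary mask is carried through an interpolating transform
    (rotation, translation, grid resampling); it is binarised later at the
    partial-volume threshold.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.clip(np.asarray(self.values, dtype=np.float64), 0.0, 1.0)
        if self.values.ndim != 3:
            raise GeometryError("fractional mask must be 3D")
        self.spacing = _as_triplet(self.spacing)
        self.origin = _as_triplet(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def binarise(self, threshold: float = 0.5, kind: str = "original") -> RoiMask:
        """Threshold fractional occupancy; ``>= threshold`` becomes foreground."""
        return RoiMask(self.values >= threshold, self.spacing, self.origin, kind)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_nifti(path: Path) -> VolumetricImage:
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel raises many types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    affine = img.affine
    origin = tuple(float(x) for x in affine[:3, 3])
    return VolumetricImage(data, tuple(float(z) for z in zooms), origin)


def _read_dicom_series(path: Path, spacing_tol: float = 1e-3) -> VolumetricImage:
    """Read a directory of single-frame CT DICOM slices into one volume."""
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "ImagePositionPatient") and hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no readable DICOM image slices under {path}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    dz = np.diff(zs)
    if len(dz) == 0:
        raise GeometryError(f"{path}: series has a single slice")
    if np.ptp(dz) > spacing_tol * max(1.0, abs(np.median(dz))):
        raise GeometryError(
            f"{path}: non-uniform slice spacing (range {dz.min():.4f}..{dz.max():.4f} mm); "
            "a slice may be missing"
        )
    first = slices[0]
    px, py = (float(v) for v in first.PixelSpacing)
    spacing = (px, py, float(np.median(dz)))
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # DICOM pixel arrays are (row=y, col=x); reorder to (x, y, z)
    vol = np.stack(planes, axis=-1).transpose(1, 0, 2)
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    return VolumetricImage(vol, spacing, origin)


def read_image(path: str | Path, format: str = "nifti") -> VolumetricImage:
    """Read a 3D scalar image.

    Parameters
    ----------
    path:
        A ``.nii``/``.nii.gz`` file (``format='nifti'``) or a directory of CT
        DICOM slices (``format='dicom-series'``).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom-series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def write_nifti(obj: VolumetricImage | RoiMask, path: str | Path) -> None:
    """Write an image or mask as NIfTI-1 with a diagonal affine."""
    import nibabel as nib

    if isinstance(obj, RoiMask):
        data = obj.labels.astype(np.uint8)
    else:
        data = obj.voxels
    affine = np.diag(list(obj.spacing) + [1.0])
    affine[:3, 3] = obj.origin
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_mask(path: str | Path, kind: str = "original") -> RoiMask:
    img = read_image(path, "nifti")
    return RoiMask(img.voxels > 0.5, img.spacing, img.origin, kind)


# ---------------------------------------------------------------------------
# Polygon rasterisation
# ---------------------------------------------------------------------------

def _points_in_polygon_evenodd(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorised even–odd (ray casting) point-in-polygon test.

    Rays are cast in +x; edges are treated half-open in y so shared vertices
    are counted once.  Points exactly on a horizontal edge follow the ray
    parity, which is adequate at voxel-centre resolution.
    """
    x0, y0 = poly[:-1, 0], poly[:-1, 1]
    x1, y1 = poly[1:, 0], poly[1:, 1]
    inside = np.zeros(px.shape, dtype=bool)
    for ax, ay, bx, by in zip(x0, y0, x1, y1):
        if ay == by:
            continue
        crosses = (ay > py) != (by > py)
        with np.errstate(invalid="ignore", divide="ignore"):
            xi = ax + (py - ay) * (bx - ax) / (by - ay)
        inside ^= crosses & (px < xi)
    return inside


def _close_polygon(poly: np.ndarray) -> np.ndarray:
    poly = np.asarray(poly, dtype=np.float64)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise GeometryError("polygon must be an (n>=3, 2) array of (x, y) mm")
    if not np.allclose(poly[0], poly[-1]):
        poly = np.vstack([poly, poly[0]])
    return poly


def _segments_self_intersect(poly: np.ndarray) -> bool:
    """O(n^2) check for crossing edges (used only to report, not to reject)."""

    def ccw(a, b, c):
        return (c[1] - a[1]) * (b[0] - a[0]) - (b[1] - a[1]) * (c[0] - a[0])

    n = len(poly) - 1
    for i in range(n):
        a, b = poly[i], poly[i + 1]
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            c, d = poly[j], poly[j + 1]
            if (ccw(a, b, c) * ccw(a, b, d) < 0) and (ccw(c, d, a) * ccw(c, d, b) < 0):
                return True
    return False


def rasterise_contours(
    polygons: Iterable[tuple[float, np.ndarray]],
    grid: VolumetricImage,
    warn: callable = None,
) -> RoiMask:
    """Rasterise per-slice closed planar polygons into a binary mask.

    Parameters
    ----------
    polygons:
        Iterable of ``(z_mm, vertices)`` where ``vertices`` is an ``(n, 2)``
        array of in-plane ``(x, y)`` coordinates in mm.  Each polygon must lie
        within half a slice spacing of a grid slice (nearest-slice snapping).
    grid:
        The image supplying grid geometry.

    A voxel is foreground iff its centre lies inside the polygon by the
    even–odd rule; multiple polygons on one slice combine by XOR, so nested
    contours cut holes.  Self-intersecting polygons are reported via ``warn``
    but still rasterised under the even–odd rule.
    """
    import warnings

    polygons = list(polygons)
    if not polygons:
        raise GeometryError("empty polygon set")
    cx, cy, cz = grid.voxel_centres()
    px, py = np.meshgrid(cx, cy, indexing="ij")
    labels = np.zeros(grid.shape, dtype=bool)
    half_dz = grid.spacing[2] / 2.0
    for z_mm, verts in polygons:
        poly = _close_polygon(verts)
        k = int(round((float(z_mm) - grid.origin[2]) / grid.spacing[2]))
        if k < 0 or k >= grid.shape[2] or abs(float(z_mm) - cz[min(max(k, 0), len(cz) - 1)]) > half_dz + 1e-9:
            raise GeometryError(
                f"polygon plane z={z_mm} mm matches no grid slice "
                f"(slice range {cz[0]}..{cz[-1]} mm, spacing {grid.spacing[2]} mm)"
            )
        if _segments_self_intersect(poly):
            msg = f"self-intersecting polygon on slice z={z_mm} mm; even-odd rule applied"
            (warn or warnings.warn)(msg)
        labels[:, :, k] ^= _points_in_polygon_evenodd(px, py, poly)
    if not labels.any():
        raise DegenerateMaskError("rasterised polygon set contains no voxel centres")
    return RoiMask(labels, grid.spacing, grid.origin, "original")
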