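"""IBSI-style ROI processing between perturbation and feature computation.

Covers anti-aliased interpolation to isotropic grids, rounding of intensities
to integer HU, partial-volume thresholding of the interpolated mask,
re-segmentation of the intensity mask, and grey-level discretisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateMaskError
from .image import FractionalMask, RoiMask, VolumetricImage

__all__ = [
    "ProcessingConfig",
    "interpolate_to_isotropic",
    "round_intensities",
    "resegment",
    "discretise",
]


@dataclass
class ProcessingConfig:
    """Processing parameters.

    Attributes
    ----------
    spacings:
        Target isotropic voxel spacings in mm (features are computed at each).
    antialias_beta:
        Band-preservation fraction of the Gaussian pre-smoothing filter.  When
        downsampling by ratio r = s_target / s_source > 1, each axis is
        smoothed with σ = β · r / π (in source-voxel units) before trilinear
        resampling; upsampled axes are not smoothed.
    mask_pv_threshold:
        Partial-volume fraction at which the interpolated mask is re-labelled
        foreground (``>=``).
    resegment_range:
        Inclusive HU window retained in the intensity mask (soft tissue for
        CT; e.g. [-300, 200] lung, [-150, 180] head-and-neck).
    outlier_sigma:
        Multiplier for the σ outlier rule applied after the range filter.
    bin_numbers / bin_sizes:
        Fixed-bin-number and fixed-bin-size (HU) discretisation settings.
    """

    spacings: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    antialias_beta: float = 0.93
    image_interpolation: str = "trilinear"
    mask_pv_threshold: float = 0.5
    resegment_range: tuple[float, float] = (-300.0, 200.0)
    outlier_sigma: float = 3.0
    bin_numbers: tuple[int, ...] = (8, 16, 32, 64)
    bin_sizes: tuple[float, ...] = (6.0, 12.0, 18.0, 24.0)
    intensity_rounding: bool = True

    def __post_init__(self) -> None:
        self.spacings = tuple(float(s) for s in self.spacings)
        self.resegment_range = tuple(float(v) for v in self.resegment_range)
        self.bin_numbers = tuple(int(n) for n in self.bin_numbers)
        self.bin_sizes = tuple(float(w) for w in self.bin_sizes)
        if any(s <= 0 for s in self.spacings):
            raise ConfigurationError("spacings must be positive")
        lo, hi = self.resegment_range
        if not lo < hi:
            raise ConfigurationError("re-segmentation range must satisfy lo < hi")
        if not 0.0 < self.mask_pv_threshold < 1.0:
            raise ConfigurationError("mask partial-volume threshold must be in (0, 1)")
        if any(n < 2 for n in self.bin_numbers):
            raise ConfigurationError("fixed bin numbers must be >= 2")
        if any(w <= 0 for w in self.bin_sizes):
            raise ConfigurationError("fixed bin sizes must be > 0")
        if self.image_interpolation != "trilinear":
            raise ConfigurationError("only trilinear interpolation is supported")

    def discretisation_settings(self) -> list[tuple[str, float]]:
        """All (method, parameter) discretisation settings, FBN first."""
        return [("fixed_bin_number", n) for n in self.bin_numbers] + [
            ("fixed_bin_size", w) for w in self.bin_sizes
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "ProcessingConfig":
        d = dict(d)
        for k in ("spacings", "resegment_range", "bin_numbers", "bin_sizes"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def round_intensities(voxels: np.ndarray) -> np.ndarray:
    """Round to the nearest integer HU, halves away from zero.

    ``np.round`` rounds halves to even; radiological convention (and bit
    reproducibility across platforms) is better served by half-away-from-zero.
    """
    return np.trunc(voxels + np.copysign(0.5, voxels))


def interpolate_to_isotropic(
    image: VolumetricImage,
    mask: FractionalMask | RoiMask,
    target_spacing: float,
    config: ProcessingConfig | None = None,
) -> tuple[VolumetricImage, RoiMask]:
    """Resample image and mask to an isotropic grid.

    Downsampled axes are Gaussian pre-smoothed (anti-aliasing, see
    :class:`ProcessingConfig.antialias_beta`); both image and fractional mask
    are then resampled trilinearly onto a grid whose *centre* coincides with
    the source grid centre.  Image intensities are rounded to the nearest
    integer HU and the mask is binarised at the partial-volume threshold.
    """
    config = config or ProcessingConfig()
    if target_spacing <= 0:
        raise ConfigurationError("target spacing must be positive")
    frac = mask.as_fractional() if isinstance(mask, RoiMask) else mask

    src_spacing = np.asarray(image.spacing, dtype=float)
    tgt = float(target_spacing)
    identity = np.allclose(src_spacing, tgt)

    if identity:
        vox = image.voxels.copy()
        mvals = frac.values.copy()
        new_origin = image.origin
    else:
        # Per-axis anti-alias smoothing only where downsampling occurs.
        ratios = tgt / src_spacing
        sigmas = np.where(ratios > 1.0, config.antialias_beta * ratios / math.pi, 0.0)
        smoothed = (
            ndimage.gaussian_filter(image.voxels, sigma=sigmas, mode="nearest")
            if np.any(sigmas > 0)
            else image.voxels
        )
        shape = np.array(image.shape, dtype=float)
        extent = shape * src_spacing
        new_shape = np.maximum(np.ceil(extent / tgt).astype(int), 1)
        # Centre-aligned output grid (in index units of the source grid).
        src_centre = (shape - 1) / 2.0
        new_centre = (new_shape - 1) / 2.0
        axes_idx = [
            src_centre[a] + (np.arange(new_shape[a]) - new_centre[a]) * (tgt / src_spacing[a])
            for a in range(3)
        ]
        coords = np.meshgrid(*axes_idx, indexing="ij")
        coords = np.stack(coords)
        vox = ndimage.map_coordinates(
            smoothed, coords, order=1, mode="nearest"
        )
        mvals = ndimage.map_coordinates(frac.values, coords, order=1, mode="constant", cval=0.0)
        new_origin = tuple(
            image.origin[a] + axes_idx[a][0] * src_spacing[a] for a in range(3)
        )

    if config.intensity_rounding:
        vox = round_intensities(vox)
    out_img = VolumetricImage(vox, (tgt, tgt, tgt) if not identity else image.spacing, new_origin)
    out_mask = FractionalMask(
        mvals, out_img.spacing, out_img.origin
    ).binarise(config.mask_pv_threshold, kind="original")
    out_mask.require_nonempty("interpolation to isotropic grid")
    return out_img, out_mask


def resegment(
    image: VolumetricImage,
    morphological_mask: RoiMask,
    config: ProcessingConfig | None = None,
) -> RoiMask:
    """Derive the intensity mask from the morphological mask.

    The HU-range filter is applied first; the ROI mean μ and SD σ are then
    computed over the range-filtered voxels and intensities deviating more
    than ``outlier_sigma``·σ from μ are excluded (one pass, no iteration).
    The morphological mask itself is never modified.
    """
    config = config or ProcessingConfig()
    morphological_mask.require_nonempty("re-segmentation")
    lo, hi = config.resegment_range
    inside = morphological_mask.labels
    vox = image.voxels
    in_range = inside & (vox >= lo) & (vox <= hi)
    if not in_range.any():
        raise DegenerateMaskError(
            f"re-segmentation to [{lo}, {hi}] HU removed every ROI voxel"
        )
    vals = vox[in_range]
    mu = float(vals.mean())
    sigma = float(vals.std())
    keep = in_range & (np.abs(vox - mu) <= config.outlier_sigma * sigma + 1e-12)
    if not keep.any():
        raise DegenerateMaskError("outlier filtering removed every ROI voxel")
    return morphological_mask.copy(labels=keep, kind="intensity")


def discretise(
    intensities: np.ndarray,
    method: str,
    value: float,
    config: ProcessingConfig | None = None,
) -> np.ndarray:
    """Map HU intensities to integer grey levels >= 1.

    ``fixed_bin_number``: ``g = min(N_b, floor(N_b (x - min)/(max - min)) + 1)``
    over the ROI's own range; a constant ROI maps every voxel to level 1.

    ``fixed_bin_size``: ``g = floor((x - lo)/w) + 1`` anchored at the
    re-segmentation range minimum ``lo``, so grey levels are comparable
    across ROIs.
    """
    config = config or ProcessingConfig()
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise DegenerateMaskError("cannot discretise an empty intensity set")
    if method == "fixed_bin_number":
        nb = int(value)
        xmin, xmax = float(x.min()), float(x.max())
        if xmax == xmin:
            return np.ones(x.shape, dtype=np.int64)
        g = np.floor(nb * (x - xmin) / (xmax - xmin)).astype(np.int64) + 1
        return np.minimum(g, nb)
    if method == "fixed_bin_size":
        w = float(value)
        lo = config.resegment_range[0]
        g = np.floor((x - lo) / w).astype(np.int64) + 1
        return np.maximum(g, 1)
    raise ConfigurationError(f"unknown discretisation method {method!r}")


def n_levels(method: str, value: float, config: ProcessingConfig | None = None) -> int | None:
    """Upper bound on grey levels for a setting (None = data-dependent)."""
    config = config or ProcessingConfig()
    if method == "fixed_bin_number":
        return int(value)
    lo, hi = config.resegment_range
    return int(math.ceil((hi - lo) / float(value)))
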