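"""Intensity-based features computed without discretisation: first-order
statistics, local intensity peaks, and the intensity-volume histogram."""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from ..image import RoiMask, VolumetricImage

__all__ = [
    "intensity_statistics_features",
    "local_intensity_features",
    "intensity_volume_histogram_features",
    "PEAK_RADIUS_MM",
]

# Radius of a 1 cm^3 sphere, used for the intensity peak neighbourhood.
PEAK_RADIUS_MM = (3.0 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def intensity_statistics_features(values: np.ndarray) -> dict[str, float]:
    """18 first-order statistics on the raw HU values of the intensity mask.

    Variance is the population variance; kurtosis is excess kurtosis
    (Fisher); the robust mean absolute deviation is taken over the
    [P10, P90]-clipped subset around that subset's own mean.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    mu = float(x.mean())
    var = float(x.var())
    sd = math.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    out = {
        "mean": mu,
        "variance": var,
        "median": float(p50),
        "minimum": float(x.min()),
        "p10": float(p10),
        "p90": float(p90),
        "maximum": float(x.max()),
        "interquartile_range": float(p75 - p25),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.abs(x - mu).mean()),
        "median_absolute_deviation": float(np.abs(x - p50).mean()),
        "energy": float((x**2).sum()),
        "root_mean_square": math.sqrt(float((x**2).mean())),
    }
    if sd > 0:
        m3 = float(((x - mu) ** 3).mean())
        m4 = float(((x - mu) ** 4).mean())
        out["skewness"] = m3 / sd**3
        out["kurtosis"] = m4 / var**2 - 3.0
    else:
        out["skewness"] = 0.0
        out["kurtosis"] = 0.0
    sub = x[(x >= p10) & (x <= p90)]
    out["robust_mean_absolute_deviation"] = (
        float(np.abs(sub - sub.mean()).mean()) if sub.size else 0.0
    )
    out["coefficient_of_variation"] = sd / mu if mu != 0 else float("nan")
    denom = p75 + p25
    out["quartile_coefficient_of_dispersion"] = (
        float((p75 - p25) / denom) if denom != 0 else float("nan")
    )
    return out


def _sphere_kernel(spacing: tuple[float, float, float], radius_mm: float) -> np.ndarray:
    half = [int(math.floor(radius_mm / s)) for s in spacing]
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing)]
    d2 = (
        ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    )
    return (d2 <= radius_mm**2).astype(float)


def local_intensity_features(
    image: VolumetricImage, intensity_mask: RoiMask
) -> dict[str, float]:
    """Local and global intensity peak.

    The peak is the mean intensity within a 1 cm³ spherical neighbourhood
    (radius ≈ 6.2 mm).  The *local* peak takes the neighbourhood mean at the
    maximum-intensity ROI voxel (highest mean among ties); the *global* peak
    is the largest neighbourhood mean over all ROI voxels.  Neighbourhoods may
    extend beyond the ROI; at the image edge only in-grid voxels contribute.
    """
    intensity_mask.require_nonempty("local intensity")
    kernel = _sphere_kernel(image.spacing, PEAK_RADIUS_MM)
    sums = ndimage.convolve(image.voxels, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones(image.shape), kernel, mode="constant", cval=0.0)
    means = sums / counts
    roi = intensity_mask.labels
    roi_vals = image.voxels[roi]
    vmax = roi_vals.max()
    at_max = roi & (image.voxels == vmax)
    return {
        "local_peak": float(means[at_max].max()),
        "global_peak": float(means[roi].max()),
    }


def intensity_volume_histogram_features(values: np.ndarray) -> dict[str, float]:
    """Intensity-volume histogram features at 1-HU resolution.

    ν(i) is the fraction of ROI voxels with intensity ≥ i.  ``v{f}`` is ν at
    the intensity f% up the ROI intensity range; ``i{f}`` is the smallest
    intensity with ν ≤ f%; ``auc`` is the mean of ν over the 1-HU grid.  A
    constant ROI yields v = 1, i = the constant, differences 0 and auc 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    xmin, xmax = float(x.min()), float(x.max())
    n = x.size
    out: dict[str, float] = {}
    fracs = (10, 25, 50, 75, 90)
    if xmax == xmin:
        for f in fracs:
            out[f"v{f}"] = 1.0
            out[f"i{f}"] = xmin
        out["auc"] = 0.0
    else:
        grid = np.arange(math.floor(xmin), math.ceil(xmax) + 1.0, 1.0)
        nu_grid = (x[None, :] >= grid[:, None]).mean(axis=1)
        for f in fracs:
            i_f = xmin + (f / 100.0) * (xmax - xmin)
            out[f"v{f}"] = float((x >= i_f).mean())
            below = grid[nu_grid <= f / 100.0]
            out[f"i{f}"] = float(below[0]) if below.size else xmax
        out["auc"] = float(nu_grid.mean())
    out["v10_minus_v90"] = out["v10"] - out["v90"]
    out["v25_minus_v75"] = out["v25"] - out["v75"]
    out["i10_minus_i90"] = out["i10"] - out["i90"]
    out["i25_minus_i75"] = out["i25"] - out["i75"]
    return out
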