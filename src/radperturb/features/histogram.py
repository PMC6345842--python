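"""Intensity-histogram features on discretised grey levels."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["intensity_histogram_features"]


def intensity_histogram_features(levels: np.ndarray, n_levels: int | None = None) -> dict[str, float]:
    """23 histogram features from integer grey levels (>= 1).

    ``n_levels`` bounds the histogram support; by default the maximum
    observed level.  Moments mirror the first-order statistics but on grey
    levels; entropy/uniformity use the empirical level probabilities; the
    histogram gradient is the central difference of bin counts with zero
    padding at both ends.
    """
    g = np.asarray(levels, dtype=np.int64).ravel()
    if g.size == 0:
        raise ValueError("empty grey-level set")
    ng = int(n_levels or g.max())
    n = g.size
    counts = np.bincount(g, minlength=ng + 1)[1:].astype(float)
    p = counts / n

    x = g.astype(float)
    mu = float(x.mean())
    var = float(x.var())
    sd = math.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    out: dict[str, float] = {
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
    }
    if sd > 0:
        out["skewness"] = float(((x - mu) ** 3).mean()) / sd**3
        out["kurtosis"] = float(((x - mu) ** 4).mean()) / var**2 - 3.0
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
    # Mode: most frequent level, smallest level on ties.
    out["mode"] = float(int(np.argmax(counts)) + 1)
    nz = p[p > 0]
    out["entropy"] = float(-(nz * np.log2(nz)).sum())
    out["uniformity"] = float((nz**2).sum())

    padded = np.concatenate([[0.0], counts, [0.0]])
    grad = (padded[2:] - padded[:-2]) / 2.0
    out["max_gradient"] = float(grad.max())
    out["max_gradient_level"] = float(int(np.argmax(grad)) + 1)
    out["min_gradient"] = float(grad.min())
    out["min_gradient_level"] = float(int(np.argmin(grad)) + 1)
    return out
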