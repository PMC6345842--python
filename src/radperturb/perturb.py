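"""Image and mask perturbation operators and the chain engine.

Five operators emulate positioning, acquisition and delineation variability
around a single image:

* **R** — in-plane (axial) rotation of image and mask by an angle θ (degrees),
* **N** — additive Gaussian noise at the image's own estimated noise level,
* **T** — sub-voxel translation by per-axis fractions η of the voxel spacing,
* **V** — growth/shrinkage of the ROI mask by a volume fraction τ,
* **C** — supervoxel-based contour randomisation of the ROI mask.

Noise changes only intensities; V and C change only the mask; R and T change
both.  Chains permute every parameter grid (a full Cartesian product), with
translation fractions additionally permuted over the three axes (m fractions →
m³ shifts).  Operators always apply in the fixed processing order
R → N → T → (isotropic interpolation) → V → C, whatever the chain label's
letter order.
"""

from __future__ import annotations

import hashlib
import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, CoverageError, DegenerateMaskError, ParameterError
from .image import FractionalMask, RoiMask, VolumetricImage

__all__ = [
    "rotate",
    "estimate_noise_sd",
    "add_noise",
    "translate",
    "permute_translations",
    "adapt_volume",
    "contour_randomise",
    "SupervoxelSettings",
    "PerturbationSpec",
    "PerturbationChain",
    "PerturbedSample",
    "expand_chain",
    "default_chain_registry",
    "DEFAULT_ANGLE_RANGE",
    "DEFAULT_TAU_RANGE",
    "DEFAULT_ETA_RANGE",
]

# Default parameter domains; values outside trigger validation warnings.
DEFAULT_ANGLE_RANGE = (-13.0, 13.0)
DEFAULT_TAU_RANGE = (-0.28, 0.28)
DEFAULT_ETA_RANGE = (0.0, 0.75)


# ---------------------------------------------------------------------------
# Rotation and translation (affine, trilinear)
# ---------------------------------------------------------------------------

def _mask_centre_of_mass_mm(mask: RoiMask | FractionalMask) -> np.ndarray:
    arr = mask.labels.astype(float) if isinstance(mask, RoiMask) else mask.values
    com_idx = np.array(ndimage.center_of_mass(arr))
    return np.asarray(mask.origin) + com_idx * np.asarray(mask.spacing)


def rotate(
    image: VolumetricImage,
    mask: RoiMask | FractionalMask,
    theta: float,
    centre: str = "roi_center",
    fill: float | None = None,
) -> tuple[VolumetricImage, FractionalMask]:
    """Rotate image and mask in the axial (x, y) plane about the z axis.

    The rotation is applied in physical coordinates about the ROI centre of
    mass (default) or the grid centre, so anisotropic in-plane spacing is
    handled correctly.  The image is resampled trilinearly; the mask is
    carried as fractional occupancy for later partial-volume thresholding.
    θ = 0 is an exact no-op.
    """
    if not np.isfinite(theta):
        raise ParameterError(f"rotation angle must be finite, got {theta}")
    frac = mask.as_fractional() if isinstance(mask, RoiMask) else mask
    if theta == 0.0:
        return image.copy(), FractionalMask(frac.values.copy(), frac.spacing, frac.origin)

    if centre == "roi_center":
        c = _mask_centre_of_mass_mm(frac)
    elif centre == "image_center":
        c = np.asarray(image.origin) + (np.array(image.shape) - 1) * np.asarray(image.spacing) / 2.0
    else:
        raise ParameterError(f"unknown rotation centre {centre!r}")

    th = math.radians(theta)
    rot = np.array(
        [
            [math.cos(th), -math.sin(th), 0.0],
            [math.sin(th), math.cos(th), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    # Map output index -> physical -> inverse-rotate about c -> input index.
    s = np.diag(image.spacing)
    s_inv = np.diag(1.0 / np.asarray(image.spacing))
    o = np.asarray(image.origin)
    # x_in = R^-1 (x_out - c) + c ; idx = S^-1 (x - o)
    matrix = s_inv @ rot.T @ s
    offset = s_inv @ (rot.T @ (o - c) + c - o)

    if fill is None:
        fill = float(image.voxels.min())
    vox = ndimage.affine_transform(
        image.voxels, matrix, offset=offset, order=1, mode="constant", cval=fill
    )
    mvals = ndimage.affine_transform(
        frac.values, matrix, offset=offset, order=1, mode="constant", cval=0.0
    )
    out_mask = FractionalMask(mvals, frac.spacing, frac.origin)
    if float(out_mask.values.sum()) < 0.5:
        raise CoverageError(f"rotation by {theta} deg moved the ROI outside the grid")
    return VolumetricImage(vox, image.spacing, image.origin), out_mask


def translate(
    image: VolumetricImage,
    mask: RoiMask | FractionalMask,
    eta: Sequence[float],
    fill: float | None = None,
) -> tuple[VolumetricImage, FractionalMask]:
    """Shift image and mask by per-axis fractions η of the voxel spacing.

    A shift of η along an axis moves content by η·spacing mm, i.e. η voxels;
    realised by trilinear resampling.  η = (0, 0, 0) is an exact no-op.
    """
    eta = tuple(float(e) for e in eta)
    if len(eta) != 3:
        raise ParameterError("eta must have one fraction per axis")
    if any(not (0.0 <= e < 1.0) for e in eta):
        raise ParameterError(f"translation fractions must be in [0, 1), got {eta}")
    frac = mask.as_fractional() if isinstance(mask, RoiMask) else mask
    if all(e == 0.0 for e in eta):
        return image.copy(), FractionalMask(frac.values.copy(), frac.spacing, frac.origin)
    if fill is None:
        fill = float(image.voxels.min())
    # Content moves by +eta voxels: output[i] = input[i - eta].
    vox = ndimage.shift(image.voxels, shift=eta, order=1, mode="constant", cval=fill)
    mvals = ndimage.shift(frac.values, shift=eta, order=1, mode="constant", cval=0.0)
    out_mask = FractionalMask(mvals, frac.spacing, frac.origin)
    if float(out_mask.values.sum()) < 0.5:
        raise CoverageError(f"translation by {eta} moved the ROI outside the grid")
    return VolumetricImage(vox, image.spacing, image.origin), out_mask


def permute_translations(fractions: Sequence[float], axes: int = 3) -> list[tuple[float, ...]]:
    """Expand m translation fractions into all m**axes per-axis tuples."""
    fractions = [float(f) for f in fractions]
    if not fractions:
        raise ParameterError("translation fraction list must be non-empty")
    return [tuple(t) for t in itertools.product(fractions, repeat=axes)]


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def estimate_noise_sd(image: VolumetricImage, body_mask: np.ndarray | None = None) -> float:
    """Estimate the additive-noise SD (HU) of an image.

    Uses the 3D Laplacian pseudo-residual: the sum of second differences along
    each axis annihilates constant and linearly varying structure, leaving
    (scaled) noise.  The residual is normalised by the root of its coefficient
    sum of squares (√42 for the 6-neighbour Laplacian) and summarised by the
    median absolute deviation, which is robust to residual structure such as
    edges.
    """
    vox = image.voxels
    if vox.size < 1000:
        raise ParameterError("noise estimation requires at least 10^3 voxels")
    # 6-neighbour Laplacian on the interior; coefficient sum of squares = 42
    core = vox[1:-1, 1:-1, 1:-1]
    lap = (
        vox[:-2, 1:-1, 1:-1] + vox[2:, 1:-1, 1:-1]
        + vox[1:-1, :-2, 1:-1] + vox[1:-1, 2:, 1:-1]
        + vox[1:-1, 1:-1, :-2] + vox[1:-1, 1:-1, 2:]
        - 6.0 * core
    )
    if body_mask is not None:
        bm = np.asarray(body_mask, dtype=bool)[1:-1, 1:-1, 1:-1]
        lap = lap[bm]
    resid = lap.ravel() / math.sqrt(42.0)
    mad = np.median(np.abs(resid - np.median(resid)))
    sd = float(mad * 1.482602218505602)
    if sd == 0.0:
        warnings.warn("image appears noise-free (constant residual); estimated SD is 0")
    return sd


def add_noise(image: VolumetricImage, sd: float, seed: int) -> VolumetricImage:
    """Add i.i.d. Gaussian(0, sd²) noise to every voxel; deterministic per seed."""
    if sd < 0:
        raise ParameterError(f"noise SD must be >= 0, got {sd}")
    if sd == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    return VolumetricImage(
        image.voxels + rng.normal(0.0, sd, size=image.shape), image.spacing, image.origin
    )


# ---------------------------------------------------------------------------
# Volume adaptation
# ---------------------------------------------------------------------------

def adapt_volume(mask: RoiMask, tau: float, spacing: Sequence[float] | None = None) -> RoiMask:
    """Grow (τ > 0) or shrink (τ < 0) the mask to (1 + τ)× its voxel count.

    Voxels are ranked by the signed Euclidean distance to the mask boundary
    (negative inside, positive outside, physical mm) and the target count of
    smallest-distance voxels is selected; ties break on flat index for
    determinism.  This is the exact form of thresholding the signed distance
    map: growth adds the nearest outside shell, shrinkage peels the outermost
    inside shell, so τ > 0 yields a superset and τ < 0 a subset of the input.
    """
    if not -1.0 < tau < 1.0:
        raise ParameterError(f"volume fraction tau must satisfy |tau| < 1, got {tau}")
    mask.require_nonempty("volume adaptation")
    if tau == 0.0:
        return mask.copy()
    sp = tuple(spacing) if spacing is not None else mask.spacing
    n0 = mask.voxel_count
    n_target = int(round((1.0 + tau) * n0))
    if n_target < 1:
        raise DegenerateMaskError(f"shrinking by tau={tau} removes every voxel")
    inside = mask.labels
    d_out = ndimage.distance_transform_edt(~inside, sampling=sp)
    d_in = ndimage.distance_transform_edt(inside, sampling=sp)
    signed = d_out - d_in
    order = np.lexsort((np.arange(signed.size), signed.ravel()))
    new_flat = np.zeros(signed.size, dtype=bool)
    new_flat[order[:n_target]] = True
    out = new_flat.reshape(mask.shape)
    if tau > 0:
        out |= inside  # guaranteed by construction; cheap belt-and-braces
    else:
        out &= inside
    return mask.copy(labels=out)


# ---------------------------------------------------------------------------
# Contour randomisation (SLIC supervoxels)
# ---------------------------------------------------------------------------

@dataclass
class SupervoxelSettings:
    """Settings for SLIC-based contour randomisation.

    ``target_voxels`` is the average supervoxel volume in voxels of the
    working grid; ``keep_threshold`` is the overlap fraction above which a
    supervoxel is always kept; below it a supervoxel with overlap f is kept
    with probability f.  ``margin_voxels`` pads the clustered region around
    the ROI bounding box.
    """

    target_voxels: int = 150
    compactness: float = 0.05
    keep_threshold: float = 0.9
    margin_voxels: int = 4

    def __post_init__(self) -> None:
        if self.target_voxels < 1:
            raise ConfigurationError("target_voxels must be >= 1")
        if not 0.0 < self.keep_threshold <= 1.0:
            raise ConfigurationError("keep_threshold must be in (0, 1]")


def slic_supervoxels(
    image: VolumetricImage,
    mask: RoiMask,
    settings: SupervoxelSettings,
) -> tuple[np.ndarray, tuple[slice, slice, slice]]:
    """Partition the ROI neighbourhood into SLIC supervoxels.

    Returns the label volume over the clustered crop (labels >= 1 form a
    partition of the crop) and the crop slices into the full grid.
    """
    from skimage.segmentation import slic

    mask.require_nonempty("contour randomisation")
    idx = np.nonzero(mask.labels)
    m = settings.margin_voxels
    crop = tuple(
        slice(max(int(idx[a].min()) - m, 0), min(int(idx[a].max()) + m + 1, mask.shape[a]))
        for a in range(3)
    )
    sub = image.voxels[crop]
    n_vox = sub.size
    n_segments = max(int(round(n_vox / settings.target_voxels)), 1)
    if settings.target_voxels > mask.voxel_count:
        raise ConfigurationError(
            f"supervoxel size ({settings.target_voxels} voxels) exceeds the ROI "
            f"({mask.voxel_count} voxels)"
        )
    lo, hi = float(sub.min()), float(sub.max())
    norm = (sub - lo) / (hi - lo) if hi > lo else np.zeros_like(sub)
    labels = slic(
        norm,
        n_segments=n_segments,
        compactness=settings.compactness,
        spacing=mask.spacing,
        channel_axis=None,
        start_label=1,
        enforce_connectivity=True,
    )
    return labels, crop


def contour_randomise(
    image: VolumetricImage,
    mask: RoiMask,
    seed: int,
    settings: SupervoxelSettings | None = None,
) -> RoiMask:
    """Randomise the ROI contour by supervoxel reselection.

    SLIC supervoxels are computed over the ROI plus margin.  A supervoxel with
    fractional overlap f against the original mask is kept always when
    f >= ``keep_threshold``, with probability f when 0 < f < threshold, and
    never when f = 0.  The core of the ROI is therefore preserved while its
    rim is randomised.  Deterministic given the seed.
    """
    settings = settings or SupervoxelSettings()
    labels, crop = slic_supervoxels(image, mask, settings)
    sub_mask = mask.labels[crop]
    n_labels = int(labels.max())
    sizes = np.bincount(labels.ravel(), minlength=n_labels + 1).astype(float)
    overlaps = np.bincount(labels.ravel(), weights=sub_mask.ravel(), minlength=n_labels + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(sizes > 0, overlaps / sizes, 0.0)
    rng = np.random.default_rng(seed)
    u = rng.random(n_labels + 1)
    keep = (frac >= settings.keep_threshold) | ((frac > 0) & (u < frac))
    keep[0] = False
    new_sub = keep[labels]
    out = np.zeros(mask.shape, dtype=bool)
    out[crop] = new_sub
    if not out.any():
        raise DegenerateMaskError("contour randomisation removed every voxel")
    return mask.copy(labels=out)


# ---------------------------------------------------------------------------
# Chains
# ---------------------------------------------------------------------------

_KIND_ORDER = ("rotation", "noise", "translation", "volume_adaptation", "contour_randomisation")
_LETTER_TO_KIND = {
    "R": "rotation",
    "N": "noise",
    "T": "translation",
    "V": "volume_adaptation",
    "C": "contour_randomisation",
}


@dataclass
class PerturbationSpec:
    """One operator with its parameter grid.

    ``params`` holds, per kind: rotation — angles in degrees; noise — the
    repetition count; translation — fractions η (permuted over axes);
    volume_adaptation — fractions τ; contour_randomisation — the repetition
    count and optional :class:`SupervoxelSettings`.
    """

    kind: str
    angles: Sequence[float] | None = None
    repetitions: int | None = None
    fractions: Sequence[float] | None = None
    supervoxel: SupervoxelSettings | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KIND_ORDER:
            raise ParameterError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "rotation":
            if not self.angles:
                raise ParameterError("rotation requires a non-empty angle grid")
            self.angles = [float(a) for a in self.angles]
        elif self.kind == "noise":
            if not self.repetitions or self.repetitions < 1:
                raise ParameterError("noise requires repetitions >= 1")
        elif self.kind == "translation":
            if not self.fractions:
                raise ParameterError("translation requires a non-empty fraction grid")
            self.fractions = [float(f) for f in self.fractions]
            if any(not (0.0 <= f < 1.0) for f in self.fractions):
                raise ParameterError("translation fractions must lie in [0, 1)")
        elif self.kind == "volume_adaptation":
            if self.fractions is None or len(self.fractions) == 0:
                raise ParameterError("volume adaptation requires a non-empty tau grid")
            self.fractions = [float(f) for f in self.fractions]
        elif self.kind == "contour_randomisation":
            if not self.repetitions or self.repetitions < 1:
                raise ParameterError("contour randomisation requires repetitions >= 1")
            if self.supervoxel is None:
                self.supervoxel = SupervoxelSettings()

    def grid(self) -> list:
        """The concrete parameter values this spec permutes over."""
        if self.kind == "rotation":
            return list(self.angles)
        if self.kind == "noise":
            return [("noise_rep", i) for i in range(self.repetitions)]
        if self.kind == "translation":
            return permute_translations(self.fractions)
        if self.kind == "volume_adaptation":
            return list(self.fractions)
        return [("contour_rep", i) for i in range(self.repetitions)]

    def validate_ranges(self) -> list[str]:
        """Out-of-default-range warnings (never errors)."""
        msgs = []
        if self.kind == "rotation":
            lo, hi = DEFAULT_ANGLE_RANGE
            bad = [a for a in self.angles if not lo <= a <= hi]
            if bad:
                msgs.append(f"rotation angles {bad} outside default range [{lo}, {hi}] deg")
        if self.kind == "translation":
            lo, hi = DEFAULT_ETA_RANGE
            bad = [f for f in self.fractions if not lo <= f <= hi]
            if bad:
                msgs.append(f"translation fractions {bad} outside default range [{lo}, {hi}]")
        if self.kind == "volume_adaptation":
            lo, hi = DEFAULT_TAU_RANGE
            bad = [f for f in self.fractions if not lo <= f <= hi]
            if bad:
                msgs.append(f"volume fractions {bad} outside default range [{lo}, {hi}]")
        return msgs


@dataclass
class PerturbationChain:
    """An ordered set of perturbation specs expanded by full permutation.

    The label (e.g. ``"RVC"``) records which operators participate; the
    application order is always the fixed processing order regardless of the
    label's letter order.  Expansion size is the product of grid sizes, with
    translation contributing m³ for m fractions.
    """

    label: str
    specs: list[PerturbationSpec]

    def __post_init__(self) -> None:
        order = {k: i for i, k in enumerate(_KIND_ORDER)}
        self.specs = sorted(self.specs, key=lambda s: order[s.kind])
        kinds = [s.kind for s in self.specs]
        if len(set(kinds)) != len(kinds):
            raise ParameterError(f"chain {self.label!r} repeats an operator")

    @property
    def size(self) -> int:
        n = 1
        for s in self.specs:
            n *= len(s.grid())
        return n

    def spec(self, kind: str) -> PerturbationSpec | None:
        for s in self.specs:
            if s.kind == kind:
                return s
        return None

    @classmethod
    def from_label(
        cls, label: str, params: Mapping[str, object] | None = None
    ) -> "PerturbationChain":
        """Build a chain from its letter label and a parameter mapping.

        Recognised parameter keys: ``rotation`` (angle list), ``noise_repetitions``,
        ``translation`` (fraction list), ``volume`` (tau list),
        ``contour_repetitions``, ``supervoxel`` (:class:`SupervoxelSettings`).
        Missing parameters fall back to the defaults of
        :func:`default_chain_registry`.
        """
        letters = list(label)
        if len(set(letters)) != len(letters) or any(l not in _LETTER_TO_KIND for l in letters):
            raise ParameterError(f"invalid chain label {label!r}")
        params = dict(params or {})
        defaults = default_chain_registry().get(label.upper(), {})
        merged = {**defaults, **params}
        specs = []
        for letter in letters:
            kind = _LETTER_TO_KIND[letter]
            if kind == "rotation":
                specs.append(PerturbationSpec("rotation", angles=merged.get("rotation")))
            elif kind == "noise":
                specs.append(
                    PerturbationSpec("noise", repetitions=int(merged.get("noise_repetitions", 1)))
                )
            elif kind == "translation":
                specs.append(PerturbationSpec("translation", fractions=merged.get("translation")))
            elif kind == "volume_adaptation":
                specs.append(PerturbationSpec("volume_adaptation", fractions=merged.get("volume")))
            else:
                specs.append(
                    PerturbationSpec(
                        "contour_randomisation",
                        repetitions=int(merged.get("contour_repetitions", 1)),
                        supervoxel=merged.get("supervoxel"),
                    )
                )
        return cls(label.upper(), specs)


def default_chain_registry() -> dict[str, dict]:
    """Default parameter grids for the 18 standard chain labels.

    Every grid stays inside the default operator domains (θ ∈ [−13°, 13°],
    η ∈ [0, 0.75], τ ∈ [−0.28, 0.28]) and the expansion sizes reproduce the
    standard per-chain perturbed-image counts (27–40).  The exact grids are a
    package default and fully overridable.
    """

    def lin(lo, hi, n):
        return [round(float(v), 6) for v in np.linspace(lo, hi, n)]

    return {
        "R": {"rotation": lin(-13, 13, 27)},                                        # 27
        "N": {"noise_repetitions": 30},                                             # 30
        "T": {"translation": [0.25, 0.5, 0.75]},                                    # 3^3 = 27
        "V": {"volume": lin(-0.28, 0.28, 29)},                                      # 29
        "C": {"contour_repetitions": 30},                                           # 30
        "RT": {"rotation": [-13.0, -6.0, 6.0, 13.0], "translation": [0.25, 0.5]},   # 4*8 = 32
        "RNT": {"rotation": [-13.0, -6.0, 6.0, 13.0], "noise_repetitions": 1,
                "translation": [0.25, 0.5]},                                        # 32
        "RV": {"rotation": lin(-13, 13, 6), "volume": lin(-0.28, 0.28, 5)},         # 30
        "RC": {"rotation": lin(-13, 13, 9), "contour_repetitions": 3},              # 27
        "TV": {"translation": [0.25, 0.5], "volume": lin(-0.28, 0.28, 5)},          # 40
        "TC": {"translation": [0.25, 0.5, 0.75], "contour_repetitions": 1},         # 27
        "RTC": {"rotation": [-13.0, -6.0, 6.0, 13.0], "translation": [0.25, 0.5],
                "contour_repetitions": 1},                                          # 32
        "RNTC": {"rotation": [-13.0, -6.0, 6.0, 13.0], "noise_repetitions": 1,
                 "translation": [0.25, 0.5], "contour_repetitions": 1},             # 32
        "VC": {"volume": lin(-0.28, 0.28, 10), "contour_repetitions": 3},           # 30
        "RVC": {"rotation": [-13.0, 13.0], "volume": lin(-0.28, 0.28, 5),
                "contour_repetitions": 3},                                          # 30
        "RNVC": {"rotation": [-13.0, 13.0], "noise_repetitions": 1,
                 "volume": lin(-0.28, 0.28, 5), "contour_repetitions": 3},          # 30
        "TVC": {"translation": [0.25, 0.5], "volume": lin(-0.28, 0.28, 5),
                "contour_repetitions": 1},                                          # 40
        "NTVC": {"noise_repetitions": 1, "translation": [0.25, 0.5],
                 "volume": lin(-0.28, 0.28, 5), "contour_repetitions": 1},          # 40
    }


@dataclass
class PerturbedSample:
    """One perturbed image + mask with full provenance for exact replay."""

    image: VolumetricImage
    mask: RoiMask
    chain_label: str
    params: tuple
    seed: int
    target_spacing: float | None = None


def sample_seed(base_seed: int, chain_label: str, params: tuple) -> int:
    """Stable per-sample seed below 2^31, derived from provenance."""
    key = f"{base_seed}|{chain_label}|{params!r}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def expand_chain(
    chain: PerturbationChain,
    image: VolumetricImage,
    mask: RoiMask,
    config: "ProcessingConfig | None" = None,
    target_spacing: float | None = None,
    base_seed: int = 0,
    noise_sd: float | None = None,
) -> list[PerturbedSample]:
    """Expand a chain into its full set of perturbed samples.

    For each element of the Cartesian product of parameter grids the operators
    run in the fixed order R → N → T → isotropic interpolation → V → C; the
    interpolation step (with HU rounding and partial-volume thresholding)
    comes from :mod:`radperturb.processing`.  When ``target_spacing`` is None
    the native grid is kept and the fractional mask is thresholded directly.

    The noise SD is estimated once from the input image and reused for every
    repetition; per-sample seeds derive from ``base_seed`` and the provenance
    tuple so any sample can be replayed bit-exactly.
    """
    from .processing import ProcessingConfig, interpolate_to_isotropic

    config = config or ProcessingConfig()
    grids = [(s.kind, s.grid()) for s in chain.specs]
    needs_noise = chain.spec("noise") is not None
    if needs_noise and noise_sd is None:
        noise_sd = estimate_noise_sd(image)

    samples: list[PerturbedSample] = []
    for combo in itertools.product(*(g for _, g in grids)):
        params = tuple(zip((k for k, _ in grids), combo))
        seed = sample_seed(base_seed, chain.label, params)
        img = image
        frac: FractionalMask | None = None
        work_mask: RoiMask | FractionalMask = mask
        for (kind, _), value in zip(grids, combo):
            if kind == "rotation":
                img, work_mask = rotate(img, work_mask, float(value))
            elif kind == "noise":
                img = add_noise(img, float(noise_sd), seed)
            elif kind == "translation":
                img, work_mask = translate(img, work_mask, value)
        if isinstance(work_mask, RoiMask):
            work_mask = work_mask.as_fractional()
        if target_spacing is not None:
            img, bin_mask = interpolate_to_isotropic(img, work_mask, target_spacing, config)
        else:
            bin_mask = work_mask.binarise(config.mask_pv_threshold)
            bin_mask.require_nonempty("chain expansion")
        for (kind, _), value in zip(grids, combo):
            if kind == "volume_adaptation":
                bin_mask = adapt_volume(bin_mask, float(value))
            elif kind == "contour_randomisation":
                sv = chain.spec("contour_randomisation").supervoxel
                bin_mask = contour_randomise(img, bin_mask, seed, sv)
        samples.append(
            PerturbedSample(img, bin_mask, chain.label, params, seed, target_spacing)
        )
    return samples
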