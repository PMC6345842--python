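"""Feature computation engine: one manifest row per processed sample."""

from __future__ import annotations

import numpy as np

from ..errors import DegenerateMaskError
from ..image import RoiMask, VolumetricImage
from ..processing import ProcessingConfig, discretise, n_levels
from .histogram import intensity_histogram_features
from .intensity import (
    intensity_statistics_features,
    intensity_volume_histogram_features,
    local_intensity_features,
)
from .manifest import FeatureManifest, FeatureDescriptor, build_manifest
from .morphology import morphological_features
from .texture import (
    glcm_features,
    gldzm_features,
    glrlm_features,
    glszm_features,
    ngldm_features,
    ngtdm_features,
)

__all__ = ["compute_features"]


def _crop_slices(mask: np.ndarray, pad: int = 1) -> tuple[slice, slice, slice]:
    idx = np.nonzero(mask)
    return tuple(
        slice(max(int(idx[a].min()) - pad, 0), min(int(idx[a].max()) + pad + 1, mask.shape[a]))
        for a in range(3)
    )


def compute_features(
    image: VolumetricImage,
    morph_mask: RoiMask,
    intensity_mask: RoiMask,
    manifest: FeatureManifest | None = None,
    config: ProcessingConfig | None = None,
) -> tuple[dict[str, float], dict[str, str]]:
    """Compute every feature of ``manifest`` matching the image's spacing.

    ``image`` must already be on the isotropic grid of the manifest entries
    being computed (the pipeline interpolates first).  The morphological
    family uses the morphological mask; every other family uses the
    re-segmented intensity mask.  Returns ``(values, flags)``: ``values`` has
    one entry per descriptor (NaN when degenerate) and ``flags`` records a
    reason code per degenerate feature, so failures never propagate silently.
    """
    config = config or ProcessingConfig()
    if manifest is None:
        manifest = build_manifest(config)
    spacing = float(image.spacing[0])
    descs = [d for d in manifest.descriptors if d.spacing == spacing]
    if not descs:
        raise ValueError(f"manifest holds no descriptors for spacing {spacing} mm")
    morph_mask.require_nonempty("feature computation (morphological mask)")
    intensity_mask.require_nonempty("feature computation (intensity mask)")

    values: dict[str, float] = {}
    flags: dict[str, str] = {}

    def emit(desc: FeatureDescriptor, family_values: dict[str, float] | None, reason: str | None):
        if family_values is not None and desc.name in family_values:
            v = float(family_values[desc.name])
            values[desc.full_id] = v
            if not np.isfinite(v):
                flags[desc.full_id] = reason or "degenerate_value"
        else:
            values[desc.full_id] = float("nan")
            flags[desc.full_id] = reason or "not_computed"

    ivals = image.voxels[intensity_mask.labels]

    family_cache: dict[tuple, tuple[dict[str, float] | None, str | None]] = {}

    def family_result(key: tuple, fn) -> tuple[dict[str, float] | None, str | None]:
        if key not in family_cache:
            try:
                family_cache[key] = (fn(), None)
            except (ValueError, DegenerateMaskError, ZeroDivisionError) as exc:
                family_cache[key] = (None, f"degenerate: {exc}")
        return family_cache[key]

    # Crops shared by all texture families.
    crop = _crop_slices(intensity_mask.labels)
    morph_crop = morph_mask.labels[crop]
    imask_crop = intensity_mask.labels[crop]
    vox_crop = image.voxels[crop]

    disc_cache: dict[tuple[str, float], tuple[np.ndarray, int]] = {}

    def levels_volume(method: str, value: float) -> tuple[np.ndarray, int]:
        key = (method, value)
        if key not in disc_cache:
            g = discretise(ivals, method, value, config)
            vol = np.zeros(imask_crop.shape, dtype=np.int64)
            vol[imask_crop] = discretise(vox_crop[imask_crop], method, value, config)
            ng = int(value) if method == "fixed_bin_number" else int(vol.max())
            disc_cache[key] = (vol, ng)
        return disc_cache[key]

    _FAMILY_FNS = {
        "intensity_histogram": lambda vol, ng: intensity_histogram_features(vol[vol > 0], ng),
        "glcm": glcm_features,
        "glrlm": glrlm_features,
        "glszm": glszm_features,
        "gldzm": lambda vol, ng: gldzm_features(vol, ng, morph_crop),
        "ngtdm": ngtdm_features,
        "ngldm": ngldm_features,
    }

    for desc in descs:
        if desc.family == "morphological":
            fv, reason = family_result(
                ("morph",), lambda: morphological_features(image, morph_mask, intensity_mask)
            )
        elif desc.family == "local_intensity":
            fv, reason = family_result(
                ("local",), lambda: local_intensity_features(image, intensity_mask)
            )
        elif desc.family == "intensity_statistics":
            fv, reason = family_result(
                ("stats",), lambda: intensity_statistics_features(ivals)
            )
        elif desc.family == "intensity_volume_histogram":
            fv, reason = family_result(
                ("ivh",), lambda: intensity_volume_histogram_features(ivals)
            )
        else:
            method, value = desc.disc_method, desc.disc_value
            fn = _FAMILY_FNS[desc.family]
            fv, reason = family_result(
                (desc.family, method, value),
                lambda fn=fn, method=method, value=value: fn(*levels_volume(method, value)),
            )
        emit(desc, fv, reason)
    return values, flags
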