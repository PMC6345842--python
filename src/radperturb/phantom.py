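"""Synthetic phantom generator.

Produces CT-like images with an ellipsoidal ROI so that every stage of the
pipeline is testable without patient data.  The phantom is a pure function of
its spec: the same :class:`PhantomSpec` (including seed) always yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import yaml

from .errors import SpecError
from .image import RoiMask, VolumetricImage

__all__ = ["PhantomSpec", "generate_phantom"]


@dataclass
class PhantomSpec:
    """Specification of a synthetic CT phantom.

    Attributes
    ----------
    shape:
        Grid shape (nx, ny, nz).
    spacing:
        Voxel spacing in mm.
    centre:
        Ellipsoid centre in physical mm (defaults to the grid centre).
    radii:
        Ellipsoid semi-axes in mm; a sphere when all equal.
    background, foreground:
        Intensities in HU.  ``foreground`` is the mean/base level of the ROI.
    texture:
        ``"constant"`` — uniform foreground; ``"ramp"`` — linear gradient of
        ``ramp_slope`` HU/mm along x across the whole grid (structure without
        noise); ``"random"`` — seeded voxelwise grey levels, ``texture_levels``
        distinct values spread over ``texture_range`` HU inside the ROI.
    noise_sd:
        Additive Gaussian noise SD in HU applied to the whole image (0 = off).
    seed:
        Seed that fully determines texture and noise.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    centre: tuple[float, float, float] | None = None
    radii: tuple[float, float, float] = (10.0, 10.0, 10.0)
    background: float = -100.0
    foreground: float = 40.0
    texture: str = "constant"
    ramp_slope: float = 2.0
    texture_levels: int = 16
    texture_range: float = 60.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.radii = tuple(float(r) for r in self.radii)
        if self.centre is not None:
            self.centre = tuple(float(c) for c in self.centre)
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise SpecError(f"invalid grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise SpecError(f"spacing must be positive, got {self.spacing}")
        if any(r <= 0 for r in self.radii):
            raise SpecError(f"radii must be positive, got {self.radii}")
        if self.texture not in ("constant", "ramp", "random"):
            raise SpecError(f"unknown texture model {self.texture!r}")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")
        if self.texture_levels < 2:
            raise SpecError("texture_levels must be >= 2")

    def resolved_centre(self) -> tuple[float, float, float]:
        if self.centre is not None:
            return self.centre
        return tuple((s - 1) * sp / 2.0 for s, sp in zip(self.shape, self.spacing))

    def to_yaml(self) -> str:
        d = asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        d = yaml.safe_load(text)
        for k in ("shape", "spacing", "centre", "radii"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


def generate_phantom(spec: PhantomSpec) -> tuple[VolumetricImage, RoiMask]:
    """Generate a phantom image and its ROI mask.

    The mask is exact by the voxel-centre rule: a voxel belongs to the ROI iff
    its centre lies inside the analytic ellipsoid.  Noise is added only when
    ``noise_sd > 0`` and only to the image.
    """
    centre = spec.resolved_centre()
    extent = tuple((s - 1) * sp for s, sp in zip(spec.shape, spec.spacing))
    for a in range(3):
        if centre[a] - spec.radii[a] < 0 or centre[a] + spec.radii[a] > extent[a]:
            raise SpecError(
                f"ROI exceeds grid on axis {a}: centre {centre[a]} mm, radius "
                f"{spec.radii[a]} mm, grid extent [0, {extent[a]}] mm"
            )

    cx = np.arange(spec.shape[0]) * spec.spacing[0]
    cy = np.arange(spec.shape[1]) * spec.spacing[1]
    cz = np.arange(spec.shape[2]) * spec.spacing[2]
    dx = (cx - centre[0]) / spec.radii[0]
    dy = (cy - centre[1]) / spec.radii[1]
    dz = (cz - centre[2]) / spec.radii[2]
    inside = (
        dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    ) <= 1.0 + 1e-12

    rng = np.random.default_rng(spec.seed)
    voxels = np.full(spec.shape, float(spec.background))
    if spec.texture == "constant":
        voxels[inside] = spec.foreground
    elif spec.texture == "ramp":
        ramp = spec.foreground + spec.ramp_slope * (cx - centre[0])
        voxels[inside] = np.broadcast_to(ramp[:, None, None], spec.shape)[inside]
    else:  # random: seeded grey levels centred on the foreground intensity
        levels = np.linspace(
            spec.foreground - spec.texture_range / 2,
            spec.foreground + spec.texture_range / 2,
            spec.texture_levels,
        )
        idx = rng.integers(0, spec.texture_levels, size=spec.shape)
        voxels[inside] = levels[idx][inside]

    if spec.noise_sd > 0:
        voxels = voxels + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    image = VolumetricImage(voxels, spec.spacing)
    mask = RoiMask(inside, spec.spacing, (0.0, 0.0, 0.0), "original")
    return image, mask
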