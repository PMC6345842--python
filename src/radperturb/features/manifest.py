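"""Feature manifest: the registry of base features and its expansion.

The default registry defines 182 base features in 11 families.  64 are
computed directly from intensities/geometry and 118 require grey-level
discretisation.  Expanding over the configured isotropic spacings (default
1, 2, 3, 4 mm) and discretisation settings (default 4 fixed-bin-number + 4
fixed-bin-size) yields 64×4 + 118×4×8 = 4032 feature values per image.

Family composition (discretisation-dependent): intensity histogram 23, GLCM
25, GLRLM 16, GLSZM 16, GLDZM 16, NGTDM 5, NGLDM 17.  Non-discretised:
morphology 29, local intensity 2, intensity statistics 18, intensity-volume
histogram 15 (fraction grid 10/25/50/75/90% plus two difference pairs and the
AUC, giving the documented 64-feature split).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import ConfigurationError
from ..processing import ProcessingConfig

__all__ = ["FeatureDescriptor", "FeatureManifest", "build_manifest", "FAMILY_FEATURES"]


FAMILY_FEATURES: dict[str, list[str]] = {
    "morphological": [
        "volume", "volume_approx", "surface_area", "surface_to_volume_ratio",
        "compactness_1", "compactness_2", "spherical_disproportion", "sphericity",
        "asphericity", "centre_of_mass_shift", "max_3d_diameter",
        "major_axis_length", "minor_axis_length", "least_axis_length",
        "elongation", "flatness",
        "volume_density_aabb", "area_density_aabb",
        "volume_density_ombb", "area_density_ombb",
        "volume_density_aee", "area_density_aee",
        "volume_density_mvee", "area_density_mvee",
        "volume_density_convex_hull", "area_density_convex_hull",
        "integrated_intensity", "morans_i", "gearys_c",
    ],
    "local_intensity": ["local_peak", "global_peak"],
    "intensity_statistics": [
        "mean", "variance", "skewness", "kurtosis", "median", "minimum", "p10",
        "p90", "maximum", "interquartile_range", "range",
        "mean_absolute_deviation", "robust_mean_absolute_deviation",
        "median_absolute_deviation", "coefficient_of_variation",
        "quartile_coefficient_of_dispersion", "energy", "root_mean_square",
    ],
    "intensity_volume_histogram": [
        "v10", "v25", "v50", "v75", "v90",
        "i10", "i25", "i50", "i75", "i90",
        "v10_minus_v90", "v25_minus_v75", "i10_minus_i90", "i25_minus_i75",
        "auc",
    ],
    "intensity_histogram": [
        "mean", "variance", "skewness", "kurtosis", "median", "minimum", "p10",
        "p90", "maximum", "mode", "interquartile_range", "range",
        "mean_absolute_deviation", "robust_mean_absolute_deviation",
        "median_absolute_deviation", "coefficient_of_variation",
        "quartile_coefficient_of_dispersion", "entropy", "uniformity",
        "max_gradient", "max_gradient_level", "min_gradient", "min_gradient_level",
    ],
    "glcm": [
        "joint_max", "joint_average", "joint_variance", "joint_entropy",
        "difference_average", "difference_variance", "difference_entropy",
        "sum_average", "sum_variance", "sum_entropy", "angular_second_moment",
        "contrast", "dissimilarity", "inverse_difference",
        "inverse_difference_normalised", "inverse_difference_moment",
        "inverse_difference_moment_normalised", "inverse_variance",
        "correlation", "autocorrelation", "cluster_tendency", "cluster_shade",
        "cluster_prominence", "info_correlation_1", "info_correlation_2",
    ],
    "glrlm": [
        "short_run_emphasis", "long_run_emphasis", "low_grey_level_run_emphasis",
        "high_grey_level_run_emphasis", "short_run_low_grey_level_emphasis",
        "short_run_high_grey_level_emphasis", "long_run_low_grey_level_emphasis",
        "long_run_high_grey_level_emphasis", "grey_level_non_uniformity",
        "grey_level_non_uniformity_normalised", "run_length_non_uniformity",
        "run_length_non_uniformity_normalised", "run_percentage",
        "grey_level_variance", "run_length_variance", "run_entropy",
    ],
    "glszm": [
        "small_zone_emphasis", "large_zone_emphasis", "low_grey_level_zone_emphasis",
        "high_grey_level_zone_emphasis", "small_zone_low_grey_level_emphasis",
        "small_zone_high_grey_level_emphasis", "large_zone_low_grey_level_emphasis",
        "large_zone_high_grey_level_emphasis", "grey_level_non_uniformity",
        "grey_level_non_uniformity_normalised", "zone_size_non_uniformity",
        "zone_size_non_uniformity_normalised", "zone_percentage",
        "grey_level_variance", "zone_size_variance", "zone_size_entropy",
    ],
    "gldzm": [
        "small_distance_emphasis", "large_distance_emphasis",
        "low_grey_level_zone_emphasis", "high_grey_level_zone_emphasis",
        "small_distance_low_grey_level_emphasis",
        "small_distance_high_grey_level_emphasis",
        "large_distance_low_grey_level_emphasis",
        "large_distance_high_grey_level_emphasis", "grey_level_non_uniformity",
        "grey_level_non_uniformity_normalised", "zone_distance_non_uniformity",
        "zone_distance_non_uniformity_normalised", "zone_percentage",
        "grey_level_variance", "zone_distance_variance", "zone_distance_entropy",
    ],
    "ngtdm": ["coarseness", "contrast", "busyness", "complexity", "strength"],
    "ngldm": [
        "low_dependence_emphasis", "high_dependence_emphasis",
        "low_grey_level_count_emphasis", "high_grey_level_count_emphasis",
        "low_dependence_low_grey_level_emphasis",
        "low_dependence_high_grey_level_emphasis",
        "high_dependence_low_grey_level_emphasis",
        "high_dependence_high_grey_level_emphasis", "grey_level_non_uniformity",
        "grey_level_non_uniformity_normalised", "dependence_count_non_uniformity",
        "dependence_count_non_uniformity_normalised", "dependence_count_percentage",
        "grey_level_variance", "dependence_count_variance",
        "dependence_count_entropy", "dependence_count_energy",
    ],
}

DISCRETISED_FAMILIES = ("intensity_histogram", "glcm", "glrlm", "glszm", "gldzm", "ngtdm", "ngldm")
NON_DISCRETISED_FAMILIES = (
    "morphological", "local_intensity", "intensity_statistics", "intensity_volume_histogram"
)


def _disc_tag(method: str, value: float) -> str:
    if method == "fixed_bin_number":
        return f"fbn{int(value)}"
    return f"fbs{value:g}"


@dataclass(frozen=True)
class FeatureDescriptor:
    """A fully resolved feature: base name + spacing (+ discretisation)."""

    family: str
    name: str
    spacing: float
    disc_method: str | None = None
    disc_value: float | None = None

    @property
    def requires_discretisation(self) -> bool:
        return self.family in DISCRETISED_FAMILIES

    @property
    def full_id(self) -> str:
        fid = f"{self.family}_{self.name}_{self.spacing:g}mm"
        if self.disc_method is not None:
            fid += f"_{_disc_tag(self.disc_method, self.disc_value)}"
        return fid


@dataclass
class FeatureManifest:
    """Ordered list of feature descriptors plus integrity counts."""

    descriptors: list[FeatureDescriptor]

    @property
    def n_base(self) -> int:
        return len({(d.family, d.name) for d in self.descriptors})

    @property
    def n_base_discretised(self) -> int:
        return len(
            {(d.family, d.name) for d in self.descriptors if d.requires_discretisation}
        )

    @property
    def counts_by_family(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for d in self.descriptors:
            out[d.family] = out.get(d.family, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.descriptors)

    def for_spacing(self, spacing: float) -> "FeatureManifest":
        return FeatureManifest([d for d in self.descriptors if d.spacing == float(spacing)])

    def full_ids(self) -> list[str]:
        return [d.full_id for d in self.descriptors]


def build_manifest(config: ProcessingConfig | None = None) -> FeatureManifest:
    """Expand the base registry over spacings and discretisation settings.

    With the default configuration this yields 4032 descriptors:
    64 non-discretised × 4 spacings + 118 discretised × 4 spacings ×
    (4 bin numbers + 4 bin sizes).
    """
    config = config or ProcessingConfig()
    n_nondisc = sum(len(FAMILY_FEATURES[f]) for f in NON_DISCRETISED_FAMILIES)
    n_disc = sum(len(FAMILY_FEATURES[f]) for f in DISCRETISED_FAMILIES)
    if n_nondisc + n_disc != 182 or n_disc != 118:
        raise ConfigurationError(
            f"feature registry integrity violated: {n_nondisc}+{n_disc} base features"
        )
    descriptors: list[FeatureDescriptor] = []
    settings = config.discretisation_settings()
    for spacing in config.spacings:
        for family in NON_DISCRETISED_FAMILIES:
            for name in FAMILY_FEATURES[family]:
                descriptors.append(FeatureDescriptor(family, name, float(spacing)))
        for method, value in settings:
            for family in DISCRETISED_FAMILIES:
                for name in FAMILY_FEATURES[family]:
                    descriptors.append(
                        FeatureDescriptor(family, name, float(spacing), method, float(value))
                    )
    expected = len(config.spacings) * (n_nondisc + n_disc * len(settings))
    if len(descriptors) != expected:
        raise ConfigurationError("manifest expansion does not match configured totals")
    return FeatureManifest(descriptors)
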