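"""Versioned feature manifest: the fixed, ordered catalog of feature ids.

Per ROI the catalog holds exactly 292 features:

* 14 first-order intensity features and 8 shape features, computed on the
  original image only;
* 45 texture features (22 GLCM + 13 GLRLM + 5 GLSZM + 5 NGTDM) on each of
  6 image variants — the original image, the wavelet approximation sub-band,
  and Laplacian-of-Gaussian responses at sigma = 1.0, 1.5, 2.0, 2.5 mm —
  for 270 texture features.

Two ROIs (intratumoral + peritumoral ring) give 584 features per patient.
Feature ids are ``role|variant|family|name`` and their order is frozen by
this module; the manifest constructor asserts the 14/8/270 arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FeatureManifest",
    "VARIANTS",
    "FIRST_ORDER_NAMES",
    "SHAPE_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "LOG_SIGMAS_MM",
    "WAVELET_BASIS",
]

MANIFEST_VERSION = "1.0"

#: LoG bandpass scales in mm and the (orthogonal) wavelet basis of the
#: approximation sub-band variant.
LOG_SIGMAS_MM = (1.0, 1.5, 2.0, 2.5)
WAVELET_BASIS = "coif1"

VARIANTS = (
    "original",
    "wavelet_approx",
    "log_sigma_1.0",
    "log_sigma_1.5",
    "log_sigma_2.0",
    "log_sigma_2.5",
)

FIRST_ORDER_NAMES = (
    "mean", "median", "minimum", "maximum", "range", "variance",
    "standard_deviation", "skewness", "kurtosis", "energy", "entropy",
    "root_mean_squared", "mean_absolute_deviation", "uniformity",
)

SHAPE_NAMES = (
    "volume", "surface_area", "surface_volume_ratio", "sphericity",
    "compactness1", "compactness2", "maximum_3d_diameter",
    "spherical_disproportion",
)

GLCM_NAMES = (
    "autocorrelation", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_entropy",
    "difference_variance", "dissimilarity", "energy", "entropy",
    "homogeneity", "idmn", "inverse_difference", "idn", "imc1", "imc2",
    "inverse_variance", "maximum_probability", "sum_average",
    "sum_entropy", "sum_variance",
)

GLRLM_NAMES = (
    "short_run_emphasis", "long_run_emphasis", "gray_level_nonuniformity",
    "run_length_nonuniformity", "run_percentage",
    "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis", "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis", "long_run_high_gray_level_emphasis",
    "gray_level_variance", "run_length_variance",
)

GLSZM_NAMES = (
    "small_area_emphasis", "large_area_emphasis",
    "gray_level_nonuniformity", "size_zone_nonuniformity", "zone_percentage",
)

NGTDM_NAMES = ("coarseness", "contrast", "busyness", "complexity", "strength")

TEXTURE_FAMILIES = (
    ("glcm", GLCM_NAMES),
    ("glrlm", GLRLM_NAMES),
    ("glszm", GLSZM_NAMES),
    ("ngtdm", NGTDM_NAMES),
)

ROI_ROLES = ("intratumoral", "peritumoral")


def _roi_entries(role: str) -> list[tuple[str, str, str, str]]:
    entries = [(role, "original", "first_order", n) for n in FIRST_ORDER_NAMES]
    entries += [(role, "original", "shape", n) for n in SHAPE_NAMES]
    for variant in VARIANTS:
        for family, names in TEXTURE_FAMILIES:
            entries += [(role, variant, family, n) for n in names]
    return entries


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered feature-id catalog; construction asserts the printed counts."""

    entries: tuple[tuple[str, str, str, str], ...] = field(default=None)  # type: ignore[assignment]
    version: str = MANIFEST_VERSION

    def __post_init__(self) -> None:
        if self.entries is None:
            object.__setattr__(
                self, "entries",
                tuple(e for role in ROI_ROLES for e in _roi_entries(role)),
            )
        per_roi = len(self.entries) // len(ROI_ROLES)
        n_texture = sum(len(names) for _, names in TEXTURE_FAMILIES) * len(VARIANTS)
        if len(FIRST_ORDER_NAMES) != 14 or len(SHAPE_NAMES) != 8 or n_texture != 270:
            raise AssertionError("feature family counts violate the 14/8/270 catalog")
        if per_roi != 292 or len(self.entries) != 584:
            raise AssertionError(
                f"manifest must hold 292 ids per ROI (584 total), got {per_roi}/{len(self.entries)}"
            )

    @staticmethod
    def feature_id(role: str, variant: str, family: str, name: str) -> str:
        return f"{role}|{variant}|{family}|{name}"

    @property
    def ids(self) -> list[str]:
        return [self.feature_id(*e) for e in self.entries]

    def roi_ids(self, role: str) -> list[str]:
        return [self.feature_id(*e) for e in self.entries if e[0] == role]

    def counts_per_family(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, _, family, _ in self.entries:
            counts[family] = counts.get(family, 0) + 1
        return counts

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i, *e, self.feature_id(*e)) for i, e in enumerate(self.entries)],
            columns=["index", "roi_role", "image_variant", "family", "feature_name", "feature_id"],
        )

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.insert(0, "manifest_version", self.version)
        df.to_csv(path, index=False)
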