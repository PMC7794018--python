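"""Feature extraction drivers: ROI -> 292 values, patient -> 584, cohort -> matrix."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..datatypes import CTVolume, DegenerateROIError, ROIMask
from .filters import image_variants
from .firstorder import first_order_features
from .manifest import LOG_SIGMAS_MM, VARIANTS, FeatureManifest
from .shape import shape_features
from .texture import texture_features

__all__ = ["extract_roi_features", "extract_patient_features", "extract_cohort"]

logger = logging.getLogger(__name__)


def extract_roi_features(
    volume: CTVolume,
    mask: ROIMask,
    manifest: FeatureManifest | None = None,
    variants: dict[str, CTVolume] | None = None,
) -> dict[str, float]:
    """Extract the 292-feature catalog for one ROI.

    First-order and shape features are computed on the original image; the
    45 texture features are computed on each of the 6 image variants.
    ``variants`` may be passed to reuse filter responses across the two ROIs
    of one patient.  Returns an ordered ``feature_id -> value`` mapping.
    """
    manifest = manifest or FeatureManifest()
    if mask.is_empty():
        raise DegenerateROIError(f"{mask.role} ROI is empty")
    if volume.shape != mask.shape:
        raise ValueError(f"volume {volume.shape} / mask {mask.shape} misaligned")
    if variants is None:
        variants = image_variants(volume, LOG_SIGMAS_MM)

    role = mask.role
    fid = manifest.feature_id
    out: dict[str, float] = {}
    try:
        for name, value in first_order_features(volume.values[mask.values]).items():
            out[fid(role, "original", "first_order", name)] = value
        for name, value in shape_features(mask).items():
            out[fid(role, "original", "shape", name)] = value
        for variant in VARIANTS:
            fam = texture_features(variants[variant].values, mask.values)
            for family, feats in fam.items():
                for name, value in feats.items():
                    out[fid(role, variant, family, name)] = value
    except DegenerateROIError as exc:
        raise DegenerateROIError(f"{role} ROI: {exc}") from exc

    expected = manifest.roi_ids(role)
    vector = {k: out[k] for k in expected}
    bad = [k for k, v in vector.items() if not np.isfinite(v)]
    if bad:
        raise DegenerateROIError(f"non-finite features in {role} ROI: {bad[:5]}")
    return vector


def extract_patient_features(
    volume: CTVolume,
    tumor: ROIMask,
    ring: ROIMask,
    manifest: FeatureManifest | None = None,
) -> dict[str, float]:
    """584 features for one patient: intratumoral catalog then ring catalog."""
    manifest = manifest or FeatureManifest()
    variants = image_variants(volume, LOG_SIGMAS_MM)
    vec = extract_roi_features(volume, tumor, manifest, variants)
    vec.update(extract_roi_features(volume, ring, manifest, variants))
    return {k: vec[k] for k in manifest.ids}


def extract_cohort(
    patients,  # iterable of (patient_id, CTVolume, tumor ROIMask, ring ROIMask)
    manifest: FeatureManifest | None = None,
) -> pd.DataFrame:
    """Patients x 584 feature matrix in fixed manifest column order.

    A patient whose extraction fails is logged and omitted; the run
    continues.
    """
    manifest = manifest or FeatureManifest()
    rows: dict[str, dict[str, float]] = {}
    for patient_id, volume, tumor, ring in patients:
        try:
            rows[patient_id] = extract_patient_features(volume, tumor, ring, manifest)
        except (DegenerateROIError, ValueError) as exc:
            logger.error("patient %s skipped: %s", patient_id, exc)
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=manifest.ids)
    matrix.index.name = "patient_id"
    return matrix
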