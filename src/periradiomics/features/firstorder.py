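"""First-order intensity statistics of the raw HU values inside an ROI."""

from __future__ import annotations

import numpy as np

from ..datatypes import DegenerateROIError
from .manifest import FIRST_ORDER_NAMES

__all__ = ["first_order_features"]

_N_BINS_ENTROPY = 32  # histogram bins for entropy/uniformity, matches texture discretization


def first_order_features(values: np.ndarray) -> dict[str, float]:
    """The 14 first-order features on the 1D array of in-ROI intensities.

    Variance/SD are population (ddof=0); skewness and kurtosis are the
    population 3rd/4th standardized moments (kurtosis non-excess, Pearson),
    defined as 0 for a constant ROI; entropy (bits) and uniformity use a
    32-bin equal-width histogram over the ROI range, so a constant ROI has
    entropy 0 and uniformity 1.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise DegenerateROIError("first-order features of an empty ROI")
    mean = v.mean()
    var = v.var()
    sd = np.sqrt(var)
    centred = v - mean
    if sd > 0:
        skew = np.mean(centred ** 3) / sd ** 3
        kurt = np.mean(centred ** 4) / sd ** 4
    else:
        skew = kurt = 0.0
    vmin, vmax = v.min(), v.max()
    if vmax > vmin:
        hist, _ = np.histogram(v, bins=_N_BINS_ENTROPY, range=(vmin, vmax))
        p = hist / v.size
        p = p[p > 0]
    else:
        p = np.array([1.0])
    out = {
        "mean": mean,
        "median": float(np.median(v)),
        "minimum": vmin,
        "maximum": vmax,
        "range": vmax - vmin,
        "variance": var,
        "standard_deviation": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float(np.sum(v ** 2)),
        "entropy": float(-(p * np.log2(p)).sum()),
        "root_mean_squared": float(np.sqrt(np.mean(v ** 2))),
        "mean_absolute_deviation": float(np.mean(np.abs(centred))),
        "uniformity": float(np.sum(p ** 2)),
    }
    assert set(out) == set(FIRST_ORDER_NAMES)
    return {k: float(out[k]) for k in FIRST_ORDER_NAMES}
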