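"""First-order intensity statistics within the GTV.

Nine statistics of the voxel values inside the mask, in the modality's
units (HU for CT, unitless SUV for PET).  Conventions (recorded in the
result's ``meta``): population (n) denominators for the standard deviation
and the central moments, and *non-excess* kurtosis (a Gaussian scores 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np

from .grids import RoiMask, VolumeGrid

INTENSITY_FEATURE_NAMES = (
    "Minimum", "Maximum", "Mean", "StandardDeviation", "Sum",
    "Median", "Skewness", "Kurtosis", "Variance",
)


@dataclass
class IntensityFeatureSet:
    Minimum: float
    Maximum: float
    Mean: float
    StandardDeviation: float
    Sum: float
    Median: float
    Skewness: float
    Kurtosis: float
    Variance: float
    #: conventions + degenerate-region flag
    meta: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "meta"}


def compute_intensity_features(vol: VolumeGrid, mask: RoiMask) -> IntensityFeatureSet:
    """Nine first-order statistics over the masked voxels.

    Skewness m3/m2^1.5 and kurtosis m4/m2^2 use central moments with
    denominator n; a constant region has undefined skewness/kurtosis,
    returned as 0 with ``meta['constant_region'] = True``.
    """
    if not mask.same_grid(vol):
        raise ValueError("mask is not aligned to the volume grid")
    if mask.n_foreground == 0:
        raise ValueError("intensity features require a non-empty mask")
    x = np.asarray(vol.voxels, dtype=float)[mask.mask]
    n = x.size
    mean = float(x.mean())
    centered = x - mean
    m2 = float(np.mean(centered**2))
    meta = {"moment_denominator": "n", "kurtosis_convention": "non-excess",
            "constant_region": False}
    if m2 > 0:
        skew = float(np.mean(centered**3) / m2**1.5)
        kurt = float(np.mean(centered**4) / m2**2)
    else:
        warnings.warn("constant ROI: skewness/kurtosis undefined, returning 0",
                      stacklevel=2)
        skew = kurt = 0.0
        meta["constant_region"] = True
    return IntensityFeatureSet(
        Minimum=float(x.min()),
        Maximum=float(x.max()),
        Mean=mean,
        StandardDeviation=float(np.sqrt(m2)),
        Sum=float(x.sum()),
        Median=float(np.median(x)),
        Skewness=skew,
        Kurtosis=kurt,
        Variance=m2,
        meta=meta,
    )
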