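"""Voxel-wise Z/W maps and subthreshold-voxel extent scoring.

A subject's atrophy is operationalized as the deviation of their GM map
from a normative reference: Z = (observed - reference mean) / reference SD
per voxel. Thresholding the Z-map at a fixed negative level and counting
subthreshold voxels inside an ROI yields the per-subject atrophy score
used for CN-vs-MCI classification. W-maps are the regression-adjusted
analogue, standardizing the residual from a voxel-wise age model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .references import ReferenceModel, WScoreModel
from .volumes import BrainMask, GMVolume, ROIAtlas, assert_same_grid, make_brain_mask

#: default SD floor (GM concentration units) below which voxels are excluded
DEFAULT_SD_FLOOR = 1e-4

EXTENT_COLUMNS = (
    "subject_id", "group", "roi", "z_threshold", "fwhm_mm",
    "reference_type", "n_subthreshold", "mm3_subthreshold",
)


@dataclass
class ZMap:
    """A subject's voxel-wise Z (or W) statistics.

    Values outside the brain mask, and at voxels whose reference SD fell
    below the floor, are NaN sentinels excluded from every count.
    ``flagged_voxels`` reports how many in-mask voxels the SD floor
    removed, so silent exclusions stay visible.
    """

    data: np.ndarray
    subject_id: str
    reference: str
    mask: BrainMask
    flagged_voxels: int = 0

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.data).sum())


def _standardize(
    vol: GMVolume,
    center: np.ndarray,
    scale: np.ndarray,
    mask: BrainMask,
    sd_floor: float,
    subject_id: str,
    reference: str,
) -> ZMap:
    if sd_floor <= 0:
        raise ParameterError(f"sd_floor must be > 0, got {sd_floor}")
    valid = mask.mask & (scale >= sd_floor)
    flagged = int((mask.mask & ~valid).sum())
    z = np.full(vol.data.shape, np.nan)
    z[valid] = (vol.data[valid] - center[valid]) / scale[valid]
    return ZMap(z, subject_id, reference, mask, flagged_voxels=flagged)


def compute_zmap(
    vol: GMVolume,
    ref: ReferenceModel,
    sd_floor: float = DEFAULT_SD_FLOOR,
    mask: BrainMask | None = None,
    subject_id: str = "",
    epsilon: float = 0.05,
) -> ZMap:
    """Z = (vol - reference mean) / reference SD inside the brain mask.

    If no mask is given, one is derived from the reference mean map
    (mean > epsilon).
    """
    assert_same_grid(vol, ref.mean_map)
    assert_same_grid(vol, ref.sd_map)
    if mask is None:
        mask = make_brain_mask(ref.mean_map, epsilon)
    else:
        assert_same_grid(vol, mask)
    return _standardize(
        vol, ref.mean_map.data, ref.sd_map.data, mask, sd_floor,
        subject_id, ref.describe(),
    )


def compute_wmap(
    vol: GMVolume,
    age: float,
    model: WScoreModel,
    sd_floor: float = DEFAULT_SD_FLOOR,
    mask: BrainMask | None = None,
    subject_id: str = "",
    epsilon: float = 0.05,
) -> ZMap:
    """W = (vol - (intercept + slope*age)) / residual SD, same masking as Z."""
    assert_same_grid(vol, model.intercept_map)
    predicted = model.predict(age)
    if mask is None:
        mask = make_brain_mask(
            model.intercept_map.like(model.predict(model.mean_age)), epsilon
        )
    else:
        assert_same_grid(vol, mask)
    return _standardize(
        vol, predicted, model.resid_sd_map.data, mask, sd_floor,
        subject_id, f"wscore(k={model.k})",
    )


def count_subthreshold(
    zmap: ZMap, atlas: ROIAtlas, roi: str, threshold: float
) -> int:
    """Number of in-mask, defined voxels in the ROI with Z strictly below threshold.

    ``roi`` may be any atlas ROI name or ``"total"`` (union of all labels).
    """
    if threshold >= 0:
        raise ParameterError(f"Z threshold must be negative, got {threshold}")
    roi_mask = atlas.roi_mask(roi)
    with np.errstate(invalid="ignore"):
        sub = zmap.data < threshold  # NaN compares False, sentinels drop out
    return int((sub & roi_mask).sum())


def extent_row(
    zmap: ZMap, atlas: ROIAtlas, rois, thresholds, fwhm_mm: float,
    reference_type: str, group: str,
) -> list[dict]:
    """Extent-table rows for one Z-map over the roi x threshold grid."""
    vox_mm3 = float(np.prod(atlas.voxel_size))
    rows = []
    for roi in rois:
        for thr in thresholds:
            n = count_subthreshold(zmap, atlas, roi, thr)
            rows.append(dict(
                subject_id=zmap.subject_id, group=group, roi=roi,
                z_threshold=thr, fwhm_mm=fwhm_mm,
                reference_type=reference_type,
                n_subthreshold=n, mm3_subthreshold=n * vox_mm3,
            ))
    return rows


def extent_table(rows: list[dict]) -> pd.DataFrame:
    """Tidy extent table with the canonical column order."""
    df = pd.DataFrame(rows, columns=list(EXTENT_COLUMNS))
    df["n_subthreshold"] = df["n_subthreshold"].astype(int)
    return df
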