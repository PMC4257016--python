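"""Per-subject VOI summaries feeding the cohort statistics.

For each subject, the DWI lesion and the tissue-at-risk masks are
summarised by their volume and the median of ADC and the four perfusion
parameters inside the mask.  Medians (not means) are used because the
voxelwise parameter distributions are markedly non-normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

COHORT_COLUMNS = ["subject_id", "group", "voi", "volume_ml", "adc_median",
                  "tmax_median", "cbf_median", "cbv_median", "mtt_median"]
PARAMETERS = ["adc_median", "tmax_median", "cbf_median", "cbv_median",
              "mtt_median"]


@dataclass
class SubjectResult:
    """One subject's maps and masks ready for VOI extraction."""

    subject_id: str
    group: str
    adc: np.ndarray          # mm^2/s
    perfusion: "object"      # PerfusionMaps
    masks: "object"          # LesionMasks


def median_in_mask(volume: np.ndarray, mask: np.ndarray) -> float:
    """Sample median of map values inside a mask, ignoring NaN voxels.

    Returns NaN (and logs) when no valid voxel remains.  For even counts
    the midpoint of the two central order statistics is returned.
    """
    volume = np.asarray(volume, dtype=float)
    vals = volume[np.asarray(mask, dtype=bool)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        log.warning("median_in_mask: no valid voxels in mask")
        return float("nan")
    return float(np.median(vals))


def _voi_row(subject: SubjectResult, voi_name: str, mask: np.ndarray) -> dict:
    maps = subject.perfusion
    return {
        "subject_id": subject.subject_id,
        "group": subject.group,
        "voi": voi_name,
        "volume_ml": subject.masks.volumes_ml()[voi_name],
        "adc_median": median_in_mask(subject.adc, mask),
        "tmax_median": median_in_mask(maps.tmax, mask),
        "cbf_median": median_in_mask(maps.cbf, mask),
        "cbv_median": median_in_mask(maps.cbv, mask),
        "mtt_median": median_in_mask(maps.mtt, mask),
    }


def build_cohort_table(subjects: list[SubjectResult]) -> pd.DataFrame:
    """Two rows (dwi_lesion, tar) per subject; empty TAR rows are dropped.

    Raises on duplicate subject ids.  Column order is fixed so the CSV
    matches across runs.
    """
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    rows = []
    for s in subjects:
        rows.append(_voi_row(s, "dwi_lesion", s.masks.dwi_lesion))
        if s.masks.tar.any():
            rows.append(_voi_row(s, "tar", s.masks.tar))
        else:
            log.warning("subject %s has an empty TAR; row skipped", s.subject_id)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def group_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Median and Q1-Q3 per group x VOI x parameter (linear-interpolation
    quartiles)."""
    records = []
    for (group, voi), sub in cohort.groupby(["group", "voi"]):
        for col in ["volume_ml"] + PARAMETERS:
            vals = sub[col].dropna().to_numpy()
            if vals.size == 0:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            records.append({"group": group, "voi": voi, "parameter": col,
                            "median": med, "q1": q1, "q3": q3, "n": vals.size})
    return pd.DataFrame.from_records(records)
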