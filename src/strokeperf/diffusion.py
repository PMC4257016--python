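"""ADC mapping from two-b-value diffusion-weighted volumes.

The Stejskal-Tanner decay ``S_b = S_0 * exp(-b * ADC)`` is inverted from
a b = 0 volume and three orthogonal b = 1000 s/mm^2 volumes.  The three
directions are combined into the trace-weighted signal (their geometric
mean), which makes the map identical to averaging the three per-direction
ADC values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AdcMap:
    """Apparent diffusion coefficient map in mm^2/s (NaN outside valid)."""

    adc: np.ndarray
    valid: np.ndarray
    n_clamped: int = 0   # voxels with negative ADC floored to 0 (noise)


def compute_adc(b0: np.ndarray, dwi_dirs: np.ndarray, b: float = 1000.0,
                min_b0: float = 0.0) -> AdcMap:
    """Invert the Stejskal-Tanner decay voxelwise.

    Parameters
    ----------
    b0 : 3-D unweighted volume.
    dwi_dirs : 4-D array, last axis the diffusion directions.
    b : diffusion weighting in s/mm^2 (must be positive).
    min_b0 : optional noise floor; voxels with b0 <= max(min_b0, 0) are
        marked invalid.

    Negative ADC values (direction signal above b0, pure noise) are
    clamped to 0 and counted.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    b0 = np.asarray(b0, dtype=float)
    dirs = np.asarray(dwi_dirs, dtype=float)
    if dirs.ndim != b0.ndim + 1 or dirs.shape[:-1] != b0.shape:
        raise ValueError("direction volumes must share the b0 grid")
    valid = (b0 > max(min_b0, 0.0)) & np.all(dirs > 0, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # geometric mean of the directions == mean of per-direction ADCs
        log_trace = np.log(dirs).mean(axis=-1)
        adc = (np.log(b0) - log_trace) / b
    adc[~valid] = np.nan
    neg = valid & (adc < 0)
    adc[neg] = 0.0
    return AdcMap(adc=adc, valid=valid, n_clamped=int(neg.sum()))
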