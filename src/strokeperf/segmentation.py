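"""Seeded volume-growing segmentation of the infarct core and penumbra.

Two masks are grown and differenced:

* DWI lesion — grown from operator-supplied seed voxels through voxels
  with ADC strictly below the fixed upper threshold of 550e-6 mm^2/s
  (the standard acute-stroke core criterion);
* hypoperfusion — grown from every DWI-lesion voxel through voxels with
  Tmax strictly above 6 s;
* tissue at risk (TAR) — the hypoperfusion mask minus the DWI lesion,
  so the two reported VOIs never overlap.

Growth is plain 3-D connected-component flood fill (26-connectivity by
default); NaN map values never satisfy a predicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class GrowConfig:
    adc_threshold: float = 550e-6   # mm^2/s, upper bound (strict)
    tmax_threshold: float = 6.0     # s, lower bound (strict)
    connectivity: int = 26          # 6 (faces) or 26 (full neighbourhood)

    def __post_init__(self) -> None:
        if self.adc_threshold <= 0 or self.tmax_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class LesionMasks:
    """DWI lesion, hypoperfusion and derived TAR on one grid."""

    dwi_lesion: np.ndarray
    hypoperfusion: np.ndarray
    tar: np.ndarray
    voxel_size: tuple[float, float, float]  # mm

    def volumes_ml(self) -> dict[str, float]:
        return {name: mask_volume_ml(m, self.voxel_size)
                for name, m in (("dwi_lesion", self.dwi_lesion),
                                ("hypoperfusion", self.hypoperfusion),
                                ("tar", self.tar))}


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def region_grow(volume: np.ndarray, seeds, predicate,
                connectivity: int = 26) -> np.ndarray:
    """Voxels connected to any seed through predicate-satisfying voxels.

    ``predicate`` maps the volume to a boolean array; NaNs are treated as
    failing.  Seeds that fail the predicate contribute nothing.  An empty
    seed set is an error.
    """
    volume = np.asarray(volume, dtype=float)
    seeds = [tuple(int(c) for c in s) for s in seeds]
    if not seeds:
        raise ValueError("empty seed set")
    for s in seeds:
        if any(c < 0 or c >= n for c, n in zip(s, volume.shape)):
            raise ValueError(f"seed {s} outside the grid")
    admissible = np.asarray(predicate(volume), dtype=bool)
    admissible &= np.isfinite(volume)
    labels, _ = ndimage.label(admissible, structure=_structure(connectivity))
    keep = {labels[s] for s in seeds if admissible[s]}
    keep.discard(0)
    if not keep:
        return np.zeros(volume.shape, dtype=bool)
    return np.isin(labels, sorted(keep))


def segment_dwi_lesion(adc: np.ndarray, seeds, config: GrowConfig | None = None
                       ) -> np.ndarray:
    """Grow the acute diffusion lesion from seeds, ADC < threshold (strict)."""
    config = config or GrowConfig()
    mask = region_grow(adc, seeds, lambda v: v < config.adc_threshold,
                       config.connectivity)
    if not mask.any():
        warnings.warn("no seed lies below the ADC threshold; empty DWI lesion",
                      stacklevel=2)
    return mask


def segment_hypoperfusion(tmax: np.ndarray, dwi_lesion: np.ndarray,
                          config: GrowConfig | None = None) -> np.ndarray:
    """Grow the hypoperfused region (Tmax > threshold, strict) from the lesion.

    Every DWI-lesion voxel acts as a seed, so hypoperfused tissue not
    connected to the lesion is excluded.
    """
    config = config or GrowConfig()
    dwi_lesion = np.asarray(dwi_lesion, dtype=bool)
    if not dwi_lesion.any():
        raise ValueError("empty DWI lesion: no seeds for hypoperfusion growing")
    seeds = [tuple(idx) for idx in np.argwhere(dwi_lesion)]
    return region_grow(tmax, seeds, lambda v: v > config.tmax_threshold,
                       config.connectivity)


def tissue_at_risk(hypoperfusion: np.ndarray, dwi_lesion: np.ndarray
                   ) -> np.ndarray:
    """Perfusion-diffusion mismatch: hypoperfusion minus the DWI lesion."""
    hypoperfusion = np.asarray(hypoperfusion, dtype=bool)
    dwi_lesion = np.asarray(dwi_lesion, dtype=bool)
    if hypoperfusion.shape != dwi_lesion.shape:
        raise ValueError("masks must share one grid")
    return hypoperfusion & ~dwi_lesion


def mask_volume_ml(mask: np.ndarray, voxel_size) -> float:
    """Mask volume in ml from the voxel size in mm."""
    dx, dy, dz = voxel_size
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError("voxel size must be positive")
    return float(np.count_nonzero(mask) * dx * dy * dz / 1000.0)


def segment_lesions(adc_map, perfusion_tmax: np.ndarray, seeds,
                    voxel_size, config: GrowConfig | None = None) -> LesionMasks:
    """Full mismatch segmentation: DWI lesion, hypoperfusion, TAR."""
    config = config or GrowConfig()
    adc = adc_map.adc if hasattr(adc_map, "adc") else np.asarray(adc_map)
    dwi = segment_dwi_lesion(adc, seeds, config)
    if dwi.any():
        hypo = segment_hypoperfusion(perfusion_tmax, dwi, config)
    else:
        hypo = np.zeros_like(dwi)
    tar = tissue_at_risk(hypo, dwi)
    return LesionMasks(dwi_lesion=dwi, hypoperfusion=hypo, tar=tar,
                       voxel_size=tuple(voxel_size))
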