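"""Block-circulant truncated-SVD deconvolution of the tissue curves.

Per voxel the indicator-dilution model ``C(t) = F * R(t) (x) Ca(t)`` is
solved for the flow-scaled residue ``k(t) = F * R(t)`` by building the
circular-convolution matrix of the zero-padded AIF (padding to L = 2N
avoids wrap-around of delayed curves) and applying a truncated SVD
pseudo-inverse: singular values below ``threshold * sigma_max`` are
zeroed, with the fixed relative threshold 0.2.

The circulant (delay-insensitive) formulation makes the estimates
independent of the bolus arrival delay between AIF and tissue: a pure
delay shifts the recovered residue, moving Tmax, without changing its
peak or area.

Parameter maps follow from the recovered k(t):

* CBF  = max k(t)               (peak of the flow-scaled residue)
* Tmax = argmax k(t) * dt       (first maximum on ties)
* CBV  = sum k(t) * dt          (rectangle-rule area, first N samples)
* MTT  = CBV / CBF              (central volume theorem)

Raw values (fractions and 1/s) are mapped to absolute units with the
conventional constants rho = 1.04 g/ml and k_H = 0.73:
``CBF[ml/100g/min] = k_raw_max * 6000 * k_H / rho`` and
``CBV[ml/100g] = area * 100 * k_H / rho``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import BRAIN_DENSITY_G_PER_ML, HEMATOCRIT_FACTOR
from .preprocess import Aif, DynamicSeries


@dataclass(frozen=True)
class DeconvolutionConfig:
    truncation_threshold: float = 0.2   # fraction of the largest singular value
    pad_factor: int = 2
    rho: float = BRAIN_DENSITY_G_PER_ML   # g/ml
    k_h: float = HEMATOCRIT_FACTOR        # dimensionless

    def __post_init__(self) -> None:
        if not 0 < self.truncation_threshold < 1:
            raise ValueError("truncation_threshold must lie in (0, 1)")
        if self.pad_factor < 2:
            raise ValueError("pad_factor must be >= 2")


@dataclass
class ResidueEstimate:
    """Flow-scaled residue k(t) = CBF_raw * R(t) on the padded time axis."""

    k_curve: np.ndarray   # length pad_factor * n_frames, units 1/s
    dt: float             # s

    def __post_init__(self) -> None:
        self.k_curve = np.asarray(self.k_curve, dtype=float)
        if not np.all(np.isfinite(self.k_curve)):
            raise ValueError("residue estimate contains non-finite values")


@dataclass
class PerfusionMaps:
    """Co-registered CBF/CBV/MTT/Tmax maps sharing one grid.

    Values are NaN outside ``valid``; inside, ``mtt == 60*cbv/cbf`` holds
    exactly by construction.
    """

    cbf: np.ndarray    # ml/100g/min
    cbv: np.ndarray    # ml/100g
    mtt: np.ndarray    # s
    tmax: np.ndarray   # s
    valid: np.ndarray  # bool

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"cbf": self.cbf, "cbv": self.cbv,
                "mtt": self.mtt, "tmax": self.tmax}


@dataclass
class CirculantSystem:
    """Block-circulant representation of the AIF convolution operator."""

    matrix: np.ndarray   # (L, L), entry (i,j) = dt * Ca[(i-j) mod L]
    dt: float            # s
    n_frames: int        # un-padded length N; L = pad_factor * N


def build_circulant_system(aif: Aif, n_frames: int | None = None,
                           pad_factor: int = 2) -> CirculantSystem:
    """Circular-convolution matrix of the zero-padded AIF, scaled by dt.

    Entry (i, j) is ``dt * Ca[(i - j) mod L]`` with L = pad_factor * N,
    so each column is the padded AIF circularly shifted by the column
    index and the matrix applied to a padded residue performs the
    rectangle-rule discrete convolution.
    """
    curve = np.asarray(aif.curve, dtype=float)
    n = curve.size if n_frames is None else int(n_frames)
    if curve.size != n:
        raise ValueError("AIF length does not match n_frames")
    if not np.any(curve != 0):
        raise ValueError("all-zero AIF gives a singular system")
    L = pad_factor * n
    padded = np.concatenate([curve, np.zeros(L - n)])
    idx = (np.arange(L)[:, None] - np.arange(L)[None, :]) % L
    return CirculantSystem(matrix=aif.dt * padded[idx], dt=aif.dt, n_frames=n)


def truncated_pinv(system: np.ndarray, threshold: float) -> np.ndarray:
    """SVD pseudo-inverse with singular values < threshold*sigma_max zeroed."""
    u, s, vt = np.linalg.svd(system)
    keep = s >= threshold * s.max()
    inv_s = np.where(keep, 1.0 / np.where(s == 0, 1.0, s), 0.0)
    return (vt.T * inv_s) @ u.T


def osvd_deconvolve(tissue_curve: np.ndarray, system: CirculantSystem,
                    config: DeconvolutionConfig) -> ResidueEstimate:
    """Deconvolve one tissue concentration curve against the AIF system.

    The curve is zero-padded to the system size; the result is the
    flow-scaled residue on the padded axis.
    """
    c = np.asarray(tissue_curve, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("tissue curve contains non-finite values")
    L = system.matrix.shape[0]
    if c.size > L:
        raise ValueError("tissue curve longer than the padded system")
    rhs = np.concatenate([c, np.zeros(L - c.size)])
    pinv = truncated_pinv(system.matrix, config.truncation_threshold)
    return ResidueEstimate(k_curve=pinv @ rhs, dt=system.dt)


def residue_to_parameters(est: ResidueEstimate, config: DeconvolutionConfig,
                          n_frames: int | None = None):
    """Summarise one residue estimate into (cbf, cbv, mtt, tmax).

    Only the first ``n_frames`` samples (the physical, un-padded window)
    enter the maximum and the area.  Returns NaNs when the peak is not
    positive (invalid voxel).
    """
    k = est.k_curve
    dt = est.dt
    if not np.isfinite(dt) or dt <= 0:
        raise ValueError("a positive dt is required")
    n = k.size // 2 if n_frames is None else int(n_frames)
    kn = k[:n]
    cbf_raw = float(kn.max())
    if cbf_raw <= 0:
        return (np.nan, np.nan, np.nan, np.nan)
    i_max = int(np.argmax(kn))          # first maximum on ties
    tmax = i_max * dt
    cbv_raw = float(kn.sum() * dt)
    scale = config.k_h / config.rho
    cbf = cbf_raw * 6000.0 * scale      # 1/s -> ml/100g/min
    cbv = cbv_raw * 100.0 * scale       # fraction -> ml/100g
    mtt = 60.0 * cbv / cbf              # == cbv_raw / cbf_raw, in s
    return (cbf, cbv, mtt, tmax)


def compute_perfusion_maps(conc_series: DynamicSeries, aif: Aif,
                           config: DeconvolutionConfig | None = None,
                           brain_mask: np.ndarray | None = None) -> PerfusionMaps:
    """Voxelwise deconvolution of a concentration series inside a mask.

    The truncated pseudo-inverse is computed once and applied to every
    voxel curve.  Voxels whose residue peak is not positive, or whose
    curve is not finite, are marked invalid (NaN in all four maps).
    """
    if conc_series.kind != "concentration":
        raise ValueError("expected a concentration series")
    if abs(conc_series.dt - aif.dt) > 1e-12:
        raise ValueError("series and AIF must share the frame interval")
    n = conc_series.n_frames
    if aif.curve.size != n:
        raise ValueError("series and AIF must share the frame count")
    config = config or DeconvolutionConfig()
    if brain_mask is None:
        brain_mask = np.ones(conc_series.data.shape[:3], dtype=bool)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("empty brain mask")

    system = build_circulant_system(aif, n, config.pad_factor)
    pinv = truncated_pinv(system.matrix, config.truncation_threshold)
    L = system.matrix.shape[0]

    curves = conc_series.data[brain_mask]            # (M, N)
    finite = np.all(np.isfinite(curves), axis=1)
    rhs = np.zeros((curves.shape[0], L))
    rhs[finite, :n] = curves[finite]
    k_all = rhs @ pinv.T                             # (M, L)
    kn = k_all[:, :n]

    cbf_raw = kn.max(axis=1)
    valid_vox = finite & (cbf_raw > 0)
    i_max = kn.argmax(axis=1)
    dt = conc_series.dt
    scale = config.k_h / config.rho
    cbf = np.where(valid_vox, cbf_raw * 6000.0 * scale, np.nan)
    cbv = np.where(valid_vox, kn.sum(axis=1) * dt * 100.0 * scale, np.nan)
    mtt = np.where(valid_vox, 60.0 * cbv / np.where(cbf > 0, cbf, np.nan), np.nan)
    tmax = np.where(valid_vox, i_max * dt, np.nan)

    shape = conc_series.data.shape[:3]
    maps = {name: np.full(shape, np.nan) for name in ("cbf", "cbv", "mtt", "tmax")}
    for name, vals in zip(maps, (cbf, cbv, mtt, tmax)):
        maps[name][brain_mask] = vals
    valid = np.zeros(shape, dtype=bool)
    valid[brain_mask] = valid_vox
    return PerfusionMaps(valid=valid, **maps)
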