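"""DSC-PWI signal preprocessing: raw signal to contrast concentration.

The bolus passage of a paramagnetic contrast agent shortens T2*, so the
dynamic signal drops below its pre-bolus baseline.  Quantification
proceeds in two conversions:

1. ``dR2*(t) = -(k/TE) * ln(S(t)/S0)`` with proportionality constant
   k = 1 and the echo time TE in ms.
2. tissue: ``C(t) = dR2*(t) / r_tissue`` with r_tissue = 0.044 (1.5 T);
   large vessels (the AIF) instead obey the quadratic relation
   ``dR2* = r*C + q*C^2`` with r = 7.6e-3 and q = 574e-6, inverted in
   closed form per frame.

All relaxivities are kept in ms^-1 units so the standard 1.5 T constants
are used verbatim; curve time axes are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ConversionParams:
    """Signal-to-concentration constants (defaults are the 1.5 T values)."""

    k: float = 1.0            # proportionality constant of the log conversion
    te: float = 45.0          # ms
    r_tissue: float = 0.044   # ms^-1 mM^-1
    r_vessel: float = 7.6e-3  # ms^-1 mM^-1
    q_vessel: float = 574e-6  # ms^-1 mM^-2
    n_baseline: int = 8       # pre-bolus frames averaged into S0

    def __post_init__(self) -> None:
        if self.te <= 0 or self.r_tissue <= 0 or self.q_vessel <= 0:
            raise ValueError("te, r_tissue and q_vessel must be positive")
        if self.n_baseline < 1:
            raise ValueError("n_baseline must be >= 1")


KINDS = ("signal", "delta_r2star", "concentration")
_NEXT_KIND = {"signal": "delta_r2star", "delta_r2star": "concentration"}


@dataclass
class DynamicSeries:
    """A 4-D voxel time-series with acquisition metadata.

    ``kind`` tracks the processing state and may only advance
    signal -> delta_r2star -> concentration.
    """

    data: np.ndarray   # shape (nx, ny, nz, n_frames)
    dt: float          # s
    kind: str = "signal"
    te: float = 45.0   # ms

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("DynamicSeries expects a 4-D array")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kind not in KINDS:
            raise ValueError(f"unknown series kind {self.kind!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    def advanced(self, data: np.ndarray, kind: str) -> "DynamicSeries":
        if _NEXT_KIND.get(self.kind) != kind:
            raise ValueError(f"illegal kind transition {self.kind} -> {kind}")
        return DynamicSeries(data=data, dt=self.dt, kind=kind, te=self.te)


@dataclass
class Aif:
    """Arterial input function: one voxel's concentration curve."""

    voxel: tuple[int, int, int]
    curve: np.ndarray  # mM per frame
    dt: float          # s
    delta_r2star: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.curve = np.asarray(self.curve, dtype=float)
        if not np.all(np.isfinite(self.curve)):
            raise ValueError("AIF curve must be finite")


def estimate_baseline(series: DynamicSeries, n_baseline: int):
    """Per-voxel baseline S0 = mean of the first ``n_baseline`` frames.

    Returns ``(s0, valid)`` where ``valid`` flags voxels with S0 > 0;
    invalid voxels are excluded from every later stage.
    """
    if series.kind != "signal":
        raise ValueError("baseline estimation expects a signal series")
    if n_baseline > series.n_frames:
        raise ValueError("n_baseline exceeds the number of frames")
    if n_baseline < 1:
        raise ValueError("n_baseline must be >= 1")
    s0 = series.data[..., :n_baseline].mean(axis=-1)
    return s0, s0 > 0


def _interpolate_invalid_frames(curves: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Linearly interpolate flagged frames along time, per voxel row."""
    out = curves.copy()
    n = curves.shape[-1]
    t = np.arange(n, dtype=float)
    rows = np.argwhere(bad.any(axis=-1))
    for idx in rows:
        row = tuple(idx)
        good = ~bad[row]
        if good.sum() == 0:
            out[row] = 0.0
            continue
        out[row] = np.interp(t, t[good], curves[row][good])
    return out


def signal_to_delta_r2star(series: DynamicSeries, s0: np.ndarray,
                           params: ConversionParams):
    """Convert signal to dR2*(t) = -(k/TE) ln(S/S0), in ms^-1.

    Frames with S <= 0 or S > 10*S0 (dropouts / spikes) are replaced by
    linear interpolation from their temporal neighbours before the log;
    the affected voxels are flagged.  Voxels with S0 <= 0 come back NaN.

    Returns ``(dr2s_series, flagged)`` where ``flagged`` is a boolean
    volume marking voxels with at least one repaired frame.
    """
    if series.kind != "signal":
        raise ValueError("expected a signal series")
    s0 = np.asarray(s0, dtype=float)
    sig = series.data.astype(float)
    valid0 = s0 > 0
    bad = (sig <= 0) | (sig > 10.0 * s0[..., None])
    flagged = bad.any(axis=-1) & valid0
    if flagged.any():
        sig = _interpolate_invalid_frames(sig, bad & valid0[..., None])
    with np.errstate(divide="ignore", invalid="ignore"):
        dr2s = -(params.k / params.te) * np.log(sig / s0[..., None])
    dr2s[~valid0] = np.nan
    return series.advanced(dr2s, "delta_r2star"), flagged


def delta_r2star_to_concentration(series: DynamicSeries,
                                  params: ConversionParams) -> DynamicSeries:
    """Tissue conversion C(t) = dR2*(t) / r_tissue (mM).

    Negative dR2* from noise passes through unchanged so that curve
    integrals stay unbiased.
    """
    if series.kind != "delta_r2star":
        raise ValueError("expected a delta_r2star series")
    return series.advanced(series.data / params.r_tissue, "concentration")


def correct_aif(aif_delta_r2star: np.ndarray, params: ConversionParams):
    """Invert the large-vessel quadratic dR2* = r*C + q*C^2 per frame.

    Returns ``(concentration, n_clamped)``; negative dR2* values (noise
    below baseline) are clamped to C = 0 and counted.
    """
    d = np.asarray(aif_delta_r2star, dtype=float)
    n_clamped = int(np.sum(d < 0))
    d = np.clip(d, 0.0, None)
    r, q = params.r_vessel, params.q_vessel
    conc = (-r + np.sqrt(r * r + 4.0 * q * d)) / (2.0 * q)
    return conc, n_clamped


class NoBolusError(ValueError):
    """Raised when the selected AIF voxel shows no bolus passage."""


def _voxel_delta_r2star(series: DynamicSeries, voxel, params: ConversionParams):
    curve = series.data[tuple(voxel)].astype(float)
    s0 = curve[:params.n_baseline].mean()
    if s0 <= 0:
        raise NoBolusError(f"voxel {tuple(voxel)} has non-positive baseline")
    c = curve.copy()
    bad = (c <= 0) | (c > 10.0 * s0)
    if bad.any():
        t = np.arange(c.size, dtype=float)
        c = np.interp(t, t[~bad], c[~bad])
    return -(params.k / params.te) * np.log(c / s0)


def _bolus_score(dr2s: np.ndarray, dt: float) -> float:
    """Rank AIF candidates: high peak, early arrival, narrow bolus."""
    peak = np.nanmax(dr2s)
    if peak <= 0:
        return -np.inf
    above = dr2s >= 0.5 * peak
    width = above.sum() * dt
    arrival = float(np.argmax(above)) * dt
    return peak / ((width + dt) * (arrival + dt))


def select_aif(series: DynamicSeries, coordinate,
               params: ConversionParams | None = None,
               min_peak_delta_r2star: float = 5e-3) -> Aif:
    """Extract and correct the arterial input function.

    ``coordinate`` is a 0-based voxel index, or ``"auto"`` to pick the
    highest-scoring candidate (a surrogate for the interactive selection
    next to the contralateral MCA done on patient data).  The voxel curve
    is converted to dR2*, floored at zero, and mapped to concentration
    through the large-vessel quadratic.

    Raises :class:`NoBolusError` when the peak dR2* stays below
    ``min_peak_delta_r2star`` (ms^-1), advising reselection.
    """
    params = params or ConversionParams(te=series.te)
    if isinstance(coordinate, str):
        if coordinate != "auto":
            raise ValueError(f"unknown AIF coordinate {coordinate!r}")
        coordinate = _auto_aif_voxel(series, params)
    coordinate = tuple(int(c) for c in coordinate)
    if any(c < 0 or c >= n for c, n in zip(coordinate, series.data.shape[:3])):
        raise ValueError(f"AIF voxel {coordinate} outside the grid")
    dr2s = _voxel_delta_r2star(series, coordinate, params)
    if np.nanmax(dr2s) < min_peak_delta_r2star:
        raise NoBolusError(
            f"no bolus at voxel {coordinate} (peak dR2* "
            f"{np.nanmax(dr2s):.2e} ms^-1 below {min_peak_delta_r2star:.0e}); "
            "select a different AIF voxel")
    dr2s = np.clip(dr2s, 0.0, None)
    conc, _ = correct_aif(dr2s, params)
    return Aif(voxel=coordinate, curve=conc, dt=series.dt, delta_r2star=dr2s)


def _auto_aif_voxel(series: DynamicSeries, params: ConversionParams):
    s0, valid = estimate_baseline(series, params.n_baseline)
    dr2s_series, _ = signal_to_delta_r2star(series, s0, params)
    best, best_score = None, -np.inf
    for idx in np.argwhere(valid):
        score = _bolus_score(dr2s_series.data[tuple(idx)], series.dt)
        if score > best_score:
            best, best_score = tuple(int(i) for i in idx), score
    if best is None:
        raise NoBolusError("no valid AIF candidate voxel found")
    return best


def signal_to_concentration(series: DynamicSeries,
                            params: ConversionParams | None = None):
    """Full tissue chain: baseline -> dR2* -> concentration.

    Returns ``(conc_series, valid, flagged)``.
    """
    params = params or ConversionParams(te=series.te)
    s0, valid = estimate_baseline(series, params.n_baseline)
    dr2s, flagged = signal_to_delta_r2star(series, s0, params)
    return delta_r2star_to_concentration(dr2s, params), valid, flagged
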