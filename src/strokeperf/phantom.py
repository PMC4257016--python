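"""Digital perfusion/diffusion phantom with known ground truth.

Generates co-registered synthetic DSC-PWI and DWI datasets that emulate a
1.5 T acute-stroke acquisition (TR = 2 s, TE = 45 ms, 90 s bolus passage,
b = 0 / 1000 s/mm^2 in three directions) over a simple two-compartment
lesion geometry: a diffusion-restricted infarct core surrounded by a
hypoperfused penumbra, embedded in normal white/gray matter, plus a
feeding-vessel voxel cluster that carries the arterial input function.

Every voxel class has known CBF, CBV, delay and ADC, so the whole
quantification chain downstream (signal conversion, deconvolution, ADC
mapping, mismatch segmentation) can be validated by parameter recovery.

Forward model
-------------
Tissue concentration follows the indicator-dilution convolution model
``C(t) = F * R(t) (x) Ca(t)`` with ``F`` the blood flow expressed as a
volume fraction per second.  The signal model is the inverse of the
standard DSC conversion: ``S(t) = S0 * exp(-TE * dR2*(t) / k)`` with
``dR2* = r_tissue * C`` for tissue voxels and the quadratic large-vessel
relation ``dR2* = r*C + q*C^2`` for vessel voxels.

The discrete exponential residue uses the geometric decrement
``a = 1 - dt/MTT`` (the backward-Euler discretisation of the
single-compartment washout ODE) rather than a literal sampling of
``exp(-t/MTT)``.  This keeps ``R[0] = 1`` and makes the rectangle-rule
area of the residue exactly MTT, so the discrete forward model satisfies
the central volume theorem without quadrature bias and ground truth is
well defined at any repetition time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

# unit constants shared with the quantification stage (they cancel in
# round-trip tests precisely because both sides use the same values)
BRAIN_DENSITY_G_PER_ML = 1.04
HEMATOCRIT_FACTOR = 0.73

# class-map labels
AIR = 0
NORMAL_WM = 1
NORMAL_GM = 2
CORE = 3
PENUMBRA = 4
VESSEL = 5

CLASS_NAMES = {
    AIR: "air",
    NORMAL_WM: "normal_wm",
    NORMAL_GM: "normal_gm",
    CORE: "core",
    PENUMBRA: "penumbra",
    VESSEL: "vessel",
}


@dataclass(frozen=True)
class GammaVariateParams:
    """Gamma-variate bolus model for the arterial input function.

    The curve is peak-normalised: ``Ca(t) = amplitude * (tau/(alpha*beta))**alpha
    * exp(alpha - tau/beta)`` with ``tau = t - t0``, zero before arrival.
    Its maximum is ``amplitude`` (mM), reached at ``t0 + alpha*beta``.
    """

    amplitude: float = 5.0   # mM, peak concentration
    t0: float = 18.0         # s, bolus arrival
    alpha: float = 2.0       # shape (dimensionless)
    beta: float = 1.0        # s, timescale

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("amplitude, alpha and beta must be positive")


@dataclass(frozen=True)
class TissueClass:
    """Ground-truth perfusion/diffusion parameters of one voxel class."""

    label: str
    cbf_true: float          # ml/100g/min
    cbv_true: float          # ml/100g
    delay_true: float        # s, bolus arrival delay relative to the AIF
    adc_true: float          # mm^2/s
    residue_model: str = "exponential"   # or "boxcar"

    def __post_init__(self) -> None:
        if self.cbf_true < 0 or self.cbv_true < 0:
            raise ValueError("cbf_true and cbv_true must be non-negative")
        if not 0 <= self.adc_true <= 4e-3:
            raise ValueError("adc_true outside the physiological range [0, 4e-3] mm^2/s")
        if self.residue_model not in ("exponential", "boxcar"):
            raise ValueError(f"unknown residue model {self.residue_model!r}")

    @property
    def mtt_true(self) -> float:
        """Mean transit time in seconds via the central volume theorem."""
        if self.cbf_true == 0:
            return float("nan")
        return 60.0 * self.cbv_true / self.cbf_true


# parameter table loosely matched to reported acute-stroke VOI medians:
# a low-ADC, long-delay core; a hypoperfused penumbra with delay > 6 s;
# normal white and gray matter; a vessel cluster carrying the AIF
DEFAULT_TISSUES: dict[int, TissueClass] = {
    NORMAL_WM: TissueClass("normal_wm", cbf_true=22.0, cbv_true=2.2,
                           delay_true=0.0, adc_true=800e-6),
    NORMAL_GM: TissueClass("normal_gm", cbf_true=55.0, cbv_true=3.7,
                           delay_true=0.0, adc_true=850e-6),
    CORE: TissueClass("core", cbf_true=10.9, cbv_true=2.1,
                      delay_true=10.0, adc_true=450e-6),
    PENUMBRA: TissueClass("penumbra", cbf_true=20.7, cbv_true=3.5,
                          delay_true=8.0, adc_true=824e-6),
    VESSEL: TissueClass("vessel", cbf_true=0.0, cbv_true=0.0,
                        delay_true=0.0, adc_true=3000e-6),
}


@dataclass
class PhantomSpec:
    """Full description of one synthetic acquisition."""

    grid_shape: tuple[int, int, int] = (32, 32, 4)
    voxel_size: tuple[float, float, float] = (0.94, 0.94, 5.0)  # mm
    n_frames: int = 45
    tr: float = 2.0          # s
    te: float = 45.0         # ms
    b_values: tuple[float, ...] = (0.0, 1000.0)  # s/mm^2
    aif_params: GammaVariateParams = field(default_factory=GammaVariateParams)
    s0: float = 400.0        # baseline signal, arbitrary units
    noise_sigma: float = 0.0  # signal-unit Gaussian noise sd
    rng_seed: int = 0
    class_map: np.ndarray | None = None
    tissues: dict[int, TissueClass] = field(
        default_factory=lambda: dict(DEFAULT_TISSUES))

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_frames < 2 or self.tr <= 0 or self.te <= 0:
            raise ValueError("invalid acquisition timing")
        if self.class_map is None:
            self.class_map = default_class_map(self.grid_shape)
        self.class_map = np.asarray(self.class_map)
        if tuple(self.class_map.shape) != tuple(self.grid_shape):
            raise ValueError("class_map shape must equal grid_shape")
        # the AIF must have returned to (near) zero inside the acquisition
        support_end = self.aif_params.t0 + self.aif_params.alpha * self.aif_params.beta * 8
        if support_end > self.n_frames * self.tr:
            raise ValueError("acquisition window does not cover the AIF support")

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.tr

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["class_map"] = None  # stored as its own volume, not in the sidecar
        d["tissues"] = {CLASS_NAMES.get(k, str(k)): asdict(v)
                        for k, v in self.tissues.items()}
        return d


def default_class_map(shape: tuple[int, int, int] = (32, 32, 4)) -> np.ndarray:
    """Desk-scale lesion geometry: core ellipsoid inside a penumbra shell,
    a gray-matter slab, a 2x2 vessel cluster, and a 1-voxel air frame in-plane."""
    nx, ny, nz = shape
    cm = np.full(shape, NORMAL_WM, dtype=np.int16)
    cm[0, :, :] = AIR
    cm[-1, :, :] = AIR
    cm[:, 0, :] = AIR
    cm[:, -1, :] = AIR
    # gray-matter slab along one edge of the brain
    cm[1:-1, ny - 7:ny - 1, :] = NORMAL_GM
    # lesion: ellipsoids in voxel-index space, centred mid-volume
    cx, cy, cz = nx * 0.38, ny * 0.45, (nz - 1) / 2.0
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    def ellipsoid(rx, ry, rz):
        return ((ii - cx) / rx) ** 2 + ((jj - cy) / ry) ** 2 + ((kk - cz) / rz) ** 2 <= 1.0
    penumbra = ellipsoid(nx * 0.22, ny * 0.22, max(nz * 0.48, 1.1))
    core = ellipsoid(nx * 0.11, ny * 0.11, max(nz * 0.30, 0.7))
    cm[penumbra & (cm != AIR)] = PENUMBRA
    cm[core & (cm != AIR)] = CORE
    # vessel cluster far from the lesion (mirrors an AIF voxel next to the
    # contralateral MCA)
    vx, vy = nx - 6, 3
    cm[vx:vx + 2, vy:vy + 2, nz // 2] = VESSEL
    return cm


def core_seed(spec: PhantomSpec) -> tuple[int, int, int]:
    """Centroid voxel of the core class (a segmentation seed surrogate)."""
    idx = np.argwhere(spec.class_map == CORE)
    if idx.size == 0:
        raise ValueError("phantom has no core voxels")
    return tuple(int(round(v)) for v in idx.mean(axis=0))


def vessel_voxel(spec: PhantomSpec) -> tuple[int, int, int]:
    idx = np.argwhere(spec.class_map == VESSEL)
    if idx.size == 0:
        raise ValueError("phantom has no vessel voxels")
    return tuple(int(v) for v in idx[0])


def gamma_variate_aif(params: GammaVariateParams,
                      time_grid: np.ndarray) -> np.ndarray:
    """Evaluate the peak-normalised gamma-variate bolus on a uniform grid."""
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be a 1-D array of >= 2 points")
    steps = np.diff(t)
    if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9):
        raise ValueError("time grid must be strictly increasing and uniform")
    tau = t - params.t0
    curve = np.zeros_like(t)
    pos = tau > 0
    x = tau[pos] / (params.alpha * params.beta)
    curve[pos] = params.amplitude * x ** params.alpha * np.exp(
        params.alpha * (1.0 - x))
    return curve


def flow_fraction_per_s(cbf_ml_100g_min: float) -> float:
    """Convert CBF in ml/100g/min to a blood-volume turnover rate in 1/s.

    Uses brain density rho = 1.04 g/ml and the hematocrit correction
    k_H = 0.73; the same constants are applied in reverse by the
    deconvolution stage, so they cancel in recovery experiments.
    """
    return cbf_ml_100g_min * BRAIN_DENSITY_G_PER_ML / (
        100.0 * 60.0 * HEMATOCRIT_FACTOR)


def discrete_residue(tissue: TissueClass, n_frames: int, dt: float) -> np.ndarray:
    """Sampled delayed residue function R(t - delay) on the frame grid.

    ``exponential`` uses the geometric decrement ``a = 1 - dt/MTT`` so that
    ``R[0] = 1`` and ``sum(R) * dt == MTT`` exactly (requires MTT > dt);
    ``boxcar`` is 1 for the first ``round(MTT/dt)`` samples after the delay.
    Delays are rounded to whole frames.
    """
    mtt = tissue.mtt_true
    if not np.isfinite(mtt):
        raise ValueError("residue undefined for zero-flow tissue")
    shift = int(round(tissue.delay_true / dt))
    r = np.zeros(n_frames)
    n_tail = n_frames - shift
    if n_tail <= 0:
        return r
    if tissue.residue_model == "exponential":
        if mtt <= dt:
            raise ValueError(
                f"exponential residue requires MTT > dt (MTT={mtt:.3g}, dt={dt:.3g})")
        a = 1.0 - dt / mtt
        r[shift:] = a ** np.arange(n_tail)
    else:  # boxcar
        width = max(int(round(mtt / dt)), 1)
        r[shift:shift + width] = 1.0
    return r


def tissue_concentration(aif_curve: np.ndarray, tissue: TissueClass,
                         dt: float) -> np.ndarray:
    """Forward convolution C(t) = F * sum_j Ca(j) R(t-j) dt (rectangle rule).

    Zero flow yields an all-zero curve. The rectangle-rule area ratio
    integral(C)/integral(Ca) equals the injected blood-volume fraction
    F * MTT up to tail truncation.
    """
    aif_curve = np.asarray(aif_curve, dtype=float)
    n = aif_curve.size
    if tissue.cbf_true == 0:
        return np.zeros(n)
    f = flow_fraction_per_s(tissue.cbf_true)
    r = discrete_residue(tissue, n, dt)
    return f * dt * np.convolve(aif_curve, r)[:n]


def cbv_fraction(tissue: TissueClass) -> float:
    """Dimensionless blood-volume fraction implied by cbv_true."""
    return tissue.cbv_true * BRAIN_DENSITY_G_PER_ML / (100.0 * HEMATOCRIT_FACTOR)


def _delta_r2star_tissue(conc: np.ndarray, r_tissue: float) -> np.ndarray:
    return r_tissue * conc


def _delta_r2star_vessel(conc: np.ndarray, r: float, q: float) -> np.ndarray:
    return r * conc + q * conc ** 2


def render_pwi(spec: PhantomSpec,
               r_tissue: float = 0.044,
               r_vessel: float = 7.6e-3,
               q_vessel: float = 574e-6):
    """Render the 4-D PWI signal series and the ground-truth perfusion maps.

    Returns ``(signal, truth)`` where ``signal`` has shape
    ``grid_shape + (n_frames,)`` and ``truth`` is a dict with keys
    ``cbf, cbv, mtt, tmax`` (NaN for air and vessel voxels) plus the class
    map and the injected AIF curve.

    Raises ``ValueError`` if any noiseless signal would underflow to zero
    (concentration too high for the signal model).
    """
    from .deconvolution import PerfusionMaps  # local import avoids a cycle

    t = spec.time_grid
    aif = gamma_variate_aif(spec.aif_params, t)
    nx, ny, nz = spec.grid_shape
    signal = np.zeros((nx, ny, nz, spec.n_frames))

    cbf_map = np.full(spec.grid_shape, np.nan)
    cbv_map = np.full(spec.grid_shape, np.nan)
    mtt_map = np.full(spec.grid_shape, np.nan)
    tmax_map = np.full(spec.grid_shape, np.nan)

    for label in np.unique(spec.class_map):
        sel = spec.class_map == label
        if label == AIR:
            continue  # signal stays zero
        tissue = spec.tissues[int(label)]
        if label == VESSEL:
            conc = aif
            dr2s = _delta_r2star_vessel(conc, r_vessel, q_vessel)
        else:
            conc = tissue_concentration(aif, tissue, spec.tr)
            dr2s = _delta_r2star_tissue(conc, r_tissue)
            cbf_map[sel] = tissue.cbf_true
            cbv_map[sel] = tissue.cbv_true
            mtt_map[sel] = tissue.mtt_true if tissue.cbf_true > 0 else np.nan
            # first maximum of the delayed residue sits at the delay frame
            tmax_map[sel] = round(tissue.delay_true / spec.tr) * spec.tr
        s = spec.s0 * np.exp(-spec.te * dr2s)
        if np.any(s <= 0) or np.any(~np.isfinite(s)):
            raise ValueError(
                f"signal underflow for class {CLASS_NAMES.get(int(label))}: "
                "concentration too high for the exponential signal model")
        signal[sel, :] = s

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        signal = signal + rng.normal(0.0, spec.noise_sigma, signal.shape)

    valid = (spec.class_map != AIR) & (spec.class_map != VESSEL)
    truth = PerfusionMaps(cbf=cbf_map, cbv=cbv_map, mtt=mtt_map,
                          tmax=tmax_map, valid=valid)
    return signal, truth


def render_dwi(spec: PhantomSpec, n_directions: int = 3):
    """Render b=0 and three isotropic b=1000 s/mm^2 volumes plus true ADC.

    Returns ``(b0, dirs, adc_true)`` with ``dirs`` of shape
    ``grid_shape + (n_directions,)``.  The phantom is isotropic, so the
    direction volumes differ only by noise.
    """
    if tuple(sorted(spec.b_values)) != (0.0, 1000.0):
        raise ValueError("phantom DWI expects b values {0, 1000} s/mm^2")
    b = max(spec.b_values)
    adc_true = np.full(spec.grid_shape, np.nan)
    b0 = np.zeros(spec.grid_shape)
    for label in np.unique(spec.class_map):
        if label == AIR:
            continue
        sel = spec.class_map == label
        adc_true[sel] = spec.tissues[int(label)].adc_true
        b0[sel] = spec.s0
    att = np.where(np.isnan(adc_true), 0.0, np.exp(-b * np.nan_to_num(adc_true)))
    dirs = np.repeat((b0 * att)[..., None], n_directions, axis=3)
    if spec.noise_sigma > 0:
        # distinct stream from the PWI noise so the two renders are independent
        rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 1]))
        b0 = b0 + rng.normal(0.0, spec.noise_sigma, b0.shape)
        dirs = dirs + rng.normal(0.0, spec.noise_sigma, dirs.shape)
    return b0, dirs, adc_true


def write_phantom(spec: PhantomSpec, out_dir: str | Path) -> dict:
    """Write the rendered phantom to NIfTI files plus a JSON truth sidecar."""
    from . import io as spio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    signal, truth = render_pwi(spec)
    b0, dirs, adc_true = render_dwi(spec)
    paths = {
        "pwi": out / "pwi.nii.gz",
        "b0": out / "dwi_b0.nii.gz",
        "dwi": out / "dwi_b1000.nii.gz",
        "class_map": out / "class_map.nii.gz",
        "adc_true": out / "adc_true.nii.gz",
    }
    spio.save_nifti(signal, spec.voxel_size, paths["pwi"])
    spio.save_nifti(b0, spec.voxel_size, paths["b0"])
    spio.save_nifti(dirs, spec.voxel_size, paths["dwi"])
    spio.save_nifti(spec.class_map.astype(np.int16), spec.voxel_size,
                    paths["class_map"])
    spio.save_nifti(adc_true, spec.voxel_size, paths["adc_true"])
    for name, arr in (("cbf", truth.cbf), ("cbv", truth.cbv),
                      ("mtt", truth.mtt), ("tmax", truth.tmax)):
        p = out / f"{name}_true.nii.gz"
        spio.save_nifti(arr, spec.voxel_size, p)
        paths[f"{name}_true"] = p
    sidecar = {
        "spec": spec.to_jsonable(),
        "aif_voxel": list(vessel_voxel(spec)),
        "core_seed": list(core_seed(spec)),
    }
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))
    return {k: str(v) for k, v in paths.items()}
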