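# Methods

This note documents the models, numerical conventions and design
decisions behind `strokeperf`, in the spirit of a methods appendix: what
is computed, under which assumptions, and what the synthetic validation
does and does not demonstrate.

## Signal model and conversions

DSC-PWI quantification assumes a mono-exponential T2* signal with the
bolus acting only through the relaxivity change:
`S(t) = S0 · exp(−TE · ΔR2*(t) / k)` with `k = 1`. The baseline `S0` is
the mean of the first `n_baseline = 8` frames (the acquisition places at
least 8 pre-bolus frames; the baseline window length is a package
default, configurable). Voxels with `S0 ≤ 0` are excluded. Frames with
`S(t) ≤ 0` or `S(t) > 10·S0` (dropouts/spikes) are repaired by linear
temporal interpolation before the logarithm and the voxel flagged — the
deconvolution input stays finite without inventing signal elsewhere.

Tissue concentration uses the linear relation `ΔR2* = r_tissue·C` with
`r_tissue = 0.044` at 1.5 T; the arterial input function uses the
large-vessel quadratic `ΔR2* = r·C + q·C²` (`r = 7.6×10⁻³`,
`q = 574×10⁻⁶`), inverted in closed form via the non-negative root.
Relaxivities are kept in ms⁻¹·mM⁻¹ (and ms⁻¹·mM⁻² for `q`) so the
standard printed constants are usable verbatim; dimensional analysis of
the conversion equations requires inverse-millisecond units even where
the literature prints "ms × mM⁻¹". Negative tissue ΔR2* from noise is
retained (unbiased curve integrals); negative AIF values are floored at
zero because the quadratic inverse requires `ΔR2* ≥ 0`.

AIF selection is by configured voxel coordinate (the interactive
selection of patient studies has no counterpart on synthetic data) or by
an automatic scorer ranking candidates by peak amplitude divided by
(bolus width × arrival time) — high, early, narrow boluses win. A curve
whose peak ΔR2* stays below 5×10⁻³ ms⁻¹ is rejected as "no bolus".

## Deconvolution

The convolution model is discretised with rectangle (left Riemann) sums
at the frame interval `dt = TR`, matching the forward model of the
phantom. The AIF is zero-padded to `L = 2N` and embedded in a circulant
matrix, making the estimate insensitive to bolus arrival delay (a pure
delay rotates the solution rather than corrupting it). The pseudo-inverse
zeroes singular values below `0.2 × σ_max` — a fixed relative threshold,
with no oscillation-index adaptation. Parameters are read off the first
`N` samples of the recovered flow-scaled residue: peak (CBF), first
argmax (Tmax, ties to the earliest frame for determinism), rectangle-rule
area (CBV), and their ratio (MTT), so the central volume identity
`MTT = 60·CBV/CBF` holds exactly by construction. Absolute units use
brain density ρ = 1.04 g/ml and hematocrit factor k_H = 0.73
(`CBF = k_max · 6000·k_H/ρ`, `CBV = area · 100·k_H/ρ`); the same
constants appear in the phantom's forward scaling, so they cancel in
every recovery experiment — they are conventions, not measurements.

## Phantom

The phantom emulates the target acquisition: TR = 2 s, TE = 45 ms, 45
frames (90 s), 0.94×0.94×5 mm voxels, DWI at b ∈ {0, 1000} s/mm² in
three directions, baseline signal 400 with optional Gaussian noise on
the signal (Rician behaviour is not modelled; the regime is high-SNR).
The default grid is 32×32×4 voxels — desk-scale, chosen so the full
chain runs in well under a second per subject while every class contains
enough voxels for stable medians.

Geometry: an in-plane air frame, white matter bulk, a gray-matter slab,
a diffusion-restricted core ellipsoid (ADC 450×10⁻⁶ mm²/s, delay 10 s)
inside a penumbra shell (ADC 824×10⁻⁶, delay 8 s), and a 2×2 vessel
cluster carrying the AIF through the large-vessel relation. Class
parameters follow acute-stroke VOI medians (core CBF 10.9, CBV 2.1;
penumbra CBF 20.7, CBV 3.5; WM 22/2.2; GM 55/3.7). Both lesion classes
have delay > 6 s so their true Tmax exceeds the hypoperfusion threshold,
and the core ADC sits below the 550×10⁻⁶ segmentation threshold — the
ground-truth maps and the class map are mutually consistent by
construction.

The AIF is a peak-normalised gamma-variate (amplitude 5 mM, arrival
t0 = 18 s giving 9 pre-bolus frames, shape α = 2, timescale β = 1 s —
a compact first-pass bolus of ≈3.4 s FWHM). At the study TR this bolus
gives a circulant spectrum with min/max singular value ≈ 0.34, so the
fixed 0.2 truncation keeps the full spectrum on noiseless data and the
recovery experiments probe the discretisation rather than the
truncation; noisy data still engage the threshold through the
noise-dominated modes.

**Discrete residue calibration.** A naively sampled exponential residue
`exp(−t/MTT)` has rectangle-rule area `dt/(1−e^(−dt/MTT))`, which
overshoots MTT by 37% at MTT = 3 s and TR = 2 s — a pure quadrature bias
that would contaminate ground truth. The phantom therefore uses the
discrete-time exponential with ratio `a = 1 − dt/MTT` (the backward-Euler
solution of the one-compartment washout ODE): `R[0] = 1` and
`Σ R·dt = MTT` exactly, so peak, area and their ratio encode CBF, CBV
and MTT without bias at any TR. This requires `MTT > dt`; the boxcar
alternative (`R = 1` for `t < MTT`) is provided for kernel-level tests.
Residues are delayed by whole frames (delays are rounded to the frame
grid).

What the phantom does **not** emulate: realistic anatomy, partial-volume
mixing, bolus dispersion, recirculation, motion, Rician noise, and any
registration error (PWI and DWI are generated co-registered; the
pipeline asserts grid agreement instead of registering). Passing the
recovery tests therefore demonstrates correctness of the numerics and
the chain's internal consistency — not robustness to those physical
effects.

## Diffusion and segmentation

ADC inverts `S_b = S0·e^(−b·ADC)` using the geometric mean of the three
direction volumes (identically the mean of per-direction ADCs; the
identity is property-tested). Negative ADCs from noise are clamped to 0
and counted; an optional `b0` noise floor is off by default (the phantom
is high-SNR).

Both lesions use one seeded volume-growing engine: connected components
(26-connectivity default; 6 available) of the predicate mask restricted
to components containing a seed. Predicates are strict: `ADC < 550×10⁻⁶
mm²/s` for the core, `Tmax > 6 s` for hypoperfusion (the printed
threshold "550 × 10⁹" in the source literature is dimensionally
impossible; 550×10⁻⁶ mm²/s = 550 µm²/s is the standard acute-stroke
value). Hypoperfusion grows from every DWI-lesion voxel, so disconnected
hypoperfused islands are excluded by design. TAR is the set difference,
guaranteeing disjoint VOIs. No smoothing, CSF exclusion or morphological
post-processing is applied before growing.

## VOI metrics and statistics

Each subject contributes two rows (DWI lesion, TAR) of VOI medians —
medians, not means, because voxelwise parameter distributions are
heavily skewed — plus mask volumes (`voxel count × dx·dy·dz / 1000` ml).
Subjects with an empty TAR keep their lesion row and log a warning.
Group summaries report median and Q1–Q3 with linear-interpolation
(type-7) quartiles.

Each parameter is tested in a two-way ANOVA with factors lesion
compartment and group, including the interaction, on Box–Cox-transformed
values when a Shapiro–Wilk test rejects normality at α = 0.05. The
Box–Cox λ is found by profile-likelihood grid search over [−3, 3] in
steps of 0.01 with bounded golden-section refinement inside the best
cell; non-positive data are shifted by `−min + ε` with the shift
recorded. Balanced designs use the exact cell-mean sum-of-squares
decomposition (`SS_compartment + SS_group + SS_interaction + SS_error =
SS_total`); unbalanced designs (an empty-TAR subject) fall back to
Type-II sums of squares via OLS. Partial η² = SS/(SS+SS_error) is
classified at 0.04/0.25/0.64. The compartment factor is treated as a
between-observations factor — two rows per subject with no
repeated-measures correction, mirroring the analysis style of the
clinical literature this package follows; with subject-level
correlation, compartment p-values would be anti-conservative, which is
why the package reports effect sizes alongside. An omnibus Pillai trace
over all five parameters is reported for context. Baseline group
comparisons dispatch Student's t (interval, normal), Mann–Whitney U
(interval, non-normal) or Fisher's exact test (nominal), all two-sided,
with no multiplicity correction.

The cohort simulators operate at two levels. The table-level generator
draws VOI medians log-normally around compartment-typical values
(log-sd 0.25) for fast calibration studies (type-I error of the group
F-test over 1000 null 16+16 cohorts ≈ 0.05). The imaging-level generator
builds one phantom per subject with between-subject variability composed
of a shared flow–volume factor (log-sd 0.15) plus independent CBV
(0.25) and CBF (0.40) factors — CBF the noisiest, as in acute-stroke
cohorts — and a multiplicative CBV elevation (default ×1.3) in the
stenosis-like group with CBF matched, emulating collateral-recruitment
blood-volume increase. MTT is clamped to (2.5, 18) s to keep the
discrete residue valid and tail truncation negligible. With these
settings the end-to-end 16+16 pipeline run ranks CBV as the largest
group partial η² (≈0.1–0.3 across seeds) with all other group effects
negligible-to-small.

## Numerical conventions and degenerate inputs

- All curve time axes are in seconds; TE and relaxivities in ms units.
- Determinism: every stochastic component takes a seed; identical
  spec + seed renders bit-identical phantoms, and subject manifests
  (SHA-256 of artifacts) are reproducible.
- Degenerate inputs fail loudly: all-zero AIF (singular system),
  non-finite curves, empty seed sets, empty brain masks, constant
  Box–Cox input, empty ANOVA cells (named in the error). Zero-flow
  tissue renders as a zero curve, not an error; a non-positive residue
  peak marks the voxel invalid (NaN in all maps).
- Tmax ties break to the earliest frame; Tmax, CBF and CBV are measured
  on the first N (physical) samples of the padded solution.

## Known limitations

- No leakage (K2) correction, no oscillation-index adaptive truncation,
  no Tikhonov/Bayesian deconvolution variants.
- No PWI→DWI registration (co-registered inputs are assumed and
  asserted); no partial-volume correction of the AIF beyond the
  quadratic relation.
- Absolute CBF/CBV depend on the conventional ρ and k_H constants and on
  the AIF; across-study comparability of absolute values is limited, as
  usual for DSC-MRI.
- The statistics stage models rows as independent observations (see
  above); a mixed-effects extension is out of scope.
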