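# strokeperf

Quantitative perfusion- and diffusion-MRI analysis for acute ischemic
stroke, built as a reusable Python library with a thin command-line
interface and a digital phantom for validation.

The package targets researchers who quantify dynamic susceptibility
contrast (DSC) PWI and diffusion-weighted MRI in stroke cohorts: it
converts raw bolus-passage signal to contrast concentration, solves the
indicator-dilution model per voxel by block-circulant truncated singular
value decomposition, maps the apparent diffusion coefficient, segments
the infarct core and the perfusion–diffusion mismatch (tissue at risk),
and runs the region × group effect-size statistics on the resulting VOI
medians. Because clinical stroke data cannot be redistributed, a
synthetic phantom with known ground truth exercises every stage, so the
whole chain is testable by parameter recovery.

## Model

Signal is converted to relaxivity change and concentration by

    ΔR2*(t) = −(k/TE) · ln(S(t)/S0),        k = 1
    ΔR2*(t) = r_tissue · C(t),              r_tissue = 0.044 ms⁻¹·mM⁻¹ (1.5 T)

with the large-vessel (arterial input) relation inverted per frame:

    ΔR2*(t) = r·C(t) + q·C(t)²,             r = 7.6×10⁻³, q = 574×10⁻⁶

Per voxel, the tissue curve obeys the convolution model

    C(t) = CBF · R(t) ⊗ C_a(t)

solved for the flow-scaled residue k(t) = CBF·R(t) with a block-circulant
system matrix (zero-padding to 2N, delay-insensitive) and a truncated SVD
pseudo-inverse at the fixed relative threshold 0.2. Parameters follow as
CBF = max k(t), Tmax = argmax k(t), CBV = ∫k(t)dt, and MTT = CBV/CBF
(central volume theorem). ADC comes from the Stejskal–Tanner decay
S_b = S₀·e^(−b·ADC) over b ∈ {0, 1000} s/mm² in three directions.

The DWI lesion is grown from seed voxels with a fixed upper ADC threshold
of 550×10⁻⁶ mm²/s; hypoperfusion is grown from the lesion with Tmax > 6 s;
tissue at risk (TAR) is their set difference. Per-VOI medians feed a
Box–Cox-normalised two-way ANOVA (lesion compartment × group) with
partial η² = SS_effect/(SS_effect+SS_error), labelled
small/moderate/large at 0.04/0.25/0.64.

## Worked example

`examples/02_perfusion_maps.py` renders a noiseless phantom, picks the
arterial input function at the vessel voxel, and deconvolves:

```
class         CBF est/true    CBV est/true    MTT est/true   Tmax est/true
normal_wm    22.00/22.00      2.20/2.20       6.00/6.00       0.00/0.00
normal_gm    55.00/55.00      3.70/3.70       4.04/4.04       0.00/0.00
core         10.90/10.90      2.09/2.10      11.52/11.56     10.00/10.00
penumbra     20.70/20.70      3.50/3.50      10.13/10.14      8.00/8.00
```

CBF (ml/100g/min) and Tmax (s) are recovered exactly; CBV (ml/100g) and
MTT (s) deviate below 0.5% from tail truncation of the 90 s window for
long-transit-time tissue. The lesion classes carry bolus delays of 8–10 s,
so their Tmax exceeds the 6 s hypoperfusion threshold while normal tissue
stays at 0 — exactly the contrast the mismatch segmentation uses.

`examples/04_cohort_statistics.py` simulates the study-scale cohort
(16 + 16 subjects, a stenosis-like CBV elevation in the second group) and
prints the effect-size table; CBV carries the largest group partial η²
(0.27 at seed 1) while ADC/Tmax/CBF group effects stay negligible-to-small.

The other examples cover the concentration round trip (01) and the
mismatch segmentation with VOI medians (03). The CLI mirrors the same
stages:

```sh
strokeperf phantom  --config spec.yaml --out phantom/ --seed 1
strokeperf quantify --config run.yaml  --out subject01/
strokeperf cohort   --config cohort.yaml --out cohort/
strokeperf stats    --cohort cohort/cohort.csv --out cohort/
```

## Layout

- `src/strokeperf/phantom.py` — synthetic PWI/DWI generator with ground truth
- `src/strokeperf/preprocess.py` — signal → ΔR2* → concentration, AIF handling
- `src/strokeperf/deconvolution.py` — block-circulant truncated SVD, parameter maps
- `src/strokeperf/diffusion.py` — ADC mapping
- `src/strokeperf/segmentation.py` — seeded volume growing, mismatch masks
- `src/strokeperf/voi.py` — VOI medians, cohort table
- `src/strokeperf/stats.py` — Box–Cox, two-way ANOVA/η², group tests
- `src/strokeperf/pipeline.py`, `cli.py` — orchestration and subcommands
- `docs/methods.md` — modelling choices, defaults and limitations
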