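"""Block-circulant truncated-SVD deconvolution and parameter maps."""

import numpy as np
import pytest

import strokeperf.phantom as ph
from strokeperf.deconvolution import (DeconvolutionConfig, ResidueEstimate,
                                      build_circulant_system,
                                      compute_perfusion_maps,
                                      osvd_deconvolve, residue_to_parameters,
                                      truncated_pinv)
from strokeperf.preprocess import Aif, ConversionParams, DynamicSeries, \
    signal_to_concentration


def _aif(curve, dt=1.0):
    return Aif(voxel=(0, 0, 0), curve=np.asarray(curve, float), dt=dt)


def fft_truncated_solve(aif_curve, dt, tissue_curve, threshold):
    """Independent oracle: diagonalise the circulant operator by FFT.

    A circulant matrix is normal with eigenvalues FFT(first column); its
    truncated SVD pseudo-inverse equals inverting the eigenvalues whose
    magnitude reaches ``threshold * max|eigenvalue|`` and zeroing the rest.
    """
    n = len(aif_curve)
    L = 2 * n
    lam = np.fft.fft(np.concatenate([aif_curve, np.zeros(n)])) * dt
    mag = np.abs(lam)
    keep = mag >= threshold * mag.max()
    inv = np.where(keep, 1.0 / np.where(lam == 0, 1.0, lam), 0.0)
    rhs = np.fft.fft(np.concatenate([tissue_curve, np.zeros(L - len(tissue_curve))]))
    return np.real(np.fft.ifft(inv * rhs))


class TestCirculantSystem:
    def test_impulse_aif_gives_scaled_identity(self):
        sys = build_circulant_system(_aif([1.0, 0, 0, 0], dt=2.0))
        np.testing.assert_allclose(sys.matrix, 2.0 * np.eye(8), atol=1e-15)

    def test_structure_depends_only_on_index_difference(self):
        rng = np.random.default_rng(3)
        sys = build_circulant_system(_aif(rng.random(6), dt=1.5))
        L = sys.matrix.shape[0]
        for i in range(L):
            for j in range(L):
                assert sys.matrix[i, j] == sys.matrix[(i + 1) % L, (j + 1) % L]

    def test_impulse_singular_values_all_dt(self):
        sys = build_circulant_system(_aif([1.0, 0, 0], dt=2.0))
        s = np.linalg.svd(sys.matrix, compute_uv=False)
        np.testing.assert_allclose(s, 2.0, rtol=1e-12)

    def test_all_zero_aif_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            build_circulant_system(_aif([0.0, 0.0, 0.0]))


class TestOsvdDeconvolve:
    def test_zero_tissue_gives_zero_residue(self):
        sys = build_circulant_system(_aif([1.0, 2.0, 1.0]))
        est = osvd_deconvolve(np.zeros(3), sys, DeconvolutionConfig())
        np.testing.assert_array_equal(est.k_curve, 0.0)

    def test_scaled_aif_area_ratio(self):
        # tissue = 0.5*AIF: the recovered residue area integrates to 0.5
        t = np.arange(45) * 2.0
        ca = ph.gamma_variate_aif(ph.GammaVariateParams(), t)
        sys = build_circulant_system(_aif(ca, dt=2.0))
        est = osvd_deconvolve(0.5 * ca, sys, DeconvolutionConfig())
        assert est.k_curve.sum() * 2.0 == pytest.approx(0.5, rel=0.01)

    def test_delay_shifts_argmax_exactly(self):
        t = np.arange(45) * 2.0
        ca = ph.gamma_variate_aif(ph.GammaVariateParams(), t)
        sys = build_circulant_system(_aif(ca, dt=2.0))
        cfg = DeconvolutionConfig()
        tissue = ph.tissue_concentration(
            ca, ph.TissueClass("x", 30.0, 3.0, 0.0, 800e-6), 2.0)
        base = np.argmax(osvd_deconvolve(tissue, sys, cfg).k_curve[:45])
        for shift in (1, 2, 3):
            delayed = np.concatenate([np.zeros(shift), tissue[:-shift]])
            est = osvd_deconvolve(delayed, sys, cfg)
            assert np.argmax(est.k_curve[:45]) == base + shift

    @pytest.mark.parametrize("n", [4, 6, 8])
    @pytest.mark.parametrize("threshold", [0.1, 0.2, 0.5])
    def test_matches_fft_diagonalization_oracle(self, n, threshold, rng):
        # truncated SVD pseudo-inverse == spectral truncation of the
        # circulant eigenvalues, elementwise
        for trial in range(5):
            ca = rng.random(n) + 0.1
            tissue = rng.random(n)
            sys = build_circulant_system(_aif(ca, dt=1.3))
            est = osvd_deconvolve(tissue, sys,
                                  DeconvolutionConfig(truncation_threshold=threshold))
            oracle = fft_truncated_solve(ca, 1.3, tissue, threshold)
            np.testing.assert_allclose(est.k_curve, oracle, atol=1e-8)

    def test_nonfinite_input_rejected(self):
        sys = build_circulant_system(_aif([1.0, 2.0, 1.0]))
        with pytest.raises(ValueError, match="finite"):
            osvd_deconvolve(np.array([1.0, np.nan, 0.0]), sys,
                            DeconvolutionConfig())

    def test_raising_threshold_never_increases_oscillation(self):
        t = np.arange(45) * 2.0
        ca = ph.gamma_variate_aif(ph.GammaVariateParams(), t)
        sys = build_circulant_system(_aif(ca, dt=2.0))
        tissue = ph.tissue_concentration(
            ca, ph.TissueClass("x", 30.0, 1.5, 4.0, 800e-6), 2.0)
        rng = np.random.default_rng(5)
        noisy = tissue + rng.normal(0, 0.01, tissue.size)
        tv_prev = np.inf
        for thr in (0.05, 0.1, 0.2, 0.4):
            est = osvd_deconvolve(noisy, sys,
                                  DeconvolutionConfig(truncation_threshold=thr))
            tv = np.abs(np.diff(est.k_curve)).sum()
            assert tv <= tv_prev + 1e-12
            tv_prev = tv


class TestResidueToParameters:
    def test_hand_rectangle_example(self):
        k = np.zeros(10)
        k[:5] = [0.0, 2.0, 1.0, 0.5, 0.0]
        est = ResidueEstimate(k_curve=k, dt=1.0)
        cfg = DeconvolutionConfig()
        cbf, cbv, mtt, tmax = residue_to_parameters(est, cfg, n_frames=5)
        scale = cfg.k_h / cfg.rho
        assert cbf == pytest.approx(2.0 * 6000.0 * scale)
        assert cbv == pytest.approx(3.5 * 100.0 * scale)
        assert mtt == pytest.approx(3.5 / 2.0)
        assert tmax == 1.0

    def test_all_zero_curve_is_invalid_voxel(self):
        est = ResidueEstimate(k_curve=np.zeros(8), dt=1.0)
        out = residue_to_parameters(est, DeconvolutionConfig())
        assert all(np.isnan(v) for v in out)

    def test_tmax_tie_breaks_to_earliest_frame(self):
        est = ResidueEstimate(k_curve=np.array([0.0, 1.0, 1.0, 0.0]), dt=2.0)
        *_, tmax = residue_to_parameters(est, DeconvolutionConfig(), n_frames=4)
        assert tmax == 2.0

    @pytest.mark.parametrize("mtt", [3.0, 6.0, 12.0])
    @pytest.mark.parametrize("delay", [0.0, 2.0, 4.0, 6.0])
    def test_parameter_recovery_noiseless(self, mtt, delay):
        # CBV within 5%, MTT within 15%, Tmax at the injected delay
        t = np.arange(45) * 2.0
        ca = ph.gamma_variate_aif(ph.GammaVariateParams(), t)
        cbf = 30.0
        tissue_class = ph.TissueClass("x", cbf, cbf * mtt / 60.0, delay,
                                      800e-6)
        tissue = ph.tissue_concentration(ca, tissue_class, 2.0)
        sys = build_circulant_system(_aif(ca, dt=2.0))
        cfg = DeconvolutionConfig()
        est = osvd_deconvolve(tissue, sys, cfg)
        cbf_e, cbv_e, mtt_e, tmax_e = residue_to_parameters(est, cfg,
                                                            n_frames=45)
        assert cbv_e == pytest.approx(tissue_class.cbv_true, rel=0.05)
        assert mtt_e == pytest.approx(mtt, rel=0.15)
        assert tmax_e == pytest.approx(delay, abs=1e-9)

    def test_delay_leaves_cbv_and_cbf_within_two_percent(self):
        t = np.arange(45) * 2.0
        ca = ph.gamma_variate_aif(ph.GammaVariateParams(), t)
        sys = build_circulant_system(_aif(ca, dt=2.0))
        cfg = DeconvolutionConfig()
        ref = None
        for delay in (0.0, 2.0, 4.0, 6.0):
            tc = ph.TissueClass("x", 30.0, 3.0, delay, 800e-6)
            est = osvd_deconvolve(ph.tissue_concentration(ca, tc, 2.0),
                                  sys, cfg)
            cbf_e, cbv_e, *_ = residue_to_parameters(est, cfg, n_frames=45)
            if ref is None:
                ref = (cbf_e, cbv_e)
            assert cbf_e == pytest.approx(ref[0], rel=0.02)
            assert cbv_e == pytest.approx(ref[1], rel=0.02)


@pytest.fixture(scope="module")
def maps_and_truth(noiseless_spec, noiseless_series):
    conc, valid, _ = signal_to_concentration(
        noiseless_series, ConversionParams(te=noiseless_spec.te))
    from strokeperf.preprocess import select_aif
    aif = select_aif(noiseless_series, ph.vessel_voxel(noiseless_spec))
    _, truth = ph.render_pwi(noiseless_spec)
    maps = compute_perfusion_maps(conc, aif, brain_mask=truth.valid)
    return maps, truth, noiseless_spec


class TestPerfusionMaps:
    def test_spatial_homogeneity_within_classes(self, maps_and_truth):
        maps, _, spec = maps_and_truth
        for label in (ph.NORMAL_WM, ph.NORMAL_GM, ph.CORE, ph.PENUMBRA):
            sel = spec.class_map == label
            for name, arr in maps.as_dict().items():
                vals = arr[sel]
                spread = np.nanstd(vals) / max(abs(np.nanmean(vals)), 1e-12)
                assert spread < 1e-6, (name, label)

    def test_class_cbv_ratio_recovered(self, maps_and_truth):
        maps, _, spec = maps_and_truth
        # GM/WM blood-volume ratio 3.7/2.2 recovered within 5%
        gm = np.nanmedian(maps.cbv[spec.class_map == ph.NORMAL_GM])
        wm = np.nanmedian(maps.cbv[spec.class_map == ph.NORMAL_WM])
        true_ratio = (spec.tissues[ph.NORMAL_GM].cbv_true
                      / spec.tissues[ph.NORMAL_WM].cbv_true)
        assert gm / wm == pytest.approx(true_ratio, rel=0.05)

    def test_central_volume_identity_exact(self, maps_and_truth):
        maps, _, _ = maps_and_truth
        ok = maps.valid
        np.testing.assert_allclose(maps.mtt[ok],
                                   60.0 * maps.cbv[ok] / maps.cbf[ok],
                                   rtol=1e-12)

    def test_truth_recovered_per_class(self, maps_and_truth):
        maps, truth, spec = maps_and_truth
        ok = maps.valid
        np.testing.assert_allclose(maps.cbf[ok], truth.cbf[ok], rtol=1e-6)
        np.testing.assert_allclose(maps.cbv[ok], truth.cbv[ok], rtol=0.01)
        np.testing.assert_allclose(maps.tmax[ok], truth.tmax[ok], atol=1e-9)

    def test_empty_mask_rejected(self, noiseless_series, noiseless_spec):
        conc, *_ = signal_to_concentration(noiseless_series)
        from strokeperf.preprocess import select_aif
        aif = select_aif(noiseless_series, ph.vessel_voxel(noiseless_spec))
        with pytest.raises(ValueError, match="mask"):
            compute_perfusion_maps(conc, aif,
                                   brain_mask=np.zeros(conc.data.shape[:3],
                                                       bool))
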