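import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from dscquant import leakage_cbv as lk
from dscquant.bolus_detection import BolusTiming
from dscquant.concentration import ConcentrationSeries
from dscquant.errors import FitError, MaskError
from dscquant.synthetic_phantom import (
    CLASS_GM,
    CLASS_TUMOR,
    CLASS_WM,
    PhantomSpec,
    gamma_variate,
    generate_phantom,
)


def _timing(entrance=8, trough=11, exit_=15):
    return BolusTiming(n_discarded=3, baseline_window=(0, entrance - 1),
                       entrance=entrance, trough=trough, exit=exit_)


def _conc_from_curves(curves, frame_spacing=2.2, timing=None):
    """Build a ConcentrationSeries from a (t, n) matrix of voxel curves."""
    curves = np.asarray(curves, float)
    t, n = curves.shape
    delta = curves.reshape(t, 1, 1, n)
    return ConcentrationSeries(
        delta_r2s=delta,
        s_base=np.full((1, 1, n), 200.0),
        timing=timing or _timing(),
        frame_spacing=frame_spacing,
        te=60.0,
        mask=np.ones((1, 1, n), bool),
    )


class TestReferenceCurve:
    def test_shared_curve_is_reference(self):
        t = np.arange(37) * 2.2
        g = gamma_variate(t, 18.0, 3.0, 1.5)
        conc = _conc_from_curves(np.tile(g[:, None], (1, 5)))
        model = lk.build_reference_curve(conc, np.ones((1, 1, 5), bool))
        np.testing.assert_allclose(model.reference_curve, g)

    def test_cumulative_of_constant(self):
        n, dt, c = 37, 2.2, 0.004
        conc = _conc_from_curves(np.full((n, 3), c), frame_spacing=dt)
        model = lk.build_reference_curve(conc, np.ones((1, 1, 3), bool))
        assert model.cumulative_reference[-1] == pytest.approx(c * dt * (n - 1))

    def test_cumulative_gamma_matches_fine_quadrature(self):
        dt = 2.2
        t = np.arange(37) * dt
        g = gamma_variate(t, 18.0, 3.0, 1.5)
        conc = _conc_from_curves(g[:, None], frame_spacing=dt)
        model = lk.build_reference_curve(conc, np.ones((1, 1, 1), bool))
        t_fine = np.linspace(0, t[-1], 37_000)
        fine = np.trapezoid(gamma_variate(t_fine, 18.0, 3.0, 1.5), t_fine)
        assert model.cumulative_reference[-1] == pytest.approx(fine, rel=0.01)

    def test_empty_mask_raises(self):
        conc = _conc_from_curves(np.ones((37, 2)))
        with pytest.raises(MaskError):
            lk.build_reference_curve(conc, np.zeros((1, 1, 2), bool))


class TestFitLeakage:
    def _reference_conc(self, n_extra=0, k1=None, k2=None, noise=0.0, seed=0):
        """Voxels 0..4 share the reference curve; extras are leaky variants."""
        rng = np.random.default_rng(seed)
        dt = 2.2
        t = np.arange(37) * dt
        g = 0.01 * gamma_variate(t, 18.0, 3.0, 1.5) / gamma_variate(
            t, 18.0, 3.0, 1.5).max()
        cum = cumulative_trapezoid(g, dx=dt, initial=0.0)
        cols = [g] * 5
        for _ in range(n_extra):
            cols.append(k1 * g - k2 * cum + rng.normal(0, noise, size=g.size))
        conc = _conc_from_curves(np.column_stack(cols), frame_spacing=dt)
        return conc, g, cum

    def test_exact_representation_k1_one_k2_zero(self):
        conc, _, _ = self._reference_conc()
        model = lk.build_reference_curve(conc, np.ones((1, 1, 5), bool))
        model = lk.fit_leakage(conc, model)
        np.testing.assert_allclose(model.k1_map, 1.0, atol=1e-12)
        np.testing.assert_allclose(model.k2_map, 0.0, atol=1e-12)

    def test_generative_recovery_within_three_se(self):
        k1, k2, sigma = 0.8, 0.01, 2e-5
        conc, g, cum = self._reference_conc(n_extra=1, k1=k1, k2=k2,
                                            noise=sigma, seed=11)
        mask_ref = np.zeros((1, 1, 6), bool)
        mask_ref[0, 0, :5] = True
        model = lk.fit_leakage(conc, lk.build_reference_curve(conc, mask_ref))
        # OLS standard errors from the design on the fit window
        t0 = conc.timing.entrance
        X = np.column_stack([g[t0:], -cum[t0:]])
        resid = conc.delta_r2s[t0:, 0, 0, 5] - X @ [
            model.k1_map[0, 0, 5], model.k2_map[0, 0, 5]]
        s2 = resid @ resid / (X.shape[0] - 2)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert abs(model.k1_map[0, 0, 5] - k1) <= 3 * se[0]
        assert abs(model.k2_map[0, 0, 5] - k2) <= 3 * se[1]

    def test_zero_k2_correction_is_identity(self):
        conc, _, _ = self._reference_conc()
        model = lk.build_reference_curve(conc, np.ones((1, 1, 5), bool))
        model = lk.fit_leakage(conc, model)
        corrected = lk.corrected_curves(conc, model)
        np.testing.assert_allclose(corrected, conc.delta_r2s, atol=1e-12)

    def test_zero_reference_raises(self):
        conc = _conc_from_curves(np.zeros((37, 5)))
        model = lk.LeakageModel(reference_curve=np.zeros(37),
                                cumulative_reference=np.zeros(37))
        with pytest.raises(FitError):
            lk.fit_leakage(conc, model)

    def test_noiseless_phantom_recovery_exact(self):
        series, truth = generate_phantom(
            PhantomSpec(noise_sd=0.0, tumor_k1=0.8, tumor_k2=0.01))
        from dscquant import bolus_detection as bd
        from dscquant import concentration as cc

        trimmed, timing = bd.detect_bolus(series)
        conc = cc.to_concentration(trimmed, cc.baseline_map(trimmed, timing),
                                   timing)
        nonenh = (truth.class_labels == CLASS_WM) | (truth.class_labels == CLASS_GM)
        model = lk.fit_leakage(conc, lk.build_reference_curve(conc, nonenh))
        tumor = truth.class_labels == CLASS_TUMOR
        assert np.nanmax(np.abs(model.k1_map[tumor] - 0.8)) < 1e-10
        assert np.nanmax(np.abs(model.k2_map[tumor] - 0.01)) < 1e-10


class TestIntegrateCbv:
    def test_triangle_area(self):
        k, h, dt = 6, 0.01, 2.2
        tri = np.concatenate([np.linspace(0, h, k + 1),
                              np.linspace(h, 0, k + 1)[1:]])
        curve = np.zeros(37)
        curve[8 : 8 + 2 * k + 1] = tri
        conc = _conc_from_curves(curve[:, None], frame_spacing=dt,
                                 timing=_timing(entrance=8, trough=8 + k,
                                                exit_=8 + 2 * k))
        maps = lk.integrate_cbv(conc, None, conc.timing)
        assert maps.cbv_uncorrected[0, 0, 0] == pytest.approx(h * k * dt)

    def test_noiseless_ratio_three_within_two_percent(self, noiseless_phantom,
                                                      noiseless_conc):
        _, truth = noiseless_phantom
        _, timing, conc = noiseless_conc
        maps = lk.integrate_cbv(conc, None, timing)
        wm = truth.class_labels == CLASS_WM
        tm = truth.class_labels == CLASS_TUMOR
        ratio = np.nanmean(maps.cbv_uncorrected[tm]) / np.nanmean(
            maps.cbv_uncorrected[wm])
        assert ratio == pytest.approx(3.0, rel=0.02)

    def test_zero_k2_maps_identical(self, noiseless_conc):
        _, timing, conc = noiseless_conc
        ref = lk.build_reference_curve(conc, conc.mask)
        model = lk.LeakageModel(
            reference_curve=ref.reference_curve,
            cumulative_reference=ref.cumulative_reference,
            k1_map=np.ones(conc.spatial_shape),
            k2_map=np.zeros(conc.spatial_shape),
        )
        maps = lk.integrate_cbv(conc, model, timing)
        np.testing.assert_allclose(maps.cbv_corrected, maps.cbv_uncorrected,
                                   atol=1e-14, equal_nan=True)

    def test_cbv_scales_linearly_with_concentration(self, noiseless_conc):
        _, timing, conc = noiseless_conc
        maps1 = lk.integrate_cbv(conc, None, timing)
        scaled = ConcentrationSeries(
            delta_r2s=conc.delta_r2s * 2.5, s_base=conc.s_base, timing=timing,
            frame_spacing=conc.frame_spacing, te=conc.te, mask=conc.mask)
        maps2 = lk.integrate_cbv(scaled, None, timing)
        np.testing.assert_allclose(maps2.cbv_uncorrected,
                                   2.5 * maps1.cbv_uncorrected,
                                   rtol=1e-12, equal_nan=True)

    def test_widening_bounds_never_decreases_nonneg_integral(self):
        t = np.arange(37) * 2.2
        curve = gamma_variate(t, 18.0, 3.0, 1.5)
        dt = 2.2
        areas = [np.trapezoid(curve[8 - w : 16 + w], dx=dt) for w in range(0, 8)]
        assert np.all(np.diff(areas) >= 0)

    def test_corrected_beats_uncorrected_on_leaky_voxels(self, default_phantom):
        series, truth = default_phantom
        from dscquant import bolus_detection as bd
        from dscquant import concentration as cc

        trimmed, timing = bd.detect_bolus(series)
        conc = cc.to_concentration(trimmed, cc.baseline_map(trimmed, timing),
                                   timing)
        tumor = truth.class_labels == CLASS_TUMOR
        model = lk.fit_leakage(
            conc, lk.build_reference_curve(conc, lk.nonenhancing_mask(
                conc, tumor_mask=tumor)))
        maps = lk.integrate_cbv(conc, model, timing)
        # ground truth: integral of the non-leaky tumor curve on these bounds
        ideal = 3.0 * truth.unit_curve
        truth_cbv = np.trapezoid(ideal[timing.entrance : timing.exit + 1],
                                 dx=series.frame_spacing)
        err_corr = np.abs(maps.cbv_corrected[tumor] - truth_cbv)
        err_unc = np.abs(maps.cbv_uncorrected[tumor] - truth_cbv)
        assert np.mean(err_corr < err_unc) >= 0.95


class TestNonenhancingMask:
    def test_phantom_classes_separated(self, noisy_conc, default_phantom):
        _, truth = default_phantom
        _, _, conc = noisy_conc
        ne = lk.nonenhancing_mask(conc)
        assert ne[truth.class_labels == CLASS_WM].mean() > 0.95
        assert ne[truth.class_labels == CLASS_GM].mean() > 0.95
        assert ne[truth.class_labels == CLASS_TUMOR].mean() < 0.05

    def test_tumor_mask_always_excluded(self, noisy_conc, default_phantom):
        _, truth = default_phantom
        _, _, conc = noisy_conc
        tumor = truth.class_labels == CLASS_TUMOR
        ne = lk.nonenhancing_mask(conc, tumor_mask=tumor)
        assert not (ne & tumor).any()
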