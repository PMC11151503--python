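"""Phasor transform, calibration, lifetime estimators and the bi-exp fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from stromascope.core import DecayHistogram
from stromascope.phasor import (
    BiExpFit,
    apply_calibration,
    build_calibration,
    fit_biexponential,
    mean_lifetime,
    metabolic_index,
    mono_lifetime,
    mono_phasor,
    phasor_transform,
    per_cell_flim,
)
from stromascope.simulate import (
    CellSpec,
    DecaySimSpec,
    SceneSpec,
    simulate_decay,
    simulate_flim_image,
)

OMEGA1 = 2 * np.pi / 50.0


def _mono(tau, n_bins=256, photons=1e6):
    return simulate_decay(
        DecaySimSpec([tau], [1.0], total_photons=photons, n_bins=n_bins)
    )


class TestTransform:
    def test_delta_decay_maps_to_unit_phasor(self):
        counts = np.zeros(256)
        counts[0] = 1000.0
        p = phasor_transform(DecayHistogram(counts), [1])[0]
        # all photons in the first bin: (g, s) -> (1, 0) up to the half-bin lag
        assert p.g == pytest.approx(1.0, abs=1e-3)
        assert p.s == pytest.approx(0.0, abs=2e-2)
        assert p.phi == pytest.approx(OMEGA1 * 50 / 512, abs=1e-9)  # half-bin

    def test_uniform_counts_map_to_origin(self):
        p = phasor_transform(DecayHistogram(np.ones(256)), [1, 2, 3])[0]
        assert abs(p.g) < 1e-9 and abs(p.s) < 1e-9

    def test_empty_histogram_raises_naming_origin(self):
        with pytest.raises(ValueError, match="px7"):
            phasor_transform(DecayHistogram(np.zeros(8), origin="px7"), [1])

    def test_modulation_and_phase_consistent_with_g_s(self):
        p = phasor_transform(_mono(2.0), [3])[0]
        assert p.m == pytest.approx(np.hypot(p.g, p.s), abs=1e-12)
        assert p.phi == pytest.approx(np.arctan2(p.s, p.g), abs=1e-12)


class TestCalibration:
    def test_theoretical_reference_phasor_closed_form(self):
        # tau_ref = 3.6 ns at the 20 MHz fundamental; values verified by
        # brute-force numerical integration of the continuous transform:
        # m = hypot(0.8301, 0.3755) = 0.9111, phi = atan(w tau) = 0.4249
        g, s = mono_phasor(3.6, OMEGA1)
        assert np.hypot(g, s) == pytest.approx(0.91110, abs=1e-4)
        assert np.arctan2(s, g) == pytest.approx(0.42487, abs=1e-4)

    def test_self_calibration_is_near_identity_for_ideal_reference(
        self, ideal_calibration
    ):
        # the residual is the binning distortion, growing as (w_k dt)^2/24:
        # ~2.5e-5 at harmonic 1, ~1.6e-3 at harmonic 8 (256 bins)
        for k in ideal_calibration.harmonics:
            tol = 1e-3 if k <= 5 else 2.5e-3
            assert ideal_calibration.scale[k] == pytest.approx(1.0, abs=tol)
            assert ideal_calibration.offset[k] == pytest.approx(0.0, abs=tol)
        assert ideal_calibration.scale[1] == pytest.approx(1.0, abs=1e-4)

    def test_artificial_phase_rotation_recovered_exactly(self):
        ref = _mono(3.6)
        cal0 = build_calibration(ref, 3.6, [1])
        rotated = apply_calibration(
            phasor_transform(ref, [1]),
            type(cal0)(tau_ref_ns=3.6, scale={1: 1.0}, offset={1: 0.2}),
        )
        # rebuild calibration from the rotated reference phasor
        g, s = rotated[0].g, rotated[0].s
        m, phi = np.hypot(g, s), np.arctan2(s, g)
        g_t, s_t = mono_phasor(3.6, OMEGA1)
        offset = np.arctan2(s_t, g_t) - phi
        assert offset == pytest.approx(cal0.offset[1] - 0.2, abs=1e-9)

    def test_calibrated_reference_lands_on_theory_point(self, ideal_calibration):
        ref_pts = ideal_calibration.reference_points
        cal_pts = apply_calibration(ref_pts, ideal_calibration)
        for p in cal_pts:
            g_t, s_t = mono_phasor(3.6, p.omega)
            assert p.g == pytest.approx(g_t, abs=1e-9)
            assert p.s == pytest.approx(s_t, abs=1e-9)

    def test_universal_circle_identity_for_fine_binned_monos(self):
        # continuum identity (g-1/2)^2 + s^2 = 1/4, checked at harmonic 1
        # with fine binning where discretization is negligible
        ref = _mono(3.6, n_bins=32768)
        cal = build_calibration(ref, 3.6, [1])
        for tau in (0.4, 1.0, 3.6, 9.0):
            p = apply_calibration(phasor_transform(_mono(tau, n_bins=32768), [1]),
                                  cal)[0]
            assert (p.g - 0.5) ** 2 + p.s**2 == pytest.approx(0.25, abs=1e-6)

    def test_missing_harmonic_in_calibration_rejected(self, ideal_calibration):
        pts = phasor_transform(_mono(1.0), [12])
        with pytest.raises(ValueError, match="harmonic"):
            apply_calibration(pts, ideal_calibration)


class TestMonoLifetime:
    def test_zero_lag_point_gives_zero_lifetimes(self):
        from stromascope.phasor import PhasorPoint

        p = PhasorPoint.from_polar(1, OMEGA1, m=1.0, phi=0.0)
        assert mono_lifetime(p) == (0.0, 0.0)

    def test_calibrated_standard_recovers_3p6_ns(self, ideal_calibration):
        pts = apply_calibration(phasor_transform(_mono(3.6), [1]), ideal_calibration)
        tau_phase, tau_mod = mono_lifetime(pts[0])
        assert tau_phase == pytest.approx(3.6, rel=0.01)
        assert tau_mod == pytest.approx(3.6, rel=0.01)

    def test_mixture_point_has_tau_mod_above_tau_phase(self, ideal_calibration):
        decay = simulate_decay(
            DecaySimSpec([0.4, 2.5], [0.7, 0.3], total_photons=1e6)
        )
        pts = apply_calibration(phasor_transform(decay, [1]), ideal_calibration)
        tau_phase, tau_mod = mono_lifetime(pts[0])
        assert tau_mod > tau_phase

    def test_unphysical_point_flagged(self):
        from stromascope.phasor import PhasorPoint

        p = PhasorPoint.from_polar(1, OMEGA1, m=1.2, phi=0.1)
        with pytest.warns(UserWarning, match="unphysical"):
            tau_phase, tau_mod = mono_lifetime(p)
        assert np.isnan(tau_phase) and np.isnan(tau_mod)


class TestBiExpFit:
    def _fit(self, taus, alphas, cal, photons=1e6, seed=None, noise="none"):
        decay = simulate_decay(
            DecaySimSpec(taus, alphas, total_photons=photons, noise=noise,
                         seed=seed)
        )
        pts = apply_calibration(phasor_transform(decay), cal)
        return fit_biexponential(pts, calibration=cal)

    def test_noiseless_recovery_to_1e3_relative(self, ideal_calibration):
        fit = self._fit([0.4, 2.5], [0.7, 0.3], ideal_calibration)
        assert fit.tau1_ns == pytest.approx(0.4, rel=1e-3)
        assert fit.tau2_ns == pytest.approx(2.5, rel=1e-3)
        assert fit.alpha1 == pytest.approx(0.7, rel=1e-3)

    def test_pure_mono_exponential_collapses_with_correct_mean_lifetime(
        self, ideal_calibration
    ):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate-fit warning expected
            fit = self._fit([2.5, 2.5], [0.5, 0.5], ideal_calibration)
        assert mean_lifetime(fit) == pytest.approx(2.5, abs=1e-2)

    def test_single_harmonic_rejected(self, ideal_calibration):
        decay = simulate_decay(DecaySimSpec([1.0], [1.0], total_photons=1e4))
        pts = apply_calibration(phasor_transform(decay, [1]), ideal_calibration)
        with pytest.raises(ValueError, match="harmonics"):
            fit_biexponential(pts)

    def test_phasor_linearity_of_mixtures(self):
        # phasor of a mixture equals the intensity-fraction-weighted sum of
        # the component phasors (noiseless)
        t1, t2, a1 = 0.6, 3.0, 0.4
        mix = simulate_decay(DecaySimSpec([t1, t2], [a1, 1 - a1], total_photons=1.0))
        p_mix = phasor_transform(mix, [1, 4])
        c1 = phasor_transform(_mono(t1, photons=1.0), [1, 4])
        c2 = phasor_transform(_mono(t2, photons=1.0), [1, 4])
        T = 50.0
        w1 = a1 * t1 * (1 - np.exp(-T / t1))
        w2 = (1 - a1) * t2 * (1 - np.exp(-T / t2))
        f1 = w1 / (w1 + w2)
        for pm, pa, pb in zip(p_mix, c1, c2):
            assert pm.g == pytest.approx(f1 * pa.g + (1 - f1) * pb.g, abs=1e-9)
            assert pm.s == pytest.approx(f1 * pa.s + (1 - f1) * pb.s, abs=1e-9)

    def test_poisson_median_alpha1_error_small(self, ideal_calibration):
        # 5000 photons, 40 seeds here (the full 200-seed study runs in the
        # acceptance suite)
        errors = []
        for seed in range(40):
            fit = self._fit([0.4, 2.5], [0.7, 0.3], ideal_calibration,
                            photons=5000, noise="poisson", seed=seed)
            errors.append(abs(fit.alpha1 - 0.7))
        assert np.median(errors) <= 0.05


class TestScalarMetrics:
    def test_mean_lifetime_worked_example(self):
        fit = BiExpFit(tau1_ns=0.4, tau2_ns=2.5, alpha1=0.7)
        assert mean_lifetime(fit) == pytest.approx(1.03)

    def test_boundary_and_collapse_cases(self):
        assert mean_lifetime(BiExpFit(0.4, 2.5, alpha1=1.0)) == pytest.approx(0.4)
        assert mean_lifetime(BiExpFit(2.0, 2.0, alpha1=0.5)) == pytest.approx(2.0)

    def test_metabolic_index_examples(self):
        assert metabolic_index(BiExpFit(0.4, 2.5, 0.5)) == pytest.approx(1.0)
        assert metabolic_index(BiExpFit(0.4, 2.5, 0.7)) == pytest.approx(7 / 3)
        with pytest.raises(ValueError, match="alpha2"):
            metabolic_index(BiExpFit(0.4, 2.5, 1.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.floats(0.01, 0.98), hst.floats(0.001, 0.019))
    def test_metabolic_index_strictly_increasing_in_alpha1(self, a1, da):
        lo = metabolic_index(BiExpFit(0.4, 2.5, a1))
        hi = metabolic_index(BiExpFit(0.4, 2.5, a1 + da))
        assert hi > lo

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hst.floats(0.05, 0.95), hst.floats(0.15, 0.9), hst.floats(1.2, 8.9))
    def test_mean_lifetime_between_components_and_deterministic(self, a1, t1, t2):
        fit = BiExpFit(tau1_ns=t1, tau2_ns=t1 + t2, alpha1=a1)
        tm = mean_lifetime(fit)
        assert fit.tau1_ns <= tm <= fit.tau2_ns
        assert tm == mean_lifetime(fit)  # re-evaluation never changes it


class TestPerCellFlim:
    def _scene(self, alpha_by_cell, noise="none", seed=None):
        cells = [
            CellSpec(center=c, radius=9.0,
                     decay={"tau1_ns": 0.4, "tau2_ns": 2.5, "alpha1": a,
                            "photons_per_pixel": 3000.0})
            for c, a in alpha_by_cell
        ]
        return SceneSpec(image_shape=(64, 64), cells=cells, noise_model=noise,
                         seed=seed)

    def test_two_populations_separate_without_overlap(self, ideal_calibration):
        scene = self._scene(
            [((16, 16), 0.3), ((16, 48), 0.3), ((48, 16), 0.8), ((48, 48), 0.8)],
            noise="poisson", seed=4,
        )
        image, truth = simulate_flim_image(scene)
        table = per_cell_flim(image, truth.cell_labels, ideal_calibration)
        merged = table.merge(truth.per_cell, on="cell_id")
        low = merged[merged.true_alpha1 == 0.3].metabolic_index
        high = merged[merged.true_alpha1 == 0.8].metabolic_index
        assert low.max() < high.min()

    def test_uniform_scene_gives_equal_indices(self, ideal_calibration):
        scene = self._scene([((16, 16), 0.6), ((48, 48), 0.6)])
        image, truth = simulate_flim_image(scene)
        table = per_cell_flim(image, truth.cell_labels, ideal_calibration)
        assert table.metabolic_index.std() == pytest.approx(0.0, abs=1e-6)

    def test_infinite_photon_threshold_drops_all_cells_with_warning(
        self, ideal_calibration
    ):
        scene = self._scene([((32, 32), 0.5)])
        image, truth = simulate_flim_image(scene)
        with pytest.warns(UserWarning, match="dropped"):
            table = per_cell_flim(image, truth.cell_labels, ideal_calibration,
                                  min_photons=np.inf)
        assert table.empty
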