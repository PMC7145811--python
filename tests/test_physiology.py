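"""Microsensor flux, light-dark shift, PI-curve and growth-fit checks."""

import math

import numpy as np
import pytest

from coralight import phantoms, physiology as phys
from coralight.phantoms import D_O2_CM2_S, O2ProfileData, PhantomConfig


class TestDiffusiveFlux:
    def test_flat_profile_gives_zero_flux(self):
        p = phantoms.make_o2_profile(0.0, config=PhantomConfig(seed=1, noise_rel=0.0))
        assert phys.diffusive_flux(p).J == pytest.approx(0.0, abs=1e-12)

    def test_unit_conversion_of_unit_gradient(self):
        # dC/dz = -1 umol L^-1 um^-1 = -1e4 nmol cm^-4, so
        # J = -D dC/dz = 2.255e-5 cm^2/s * 1e4 nmol/cm^4 = 0.2255 nmol/cm^2/s
        depth = np.arange(-300.0, 1.0, 50.0)
        conc = 200.0 - 1.0 * depth
        est = phys.diffusive_flux(O2ProfileData(depth, conc), D=D_O2_CM2_S)
        assert est.J == pytest.approx(0.2255, rel=1e-9)

    def test_linear_in_d_and_gradient(self):
        depth = np.arange(-300.0, 1.0, 50.0)
        base = phys.diffusive_flux(O2ProfileData(depth, 200.0 - 0.5 * depth))
        doubled_d = phys.diffusive_flux(
            O2ProfileData(depth, 200.0 - 0.5 * depth), D=2 * D_O2_CM2_S
        )
        doubled_g = phys.diffusive_flux(O2ProfileData(depth, 200.0 - 1.0 * depth))
        assert doubled_d.J == pytest.approx(2 * base.J, rel=1e-12)
        assert doubled_g.J == pytest.approx(2 * base.J, rel=1e-12)

    def test_sign_convention_both_directions(self):
        prod = phantoms.make_o2_profile(0.3, config=PhantomConfig(seed=2, noise_rel=0.0))
        cons = phantoms.make_o2_profile(-0.3, config=PhantomConfig(seed=3, noise_rel=0.0))
        assert phys.diffusive_flux(prod).J > 0
        assert phys.diffusive_flux(cons).J < 0

    def test_phantom_roundtrip_within_confidence_interval(self):
        """The fitted flux covers the true J = 0.25 nmol cm^-2 s^-1 (the net
        photosynthesis scale at the polyp surface) at 3 sigma in the vast
        majority of noise realizations when the DBL window is known."""
        J = 0.25
        hits = 0
        errs = []
        for seed in range(20):
            p = phantoms.make_o2_profile(J, config=PhantomConfig(seed=seed, noise_rel=0.01))
            est = phys.diffusive_flux(p, window_um=(-300.0, 0.0))
            errs.append(abs(est.J - J) / J)
            if abs(est.J - J) < 3 * est.J_err:
                hits += 1
        assert hits >= 18
        assert np.median(errs) < 0.05

    def test_auto_window_accuracy_at_one_percent_noise(self):
        errs = []
        for seed in range(10):
            p = phantoms.make_o2_profile(0.25, config=PhantomConfig(seed=seed, noise_rel=0.01))
            errs.append(abs(phys.diffusive_flux(p).J - 0.25) / 0.25)
        assert np.median(errs) < 0.05

    def test_nonlinear_profile_without_window_errors(self):
        rng = np.random.default_rng(5)
        depth = np.arange(-400.0, 1.0, 25.0)
        conc = 200.0 + 50 * np.sin(depth / 40.0) + rng.normal(0, 20, depth.size)
        with pytest.raises(ValueError, match="R\\^2"):
            phys.diffusive_flux(O2ProfileData(depth, conc))

    def test_user_window_is_respected(self):
        depth = np.arange(-400.0, 1.0, 50.0)
        conc = 200.0 - 0.8 * np.clip(depth, -200.0, 0.0)
        est = phys.diffusive_flux(O2ProfileData(depth, conc), window_um=(-200.0, 0.0))
        assert est.window_um == (-200.0, 0.0)
        assert est.J == pytest.approx(0.8 * D_O2_CM2_S * 1e4, rel=1e-9)


class TestLightDarkShift:
    def test_constant_trace_gives_zero(self):
        t = np.arange(0.0, 10.0, 0.05)
        rate, _ = phys.gross_photosynthesis(t, np.full_like(t, 250.0), darkening_time=5.0)
        assert rate == pytest.approx(0.0, abs=1e-12)

    def test_known_decline_slope_recovered_exactly(self):
        t = np.arange(0.0, 10.0, 0.05)
        conc = np.where(t < 5.0, 250.0, 250.0 - 0.8 * (t - 5.0))
        rate, _ = phys.gross_photosynthesis(t, conc, darkening_time=5.0)
        assert rate == pytest.approx(0.8, rel=1e-9)

    def test_noisy_traces_recover_within_two_se(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            t = np.arange(0.0, 10.0, 0.05)
            conc = np.where(t < 5.0, 250.0, 250.0 - 0.8 * (t - 5.0))
            conc = conc + rng.normal(0, 0.05, t.size)
            rate, se = phys.gross_photosynthesis(t, conc, darkening_time=5.0)
            if abs(rate - 0.8) < 2 * se:
                hits += 1
        assert hits >= 16  # ~95% nominal coverage of 2 SE

    def test_window_beyond_trace_rejected(self):
        t = np.arange(0.0, 4.0, 0.1)
        with pytest.raises(ValueError):
            phys.gross_photosynthesis(t, np.zeros_like(t), darkening_time=3.5)


class TestPICurve:
    def test_exact_model_data_recovered(self):
        E = np.array([0.0, 50, 110, 220, 600, 1200.0])
        P = 2.0 * (1 - np.exp(-E / 150.0))
        fit = phys.fit_pi_curve(P, E)
        assert fit.Pmax == pytest.approx(2.0, rel=1e-6)
        assert fit.Ek == pytest.approx(150.0, rel=1e-6)

    def test_rate_at_ek_is_63_percent_of_pmax(self):
        fit = phys.fit_pi_curve(
            2.0 * (1 - np.exp(-np.array([0.0, 110, 220, 1200]) / 150.0)),
            np.array([0.0, 110, 220, 1200]),
        )
        assert fit.predict(fit.Ek) == pytest.approx(fit.Pmax * (1 - 1 / math.e), rel=1e-6)

    def test_phantom_roundtrip_at_five_percent_noise(self):
        errs = []
        for seed in range(10):
            df = phantoms.make_pi_data(
                2.0, 150.0, config=PhantomConfig(seed=seed, noise_rel=0.05), replicates=3
            )
            fit = phys.fit_pi_curve(df["rate"], df["irradiance"])
            errs.append(max(abs(fit.Pmax - 2.0) / 2.0, abs(fit.Ek - 150.0) / 150.0))
        assert np.median(errs) < 0.10

    def test_missing_dark_level_rejected(self):
        with pytest.raises(ValueError, match="dark"):
            phys.fit_pi_curve([1.0, 1.5, 1.8], [300.0, 600, 1200])


class TestFluenceNormalization:
    def test_reference_profile_reads_100_percent(self):
        prof = phys.normalize_fluence(np.arange(5.0), np.full(5, 80.0), 80.0)
        assert np.allclose(prof.e0_percent, 100.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            phys.normalize_fluence(np.arange(3.0), np.ones(3), 0.0)

    def test_fold_change_between_profiles_at_depth(self):
        depth = np.arange(0.0, 1001.0, 50.0)  # 750 um is a sampled depth
        enhanced = phys.normalize_fluence(depth, 150.0 - 0.02 * depth, 100.0)
        attenuated = phys.normalize_fluence(depth, 100.0 * np.exp(-depth / 500), 100.0)
        fold = enhanced.fold_change_at(attenuated, 750.0)
        assert fold == pytest.approx((150 - 15) / (100 * math.exp(-1.5)), rel=1e-9)

    def test_collimated_beam_surface_value_near_100(self):
        from coralight.geometry import LayeredSlab
        from coralight.materials import Material
        from coralight.mc_transport import fluence_depth_profile, simulate

        slab = LayeredSlab([(Material(0.05, 0.0, 0.0, 1.0), 2.0)])
        prof = fluence_depth_profile(simulate(slab, n_photons=20_000, seed=6))
        norm = phys.normalize_fluence(prof.depth_mm * 1000, prof.values, 100.0)
        assert norm.e0_percent[0] == pytest.approx(100.0, rel=0.02)


class TestGrowthFit:
    def test_exact_logistic_data_recovered(self):
        gs = phantoms.make_growth_series(
            r=0.8, K=9e8, config=PhantomConfig(seed=7, noise_rel=0.0), replicates=1
        )
        fit = phys.fit_growth(gs)
        assert fit.r == pytest.approx(0.8, rel=1e-3)
        assert fit.K == pytest.approx(9e8, rel=1e-3)
        assert fit.N0 == pytest.approx(1e6, rel=1e-3)

    def test_default_calibration_fit_exceeds_8e8_at_day_12(self):
        gs = phantoms.make_growth_series(config=PhantomConfig(seed=8, noise_rel=0.05))
        fit = phys.fit_growth(gs)
        assert fit.predict(12.0) > 8.0e8

    def test_prediction_band_strictly_contains_confidence_band(self):
        gs = phantoms.make_growth_series(config=PhantomConfig(seed=9, noise_rel=0.05))
        fit = phys.fit_growth(gs)
        days = np.linspace(0.0, 12.0, 25)
        clo, chi = fit.confidence_band(days)
        plo, phi = fit.prediction_band(days)
        assert np.all(plo < clo) and np.all(phi > chi)

    def test_prediction_interval_coverage_near_95_percent(self):
        """Over 200 synthetic datasets, a held-out replicate observation
        falls inside the 95% prediction band ~95% of the time."""
        covered = 0
        total = 0
        for seed in range(200):
            gs = phantoms.make_growth_series(
                config=PhantomConfig(seed=seed, noise_rel=0.10), replicates=4
            )
            fit = phys.fit_growth(gs)
            rng = np.random.default_rng(10_000 + seed)
            days = np.array([0.0, 3.0, 6.0, 10.0, 12.0])
            truth = 9e8 / (1 + ((9e8 - 1e6) / 1e6) * np.exp(-0.8 * days))
            new_obs = truth * np.exp(0.10 * rng.standard_normal(days.size))
            lo, hi = fit.prediction_band(days)
            covered += int(np.sum((new_obs >= lo) & (new_obs <= hi)))
            total += days.size
        coverage = covered / total
        assert abs(coverage - 0.95) < 0.04

    def test_flat_series_flags_degenerate_fit(self):
        gs = phantoms.make_growth_series(
            r=0.0, config=PhantomConfig(seed=11, noise_rel=0.01)
        )
        with pytest.warns(UserWarning, match="degenerate"):
            phys.fit_growth(gs)
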