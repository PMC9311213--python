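"""Photon bookkeeping, photolysis simulation, and quantum-yield fitting."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from ppgkit.photochem_kinetics import (
    IrradiationSetup,
    KineticsTrace,
    PhotophysicalProfile,
    TissueExperiment,
    absorbed_fraction,
    fit_quantum_yield,
    load_setup_yaml,
    photolysis_concentration,
    photon_flux,
    read_trace_csv,
    relative_quantum_yield,
    simulate_photolysis,
    stokes_shift,
    tissue_relative_rate,
    uncaging_cross_section,
    write_trace_csv,
)
from ppgkit.synthetic_fixtures import make_noisy_trace


class TestPhotonBookkeeping:
    def test_flux_at_760nm(self):
        assert photon_flux(1.0, 760.0) == pytest.approx(6.35e-6, rel=1e-3)

    def test_flux_linear_in_power(self):
        assert photon_flux(2.0, 760.0) == pytest.approx(2 * photon_flux(1.0, 760.0))

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError):
            photon_flux(0.0, 760.0)

    @pytest.mark.parametrize("a, expected", [(0.0, 0.0), (1.0, 0.9), (2.0, 0.99)])
    def test_absorbed_fraction(self, a, expected):
        assert absorbed_fraction(a) == pytest.approx(expected, abs=1e-12)

    def test_negative_absorbance_rejected(self):
        with pytest.raises(ValueError):
            absorbed_fraction(-0.1)

    def test_setup_requires_exactly_one_light_source(self):
        with pytest.raises(ValueError, match="exactly one"):
            IrradiationSetup(760, 3e-3, 1.0)
        with pytest.raises(ValueError, match="exactly one"):
            IrradiationSetup(
                760, 3e-3, 1.0, incident_power_W=1.0, photon_flux_einstein_s=1e-6
            )


class TestSimulation:
    def test_zero_quantum_yield_is_constant(self, setup_760nm):
        t = np.linspace(1, 100, 10)
        trace = simulate_photolysis(0.0, 2.76e5, 1e-6, setup_760nm, t)
        np.testing.assert_array_equal(trace.values, 1e-6)

    def test_strictly_decreasing_to_zero(self, setup_760nm):
        t = np.geomspace(1, 600, 40)
        trace = simulate_photolysis(0.00334, 2.76e5, 1e-6, setup_760nm, t)
        assert np.all(np.diff(trace.values) < 0)
        assert trace.values[-1] < 1e-9

    def test_low_absorbance_matches_exponential(self, setup_760nm):
        """eps*l*c0 = 1e-3: decay matches k_obs = phi*I0*ln10*eps*l/V to 0.1 %."""
        from scipy.optimize import brentq

        phi, eps, c0 = 0.01, 1e3, 1e-6
        k_obs = phi * setup_760nm.flux * math.log(10) * eps / setup_760nm.volume_L
        t = np.linspace(0.1, 1.5 / k_obs, 60)
        trace = simulate_photolysis(phi, eps, c0, setup_760nm, t)
        expected = c0 * np.exp(-k_obs * t)
        np.testing.assert_allclose(trace.values, expected, rtol=1e-3)
        half_life = brentq(
            lambda tau: photolysis_concentration(tau, phi, eps, c0, setup_760nm) - c0 / 2,
            0.01 / k_obs,
            10 / k_obs,
            xtol=1e-12,
        )
        assert half_life == pytest.approx(math.log(2) / k_obs, rel=1e-3)

    def test_agrees_with_independent_ode_integration(self, setup_760nm):
        """Closed-form trace vs scipy's initial-value integrator."""
        phi, eps, c0 = 0.00334, 2.76e5, 1e-6
        t = np.geomspace(1, 500, 25)
        trace = simulate_photolysis(phi, eps, c0, setup_760nm, t)
        a = phi * setup_760nm.flux / setup_760nm.volume_L

        def rhs(_, c):
            return [-a * (1.0 - 10 ** (-eps * setup_760nm.path_length_cm * c[0]))]

        sol = solve_ivp(
            rhs, (0, t[-1]), [c0], t_eval=t, rtol=1e-10, atol=1e-16, method="LSODA"
        )
        np.testing.assert_allclose(trace.values, sol.y[0], rtol=1e-6)

    def test_released_equals_phi_times_absorbed(self, setup_760nm):
        """Moles released = phi * cumulative absorbed einsteins, at all times."""
        phi, eps, c0 = 0.00334, 2.76e5, 1e-6
        t = np.geomspace(10, 2e4, 12)
        trace = simulate_photolysis(phi, eps, c0, setup_760nm, t)
        l = setup_760nm.path_length_cm

        def absorbed_rate(tau):
            c = photolysis_concentration(tau, phi, eps, c0, setup_760nm)
            return setup_760nm.flux * (1.0 - 10 ** (-eps * l * c))

        for ti, ci in zip(t, trace.values):
            released_mol = (c0 - ci) * setup_760nm.volume_L
            absorbed_einstein, _ = quad(absorbed_rate, 0, ti, limit=200)
            assert released_mol == pytest.approx(
                phi * absorbed_einstein, rel=1e-6
            )
            assert released_mol <= c0 * setup_760nm.volume_L

    def test_non_monotonic_grid_rejected(self, setup_760nm):
        with pytest.raises(ValueError):
            simulate_photolysis(0.1, 1e4, 1e-6, setup_760nm, np.array([0.0, 2.0, 1.0]))


class TestQuantumYieldFit:
    def test_noiseless_recovery_is_exact(self):
        trace = make_noisy_trace(0.00334, noise_frac=0.0)
        fit = fit_quantum_yield(trace, 2.76e5, n_boot=0)
        assert fit.phi == pytest.approx(0.00334, rel=1e-5)

    def test_initial_rate_estimate_close(self):
        trace = make_noisy_trace(0.00334, noise_frac=0.0)
        fit = fit_quantum_yield(trace, 2.76e5, n_boot=0)
        assert fit.phi_initial_rate == pytest.approx(0.00334, rel=0.05)

    def test_noisy_recovery_within_two_percent(self):
        trace = make_noisy_trace(0.00334, noise_frac=0.02, n_points=20, seed=11)
        fit = fit_quantum_yield(trace, 2.76e5, n_boot=0, seed=11)
        assert fit.phi == pytest.approx(0.00334, rel=0.02)

    def test_bootstrap_ci_covers_truth_for_most_seeds(self):
        """Residual-bootstrap 95 % CI contains the generating value in
        >= 90 % of 50 seeded replicates at 2 % noise."""
        phi_true, covered = 0.00334, 0
        for seed in range(50):
            trace = make_noisy_trace(phi_true, noise_frac=0.02, n_points=20, seed=seed)
            with np.errstate(all="ignore"):
                fit = fit_quantum_yield(trace, 2.76e5, n_boot=100, seed=seed)
            if fit.ci_low <= phi_true <= fit.ci_high:
                covered += 1
        assert covered >= 45

    def test_constant_trace_gives_zero_phi(self, setup_760nm):
        trace = KineticsTrace(
            times=np.linspace(1, 100, 8),
            values=np.full(8, 1e-6),
            setup=setup_760nm,
        )
        fit = fit_quantum_yield(trace, 2.76e5, n_boot=0)
        assert fit.phi == pytest.approx(0.0, abs=1e-8)

    def test_too_few_points_rejected(self, setup_760nm):
        trace = KineticsTrace(
            times=np.array([1.0, 2, 3, 4]), values=np.full(4, 1e-6), setup=setup_760nm
        )
        with pytest.raises(ValueError, match="5 time points"):
            fit_quantum_yield(trace, 2.76e5)

    def test_rising_trace_warns_but_fits(self, setup_760nm):
        trace = KineticsTrace(
            times=np.linspace(1, 100, 8),
            values=np.linspace(1e-6, 2e-6, 8),
            setup=setup_760nm,
            noise_sigma=0.001,
        )
        with pytest.warns(UserWarning, match="monoton"):
            fit_quantum_yield(trace, 2.76e5, n_boot=0)


class TestScalarQuantities:
    def test_cross_section_worked_example(self):
        xs = uncaging_cross_section(2.76e5, 0.00334)
        assert abs(xs.value - 921) <= 1.0
        assert xs.ideal

    def test_cross_section_zero_phi(self):
        xs = uncaging_cross_section(1e5, 0.0)
        assert xs.value == 0.0 and not xs.ideal

    def test_cross_section_boundary_inclusive(self):
        xs = uncaging_cross_section(1e4, 0.01)
        assert xs.value == 100.0 and xs.ideal

    def test_cross_section_over_epsilon_is_phi(self):
        phi = 0.004
        assert uncaging_cross_section(1e5, phi).value / 1e5 == pytest.approx(
            phi, rel=5e-3
        )

    @pytest.mark.parametrize(
        "lam_abs, lam_em, expected", [(746, 836, 90), (736, 771, 35), (500, 500, 0)]
    )
    def test_stokes_shift(self, lam_abs, lam_em, expected):
        assert stokes_shift(lam_abs, lam_em) == expected

    def test_negative_stokes_shift_flagged(self):
        with pytest.warns(UserWarning, match="anomalous"):
            assert stokes_shift(800, 750) == -50

    def test_relative_quantum_yield_identity(self):
        assert relative_quantum_yield(1.0, 1.0, 0.5, 0.5, 0.039) == 0.039

    def test_relative_quantum_yield_zero_sample(self):
        assert relative_quantum_yield(0.0, 1.0, 0.5, 0.5, 0.039) == 0.0

    def test_relative_quantum_yield_arithmetic(self):
        # slope ratio 0.1, absorbed-fraction ratio (ref/sample) 2, reference 3.9 %
        assert relative_quantum_yield(0.1, 1.0, 0.25, 0.5, 0.039) == pytest.approx(
            0.0078
        )

    def test_relative_quantum_yield_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_quantum_yield(1.0, 0.0, 0.5, 0.5, 0.039)

    @pytest.mark.parametrize(
        "ratio, expected", [(1.0, 100.0), (0.78, 78.0), (0.0, 0.0), (0.86, 86.0)]
    )
    def test_tissue_relative_rate(self, ratio, expected):
        exp = TissueExperiment(rate_free=2.5, rate_tissue=2.5 * ratio)
        assert tissue_relative_rate(exp) == expected

    def test_zero_free_rate_rejected(self):
        with pytest.raises(ValueError):
            tissue_relative_rate(TissueExperiment(rate_free=0.0, rate_tissue=1.0))


class TestProfileAndIO:
    def test_profile_summary_flags(self):
        prof = PhotophysicalProfile(
            lambda_max_nm=746, epsilon=2.76e5, phi_het=0.00334, lambda_em_nm=836
        )
        s = prof.summary()
        assert s["stokes_shift_nm"] == 90
        assert abs(s["cross_section_M_cm"] - 921) <= 1
        assert s["cross_section_ideal"] and s["in_therapeutic_window"]

    def test_out_of_window_flag(self):
        prof = PhotophysicalProfile(lambda_max_nm=650, epsilon=1e5)
        assert not prof.in_therapeutic_window

    def test_trace_csv_roundtrip(self, tmp_path, setup_760nm):
        trace = make_noisy_trace(0.00334, noise_frac=0.02, seed=3)
        path = tmp_path / "trace.csv"
        write_trace_csv(trace, path)
        back = read_trace_csv(path, setup=setup_760nm, c0_M=1e-6)
        assert back.mode == "concentration_M"
        np.testing.assert_allclose(back.times, trace.times)
        np.testing.assert_allclose(back.values, trace.values)

    def test_setup_yaml(self, tmp_path):
        path = tmp_path / "setup.yaml"
        path.write_text(
            "wavelength_nm: 760\npower_W: 0.005\nvolume_L: 0.003\npath_cm: 1.0\n"
        )
        setup = load_setup_yaml(path)
        assert setup.flux == pytest.approx(photon_flux(0.005, 760))
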