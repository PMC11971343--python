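"""Binding models: burst efficiencies, histogram peaks, titration and salt fits."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from dynacomplex.binding import (DEFAULT_ALPHA, GaussianPeakFit, SaltSeries,
                                 TitrationSeries, bound_fraction_1to1,
                                 burst_efficiencies, fit_population_curves,
                                 fit_salt_dependence, fit_titration,
                                 predict_mean_e_1to1, predict_mean_e_multistate,
                                 solve_sequential_populations)
from dynacomplex.config import CorrectionFactors
from dynacomplex.synth import make_salt_series, make_titration


class TestBurstEfficiencies:
    def test_identity_corrections(self):
        df = pd.DataFrame({"n_A": [50, 0, 30], "n_D": [50, 80, 0]})
        out = burst_efficiencies(df)
        assert out["E"].tolist() == [0.5, 0.0, 1.0]

    def test_stoichiometry_window_selection(self):
        df = pd.DataFrame({"n_A": [50, 50, 50], "n_D": [50, 50, 50],
                           "S": [0.1, 0.5, 0.8]})
        out = burst_efficiencies(df, s_window=(0.2, 0.75))
        assert len(out) == 1 and out["S"].iloc[0] == 0.5

    def test_empty_after_correction_dropped_and_counted(self):
        corr = CorrectionFactors(background_donor=10, background_acceptor=10)
        df = pd.DataFrame({"n_A": [10.0, 100.0], "n_D": [10.0, 100.0]})
        out = burst_efficiencies(df, corr)
        assert out.attrs["n_dropped_empty"] == 1 and len(out) == 1

    def test_gamma_correction_shifts_e(self):
        df = pd.DataFrame({"n_A": [50], "n_D": [50]})
        out = burst_efficiencies(df, CorrectionFactors(gamma=2.0))
        assert out["E"].iloc[0] == pytest.approx(50 / 150)


class TestGaussianPeaks:
    def test_single_peak_mean_recovered(self, rng):
        # free-chain-like histogram: mu = 0.334, sigma = 0.05, 5000 bursts
        e = rng.normal(0.334, 0.05, 5000)
        fit = GaussianPeakFit(n_peaks=1).fit(e)
        se = 0.05 / np.sqrt(5000)
        assert abs(fit.means_[0] - 0.334) < 2.5 * se
        assert fit.areas_[0] == pytest.approx(1.0)

    def test_two_equal_peaks_split_areas(self, rng):
        e = np.concatenate([rng.normal(0.3, 0.04, 4000),
                            rng.normal(0.7, 0.04, 4000)])
        fit = GaussianPeakFit(n_peaks=2).fit(e)
        assert fit.means_[0] < fit.means_[1]
        np.testing.assert_allclose(fit.areas_, [0.5, 0.5], atol=0.03)

    def test_overfit_flags_degenerate_component(self, rng):
        e = rng.normal(0.4, 0.05, 6000)
        fit = GaussianPeakFit(n_peaks=3).fit(e)
        assert fit.degenerate_.any()
        assert fit.areas_.max() > 0.9


class TestOneToOneModel:
    def test_zero_ligand_gives_e0(self):
        assert predict_mean_e_1to1(15e-6, 0.33, 0.25, 0.0, 1e-10) == 0.33

    def test_half_saturation_at_kd_in_excess_limit(self):
        kd = 20e-6
        e = predict_mean_e_1to1(kd, 0.3, 0.2, kd, 1e-13)
        assert e == pytest.approx(0.3 + 0.1, rel=1e-4)

    def test_matches_brute_force_equilibrium(self):
        kd, g_tot, p_tot = 17e-6, 40e-6, 8e-6

        def residual(free_g):
            bound = free_g * p_tot / (kd + free_g)
            return free_g + bound - g_tot

        free_g = optimize.brentq(residual, 0, g_tot, xtol=1e-25, rtol=1e-15)
        fb_oracle = free_g / (kd + free_g)
        assert abs(bound_fraction_1to1(kd, g_tot, p_tot) - fb_oracle) < 1e-10

    @given(st.floats(1e-7, 1e-3), st.floats(1e-7, 1e-3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_ligand(self, g1, g2):
        lo, hi = sorted([g1, g2])
        e_lo = predict_mean_e_1to1(15e-6, 0.3, 0.25, lo, 1e-6)
        e_hi = predict_mean_e_1to1(15e-6, 0.3, 0.25, hi, 1e-6)
        assert e_hi >= e_lo - 1e-12


class TestSequentialPopulations:
    def test_reduces_to_quadratic_for_n1(self):
        p, *_ = solve_sequential_populations([15e-6], 30e-6, 2e-6)
        assert abs(p[1] - bound_fraction_1to1(15e-6, 30e-6, 2e-6)) < 1e-12

    def test_infinite_kd_leaves_chain_free(self):
        p, *_ = solve_sequential_populations([1e3] * 4, 1e-5, 1e-6)
        assert p[0] == pytest.approx(1.0, abs=1e-7)

    def test_matches_independent_nonlinear_solver(self):
        kds = np.array([5e-6, 20e-6, 80e-6, 300e-6])
        g_tot, p_tot = 60e-6, 10e-6
        p, free_g, free_p, cx = solve_sequential_populations(kds, g_tot, p_tot)

        # independent oracle: solve the 4 coupled equilibria + mass balances
        # for ([G], [PG1..PG4]) with [P] eliminated via the total; work in
        # uM units so fsolve sees O(1) numbers
        kds_u, g_tot_u, p_tot_u = kds * 1e6, g_tot * 1e6, p_tot * 1e6

        def system(x):
            g, pg = x[0], x[1:]
            p_free = p_tot_u - pg.sum()
            eqs = [kds_u[0] * pg[0] - p_free * g]
            for i in range(1, 4):
                eqs.append(kds_u[i] * pg[i] - pg[i - 1] * g)
            eqs.append(g + np.arange(1, 5) @ pg - g_tot_u)
            return eqs

        x0 = np.array([g_tot_u / 2] + [p_tot_u / 8] * 4)
        sol, info, ier, msg = optimize.fsolve(system, x0, full_output=True,
                                              xtol=1e-13)
        assert ier == 1, msg
        pg = sol[1:]
        p_oracle = np.concatenate([[p_tot_u - pg.sum()], pg]) / p_tot_u
        np.testing.assert_allclose(p, p_oracle, atol=1e-9)

    @given(st.floats(1e-7, 1e-3), st.floats(1e-8, 1e-4),
           st.lists(st.floats(1e-7, 1e-3), min_size=1, max_size=4))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conservation_and_mass_balance(self, g_tot, p_tot, kds):
        p, free_g, free_p, cx = solve_sequential_populations(kds, g_tot, p_tot)
        assert abs(p.sum() - 1.0) < 1e-10
        i = np.arange(len(p))
        bound_g = float((i * p) @ np.ones(1)) * p_tot if False else (i @ p) * p_tot
        assert abs(free_g + bound_g - g_tot) < 1e-10 * max(g_tot, 1e-30) + 1e-16

    def test_anticooperative_populations_peak_in_order(self):
        # increasing macroscopic Kd: higher complexes populate at higher [G]
        kds = [2e-6, 8e-6, 32e-6, 128e-6]
        g_grid = np.geomspace(1e-7, 1e-3, 40)
        peaks = []
        for i in range(1, 4):
            pops = [solve_sequential_populations(kds, g, 1e-6)[0][i]
                    for g in g_grid]
            peaks.append(g_grid[int(np.argmax(pops))])
        assert peaks == sorted(peaks)


class TestMultistateModel:
    def test_reduces_to_1to1_with_step_alpha(self):
        e_multi = predict_mean_e_multistate([15e-6], [0.0, 1.0], 0.3, 0.25,
                                            40e-6, 2e-6)
        e_11 = predict_mean_e_1to1(15e-6, 0.3, 0.25, 40e-6, 2e-6)
        assert e_multi == pytest.approx(e_11, abs=1e-12)

    def test_zero_ligand_gives_e0(self):
        e = predict_mean_e_multistate([1e-5] * 4, DEFAULT_ALPHA, 0.31, 0.2,
                                      0.0, 1e-6)
        assert e == 0.31

    def test_default_alpha_profile_shape(self):
        # first binding event carries ~80% of the efficiency change,
        # subsequent ones ~11% and ~7%
        a = np.asarray(DEFAULT_ALPHA)
        assert a[0] == 0.0 and a[-1] == 1.0
        assert np.all(np.diff(a) >= 0)
        assert a[1] == pytest.approx(0.80)
        np.testing.assert_allclose(np.diff(a)[1:3], [0.11, 0.07], atol=1e-12)


class TestTitrationFit:
    def test_noiseless_exact_recovery(self):
        g = np.geomspace(1e-7, 3e-4, 12)
        series = make_titration(17e-6, 0.33, 0.25, g, 1e-10, 0.0, seed=0)
        fit = fit_titration(series)
        assert fit.kd_ == pytest.approx(17e-6, rel=1e-6)
        assert fit.e0_ == pytest.approx(0.33, abs=1e-8)
        assert fit.de_sat_ == pytest.approx(0.25, abs=1e-8)

    def test_noisy_recovery_within_2se(self):
        g = np.geomspace(1e-7, 3e-4, 12)
        series = make_titration(15e-6, 0.33, 0.25, g, 1e-10, 0.005, seed=1)
        fit = fit_titration(series)
        assert abs(fit.kd_ - 15e-6) < 2 * fit.kd_se_

    def test_too_few_points_rejected(self):
        series = TitrationSeries([0, 1e-5, 1e-4], 1e-10, [0.3, 0.4, 0.5])
        with pytest.raises(ValueError, match="4 titration points"):
            fit_titration(series)

    def test_multistate_fit_recovers_and_flags_overparameterization(self):
        g = np.geomspace(1e-7, 1e-3, 16)
        kds = [15e-6, 60e-6, 240e-6, 960e-6]
        series = make_titration(kds, 0.33, 0.25, g, 1e-10, 0.003, seed=3,
                                alpha=DEFAULT_ALPHA)
        fit = fit_titration(series, model="1:N", alpha=DEFAULT_ALPHA)
        # the first binding event dominates <E>; its Kd must be meaningful
        assert abs(fit.kd_[0] - 15e-6) < max(2 * fit.kd_se_[0], 0.3 * 15e-6)
        assert not fit.overparameterized_[0]
        # higher-order constants are weakly determined at best
        assert hasattr(fit, "overparameterized_")


class TestPopulationCurves:
    def test_noiseless_recovery(self):
        kds = np.array([5e-6, 25e-6, 100e-6, 400e-6])
        g_grid = np.geomspace(1e-7, 2e-3, 25)
        p_tot = 1e-6
        pops = np.stack([solve_sequential_populations(kds, g, p_tot)[0]
                         for g in g_grid])
        est, se = fit_population_curves(g_grid, pops, p_tot)
        np.testing.assert_allclose(est, kds, rtol=1e-6)

    def test_noisy_recovery_within_2se(self, rng):
        kds = np.array([5e-6, 25e-6, 100e-6, 400e-6])
        g_grid = np.geomspace(1e-7, 2e-3, 25)
        pops = np.stack([solve_sequential_populations(kds, g, 1e-6)[0]
                         for g in g_grid])
        noisy = np.clip(pops + rng.normal(0, 0.01, pops.shape), 0, 1)
        noisy /= noisy.sum(axis=1, keepdims=True)
        est, se = fit_population_curves(g_grid, noisy, 1e-6,
                                        se=np.full_like(pops, 0.01))
        assert np.all(np.abs(est - kds) < 2.5 * se + 0.05 * kds)

    def test_n1_reduces_to_bound_fraction_fit(self):
        kd = 12e-6
        g_grid = np.geomspace(1e-7, 5e-4, 15)
        pops = np.stack([solve_sequential_populations([kd], g, 1e-9)[0]
                         for g in g_grid])
        est, _ = fit_population_curves(g_grid, pops, 1e-9)
        assert est[0] == pytest.approx(kd, rel=1e-6)


class TestSaltDependence:
    def test_exact_line_recovered(self):
        i_s = np.geomspace(0.01, 1.0, 6)
        kd = 1e-6 * (i_s / 0.165) ** 4.6
        fit = fit_salt_dependence(SaltSeries(i_s, kd))
        assert fit.n_ions_ == pytest.approx(4.6, abs=1e-12)

    def test_noisy_recovery_within_ci(self):
        series = make_salt_series(17e-6, 4.6, np.geomspace(0.06, 0.3, 6),
                                  0.05, seed=2)
        fit = fit_salt_dependence(series)
        assert fit.ci90_[0] < 4.6 < fit.ci90_[1]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_salt_dependence(SaltSeries([0.1, 0.2], [1e-6, 2e-6]))

    def test_single_ionic_strength_generator_rejected(self):
        with pytest.raises(ValueError, match="more than one"):
            make_salt_series(17e-6, 4.6, [0.165], 0.05, seed=0)
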