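"""CSP metrics, relaxation decay fits, and back-calculated 15N relaxation."""
import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from dynacomplex.config import GAMMA_H, GAMMA_N
from dynacomplex.nmr import (NHVectorTrajectory, RelaxConstants, SpectralModel,
                             block_uncertainty, back_calculate_rates,
                             compute_csp, fit_exponential_decay,
                             fit_spectral_model, normalized_csp_sum,
                             orientation_correlation, relaxation_rates)


def _peaks(residues, dh, dn):
    return pd.DataFrame({"residue": residues, "delta_H_ppm": dh,
                         "delta_N_ppm": dn})


class TestCsp:
    def test_no_shift_gives_zero(self):
        free = _peaks([1, 2], [8.0, 8.1], [120.0, 121.0])
        out = compute_csp(free, free.copy())
        assert (out["csp_ppm"] == 0).all()

    def test_hand_evaluated_formula(self):
        free = _peaks([5], [8.0], [120.0])
        bound = _peaks([5], [8.01], [120.1])
        out = compute_csp(free, bound)
        # sqrt(0.01^2 + (0.154*0.1)^2) = 0.0183616...
        assert out["csp_ppm"].iloc[0] == pytest.approx(0.0183616, abs=1e-6)

    def test_homogeneity_in_nitrogen_shift(self):
        free = _peaks([1], [8.0], [120.0])
        b1 = _peaks([1], [8.0], [120.2])
        b2 = _peaks([1], [8.0], [120.4])
        c1 = compute_csp(free, b1)["csp_ppm"].iloc[0]
        c2 = compute_csp(free, b2)["csp_ppm"].iloc[0]
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_reference_offset_invariance(self):
        free = _peaks([1, 2, 3], [8.0, 8.2, 7.9], [118.0, 120.0, 122.0])
        bound = _peaks([1, 2, 3], [8.05, 8.21, 7.88], [118.5, 120.2, 121.7])
        base = compute_csp(free, bound)["csp_ppm"]
        off_f = free.copy()
        off_b = bound.copy()
        for df in (off_f, off_b):
            df["delta_H_ppm"] += 0.3
            df["delta_N_ppm"] -= 1.7
        shifted = compute_csp(off_f, off_b)["csp_ppm"]
        np.testing.assert_allclose(shifted, base, atol=1e-12)

    def test_missing_residues_reported_not_imputed(self):
        free = _peaks([1, 2, 3], [8.0, 8.1, 8.2], [120, 121, 122])
        bound = _peaks([2, 3, 4], [8.1, 8.2, 8.3], [121, 122, 123])
        out = compute_csp(free, bound)
        assert list(out["residue"]) == [2, 3]
        assert out.attrs["missing_residues"] == [1, 4]

    def test_disjoint_residues_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            compute_csp(_peaks([1], [8], [120]), _peaks([2], [8], [120]))


def _csp_table(residues, values):
    return pd.DataFrame({"residue": residues, "csp_ppm": values})


class TestNormalizedCspSum:
    def test_identical_data_gives_unity(self):
        wt = _csp_table([1, 2, 3], [0.1, 0.2, 0.3])
        ratio, err = normalized_csp_sum(wt, [wt.copy(), wt.copy(), wt.copy()])
        assert ratio == pytest.approx(1.0)
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_doubled_csps_give_two(self):
        wt = _csp_table([1, 2, 3], [0.1, 0.2, 0.3])
        var = _csp_table([1, 2, 3], [0.2, 0.4, 0.6])
        ratio, _ = normalized_csp_sum(var, [wt] * 3)
        assert ratio == pytest.approx(2.0)

    def test_error_propagation_matches_bootstrap(self, rng):
        base = np.array([0.1, 0.2, 0.3, 0.15])
        reps = [_csp_table([1, 2, 3, 4], base * f)
                for f in (0.95, 1.0, 1.05)]  # ~5% spread of replicate sums
        var = _csp_table([1, 2, 3, 4], base * 1.4)
        ratio, err = normalized_csp_sum(var, reps)
        # bootstrap oracle over the three replicate sums
        sums = np.array([r["csp_ppm"].sum() for r in reps])
        v_sum = var["csp_ppm"].sum()
        boot = v_sum / np.array([rng.choice(sums, 3).mean()
                                 for _ in range(20000)])
        assert err == pytest.approx(boot.std(), rel=0.35)

    def test_zero_reference_rejected(self):
        var = _csp_table([1], [0.1])
        with pytest.raises(ZeroDivisionError):
            normalized_csp_sum(var, [_csp_table([1], [0.0])])


class TestExponentialDecay:
    def test_exact_rate_recovered(self):
        t = np.array([0.034, 0.068, 0.102, 0.136, 0.204, 0.271, 0.407, 0.475,
                      0.543])
        y = 100.0 * np.exp(-3.1 * t)
        fit = fit_exponential_decay(t, y)
        assert fit.rate_ == pytest.approx(3.1, abs=1e-10)

    def test_noisy_recovery_on_transverse_delay_grid(self, rng):
        t = np.tile([0.034, 0.068, 0.102, 0.136, 0.204, 0.271, 0.407, 0.475,
                     0.543], 3)  # triplicates as replicates
        y = 100.0 * np.exp(-3.1 * t) * (1 + rng.normal(0, 0.02, t.size))
        fit = fit_exponential_decay(t, y)
        assert abs(fit.rate_ - 3.1) < 2 * fit.rate_se_

    def test_constant_signal_flagged(self):
        with pytest.warns(UserWarning, match="zero rate"):
            fit = fit_exponential_decay([0.1, 0.2, 0.3, 0.4], [50.0] * 4)
        assert fit.nondecaying_
        assert fit.rate_ == pytest.approx(0.0, abs=1e-6)


class TestOrientationCorrelation:
    def test_static_vector_gives_unity(self):
        v = np.tile([0.0, 0.0, 1.0], (1, 100, 1)).reshape(1, 100, 3)
        traj = NHVectorTrajectory(v, dt=5.0)
        c = orientation_correlation(traj, 0, 50)
        np.testing.assert_allclose(c, 1.0, atol=1e-12)

    def test_matches_exponential_for_isotropic_tumbling(self, tumbling_5ns):
        lags = 150  # 15 ns = 3 tau_c at 100 ps sampling
        t = np.arange(lags + 1) * 0.1
        ref = np.exp(-t / 5.0)
        for i in (0, 1):
            c = orientation_correlation(tumbling_5ns, i, lags)
            assert np.abs(c - ref).max() < 0.03

    def test_bounded_by_p2_range(self, tumbling_5ns):
        c = orientation_correlation(tumbling_5ns, 0, 5000)
        assert c.max() <= 1.0 + 1e-9 and c.min() >= -0.5 - 1e-9

    def test_lag_limit_enforced(self, tumbling_5ns):
        with pytest.raises(ValueError, match="half"):
            orientation_correlation(tumbling_5ns, 0, tumbling_5ns.n_steps)


class TestSpectralModel:
    def test_single_exponential_dominates(self):
        t = np.linspace(0, 20, 200)
        c = 0.9 * np.exp(-t / 4.0)
        model = fit_spectral_model(t, c)
        order = np.argsort(model.amplitudes)[::-1]
        assert model.amplitudes[order[0]] == pytest.approx(0.9, abs=1e-6)
        assert model.timescales[order[0]] == pytest.approx(4.0, rel=1e-4)
        assert model.amplitudes[order[1:]].max() < 1e-6

    def test_triple_exponential_noiseless_recovery(self):
        t = np.linspace(0, 50, 500)
        amps, taus = [0.5, 0.3, 0.2], [0.3, 3.0, 20.0]
        c = sum(a * np.exp(-t / tau) for a, tau in zip(amps, taus))
        model = fit_spectral_model(t, c)
        order = np.argsort(model.timescales)
        np.testing.assert_allclose(model.timescales[order], taus, rtol=1e-4)
        np.testing.assert_allclose(model.amplitudes[order], amps, atol=1e-5)

    def test_j0_matches_numeric_integral_of_fit(self):
        t = np.linspace(0, 50, 500)
        c = 0.6 * np.exp(-t / 2.0) + 0.4 * np.exp(-t / 12.0)
        model = fit_spectral_model(t, c)
        j0_numeric, _ = integrate.quad(
            lambda tt: 2.0 * model.correlation(np.array([tt]))[0] * 1e-9,
            0, np.inf, limit=200)
        assert model.spectral_density(0.0) == pytest.approx(j0_numeric, abs=1e-8)


class TestRelaxationRates:
    def test_extreme_narrowing_r1_equals_r2(self):
        const = RelaxConstants(750.0)
        const.csa = 0.0  # dipolar only for the flat-J identity
        fast = SpectralModel([1.0], [1e-3])  # omega tau << 1
        r1, r2, _ = relaxation_rates(fast, const)
        assert r2 == pytest.approx(r1, rel=1e-3)

    def test_extreme_narrowing_noe_limit(self):
        const = RelaxConstants(750.0)
        const.csa = 0.0
        fast = SpectralModel([1.0], [1e-3])
        _, _, eta = relaxation_rates(fast, const)
        assert eta == pytest.approx(1.0 + GAMMA_H / (2 * GAMMA_N), rel=1e-3)

    @pytest.mark.parametrize("mhz", [600.0, 750.0])
    def test_lorentzian_against_direct_reimplementation(self, mhz):
        # independent evaluation of the dipolar+CSA formulas written out
        # from scratch for a single Lorentzian J
        tau_c = 5e-9
        const = RelaxConstants(mhz)
        wh, wn = const.omega_h, const.omega_n
        j = lambda w: 2.0 * tau_c / (1.0 + (w * tau_c) ** 2)
        d, c = const.dipolar, const.csa
        r1_ref = d * (j(wh - wn) + 3 * j(wn) + 6 * j(wh + wn)) + c * j(wn)
        r2_ref = d / 2 * (4 * j(0) + j(wh - wn) + 3 * j(wn) + 6 * j(wh)
                          + 6 * j(wh + wn)) + c / 6 * (4 * j(0) + 3 * j(wn))
        eta_ref = 1 + d * (GAMMA_H / GAMMA_N) / r1_ref \
            * (6 * j(wh + wn) - j(wh - wn))
        model = SpectralModel([1.0], [5.0])
        r1, r2, eta = relaxation_rates(model, const)
        assert r1 == pytest.approx(r1_ref, rel=1e-10)
        assert r2 == pytest.approx(r2_ref, rel=1e-10)
        assert eta == pytest.approx(eta_ref, rel=1e-10)

    def test_slow_tumbling_r2_exceeds_r1(self):
        model = SpectralModel([1.0], [5.0])
        r1, r2, _ = relaxation_rates(model, RelaxConstants(750.0))
        assert r2 > r1 > 0


class TestBlockUncertainty:
    def test_identical_blocks_give_zero_sigma(self):
        block = np.tile([0.0, 0.0, 1.0], (1, 10, 1)).reshape(1, 10, 3)
        v = np.concatenate([block] * 10, axis=1)
        traj = NHVectorTrajectory(v, dt=5.0)
        means, sigmas = block_uncertainty(
            traj, lambda b, i: np.array([float(b.vectors[i, :, 2].mean())]))
        assert sigmas[0][0] == 0.0

    def test_iid_blocks_match_sd_over_sqrt_n(self, rng):
        # observable = mean x-component; blocks are independent random vectors
        v = rng.standard_normal((1, 1000, 3))
        v /= np.linalg.norm(v, axis=2, keepdims=True)
        traj = NHVectorTrajectory(v, dt=1.0)
        means, sigmas = block_uncertainty(
            traj, lambda b, i: np.array([float(b.vectors[i, :, 0].mean())]),
            n_blocks=10)
        per_block = np.array([v[0, k * 100:(k + 1) * 100, 0].mean()
                              for k in range(10)])
        expected = per_block.std(ddof=0) / np.sqrt(10)
        assert sigmas[0][0] == pytest.approx(expected, rel=1e-10)


class TestBackCalculationPipeline:
    def test_reproduces_lorentzian_rates_for_tumbling(self, tumbling_5ns):
        rates = back_calculate_rates(tumbling_5ns, spectrometer_mhz=750.0,
                                     max_lag=200)
        ref = SpectralModel([1.0], [5.0])
        r1_ref, r2_ref, eta_ref = relaxation_rates(ref, RelaxConstants(750.0))
        for col, refval in (("R1", r1_ref), ("R2", r2_ref), ("hetNOE", eta_ref)):
            rel_dev = np.abs(rates[col] / refval - 1.0)
            assert rel_dev.max() < 0.05, (col, rates[col].tolist(), refval)
        assert (rates["R1_err"] > 0).all()
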