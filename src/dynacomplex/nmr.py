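"""Chemical-shift perturbations and 15N backbone relaxation.

Experimental side: amide CSPs with the standard 0.154 nitrogen
weighting, normalized CSP sums across titrations, and single-exponential
fits of relaxation decays.

Simulation side: back-calculation of R1, R2, and the steady-state
heteronuclear NOE from backbone N-H bond-vector trajectories. The
orientational correlation function C_i(t) = <P2(mu(t).mu(0))> is
fitted with a triple exponential whose analytic cosine transform gives
the spectral density J(omega) = 2 sum_k a_k tau_k / (1 + (omega tau_k)^2);
the rates follow from the dipolar (N-H, r = 0.1041 nm) and CSA
(delta = -170 ppm) interactions at the spectrometer field. Uncertainties
use block averaging over 10 non-overlapping trajectory windows.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .config import GAMMA_H, GAMMA_N, HBAR, MU_0, larmor_frequencies

NITROGEN_WEIGHT = 0.154   # 15N shift weighting in the combined amide CSP
R_NH_NM = 0.1041          # amide N-H bond length, nm
DELTA_CSA_PPM = -170.0    # 15N chemical shift anisotropy, ppm


# ---------------------------------------------------------------------------
# chemical shift perturbations
# ---------------------------------------------------------------------------

def compute_csp(free: pd.DataFrame, bound: pd.DataFrame) -> pd.DataFrame:
    """Combined amide CSP per residue between two titration points.

    Inputs need columns ``residue``, ``delta_H_ppm``, ``delta_N_ppm``.
    Returns residue, d_H, d_N, and csp = sqrt(dH^2 + (0.154 dN)^2);
    residues present in only one state are reported in
    ``attrs['missing_residues']`` and never imputed.
    """
    f = free.set_index("residue")
    b = bound.set_index("residue")
    shared = f.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared residues between the two states")
    d_h = (b.loc[shared, "delta_H_ppm"] - f.loc[shared, "delta_H_ppm"]).to_numpy()
    d_n = (b.loc[shared, "delta_N_ppm"] - f.loc[shared, "delta_N_ppm"]).to_numpy()
    out = pd.DataFrame({
        "residue": shared.to_numpy(),
        "d_H_ppm": d_h,
        "d_N_ppm": d_n,
        "csp_ppm": np.sqrt(d_h ** 2 + (NITROGEN_WEIGHT * d_n) ** 2),
    })
    out.attrs["missing_residues"] = sorted(
        set(f.index).symmetric_difference(b.index))
    return out


def normalized_csp_sum(variant_csp: pd.DataFrame,
                       wt_replicate_csps: list[pd.DataFrame]) -> tuple[float, float]:
    """Ratio of summed CSPs of a variant to the wild-type reference.

    Sums run over the residues shared by the variant and all wild-type
    replicate titrations (recorded at the same molar ratio). The error
    is propagated from the spread of the replicate wild-type sums:
    sigma_ratio = ratio * SE(wt sums) / mean(wt sums).
    """
    common = variant_csp["residue"]
    for rep in wt_replicate_csps:
        common = common[common.isin(rep["residue"])]
    common = common.to_numpy()
    if common.size == 0:
        raise ValueError("no residues shared between variant and reference")
    v_sum = variant_csp.set_index("residue").loc[common, "csp_ppm"].sum()
    wt_sums = np.array([rep.set_index("residue").loc[common, "csp_ppm"].sum()
                        for rep in wt_replicate_csps])
    wt_mean = wt_sums.mean()
    if wt_mean == 0:
        raise ZeroDivisionError("wild-type CSP sum is zero; ratio undefined")
    ratio = float(v_sum / wt_mean)
    rel_err = wt_sums.std(ddof=1) / np.sqrt(len(wt_sums)) / wt_mean \
        if len(wt_sums) > 1 else 0.0
    return ratio, ratio * float(rel_err)


def hetnoe_from_intensities(saturated, unsaturated) -> np.ndarray:
    """Steady-state NOE as the saturated/unsaturated intensity ratio."""
    return np.asarray(saturated, float) / np.asarray(unsaturated, float)


# ---------------------------------------------------------------------------
# relaxation decay fitting
# ---------------------------------------------------------------------------

class ExponentialDecayFit(BaseEstimator):
    """Single-exponential fit I(t) = I0 exp(-R t) of a relaxation decay.

    Replicate delays are used as independent points. Fitted attributes:
    ``rate_`` (1/s), ``rate_se_``, ``i0_``, ``i0_se_``,
    ``nondecaying_`` (95% CI of the rate includes 0).
    """

    def fit(self, delays, intensities):
        t = np.asarray(delays, dtype=float)
        y = np.asarray(intensities, dtype=float)
        if len(np.unique(t)) < 3:
            raise ValueError("need >= 3 distinct delays")
        span = t.max() - t.min()
        y0 = y[np.argmin(t)]
        r0 = max(1.0 / span, 1e-6)
        if y0 > 0 and y[np.argmax(t)] > 0 and y0 > y[np.argmax(t)]:
            r0 = np.log(y0 / y[np.argmax(t)]) / span
        popt, pcov = optimize.curve_fit(
            lambda tt, i0, r: i0 * np.exp(-r * tt), t, y, p0=[y0, r0],
            maxfev=20000)
        perr = np.sqrt(np.diag(pcov))
        self.i0_, self.rate_ = popt
        self.i0_se_, self.rate_se_ = perr
        # flagged when the 95% CI includes zero or the decay over the
        # sampled span is negligible
        self.nondecaying_ = bool(self.rate_ - 1.96 * self.rate_se_ <= 0
                                 or self.rate_ * span < 1e-6)
        if self.nondecaying_:
            warnings.warn("relaxation decay is consistent with a zero rate",
                          stacklevel=2)
        return self

    def predict(self, delays):
        return self.i0_ * np.exp(-self.rate_ * np.asarray(delays, float))


def fit_exponential_decay(delays, intensities) -> ExponentialDecayFit:
    return ExponentialDecayFit().fit(delays, intensities)


# ---------------------------------------------------------------------------
# N-H vector trajectories and orientational correlation
# ---------------------------------------------------------------------------

@dataclass
class NHVectorTrajectory:
    """Per-residue amide N-H unit-vector time series.

    vectors: (n_residues, n_steps, 3), unit norm; dt in ps;
    residues: 1-based residue indices.
    """

    vectors: np.ndarray
    dt: float  # ps
    residues: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise ValueError("vectors must have shape (n_residues, n_steps, 3)")
        norms = np.linalg.norm(self.vectors, axis=2)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("N-H vectors must be unit length (|mu| = 1 +/- 1e-6)")
        if self.dt <= 0:
            raise ValueError("sampling interval must be > 0 ps")
        if self.residues is None:
            self.residues = np.arange(1, self.vectors.shape[0] + 1)
        self.residues = np.asarray(self.residues)

    @property
    def n_steps(self) -> int:
        return self.vectors.shape[1]


def nh_vectors_from_frames(frames, chain=None) -> NHVectorTrajectory:
    """Extract amide N-H unit vectors from trajectory frames.

    Pairs each backbone N with the amide H ("H" or "HN") of the same
    residue; residues without both atoms are skipped.
    """
    atoms = frames.atoms
    sel = atoms if chain is None else atoms[atoms["chain"] == chain]
    vecs, resids = [], []
    for resid, grp in sel.groupby("resid"):
        idx_n = grp.index[(grp["name"] == "N")]
        idx_h = grp.index[grp["name"].isin(["H", "HN"])]
        if len(idx_n) == 1 and len(idx_h) == 1:
            v = frames.coords[:, idx_h[0], :] - frames.coords[:, idx_n[0], :]
            v = v / np.linalg.norm(v, axis=1, keepdims=True)
            vecs.append(v)
            resids.append(resid)
    if not vecs:
        raise ValueError("no complete amide N-H pairs found")
    return NHVectorTrajectory(np.stack(vecs), frames.frame_interval,
                              np.asarray(resids))


def orientation_correlation(traj: NHVectorTrajectory, residue_index: int,
                            max_lag: int) -> np.ndarray:
    """C(t) = <P2(mu(t0+t) . mu(t0))> for one residue, lags 0..max_lag.

    Computed via FFT correlations of the six independent products
    mu_a mu_b, exploiting (mu.mu')^2 = sum_ab (mu_a mu_b)(mu'_a mu'_b).
    """
    if max_lag > traj.n_steps // 2:
        raise ValueError("max_lag must not exceed half the trajectory length")
    mu = traj.vectors[residue_index]
    n = mu.shape[0]
    pairs = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
    weights = [1.0, 1.0, 1.0, 2.0, 2.0, 2.0]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    acc = np.zeros(max_lag + 1)
    for (a, b), w in zip(pairs, weights):
        q = mu[:, a] * mu[:, b]
        fq = np.fft.rfft(q, nfft)
        corr = np.fft.irfft(fq * np.conj(fq), nfft)[:max_lag + 1]
        acc += w * corr
    counts = n - np.arange(max_lag + 1)
    dot_sq = acc / counts
    return 1.5 * dot_sq - 0.5


# ---------------------------------------------------------------------------
# spectral density from a multi-exponential fit of C(t)
# ---------------------------------------------------------------------------

@dataclass
class SpectralModel:
    """Multi-exponential model of C(t); J via the analytic transform."""

    amplitudes: np.ndarray  # a_k >= 0
    timescales: np.ndarray  # tau_k, ns
    fallback_biexp: bool = False

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.timescales = np.asarray(self.timescales, dtype=float)
        if (self.amplitudes < -1e-9).any() or (self.timescales <= 0).any():
            raise ValueError("amplitudes must be >= 0 and timescales > 0")

    def correlation(self, t_ns):
        t = np.asarray(t_ns, dtype=float)
        return np.sum(self.amplitudes[:, None]
                      * np.exp(-t[None, :] / self.timescales[:, None]), axis=0)

    def spectral_density(self, omega: float) -> float:
        """J(omega) in seconds; omega in rad/s (tau stored in ns)."""
        tau_s = self.timescales * 1e-9
        return float(np.sum(2.0 * self.amplitudes * tau_s
                            / (1.0 + (omega * tau_s) ** 2)))


class SpectralDensityFit(BaseEstimator):
    """Constrained triple-exponential fit of an orientational C(t).

    Amplitudes are bounded below by 0 and their sum above by C at the
    first lag (plus 1e-6), absorbing unresolved sub-sampling librational
    decay. ``fit_window`` limits the lags used (default: all provided;
    back-calculation pipelines pass one-tenth of the trajectory length).
    On non-convergence the fit falls back to a bi-exponential and flags
    it.

    Timescales are bounded above by ``tau_max_factor`` times the fitted
    lag span: components slower than the observation window are not
    identifiable from C(t) and would otherwise inflate J(0) without
    bound. Components converging to the same timescale (within 1% in
    log space) are merged.

    Fitted attributes: ``model_`` (:class:`SpectralModel`),
    ``residual_rms_``.
    """

    def __init__(self, n_exp: int = 3, fit_window: int | None = None,
                 tau_max_factor: float = 1.0):
        self.n_exp = n_exp
        self.fit_window = fit_window
        self.tau_max_factor = tau_max_factor

    def fit(self, t_ns, c):
        t = np.asarray(t_ns, dtype=float)
        c = np.asarray(c, dtype=float)
        if self.fit_window is not None:
            t, c = t[:self.fit_window], c[:self.fit_window]
        if len(t) < 20:
            raise ValueError("need >= 20 lags to fit the spectral model")
        c0 = c[0]
        model = self._try_fit(t, c, self.n_exp, c0, self.tau_max_factor)
        fallback = False
        if model is None and self.n_exp >= 3:
            model = self._try_fit(t, c, 2, c0, self.tau_max_factor)
            fallback = True
        if model is None:
            raise RuntimeError("multi-exponential fit of C(t) failed to converge")
        model = self._merge_degenerate(model)
        model.fallback_biexp = fallback
        self.model_ = model
        self.residual_rms_ = float(np.sqrt(np.mean(
            (model.correlation(t) - c) ** 2)))
        return self

    @staticmethod
    def _merge_degenerate(model: SpectralModel) -> SpectralModel:
        amps = model.amplitudes.copy()
        taus = model.timescales.copy()
        for i in range(len(taus)):
            for j in range(i + 1, len(taus)):
                if amps[j] > 0 and amps[i] > 0 and \
                        abs(np.log(taus[i] / taus[j])) < 0.01:
                    amps[i] += amps[j]
                    amps[j] = 0.0
        return SpectralModel(amps, taus, fallback_biexp=model.fallback_biexp)

    @staticmethod
    def _try_fit(t, c, k, c0, tau_max_factor):
        t_pos = t[t > 0]
        span = t_pos.max() if t_pos.size else 1.0
        tau_max = tau_max_factor * span
        tau_min = max(t_pos.min() / 10.0, 1e-6) if t_pos.size else 1e-6
        tau0 = np.geomspace(max(t_pos.min(), tau_min * 10), span / 3.0, k)
        a0 = np.full(k, max(c0, 0.1) / k)
        p0 = np.concatenate([a0, np.log(tau0)])
        lo = np.concatenate([np.zeros(k), np.full(k, np.log(tau_min))])
        hi = np.concatenate([np.full(k, max(c0, 1.0) + 1e-6),
                             np.full(k, np.log(tau_max))])

        def resid(p):
            amps, taus = p[:k], np.exp(p[k:])
            model = np.sum(amps[:, None] * np.exp(-t[None, :] / taus[:, None]),
                           axis=0)
            # soft penalty keeps sum(a) <= C(first lag)
            overshoot = max(amps.sum() - (c0 + 1e-6), 0.0)
            return np.concatenate([model - c, [100.0 * overshoot]])

        res = optimize.least_squares(resid, p0, bounds=(lo, hi), max_nfev=40000)
        if not res.success:
            return None
        return SpectralModel(res.x[:k], np.exp(res.x[k:]))


def fit_spectral_model(t_ns, c, **kwargs) -> SpectralModel:
    return SpectralDensityFit(**kwargs).fit(t_ns, c).model_


# ---------------------------------------------------------------------------
# relaxation rates
# ---------------------------------------------------------------------------

@dataclass
class RelaxConstants:
    """Field-dependent constants of the dipolar + CSA relaxation formulas."""

    spectrometer_mhz: float = 750.0
    r_nh: float = R_NH_NM          # nm
    delta_csa_ppm: float = DELTA_CSA_PPM

    def __post_init__(self) -> None:
        self.omega_h, self.omega_n = larmor_frequencies(self.spectrometer_mhz)
        r_m = self.r_nh * 1e-9
        self.dipolar = (1.0 / 20.0) * (MU_0 / (4.0 * np.pi)) ** 2 * HBAR ** 2 \
            * GAMMA_H ** 2 * GAMMA_N ** 2 / r_m ** 6           # s^-2
        self.csa = (1.0 / 15.0) * self.omega_n ** 2 \
            * (self.delta_csa_ppm * 1e-6) ** 2                 # s^-2
        if self.dipolar <= 0 or self.csa <= 0:
            raise ValueError("relaxation constants must be positive")


FIELD_PRESETS = {600.0: RelaxConstants(600.0), 750.0: RelaxConstants(750.0)}


def relaxation_rates(model: SpectralModel,
                     constants: RelaxConstants) -> tuple[float, float, float]:
    """R1 (1/s), R2 (1/s), and hetNOE eta from a spectral model."""
    j = model.spectral_density
    wh, wn = constants.omega_h, constants.omega_n
    d, c = constants.dipolar, constants.csa
    r1 = d * (j(wh - wn) + 3.0 * j(wn) + 6.0 * j(wh + wn)) + c * j(wn)
    r2 = 0.5 * d * (4.0 * j(0.0) + j(wh - wn) + 3.0 * j(wn) + 6.0 * j(wh)
                    + 6.0 * j(wh + wn)) \
        + (c / 6.0) * (4.0 * j(0.0) + 3.0 * j(wn))
    eta = 1.0 + d * (GAMMA_H / GAMMA_N) / r1 * (6.0 * j(wh + wn) - j(wh - wn))
    return float(r1), float(r2), float(eta)


# ---------------------------------------------------------------------------
# block-averaged back-calculation pipeline
# ---------------------------------------------------------------------------

def block_uncertainty(traj: NHVectorTrajectory, observable, n_blocks: int = 10):
    """Observable per residue with block-averaged mean and sigma_M.

    ``observable(block_traj, residue_index)`` returns a 1-D array of
    observables for one residue on one block. The trajectory is split
    into ``n_blocks`` equal non-overlapping windows;
    sigma_M = sqrt((<O^2> - <O>^2) / N).
    """
    n = traj.n_steps
    m = n // n_blocks
    if m < 2:
        raise ValueError("blocks too short for the requested observable")
    n_res = traj.vectors.shape[0]
    means, sigmas = [], []
    for i in range(n_res):
        vals = np.array([
            observable(NHVectorTrajectory(traj.vectors[:, k * m:(k + 1) * m, :],
                                          traj.dt, traj.residues), i)
            for k in range(n_blocks)])
        means.append(vals.mean(axis=0))
        sigmas.append(np.sqrt(np.maximum(
            (vals ** 2).mean(axis=0) - vals.mean(axis=0) ** 2, 0.0) / n_blocks))
    return np.asarray(means), np.asarray(sigmas)


def back_calculate_rates(traj: NHVectorTrajectory,
                         spectrometer_mhz: float = 750.0,
                         max_lag: int | None = None,
                         n_blocks: int = 10) -> pd.DataFrame:
    """Full pipeline vectors -> C(t) -> J(omega) -> (R1, R2, hetNOE).

    Rates are computed per block (10 non-overlapping windows by
    default) and reported as block means with sigma_M uncertainties.
    ``max_lag`` defaults to one-tenth of the block length.
    """
    constants = RelaxConstants(spectrometer_mhz)
    block_len = traj.n_steps // n_blocks

    def rates_for_block(block: NHVectorTrajectory, i: int) -> np.ndarray:
        lag = max_lag if max_lag is not None else block.n_steps // 10
        lag = min(lag, block.n_steps // 2)
        c = orientation_correlation(block, i, lag)
        t_ns = np.arange(lag + 1) * block.dt * 1e-3
        model = fit_spectral_model(t_ns, c)
        return np.array(relaxation_rates(model, constants))

    if block_len // 2 < 20:
        raise ValueError("trajectory too short for block-wise back-calculation")
    means, sigmas = block_uncertainty(traj, rates_for_block, n_blocks=n_blocks)
    return pd.DataFrame({
        "residue": traj.residues,
        "R1": means[:, 0], "R1_err": sigmas[:, 0],
        "R2": means[:, 1], "R2_err": sigmas[:, 1],
        "hetNOE": means[:, 2], "hetNOE_err": sigmas[:, 2],
    })
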