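"""Binding analysis for a charged disordered chain titrated with a folded domain.

Single-molecule FRET titrations report the mean transfer efficiency <E> of
the labeled chain as a function of total ligand (folded-domain)
concentration. The 1:1 model treats <E> as a two-state population average
with apparent dissociation constant K_D,app; the sequential 1:N model
resolves complexes of increasing stoichiometry, each contributing a fixed
fraction alpha_i of the saturation change in <E>. Salt dependence of
K_D,app is analysed with the Lohman-Record formalism: the slope of
log10 K_D vs log10 ionic strength counts the ions released on binding.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .config import CorrectionFactors

#: Relative transfer-efficiency increments of the 1:i complexes
#: (i = 0..4) from coarse-grained simulations of multivalent binding:
#: the first bound domain produces ~80% of the saturation change, the
#: second and third ~11% and ~7% more.
DEFAULT_ALPHA = (0.0, 0.80, 0.91, 0.98, 1.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TitrationSeries:
    """One titration: total concentrations and observed mean efficiencies."""

    g_tot: np.ndarray        # total ligand (folded domain), mol/L
    p_tot: np.ndarray        # total chain (labeled + unlabeled), mol/L
    mean_e: np.ndarray
    se_e: np.ndarray | None = None
    ionic_strength: float | None = None  # mol/L, total incl. buffer
    mode: str = "excess"     # "excess" or "stoichiometric"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.g_tot = np.asarray(self.g_tot, dtype=float)
        self.p_tot = np.broadcast_to(np.asarray(self.p_tot, dtype=float),
                                     self.g_tot.shape).copy()
        self.mean_e = np.asarray(self.mean_e, dtype=float)
        if self.se_e is not None:
            self.se_e = np.asarray(self.se_e, dtype=float)
        if (self.g_tot < 0).any() or (self.p_tot < 0).any():
            raise ValueError("concentrations must be >= 0")
        if not np.isfinite(self.mean_e).all():
            raise ValueError("mean transfer efficiencies must be finite")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"g_tot_M": self.g_tot, "p_tot_M": self.p_tot,
                           "mean_E": self.mean_e})
        if self.se_e is not None:
            df["se_E"] = self.se_e
        return df


@dataclass
class SaltSeries:
    """Apparent K_D of the 1:1 complex at several ionic strengths."""

    ionic_strength: np.ndarray  # mol/L, total including buffer contribution
    kd: np.ndarray              # mol/L
    se_kd: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ionic_strength = np.asarray(self.ionic_strength, dtype=float)
        self.kd = np.asarray(self.kd, dtype=float)
        if self.se_kd is not None:
            self.se_kd = np.asarray(self.se_kd, dtype=float)
        if (self.ionic_strength <= 0).any():
            raise ValueError("ionic strengths must be > 0")
        if (self.kd <= 0).any():
            raise ValueError("dissociation constants must be > 0")


# ---------------------------------------------------------------------------
# burst-level transfer efficiencies
# ---------------------------------------------------------------------------

def burst_efficiencies(bursts: pd.DataFrame,
                       corrections: CorrectionFactors | None = None,
                       s_window: tuple[float, float] = (0.2, 0.75),
                       n_acceptor_excitation: np.ndarray | None = None):
    """Corrected transfer efficiencies E = nA/(nA + gamma nD) per burst.

    ``bursts`` needs columns ``n_A`` and ``n_D`` (raw photon counts);
    an optional ``S`` column (stoichiometry ratio under alternating
    excitation) triggers selection inside ``s_window``. Corrections are
    applied as background subtraction per channel, donor-crosstalk and
    acceptor direct-excitation subtraction from the acceptor counts, and
    a gamma factor on the donor counts. Bursts with no photons left
    after correction are dropped (count reported in attrs).
    """
    corr = corrections or CorrectionFactors()
    n_a = bursts["n_A"].to_numpy(dtype=float)
    n_d = bursts["n_D"].to_numpy(dtype=float)
    if (n_a < 0).any() or (n_d < 0).any():
        raise ValueError("photon counts must be >= 0")
    n_d_c = n_d - corr.background_donor
    n_a_c = n_a - corr.background_acceptor - corr.crosstalk * n_d_c
    if n_acceptor_excitation is not None:
        n_a_c = n_a_c - corr.direct_excitation * np.asarray(n_acceptor_excitation, float)
    total = n_a_c + corr.gamma * n_d_c
    keep = total > 0
    n_dropped = int((~keep).sum())
    if "S" in bursts.columns:
        s = bursts["S"].to_numpy(dtype=float)
        keep &= (s > s_window[0]) & (s < s_window[1])
    out = pd.DataFrame({
        "n_A": n_a[keep], "n_D": n_d[keep],
        "E": n_a_c[keep] / total[keep],
    })
    if "S" in bursts.columns:
        out["S"] = bursts["S"].to_numpy(dtype=float)[keep]
    out.attrs["n_dropped_empty"] = n_dropped
    out.attrs["n_selected"] = int(keep.sum())
    return out


# ---------------------------------------------------------------------------
# Gaussian decomposition of transfer-efficiency histograms
# ---------------------------------------------------------------------------

class GaussianPeakFit(BaseEstimator):
    """Gaussian mixture fit to a (binned) transfer-efficiency histogram.

    Parameters
    ----------
    n_peaks : number of Gaussian components.
    bin_width : histogram bin width in efficiency units.
    hist_range : histogram range; must accommodate correction overshoot
        slightly outside [0, 1].

    Fitted attributes: ``means_``, ``sigmas_``, ``areas_`` (normalized to
    sum to 1, sorted by ascending mean), ``degenerate_`` (area < 1e-3).
    """

    def __init__(self, n_peaks: int = 1, bin_width: float = 0.02,
                 hist_range: tuple[float, float] = (-0.1, 1.1)):
        self.n_peaks = n_peaks
        self.bin_width = bin_width
        self.hist_range = hist_range

    def fit(self, e_values, y=None):
        e = np.asarray(e_values, dtype=float)
        nbin = int(round((self.hist_range[1] - self.hist_range[0]) / self.bin_width))
        counts, edges = np.histogram(e, bins=nbin, range=self.hist_range)
        centers = 0.5 * (edges[:-1] + edges[1:])
        self._fit_binned(centers, counts, samples=e)
        return self

    def fit_histogram(self, centers, counts):
        self._fit_binned(np.asarray(centers, float), np.asarray(counts, float))
        return self

    @staticmethod
    def _fit_k(centers, counts, amp0, mu0, sig0):
        """Poisson-weighted Gaussian-mixture fit; returns chi-square."""
        k = len(mu0)
        w = 1.0 / np.sqrt(np.maximum(counts, 1.0))

        def model(p):
            amps, mus, sigs = p[:k], p[k:2 * k], p[2 * k:]
            return np.sum(amps[:, None] * np.exp(
                -0.5 * ((centers[None, :] - mus[:, None]) / sigs[:, None]) ** 2),
                axis=0)

        p0 = np.concatenate([amp0, mu0, sig0])
        lo = np.concatenate([np.zeros(k), np.full(k, centers[0]),
                             np.full(k, 1e-4)])
        hi = np.concatenate([np.full(k, np.inf), np.full(k, centers[-1]),
                             np.full(k, 2.0)])
        res = optimize.least_squares(lambda p: (model(p) - counts) * w, p0,
                                     bounds=(lo, hi), max_nfev=40000)
        if not res.success:
            raise RuntimeError("Gaussian peak fit did not converge: "
                               f"{res.message}; final cost {res.cost:.3g}")
        return (res.x[:k], res.x[k:2 * k], res.x[2 * k:], 2.0 * res.cost,
                model(res.x) - counts)

    def _fit_binned(self, centers, counts, samples=None):
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        if int((counts > 0).sum()) <= 3 * self.n_peaks:
            raise ValueError("histogram has too few populated bins for the "
                             f"requested {self.n_peaks} peaks")
        k = self.n_peaks
        if samples is not None and k > 1:
            from sklearn.cluster import KMeans
            km = KMeans(n_clusters=k, n_init=5, random_state=0).fit(
                samples.reshape(-1, 1))
            mu0 = np.sort(km.cluster_centers_.ravel())
        else:
            qs = np.linspace(0.5 / k, 1 - 0.5 / k, k)
            cdf = np.cumsum(counts) / counts.sum()
            mu0 = np.interp(qs, cdf, centers)
        sig0 = np.full(k, max(0.03, (centers[-1] - centers[0]) / (8 * k)))
        amp0 = np.full(k, counts.max() / k)
        amps, mus, sigs, chi2, resid = self._fit_k(centers, counts, amp0, mu0,
                                                   sig0)
        # overfit guard: a component is kept only if its 3 parameters buy a
        # significant chi-square reduction (likelihood-ratio, p ~ 0.01)
        dchi2_crit = 11.3
        dropped: list[tuple[float, float]] = []
        while len(mus) > 1:
            smallest = int(np.argmin(amps * sigs))
            keep = np.ones(len(mus), dtype=bool)
            keep[smallest] = False
            try:
                trial = self._fit_k(centers, counts, amps[keep], mus[keep],
                                    sigs[keep])
            except RuntimeError:
                break
            if trial[3] - chi2 < dchi2_crit:  # extra component was not needed
                dropped.append((mus[smallest], sigs[smallest]))
                amps, mus, sigs, chi2, resid = trial
            else:
                break
        areas = amps * sigs * np.sqrt(2 * np.pi)
        total = areas.sum()
        # re-attach dropped components with zero area so the output always
        # carries n_peaks entries
        for mu_d, sig_d in dropped:
            mus = np.append(mus, mu_d)
            sigs = np.append(sigs, sig_d)
            areas = np.append(areas, 0.0)
        order = np.argsort(mus)
        self.means_ = mus[order]
        self.sigmas_ = sigs[order]
        self.areas_ = areas[order] / total
        self.degenerate_ = self.areas_ < 1e-3
        self.residual_ = resid
        return self


def fit_gaussian_peaks(e_values, n_peaks: int = 1, **kwargs):
    """Functional wrapper over :class:`GaussianPeakFit` on burst E values."""
    f = GaussianPeakFit(n_peaks=n_peaks, **kwargs).fit(e_values)
    return f.means_, f.sigmas_, f.areas_


# ---------------------------------------------------------------------------
# binding models
# ---------------------------------------------------------------------------

def bound_fraction_1to1(kd: float, g_tot, p_tot):
    """Fraction of chain bound in the 1:1 model (exact quadratic root).

    Uses the subtraction-free form 2g/(s + sqrt(s^2 - 4 g p)) with
    s = g + K + p, stable down to the excess-titration limit p -> 0.
    """
    g = np.asarray(g_tot, dtype=float)
    p = np.asarray(p_tot, dtype=float)
    s = g + kd + p
    disc = np.sqrt(np.maximum(s * s - 4.0 * g * p, 0.0))
    return np.where(s + disc > 0, 2.0 * g / (s + disc), 0.0)


def predict_mean_e_1to1(kd: float, e0: float, de_sat: float, g_tot, p_tot):
    """Mean transfer efficiency of the 1:1 binding model."""
    return e0 + de_sat * bound_fraction_1to1(kd, g_tot, p_tot)


def solve_sequential_populations(kds, g_tot: float, p_tot: float):
    """Populations of a sequential 1:N binding equilibrium.

    Macroscopic dissociation constants ``kds[i-1]`` = K_Di govern the
    step PG_(i-1) + G <-> PG_i. Solves the ligand mass balance
    g_tot = [G] + sum_i i p_i p_tot for free [G] by bracketed root
    finding on [0, g_tot] and returns (p, free_g, free_p, complexes)
    where p has length N+1 (p[0] = free chain fraction) and complexes
    are the [PG_i] concentrations for i = 1..N.
    """
    kds = np.asarray(kds, dtype=float)
    if (kds <= 0).any():
        raise ValueError("all K_D values must be > 0")
    n = len(kds)
    i_arr = np.arange(n + 1, dtype=float)

    def populations(free_g: float) -> np.ndarray:
        # c_i = prod_{j<=i} [G]/K_j, p_i = c_i / sum(c); computed in log space
        with np.errstate(divide="ignore"):
            logc = np.concatenate([[0.0], np.cumsum(np.log(free_g) - np.log(kds))]) \
                if free_g > 0 else np.concatenate([[0.0], np.full(n, -np.inf)])
        logc -= logc.max()
        c = np.exp(logc)
        return c / c.sum()

    def residual(free_g: float) -> float:
        p = populations(free_g)
        return free_g + p_tot * float(i_arr @ p) - g_tot

    if g_tot <= 0:
        p = np.zeros(n + 1)
        p[0] = 1.0
        return p, 0.0, p_tot, np.zeros(n)
    lo, hi = 0.0, g_tot
    if residual(lo) > 0 or residual(hi) < 0:
        raise RuntimeError("mass-balance residual has no sign change on "
                           "[0, g_tot]; invalid inputs")
    free_g = optimize.brentq(residual, lo, hi, xtol=1e-30, rtol=1e-15)
    p = populations(free_g)
    free_p = p[0] * p_tot
    complexes = p[1:] * p_tot
    return p, free_g, free_p, complexes


def predict_mean_e_multistate(kds, alpha, e0: float, de_sat: float,
                              g_tot, p_tot):
    """Mean efficiency of the sequential model: sum_i p_i (alpha_i dE + E0)."""
    alpha = np.asarray(alpha, dtype=float)
    if len(alpha) != len(kds) + 1:
        raise ValueError("alpha profile must have length N+1")
    g = np.atleast_1d(np.asarray(g_tot, dtype=float))
    p = np.broadcast_to(np.atleast_1d(np.asarray(p_tot, dtype=float)), g.shape)
    out = np.empty_like(g)
    for j, (gj, pj) in enumerate(zip(g, p)):
        pops, *_ = solve_sequential_populations(kds, gj, pj)
        out[j] = float(pops @ (alpha * de_sat + e0))
    return out if np.ndim(g_tot) else float(out[0])


def validate_alpha(alpha) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float)
    if alpha[0] != 0.0 or abs(alpha[-1] - 1.0) > 1e-12:
        raise ValueError("alpha profile must start at 0 and end at 1")
    if (np.diff(alpha) < -1e-12).any():
        raise ValueError("alpha profile must be non-decreasing")
    return alpha


# ---------------------------------------------------------------------------
# titration fitting
# ---------------------------------------------------------------------------

class TitrationBindingModel(BaseEstimator):
    """Weighted least-squares fit of a FRET titration.

    Parameters
    ----------
    model : "1:1" for the two-state quadratic model, "1:N" for the
        sequential multistate model (N = len(alpha) - 1) with the
        alpha profile fixed from input.
    alpha : relative efficiency increments (length N+1); defaults to
        the coarse-grained 1:4 profile for the multistate model.

    Fitted attributes: ``kd_`` (float for 1:1, array for 1:N), ``e0_``,
    ``de_sat_``, matching ``*_se_``, ``cov_``, and for the multistate
    model ``overparameterized_`` flags (SE exceeds the estimate).
    """

    def __init__(self, model: str = "1:1", alpha=None):
        self.model = model
        self.alpha = alpha

    def fit(self, series: TitrationSeries):
        g, p, e = series.g_tot, series.p_tot, series.mean_e
        se = series.se_e if series.se_e is not None else np.full_like(e, 1.0)
        se = np.where(se > 0, se, np.nanmax(se[se > 0]) if (se > 0).any() else 1.0)
        e0_guess = e[np.argmin(g)]
        de_guess = e[np.argmax(g)] - e0_guess
        if de_guess == 0:
            de_guess = 0.1
        half = e0_guess + 0.5 * de_guess
        kd_guess = float(np.interp(half, np.sort(e), g[np.argsort(e)]))
        kd_guess = max(kd_guess, 1e-12)

        if self.model == "1:1":
            if len(g) < 4:
                raise ValueError("need >= 4 titration points for the 1:1 fit")

            def f(x, kd, e0, de):
                return predict_mean_e_1to1(kd, e0, de, x[0], x[1])

            popt, pcov = optimize.curve_fit(
                f, np.vstack([g, p]), e, sigma=se, absolute_sigma=series.se_e is not None,
                p0=[kd_guess, e0_guess, de_guess],
                bounds=([1e-15, -1.0, -2.0], [1.0, 2.0, 2.0]), maxfev=20000)
            perr = np.sqrt(np.diag(pcov))
            self.kd_, self.e0_, self.de_sat_ = popt
            self.kd_se_, self.e0_se_, self.de_sat_se_ = perr
            self.cov_ = pcov
        elif self.model in ("1:N", "multistate", "1:4"):
            alpha = validate_alpha(self.alpha if self.alpha is not None
                                   else DEFAULT_ALPHA)
            n = len(alpha) - 1
            if len(g) < n + 2:
                raise ValueError("fewer titration points than parameters")

            def f(x, *params):
                kds = 10.0 ** np.asarray(params[:n])
                return predict_mean_e_multistate(kds, alpha, params[n],
                                                 params[n + 1], x[0], x[1])

            # anti-cooperative ladder as the starting point
            p0 = list(np.log10(kd_guess * 4.0 ** np.arange(n))) + [e0_guess, de_guess]
            popt, pcov = optimize.curve_fit(
                f, np.vstack([g, p]), e, sigma=se, absolute_sigma=series.se_e is not None,
                p0=p0, maxfev=40000)
            perr = np.sqrt(np.diag(pcov))
            self.kd_ = 10.0 ** popt[:n]
            # SE on Kd from the log-space covariance
            self.kd_se_ = self.kd_ * np.log(10.0) * perr[:n]
            self.e0_, self.de_sat_ = popt[n], popt[n + 1]
            self.e0_se_, self.de_sat_se_ = perr[n], perr[n + 1]
            self.cov_ = pcov
            self.alpha_ = alpha
            self.overparameterized_ = self.kd_se_ > self.kd_
        else:
            raise ValueError(f"unknown binding model {self.model!r}")
        self.n_points_ = len(g)
        return self

    def predict(self, g_tot, p_tot):
        if self.model == "1:1":
            return predict_mean_e_1to1(self.kd_, self.e0_, self.de_sat_, g_tot, p_tot)
        return predict_mean_e_multistate(self.kd_, self.alpha_, self.e0_,
                                         self.de_sat_, g_tot, p_tot)


def fit_titration(series: TitrationSeries, model: str = "1:1", alpha=None):
    return TitrationBindingModel(model=model, alpha=alpha).fit(series)


def fit_population_curves(g_tot, populations, p_tot, se=None):
    """Joint fit of subpopulation curves p_i(g_tot) with shared K_Di.

    ``populations`` is (n_points, N+1) with rows summing to ~1 (column 0
    is the free chain). Returns (kds, kd_ses); unidentifiable constants
    (flat curves) come back with infinite SE.
    """
    g_tot = np.asarray(g_tot, dtype=float)
    pops = np.asarray(populations, dtype=float)
    if not np.allclose(pops.sum(axis=1), 1.0, atol=0.05):
        raise ValueError("population fractions must sum to ~1 per condition")
    n = pops.shape[1] - 1
    sig = np.asarray(se, dtype=float) if se is not None else np.ones_like(pops)

    def residuals(logk):
        kds = 10.0 ** logk
        model = np.empty_like(pops)
        for j, gj in enumerate(g_tot):
            model[j], *_ = solve_sequential_populations(kds, gj, float(np.atleast_1d(p_tot)[0])
                                                        if np.ndim(p_tot) == 0 else p_tot[j])
        return ((model - pops) / sig).ravel()

    # initial guess: ladder anchored at the half-depletion point of p_0
    k0 = g_tot[np.argmin(np.abs(pops[:, 0] - 0.5))] or np.median(g_tot)
    x0 = np.log10(np.maximum(k0, 1e-12) * 4.0 ** np.arange(n))
    res = optimize.least_squares(residuals, x0, method="lm", max_nfev=20000)
    jac = res.jac
    dof = max(res.fun.size - n, 1)
    s2 = 2 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        logk_se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        logk_se = np.full(n, np.inf)
    kds = 10.0 ** res.x
    return kds, kds * np.log(10.0) * logk_se


# ---------------------------------------------------------------------------
# salt dependence (Lohman-Record)
# ---------------------------------------------------------------------------

class SaltDependenceModel(BaseEstimator):
    """Counterion-release analysis: log10 K_D vs log10 ionic strength.

    The slope (positive convention: K_D grows with salt) counts the ions
    released upon binding. Weighted linear regression with symmetric
    errors in log K_D propagated as se_kd/kd/ln(10); the confidence
    interval is a t-interval on the regression slope.

    Fitted attributes: ``n_ions_``, ``intercept_``, ``n_ions_se_``,
    ``ci90_`` (slope), ``intercept_se_``.
    """

    def __init__(self, ci_level: float = 0.90):
        self.ci_level = ci_level

    def fit(self, series: SaltSeries):
        if len(np.unique(series.ionic_strength)) < 3:
            raise ValueError("need >= 3 distinct ionic strengths")
        x = np.log10(series.ionic_strength)
        y = np.log10(series.kd)
        if series.se_kd is not None:
            w = 1.0 / (series.se_kd / series.kd / np.log(10.0)) ** 2
        else:
            w = np.ones_like(y)
        sw = w.sum()
        xbar = (w * x).sum() / sw
        ybar = (w * y).sum() / sw
        sxx = (w * (x - xbar) ** 2).sum()
        slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
        intercept = ybar - slope * xbar
        resid = y - (intercept + slope * x)
        dof = len(x) - 2
        s2 = (w * resid ** 2).sum() / dof if dof > 0 else np.nan
        slope_se = np.sqrt(s2 / sxx)
        intercept_se = np.sqrt(s2 * (1.0 / sw + xbar ** 2 / sxx))
        tcrit = stats.t.ppf(0.5 + self.ci_level / 2.0, dof) if dof > 0 else np.nan
        self.n_ions_ = slope
        self.n_ions_se_ = slope_se
        self.ci90_ = (slope - tcrit * slope_se, slope + tcrit * slope_se)
        self.intercept_ = intercept
        self.intercept_se_ = intercept_se
        self.dof_ = dof
        return self

    def predict(self, ionic_strength):
        return 10.0 ** (self.intercept_ + self.n_ions_ * np.log10(ionic_strength))


def fit_salt_dependence(series: SaltSeries, ci_level: float = 0.90):
    return SaltDependenceModel(ci_level=ci_level).fit(series)


def saturated_complex_ligand_charge(z_ligand: float = 9.0, n_bound: int = 4) -> float:
    """Net charge contributed by n bound copies of the charged ligand.

    For the fully loaded 1:4 complex of a +9 folded domain this is +36,
    nearly balancing the -44 chain.
    """
    return z_ligand * n_bound
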