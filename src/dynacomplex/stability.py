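"""Two-state protein stability analysis from circular dichroism data.

Ellipticity is converted to mean-residue-weight units, chemical
(denaturant) and thermal unfolding curves are fitted with linear-baseline
two-state models, and stability changes of variants are estimated from
melting-temperature shifts via
ddG(T) ~ -dH_avg(Tm) * T / (Tm_wt * Tm_mut) * dTm, assuming a
temperature-independent heat capacity change that is itself unchanged
between variants.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .config import R_GAS


@dataclass
class CDCurve:
    """A CD signal versus denaturant concentration or temperature."""

    x: np.ndarray              # mol/L (chemical) or K (thermal)
    signal: np.ndarray         # mdeg or MRW ellipticity
    mode: str = "thermal"      # "thermal" | "chemical"
    se: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if not (np.all(np.diff(self.x) > 0) or np.all(np.diff(self.x) < 0)):
            raise ValueError("x axis must be monotone")
        if self.mode not in ("thermal", "chemical"):
            raise ValueError("mode must be 'thermal' or 'chemical'")


def mrw_convert(mdeg, mw: float, n_residues: int, conc_g_l: float,
                path_cm: float):
    """Mean residue weight ellipticity [theta]_MRW = (MW/(n-1)) mdeg / (10 c d).

    mdeg in millidegrees, MW in Da, c in g/L, d in cm; result in
    deg cm^2 dmol^-1.
    """
    if n_residues <= 1:
        raise ValueError("n_residues must be > 1")
    if conc_g_l <= 0 or path_cm <= 0 or mw <= 0:
        raise ValueError("MW, concentration and path length must be > 0")
    return (mw / (n_residues - 1)) * np.asarray(mdeg, float) / (10.0 * conc_g_l * path_cm)


def two_state_chemical(x, a_n, b_n, a_d, b_d, m, c_m, temperature):
    """Linear-baseline two-state denaturant unfolding curve.

    y = [(a_N x + b_N) + (a_D x + b_D) exp(m (x - c_m)/RT)] /
        [1 + exp(m (x - c_m)/RT)], with m in J/mol/M and R T in J/mol.
    """
    k = np.exp(m * (np.asarray(x, float) - c_m) / (R_GAS * temperature))
    return ((a_n * x + b_n) + (a_d * x + b_d) * k) / (1.0 + k)


def two_state_thermal(t, m_n, y_n, m_d, y_d, dh, t_m):
    """Linear-baseline two-state thermal melting curve (van't Hoff dH in J/mol)."""
    t = np.asarray(t, float)
    k = np.exp(-dh * (1.0 - t / t_m) / (R_GAS * t))
    return ((m_n * t + y_n) + (m_d * t + y_d) * k) / (1.0 + k)


class ChemicalDenaturationFit(BaseEstimator):
    """Two-state fit of a chemical (urea) unfolding curve.

    Fitted attributes: ``a_n_``, ``b_n_``, ``a_d_``, ``b_d_``,
    ``m_kj_`` (kJ/mol/M), ``c_m_`` (mol/L) with ``*_se_`` counterparts,
    and ``transition_in_range_``.
    """

    def __init__(self, temperature: float = 298.15):
        self.temperature = temperature

    def fit(self, curve: CDCurve):
        x, y = curve.x, curve.signal
        if len(x) < 8:
            raise ValueError("need >= 8 points spanning both baselines")
        b_n0, b_d0 = y[np.argmin(x)], y[np.argmax(x)]
        mid = 0.5 * (b_n0 + b_d0)
        c_m0 = float(np.interp(mid, y, x)) if b_d0 != b_n0 else np.median(x)
        p0 = [0.0, b_n0, 0.0, b_d0, 5e3, c_m0]
        popt, pcov = optimize.curve_fit(
            lambda xx, *p: two_state_chemical(xx, *p, self.temperature),
            x, y, p0=p0, sigma=curve.se, absolute_sigma=curve.se is not None,
            maxfev=40000)
        perr = np.sqrt(np.diag(pcov))
        (self.a_n_, self.b_n_, self.a_d_, self.b_d_, m_j, self.c_m_) = popt
        self.m_kj_ = m_j / 1e3
        (self.a_n_se_, self.b_n_se_, self.a_d_se_, self.b_d_se_,
         m_j_se, self.c_m_se_) = perr
        self.m_kj_se_ = m_j_se / 1e3
        self.transition_in_range_ = bool(x.min() <= self.c_m_ <= x.max())
        self.cov_ = pcov
        return self

    def predict(self, x):
        return two_state_chemical(x, self.a_n_, self.b_n_, self.a_d_, self.b_d_,
                                  self.m_kj_ * 1e3, self.c_m_, self.temperature)


class ThermalMeltFit(BaseEstimator):
    """Two-state van't Hoff fit of a thermal melting curve.

    Fitted attributes: ``m_n_``, ``y_n_``, ``m_d_``, ``y_d_``,
    ``dh_kj_`` (kJ/mol at Tm), ``t_m_`` (K) with ``*_se_``, and
    ``transition_in_range_``. Reversibility is not assessed.
    """

    def fit(self, curve: CDCurve):
        t, y = curve.x, curve.signal
        if len(t) < 10:
            raise ValueError("need >= 10 points spanning the transition")
        y_n0, y_d0 = y[np.argmin(t)], y[np.argmax(t)]
        mid = 0.5 * (y_n0 + y_d0)
        t_m0 = float(np.interp(mid, y, t)) if y_d0 != y_n0 else np.median(t)
        p0 = [0.0, y_n0, 0.0, y_d0, 3e5, t_m0]
        popt, pcov = optimize.curve_fit(
            two_state_thermal, t, y, p0=p0, sigma=curve.se,
            absolute_sigma=curve.se is not None, maxfev=40000)
        perr = np.sqrt(np.diag(pcov))
        (self.m_n_, self.y_n_, self.m_d_, self.y_d_, dh_j, self.t_m_) = popt
        self.dh_kj_ = dh_j / 1e3
        (self.m_n_se_, self.y_n_se_, self.m_d_se_, self.y_d_se_,
         dh_j_se, self.t_m_se_) = perr
        self.dh_kj_se_ = dh_j_se / 1e3
        self.transition_in_range_ = bool(t.min() <= self.t_m_ <= t.max())
        self.cov_ = pcov
        return self

    def predict(self, t):
        return two_state_thermal(t, self.m_n_, self.y_n_, self.m_d_, self.y_d_,
                                 self.dh_kj_ * 1e3, self.t_m_)


def fit_chemical_denaturation(curve: CDCurve,
                              temperature: float = 298.15) -> ChemicalDenaturationFit:
    return ChemicalDenaturationFit(temperature=temperature).fit(curve)


def fit_thermal_melt(curve: CDCurve) -> ThermalMeltFit:
    return ThermalMeltFit().fit(curve)


@dataclass
class DdgResult:
    ddg_kj: float
    ddg_se_kj: float
    dh_average_kj: float
    dt_m: float
    t_m_wt: float
    t_m_mut: float


def ddg_from_tm_shift(t_m_wt: float, t_m_mut: float,
                      dh_wt_kj: float, dh_mut_kj: float,
                      t_m_wt_se: float = 0.0, t_m_mut_se: float = 0.0,
                      dh_wt_se_kj: float = 0.0, dh_mut_se_kj: float = 0.0,
                      temperature: float = 298.0) -> DdgResult:
    """Stability change from the Tm shift of a variant (kJ/mol at 298 K).

    ddG = -dH_avg(Tm) T / (Tm_wt Tm_mut) * dTm with dTm = Tm_mut - Tm_wt;
    a destabilized variant (dTm < 0) gives ddG > 0 when dH_avg > 0.
    Errors are propagated to first order from the Tm and dH SEs.
    """
    if dh_wt_kj <= 0 or dh_mut_kj <= 0:
        raise ValueError("both fits must carry positive unfolding enthalpy")
    dh_avg = 0.5 * (dh_wt_kj + dh_mut_kj)
    dt_m = t_m_mut - t_m_wt
    pref = -temperature / (t_m_wt * t_m_mut)
    ddg = pref * dh_avg * dt_m
    # first-order propagation
    d_dh = pref * dt_m * 0.5
    d_twt = -pref * dh_avg * (1.0 + dt_m / t_m_wt)   # d/dTwt of [dTm/(Twt Tmut)]
    d_tmut = pref * dh_avg * (1.0 - dt_m / t_m_mut)
    var = (d_dh * dh_wt_se_kj) ** 2 + (d_dh * dh_mut_se_kj) ** 2 \
        + (d_twt * t_m_wt_se) ** 2 + (d_tmut * t_m_mut_se) ** 2
    return DdgResult(float(ddg), float(np.sqrt(var)), dh_avg, dt_m,
                     t_m_wt, t_m_mut)
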