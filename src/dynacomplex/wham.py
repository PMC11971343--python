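"""Umbrella-sampling analysis: WHAM, K_D from the PMF, van't Hoff fits.

Biased samples of the center-of-mass separation r from harmonic umbrella
windows are combined with the weighted histogram analysis method into an
unbiased potential of mean force W(r). The dissociation constant follows
from the Boltzmann-weighted volume integral of the bound region,

    1/K_D = N_A integral_0^rc 4 pi r^2 exp(-W(r)/kT) dr   (vs 1 M standard state)

and the protein contributions to binding enthalpy and entropy from the
temperature dependence of K_D (ln K_D = dH/RT - dS/R).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .config import N_AVOGADRO, R_GAS

#: nm^3 per molecule at the 1 mol/L standard state
_NM3_PER_LITER = 1e24


@dataclass
class UmbrellaWindow:
    center: float            # nm
    spring_k: float          # kJ/mol/nm^2
    samples: np.ndarray      # reaction-coordinate samples, nm

    def __post_init__(self) -> None:
        if self.spring_k <= 0:
            raise ValueError("spring constant must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class UmbrellaSet:
    windows: list
    temperature: float       # K
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in zip(self.windows[:-1], self.windows[1:]):
            if a.samples.max() < b.samples.min():
                warnings.warn(
                    f"windows at {a.center} and {b.center} nm do not overlap; "
                    "WHAM may be ill-conditioned", stacklevel=2)


@dataclass
class PMFProfile:
    r: np.ndarray            # bin centers, nm
    w_kt: np.ndarray         # PMF in kT, zeroed on the unbound plateau
    se_kt: np.ndarray
    temperature: float
    meta: dict = field(default_factory=dict)


def default_window_layout(r_max: float = 24.5):
    """Umbrella centers 0.5 nm apart up to 2.5 nm, then 1 nm apart."""
    inner = np.arange(0.0, 2.5 + 1e-9, 0.5)
    outer = np.arange(3.5, r_max + 1e-9, 1.0)
    return np.concatenate([inner, outer])


def wham_pmf(umbrella: UmbrellaSet, n_bins: int = 100, tol: float = 1e-8,
             max_iter: int = 100000, r_range: tuple[float, float] | None = None,
             plateau_fraction: float = 0.2) -> PMFProfile:
    """Self-consistent WHAM reconstruction of the PMF.

    Iterates the window free energies f_k until the largest relative
    change falls below ``tol``; the PMF is zeroed on the mean over the
    outer ``plateau_fraction`` of the grid. Per-bin uncertainties are
    the Poisson estimate 1/sqrt(n_counts) in kT.
    """
    kt_kj = R_GAS * umbrella.temperature / 1e3  # kJ/mol per kT
    windows = umbrella.windows
    all_samples = np.concatenate([w.samples for w in windows])
    lo, hi = (all_samples.min(), all_samples.max()) if r_range is None else r_range
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    n_k = counts.sum(axis=1).astype(float)
    total = counts.sum(axis=0).astype(float)
    uncovered = np.nonzero(total == 0)[0]
    if uncovered.size:
        raise ValueError("bins not covered by any window around r = "
                         f"{centers[uncovered[:3]]} nm")
    # bias energies in kT: 0.5 k (r - r0)^2 / kT
    bias = np.stack([0.5 * w.spring_k * (centers - w.center) ** 2 / kt_kj
                     for w in windows])
    f = np.zeros(len(windows))
    for _ in range(max_iter):
        # unbiased probability estimate
        denom = np.einsum("k,ki->i", n_k, np.exp(f[:, None] - bias))
        p = total / denom
        f_new = -np.log(np.einsum("ki,i->k", np.exp(-bias), p))
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    else:
        warnings.warn("WHAM did not reach the requested tolerance", stacklevel=2)
    denom = np.einsum("k,ki->i", n_k, np.exp(f[:, None] - bias))
    p = total / denom
    with np.errstate(divide="ignore"):
        w_kt = -np.log(p)
    n_plateau = max(int(plateau_fraction * n_bins), 1)
    w_kt -= w_kt[-n_plateau:].mean()
    se = 1.0 / np.sqrt(np.maximum(total, 1.0))
    return PMFProfile(centers, w_kt, se, umbrella.temperature,
                      meta={"window_free_energies_kt": f, "n_bins": n_bins})


def default_bound_cutoff(pmf: PMFProfile, plateau_band_kt: float = 0.5) -> float:
    """First r where the PMF returns to within ``plateau_band_kt`` of the plateau."""
    i_min = int(np.argmin(pmf.w_kt))
    after = np.nonzero(pmf.w_kt[i_min:] > -plateau_band_kt)[0]
    if after.size == 0:
        raise ValueError("PMF never returns to the plateau; no bound/unbound split")
    return float(pmf.r[i_min + after[0]])


def kd_from_pmf(pmf: PMFProfile, bound_cutoff: float | None = None,
                n_resample: int = 200, seed: int = 0) -> tuple[float, float]:
    """Dissociation constant (mol/L) from the PMF's bound-region integral.

    1/K_D = N_A * integral_0^rc 4 pi r^2 exp(-W/kT) dr relative to the
    1 M standard state, with a spherical volume element for the
    isotropic center-of-mass separation coordinate. Uncertainty is
    propagated from the per-bin PMF errors by Gaussian resampling.
    """
    rc = default_bound_cutoff(pmf) if bound_cutoff is None else bound_cutoff
    n_tail = max(int(0.2 * len(pmf.r)), 2)
    if abs(pmf.w_kt[-n_tail:].mean()) > 0.5:
        raise ValueError("PMF shows no plateau beyond the bound region")

    def integrate(w):
        mask = pmf.r <= rc
        rr = pmf.r[mask]
        ww = w[mask]
        if rr[-1] < rc and mask.sum() < len(pmf.r):
            # close the integration interval exactly at the cutoff
            rr = np.append(rr, rc)
            ww = np.append(ww, np.interp(rc, pmf.r, w))
        integrand = 4.0 * np.pi * rr ** 2 * np.exp(-ww)
        vol_nm3 = np.trapezoid(integrand, rr)
        ka = vol_nm3 * N_AVOGADRO / _NM3_PER_LITER  # 1/M
        return 1.0 / ka

    kd = integrate(pmf.w_kt)
    rng = np.random.default_rng(seed)
    kds = [integrate(pmf.w_kt + rng.standard_normal(len(pmf.r)) * pmf.se_kt)
           for _ in range(n_resample)]
    return float(kd), float(np.std(kds, ddof=1))


def square_well_kd(depth_kt: float, width_nm: float) -> float:
    """Closed-form K_D (mol/L) of a square-well PMF: 1/K_D = N_A (4/3) pi a^3 e^eps."""
    ka = (4.0 / 3.0) * np.pi * width_nm ** 3 * np.exp(depth_kt) \
        * N_AVOGADRO / _NM3_PER_LITER
    return 1.0 / ka


@dataclass
class VantHoffResult:
    dh_kj: float             # binding enthalpy, kJ/mol
    ds_j: float              # binding entropy, J/mol/K
    dh_se_kj: float
    ds_se_j: float
    temperatures: np.ndarray
    kd: np.ndarray


class VantHoffFit(BaseEstimator):
    """Enthalpy/entropy decomposition from the temperature dependence of K_D.

    ln K_D = dH/(R T) - dS/R with K_D in 1 M standard-state units, so
    dH = R * slope of ln K_D vs 1/T and dS = -R * intercept.

    Fitted attributes: ``dh_kj_``, ``ds_j_``, ``dh_se_kj_``, ``ds_se_j_``.
    """

    def fit(self, temperatures, kd):
        t = np.asarray(temperatures, dtype=float)
        kd = np.asarray(kd, dtype=float)
        if len(t) < 2:
            raise ValueError("need K_D at >= 2 temperatures")
        x = 1.0 / t
        y = np.log(kd)
        if len(t) == 2:
            slope = (y[1] - y[0]) / (x[1] - x[0])
            intercept = y[0] - slope * x[0]
            slope_se = intercept_se = 0.0
        else:
            res = stats.linregress(x, y)
            slope, intercept = res.slope, res.intercept
            slope_se, intercept_se = res.stderr, res.intercept_stderr
        self.dh_kj_ = R_GAS * slope / 1e3
        self.ds_j_ = -R_GAS * intercept
        self.dh_se_kj_ = R_GAS * slope_se / 1e3
        self.ds_se_j_ = R_GAS * intercept_se
        self.result_ = VantHoffResult(self.dh_kj_, self.ds_j_, self.dh_se_kj_,
                                      self.ds_se_j_, t, kd)
        return self

    def predict(self, temperatures):
        t = np.asarray(temperatures, dtype=float)
        return np.exp(self.dh_kj_ * 1e3 / (R_GAS * t) - self.ds_j_ / R_GAS)


def vant_hoff_decomposition(temperatures, kd) -> VantHoffResult:
    return VantHoffFit().fit(temperatures, kd).result_
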