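"""Polymer-model transfer-efficiency analysis and nanosecond FCS.

The inter-dye distance distribution of a disordered chain is modelled
with the SAW-nu form

    P(r) = A (4 pi / s) (r/s)^(2 + (gamma-1)/nu) exp[-alpha (r/s)^(1/(1-nu))]

with s = sqrt(<R^2>) = b N^nu the root-mean-squared end-to-end distance,
nu the scaling exponent, gamma ~ 1.1615 the universal exponent, and A,
alpha fixed by unit normalization and the second-moment condition. The
Forster relation E(r) = 1/(1 + (r/R0)^6) maps distances to transfer
efficiencies; <E> = integral P(r) E(r) dr is inverted for sqrt(<R^2>).

Nanosecond FCS correlograms (donor/acceptor auto- and cross-correlations)
are fitted globally with shared chain-dynamics time tau_cd, which is then
converted to the chain reconfiguration time tau_rec by modelling chain
dynamics as diffusion in the potential of mean force -kT ln P(r).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, linalg, optimize
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .timeseries import integrated_correlation_time

GAMMA_UNIVERSAL = 1.1615
SEGMENT_LENGTH_NM = 0.55  # effective segment length b for polypeptides


# ---------------------------------------------------------------------------
# SAW-nu distance distribution
# ---------------------------------------------------------------------------

@dataclass
class SawNuModel:
    """Evaluable SAW-nu inter-dye distance distribution."""

    nu: float
    rms_r: float                      # sqrt(<R^2>), nm
    n_residues: int | None = None     # inter-dye residue count, if b-derived
    b: float = SEGMENT_LENGTH_NM
    gamma: float = GAMMA_UNIVERSAL
    A: float = field(init=False)
    alpha: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.33 <= self.nu <= 1.0:
            raise ValueError("scaling exponent nu must lie in [0.33, 1]")
        if self.rms_r <= 0:
            raise ValueError("rms end-to-end distance must be > 0")
        q = 2.0 + (self.gamma - 1.0) / self.nu
        p = 1.0 / (1.0 - self.nu)
        # The normalization and second-moment conditions reduce to gamma
        # functions: integral x^q exp(-a x^p) dx = Gamma((q+1)/p) / (p a^((q+1)/p))
        self._q, self._p = q, p
        log_ratio = gammaln((q + 3.0) / p) - gammaln((q + 1.0) / p)
        self.alpha = float(np.exp(log_ratio * p / 2.0))
        self.A = float(p * self.alpha ** ((q + 1.0) / p)
                       / (4.0 * np.pi * np.exp(gammaln((q + 1.0) / p))))

    @classmethod
    def from_residues(cls, nu: float, n_residues: int, b: float = SEGMENT_LENGTH_NM,
                      gamma: float = GAMMA_UNIVERSAL) -> "SawNuModel":
        """Build from chain length using sqrt(<R^2>) = b N^nu."""
        if n_residues < 1:
            raise ValueError("need at least one residue")
        return cls(nu=nu, rms_r=b * n_residues ** nu, n_residues=n_residues,
                   b=b, gamma=gamma)

    def pdf(self, r):
        """P(r) in 1/nm; normalized so integral P dr = 1."""
        x = np.asarray(r, dtype=float) / self.rms_r
        with np.errstate(divide="ignore"):
            out = (self.A * 4.0 * np.pi / self.rms_r * x ** self._q
                   * np.exp(-self.alpha * x ** self._p))
        return np.where(np.asarray(r) > 0, out, 0.0)

    def r_max(self, tail_mass: float = 1e-10) -> float:
        """Upper truncation radius leaving less than ``tail_mass`` outside."""
        # conservative: solve alpha x^p = -ln(tail_mass) + margin
        x = ((-np.log(tail_mass) + 20.0) / self.alpha) ** (1.0 / self._p)
        return float(max(x, 3.0) * self.rms_r)


def saw_nu_distribution(nu: float, n_residues: int | None = None,
                        b: float = SEGMENT_LENGTH_NM,
                        rms_r: float | None = None) -> SawNuModel:
    """SAW-nu model from either (nu, N, b) or (nu, sqrt(<R^2>))."""
    if rms_r is not None:
        return SawNuModel(nu=nu, rms_r=rms_r)
    if n_residues is None:
        raise ValueError("provide either n_residues or rms_r")
    return SawNuModel.from_residues(nu, n_residues, b=b)


def forster_efficiency(r, r0: float):
    """E(r) = 1 / (1 + (r/R0)^6)."""
    rr = np.asarray(r, dtype=float) / r0
    return 1.0 / (1.0 + rr ** 6)


def mean_efficiency(distribution, r0: float, r_max: float | None = None,
                    points=None) -> float:
    """<E> = integral P(r) E(r) dr by adaptive quadrature (abs tol 1e-8).

    ``points`` marks known sharp features of a bare callable
    distribution for the quadrature (e.g. the location of a narrow
    peak); the SAW-nu model supplies its own.
    """
    if isinstance(distribution, SawNuModel):
        pdf = distribution.pdf
        upper = distribution.r_max() if r_max is None else r_max
        if points is None:
            points = (distribution.rms_r,)
    else:
        pdf = distribution
        if r_max is None:
            raise ValueError("r_max required for a bare callable distribution")
        upper = r_max
    val, _ = integrate.quad(lambda r: pdf(r) * forster_efficiency(r, r0),
                            0.0, upper, epsabs=1e-10, epsrel=1e-10, limit=300,
                            points=points)
    return float(val)


def infer_rms_end_to_end(mean_e: float, nu: float, n_residues: int, r0: float,
                         b: float = SEGMENT_LENGTH_NM) -> float:
    """Invert <E> for sqrt(<R^2>) under the SAW-nu model (bisection).

    Unique by monotonicity of <E> in the chain dimension.
    """
    if not 0.0 < mean_e < 1.0:
        raise ValueError("mean transfer efficiency must lie strictly in (0, 1)")
    lo, hi = 0.1, 3.0 * b * n_residues

    def resid(s):
        return mean_efficiency(SawNuModel(nu=nu, rms_r=s), r0) - mean_e

    f_lo, f_hi = resid(lo), resid(hi)
    if f_lo < 0 or f_hi > 0:
        raise ValueError("observed <E> outside the range attainable on "
                         f"[{lo}, {hi:.2f}] nm")
    return float(optimize.brentq(resid, lo, hi, xtol=1e-10, rtol=1e-12))


def interdye_distance_from_backbone(d, n_residues: int, nu: float = 0.6):
    """Map a backbone C-alpha distance to an inter-dye distance.

    Dyes and linkers are approximated by nine additional effective
    residues: r = d ((N+9)/N)^nu.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue between the labels")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be >= 0")
    scale = ((n_residues + 9.0) / n_residues) ** nu
    out = d * scale
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# nanosecond FCS
# ---------------------------------------------------------------------------

CHANNELS = ("AA", "DD", "AD")
_PER_CURVE_SHORT = ("c_ab", "tau_ab", "c_cd", "c_T", "tau_T")
_PER_CURVE_FULL = _PER_CURVE_SHORT + ("c_T2", "tau_T2")


def nsfcs_curve(lag, params: dict, model: str = "short"):
    """Evaluate one nsFCS correlation curve.

    ``params`` carries c, tau_cd (shared), c_ab, tau_ab, c_cd, c_T,
    tau_T (per curve), and for the full model also c_T2, tau_T2,
    tau_D, s. Times in seconds.
    """
    t = np.abs(np.asarray(lag, dtype=float))
    core = (1.0 + params["c_ab"] * np.exp(-t / params["tau_ab"])) \
        * (1.0 + params["c_cd"] * np.exp(-t / params["tau_cd"])) \
        * (1.0 + params["c_T"] * np.exp(-t / params["tau_T"]))
    if model == "short":
        return 1.0 + params["c"] * core
    if model == "full":
        core = core * (1.0 + params["c_T2"] * np.exp(-t / params["tau_T2"]))
        diff = (1.0 + t / params["tau_D"]) * np.sqrt(1.0 + t / (params["s"] ** 2 * params["tau_D"]))
        return 1.0 + params["c"] * core / diff
    raise ValueError(f"unknown nsFCS model {model!r}")


class NsfcsModel(BaseEstimator):
    """Global fit of acceptor/donor auto- and cross-correlations.

    The chain-dynamics time tau_cd and overall amplitude c (and for the
    full model the diffusion time tau_D and aspect ratio s) are shared
    across the AA, DD, and AD curves; antibunching, chain-dynamics
    amplitude, and triplet parameters are per curve. Distance dynamics
    show up with positive c_cd in the autocorrelations and negative
    c_cd in the cross-correlation.

    Fitted attributes: ``params_`` (dict per channel, shared values
    repeated), ``tau_cd_``, ``tau_cd_se_``, ``cost_``.
    """

    def __init__(self, model: str = "short", p0: dict | None = None):
        self.model = model
        self.p0 = p0

    # parameter vector layout: shared then per-curve blocks
    def _shared_names(self):
        return ("c", "tau_cd") + (("tau_D", "s") if self.model == "full" else ())

    def _per_curve_names(self):
        return _PER_CURVE_FULL if self.model == "full" else _PER_CURVE_SHORT

    def _unpack(self, x):
        shared = dict(zip(self._shared_names(), x[:len(self._shared_names())]))
        for name in shared:
            if name.startswith("tau"):
                shared[name] = np.exp(shared[name])
        out = {}
        npc = len(self._per_curve_names())
        for k, ch in enumerate(CHANNELS):
            blk = x[len(shared) + k * npc: len(shared) + (k + 1) * npc]
            d = dict(zip(self._per_curve_names(), blk))
            for name in d:
                if name.startswith("tau"):
                    d[name] = np.exp(d[name])
            d.update(shared)
            out[ch] = d
        return out

    def _default_p0(self, lag):
        guess = {"c": 0.5, "tau_cd": 5e-8, "tau_D": 1e-3, "s": 5.0}
        per = {"AA": dict(c_ab=-0.8, tau_ab=5e-9, c_cd=0.3, c_T=0.3, tau_T=3e-6,
                          c_T2=0.1, tau_T2=3e-5),
               "DD": dict(c_ab=-0.8, tau_ab=5e-9, c_cd=0.3, c_T=0.3, tau_T=3e-6,
                          c_T2=0.1, tau_T2=3e-5),
               "AD": dict(c_ab=-0.8, tau_ab=5e-9, c_cd=-0.3, c_T=0.3, tau_T=3e-6,
                          c_T2=0.1, tau_T2=3e-5)}
        if self.p0:
            guess.update({k: v for k, v in self.p0.items() if k in guess})
            for ch in CHANNELS:
                if ch in self.p0:
                    per[ch].update(self.p0[ch])
        x = [guess[n] if not n.startswith("tau") else np.log(guess[n])
             for n in self._shared_names()]
        for ch in CHANNELS:
            x += [per[ch][n] if not n.startswith("tau") else np.log(per[ch][n])
                  for n in self._per_curve_names()]
        return np.array(x)

    def fit(self, lag, curves: dict, se: dict | None = None):
        """``curves`` maps channel pair ("AA", "DD", "AD") to g(tau)."""
        lag = np.asarray(lag, dtype=float)
        if self.model == "short" and lag.max() > 1.05e-6:
            raise ValueError("short model is restricted to |tau| <= 1 us")

        def residuals(x):
            p = self._unpack(x)
            res = []
            for ch in CHANNELS:
                r = nsfcs_curve(lag, p[ch], self.model) - curves[ch]
                if se is not None:
                    r = r / se[ch]
                res.append(r)
            return np.concatenate(res)

        x0 = self._default_p0(lag)
        fit = optimize.least_squares(residuals, x0, max_nfev=60000)
        if not fit.success:
            p = self._unpack(fit.x)
            per_curve = {ch: float(np.sum((nsfcs_curve(lag, p[ch], self.model)
                                           - curves[ch]) ** 2)) for ch in CHANNELS}
            raise RuntimeError(f"nsFCS global fit did not converge: {fit.message}; "
                               f"per-curve residual SS {per_curve}")
        self.params_ = self._unpack(fit.x)
        self.tau_cd_ = self.params_["AA"]["tau_cd"]
        # SE via linearized covariance; tau_cd is the second shared parameter
        dof = max(fit.fun.size - fit.x.size, 1)
        s2 = 2 * fit.cost / dof
        try:
            cov = s2 * np.linalg.inv(fit.jac.T @ fit.jac)
            self.tau_cd_se_ = float(np.sqrt(cov[1, 1])) * self.tau_cd_  # log-space
        except np.linalg.LinAlgError:
            self.tau_cd_se_ = np.inf
        self.cost_ = float(fit.cost)
        return self

    def predict(self, lag, channel: str):
        return nsfcs_curve(lag, self.params_[channel], self.model)


def fit_nsfcs(lag, curves: dict, model: str = "short", se: dict | None = None,
              p0: dict | None = None) -> NsfcsModel:
    return NsfcsModel(model=model, p0=p0).fit(lag, curves, se=se)


# ---------------------------------------------------------------------------
# reconfiguration time: diffusion in the PMF of P(r)
# ---------------------------------------------------------------------------

@dataclass
class ReconfigurationResult:
    tau_cd: float           # ns, input (correlation time of E fluctuations)
    tau_rec: float          # ns, correlation time of r fluctuations
    diffusion_coefficient: float  # nm^2/ns
    r_grid: np.ndarray      # nm
    pmf_kt: np.ndarray      # -ln P(r), kT units

    def __post_init__(self) -> None:
        if self.tau_rec <= 0:
            raise ValueError("reconfiguration time must be > 0")


def _smoluchowski_correlation_time(pi: np.ndarray, f: np.ndarray, h: float,
                                   diffusion: float = 1.0) -> float:
    """Integrated correlation time of observable f under 1-D diffusion.

    Discretizes the Smoluchowski operator as a birth-death chain with
    jump rates (D/h^2) sqrt(pi_j/pi_i) (detailed balance by
    construction, reflecting boundaries). After symmetrization the
    off-diagonals are constant D/h^2, giving a symmetric tridiagonal
    eigenproblem. tau = sum_k a_k/|lambda_k| / sum_k a_k with
    a_k = <f sqrt(pi) v_k>^2 over the non-stationary modes.
    """
    pi = pi / pi.sum()
    n = len(pi)
    w = diffusion / h ** 2
    up = w * np.sqrt(pi[1:] / pi[:-1])    # rate i -> i+1
    down = w * np.sqrt(pi[:-1] / pi[1:])  # rate i+1 -> i
    diag = np.zeros(n)
    diag[:-1] -= up
    diag[1:] -= down
    off = np.full(n - 1, w)
    evals, evecs = linalg.eigh_tridiagonal(diag, off)
    sqrt_pi = np.sqrt(pi)
    proj = evecs.T @ (sqrt_pi * f)
    # drop the stationary mode (eigenvalue ~ 0, largest)
    order = np.argsort(evals)
    lam = evals[order][:-1]
    a = proj[order][:-1] ** 2
    denom = a.sum()
    if denom <= 0:
        raise ValueError("observable has no fluctuations under this distribution")
    return float(np.sum(a / np.abs(lam)) / denom)


def reconfiguration_time(tau_cd: float, distribution, r0: float,
                         n_grid: int = 600, efficiency_map=None,
                         r_range: tuple[float, float] | None = None) -> ReconfigurationResult:
    """Convert a chain-dynamics time into the chain reconfiguration time.

    Chain dynamics are modelled as diffusive motion on the potential of
    mean force U(r) = -kT ln P(r) (P already contains the radial
    measure, so no extra Jacobian) with reflecting boundaries. The
    diffusion coefficient D is fixed by requiring that the integrated
    correlation time of E(r(t)) equals ``tau_cd``; tau_rec is then the
    integrated correlation time of r(t) at that D. Both correlation
    times scale exactly as 1/D, so a single spectral solve at D = 1
    nm^2/ns suffices.
    """
    if tau_cd <= 0:
        raise ValueError("tau_cd must be > 0")
    if isinstance(distribution, SawNuModel):
        pdf = distribution.pdf
        lo, hi = 1e-3, distribution.r_max(1e-8)
    else:
        pdf = distribution
        if r_range is None:
            raise ValueError("r_range required for a bare callable distribution")
        lo, hi = r_range
    r = np.linspace(lo, hi, n_grid)
    h = r[1] - r[0]
    pi = pdf(r)
    pi = np.maximum(pi, pi.max() * 1e-300)
    e_of_r = (forster_efficiency(r, r0) if efficiency_map is None
              else efficiency_map(r))
    tau_e_unit = _smoluchowski_correlation_time(pi, e_of_r, h, diffusion=1.0)
    tau_r_unit = _smoluchowski_correlation_time(pi, r, h, diffusion=1.0)
    diffusion = tau_e_unit / tau_cd           # nm^2/ns
    tau_rec = tau_r_unit / diffusion
    with np.errstate(divide="ignore"):
        pmf = -np.log(pi / pi.max())
    return ReconfigurationResult(tau_cd=tau_cd, tau_rec=tau_rec,
                                 diffusion_coefficient=diffusion,
                                 r_grid=r, pmf_kt=pmf)


def brownian_correlation_time(distribution, r0: float, diffusion: float,
                              dt: float, n_steps: int, seed: int,
                              observable: str = "r",
                              r_range: tuple[float, float] | None = None) -> float:
    """Seeded Brownian-dynamics estimate of the integrated correlation time.

    Euler-Maruyama on U(r) = -kT ln P(r) with reflecting boundaries;
    cross-checks the spectral solver. Times in ns, distances in nm.
    """
    if isinstance(distribution, SawNuModel):
        pdf = distribution.pdf
        lo, hi = 1e-3, distribution.r_max(1e-8)
    else:
        pdf = distribution
        lo, hi = r_range
    grid = np.linspace(lo, hi, 4000)
    p = np.maximum(pdf(grid), 1e-300)
    logp = np.log(p)
    force = np.gradient(logp, grid)  # -dU/dr in 1/nm (kT units)
    rng = np.random.default_rng(seed)
    r = np.empty(n_steps)
    r[0] = grid[np.argmax(p)]
    noise = rng.standard_normal(n_steps - 1) * np.sqrt(2.0 * diffusion * dt)
    for i in range(1, n_steps):
        fr = np.interp(r[i - 1], grid, force)
        x = r[i - 1] + diffusion * fr * dt + noise[i - 1]
        # reflecting boundaries
        if x < lo:
            x = 2 * lo - x
        elif x > hi:
            x = 2 * hi - x
        r[i] = x
    series = r if observable == "r" else forster_efficiency(r, r0)
    return integrated_correlation_time(series, dt)
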