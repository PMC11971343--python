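"""Synthetic data generators with the statistical structure of each stage's inputs.

Each generator draws from the model the corresponding analysis stage
assumes and records its true parameters (and the seed) in the output
metadata, so every fitter can be validated by parameter recovery. The
generators are statistical stand-ins for measured data and simulation
trajectories; they do not emulate any force field.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .binding import (SaltSeries, TitrationSeries, predict_mean_e_1to1,
                      predict_mean_e_multistate)
from .io import TrajectoryFrames
from .nmr import NHVectorTrajectory
from .stability import CDCurve, two_state_chemical, two_state_thermal
from .wham import UmbrellaSet, UmbrellaWindow
from .config import R_GAS


# ---------------------------------------------------------------------------
# titrations and salt series
# ---------------------------------------------------------------------------

def make_titration(kd, e0: float, de_sat: float, g_tot, p_tot,
                   noise_sd: float, seed: int, alpha=None,
                   mode: str = "excess") -> TitrationSeries:
    """FRET titration from a 1:1 (scalar ``kd``) or sequential model.

    <E> values are the model prediction plus i.i.d. Gaussian noise of
    SD ``noise_sd``; the truth is stored in the series metadata.
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    g = np.asarray(g_tot, dtype=float)
    if np.ndim(kd) == 0:
        e = predict_mean_e_1to1(float(kd), e0, de_sat, g, p_tot)
    else:
        e = predict_mean_e_multistate(np.asarray(kd, float), alpha, e0, de_sat,
                                      g, p_tot)
    rng = np.random.default_rng(seed)
    noisy = e + rng.normal(0.0, noise_sd, size=e.shape)
    se = np.full_like(noisy, noise_sd if noise_sd > 0 else 1e-6)
    return TitrationSeries(g, p_tot, noisy, se_e=se, mode=mode,
                           meta={"true_kd": kd, "true_e0": e0,
                                 "true_de_sat": de_sat, "alpha": alpha,
                                 "noise_sd": noise_sd, "seed": seed})


def make_salt_series(kd_ref: float, n_ions: float, ionic_strengths,
                     noise_sd_log: float, seed: int,
                     i_ref: float = 0.165) -> SaltSeries:
    """K_D vs ionic strength with log10 K_D linear in log10 I (slope n_ions)."""
    i_s = np.asarray(ionic_strengths, dtype=float)
    if (i_s <= 0).any():
        raise ValueError("ionic strengths must be > 0")
    if len(np.unique(i_s)) < 2:
        raise ValueError("need more than one ionic strength for a salt series")
    rng = np.random.default_rng(seed)
    log_kd = np.log10(kd_ref) + n_ions * (np.log10(i_s) - np.log10(i_ref)) \
        + rng.normal(0.0, noise_sd_log, size=i_s.shape)
    kd = 10.0 ** log_kd
    se_kd = kd * np.log(10.0) * (noise_sd_log if noise_sd_log > 0 else 1e-6)
    return SaltSeries(i_s, kd, se_kd=se_kd,
                      meta={"true_n_ions": n_ions, "kd_ref": kd_ref,
                            "i_ref": i_ref, "seed": seed})


# ---------------------------------------------------------------------------
# rotational diffusion and Ornstein-Uhlenbeck traces
# ---------------------------------------------------------------------------

def make_tumbling_vectors(tau_c: float, dt: float, n_steps: int,
                          n_residues: int, seed: int) -> NHVectorTrajectory:
    """Unit vectors under isotropic rotational diffusion.

    tau_c in ns is the P2 orientational correlation time, i.e. the
    rotational diffusion coefficient is D_rot = 1/(6 tau_c); dt in ps.
    Small-step random rotations with per-axis angular variance
    2 D_rot dt require dt <= tau_c/50 (enforced) so that discretization
    error stays below statistical error. Per-residue realizations are
    independent.
    """
    if tau_c <= 0 or dt <= 0:
        raise ValueError("tau_c and dt must be > 0")
    dt_ns = dt * 1e-3
    if dt_ns > tau_c / 50.0:
        raise ValueError("dt must satisfy dt <= tau_c/50 for accurate "
                         "rotational diffusion")
    if n_steps * dt_ns < 10.0 * tau_c:
        warnings.warn("trajectory shorter than 10 tau_c; correlation "
                      "statistics will be poor", stacklevel=2)
    d_rot = 1.0 / (6.0 * tau_c)
    sigma = np.sqrt(2.0 * d_rot * dt_ns)
    rng = np.random.default_rng(seed)
    mu = rng.standard_normal((n_residues, 3))
    mu /= np.linalg.norm(mu, axis=1, keepdims=True)
    out = np.empty((n_residues, n_steps, 3))
    out[:, 0] = mu
    for t in range(1, n_steps):
        omega = rng.normal(0.0, sigma, size=(n_residues, 3))
        angle = np.linalg.norm(omega, axis=1, keepdims=True)
        axis = omega / np.where(angle > 0, angle, 1.0)
        cos_a = np.cos(angle)
        sin_a = np.sin(angle)
        # Rodrigues rotation of each mu about its axis
        mu = (mu * cos_a
              + np.cross(axis, mu) * sin_a
              + axis * (axis * mu).sum(axis=1, keepdims=True) * (1.0 - cos_a))
        mu /= np.linalg.norm(mu, axis=1, keepdims=True)
        out[:, t] = mu
    return NHVectorTrajectory(out, dt)


def make_ou_trace(mean: float, sd: float, relax_time: float, dt: float,
                  n_steps: int, seed: int) -> np.ndarray:
    """Exact-discretization Ornstein-Uhlenbeck series (times in ns).

    Stationary mean/SD equal the inputs and the autocorrelation time is
    exactly ``relax_time``; no Euler discretization error.
    """
    if sd < 0 or relax_time <= 0 or dt <= 0:
        raise ValueError("sd >= 0 and relax_time, dt > 0 required")
    rng = np.random.default_rng(seed)
    if sd == 0:
        return np.full(n_steps, mean)
    rho = np.exp(-dt / relax_time)
    eps = rng.standard_normal(n_steps) * sd * np.sqrt(1.0 - rho ** 2)
    eps[0] = rng.standard_normal() * sd  # stationary start
    dev = lfilter([1.0], [1.0, -rho], eps)
    return mean + dev


# ---------------------------------------------------------------------------
# scripted contact episodes
# ---------------------------------------------------------------------------

@dataclass
class ContactEpisode:
    res_a: int          # residue on chain 0 (1-based)
    res_b: int          # residue on chain 1 (1-based)
    start_frame: int
    end_frame: int      # exclusive; lifetime = (end - start) * dt
    dip_frames: tuple = ()  # frames inside the episode where the pair sits
    #                         in the 0.38-0.8 nm hysteresis band


def make_contact_frames(episodes: list[ContactEpisode], dt: float,
                        n_frames: int, n_res_a: int = 4, n_res_b: int = 4,
                        ) -> TrajectoryFrames:
    """Two-chain toy trajectory realizing scripted contact episodes.

    Each chain carries one carbon atom per residue. During an episode
    the pair's distance is 0.30 nm (0.60 nm on listed ``dip_frames``,
    exercising the hysteresis band without breaking); the approach
    frame before the episode ramps through the band at 0.60 nm, the
    frame at ``end_frame`` sits at 0.85 nm (breaking the contact), and
    the pair is otherwise >= 2 nm apart. dt in ps.
    """
    col = 100.0  # nm between residue columns; guarantees pair independence
    seen: dict[tuple, list] = {}
    by_res_b: dict[int, list] = {}
    for ep in episodes:
        for s, e in seen.get((ep.res_a, ep.res_b), []):
            if ep.start_frame < e and s < ep.end_frame:
                raise ValueError("overlapping episodes for one residue pair")
        seen.setdefault((ep.res_a, ep.res_b), []).append(
            (ep.start_frame, ep.end_frame))
        # one chain-B residue cannot sit near two chain-A residues at once
        # (ramp frames included in the exclusion window)
        for ra, s, e in by_res_b.get(ep.res_b, []):
            if ra != ep.res_a and ep.start_frame - 1 < e + 1 and \
                    s - 1 < ep.end_frame + 1:
                raise ValueError(
                    "chain-B residue scripted into concurrent episodes with "
                    "different chain-A residues")
        by_res_b.setdefault(ep.res_b, []).append(
            (ep.res_a, ep.start_frame, ep.end_frame))
    coords = np.zeros((n_frames, n_res_a + n_res_b, 3))
    for i in range(n_res_a):
        coords[:, i, 0] = col * i
    for j in range(n_res_b):
        coords[:, n_res_a + j, 0] = col * j
        coords[:, n_res_a + j, 1] = 50.0
    for ep in episodes:
        ia = ep.res_a - 1
        ib = n_res_a + ep.res_b - 1
        x_a = col * ia
        for f in range(max(ep.start_frame - 1, 0), min(ep.end_frame + 1, n_frames)):
            if f == ep.start_frame - 1 or f in ep.dip_frames:
                d = 0.60
            elif f == ep.end_frame:
                d = 0.85
            else:
                d = 0.30
            coords[f, ib] = (x_a, d, 0.0)
    atoms = pd.DataFrame({
        "name": ["CA"] * (n_res_a + n_res_b),
        "element": ["C"] * (n_res_a + n_res_b),
        "resid": list(range(1, n_res_a + 1)) + list(range(1, n_res_b + 1)),
        "resname": ["GLY"] * (n_res_a + n_res_b),
        "chain": [0] * n_res_a + [1] * n_res_b,
    })
    return TrajectoryFrames(coords, dt, atoms)


# ---------------------------------------------------------------------------
# umbrella sampling
# ---------------------------------------------------------------------------

def make_umbrella_samples(potential, centers, spring_k: float,
                          n_per_window: int, temperature: float, seed: int,
                          n_burn: int = 500, thin: int = 5) -> UmbrellaSet:
    """Metropolis samples from Boltzmann(potential + harmonic bias) per window.

    ``potential(r)`` in kJ/mol on r in nm; ``spring_k`` in kJ/mol/nm^2.
    """
    if spring_k <= 0:
        raise ValueError("spring constant must be > 0")
    centers = np.asarray(centers, dtype=float)
    kt = R_GAS * temperature / 1e3  # kJ/mol
    rng = np.random.default_rng(seed)
    step = max(np.sqrt(kt / spring_k), 0.05)

    def energy(r):
        return potential(r) + 0.5 * spring_k * (r - centers) ** 2

    r = centers.copy()
    e = energy(r)
    samples = np.empty((n_per_window, len(centers)))
    kept = 0
    for it in range(n_burn + n_per_window * thin):
        prop = r + rng.normal(0.0, step, size=r.shape)
        e_prop = energy(prop)
        accept = rng.random(r.shape) < np.exp(np.minimum(-(e_prop - e) / kt, 0.0))
        r = np.where(accept, prop, r)
        e = np.where(accept, e_prop, e)
        if it >= n_burn and (it - n_burn) % thin == 0:
            samples[kept] = r
            kept += 1
    windows = [UmbrellaWindow(c, spring_k, samples[:, i])
               for i, c in enumerate(centers)]
    return UmbrellaSet(windows, temperature,
                       meta={"seed": seed, "spring_k": spring_k,
                             "n_per_window": n_per_window})


# ---------------------------------------------------------------------------
# denaturation curves
# ---------------------------------------------------------------------------

def make_denaturation_curve(mode: str, true_params: dict, x_grid,
                            noise_sd: float, seed: int) -> CDCurve:
    """Two-state unfolding curve plus Gaussian noise; truth in metadata.

    Thermal parameters: m_n, y_n, m_d, y_d, dh_kj, t_m (x in K).
    Chemical parameters: a_n, b_n, a_d, b_d, m_kj, c_m, temperature
    (x in mol/L denaturant).
    """
    x = np.asarray(x_grid, dtype=float)
    p = dict(true_params)
    if mode == "thermal":
        y = two_state_thermal(x, p["m_n"], p["y_n"], p["m_d"], p["y_d"],
                              p["dh_kj"] * 1e3, p["t_m"])
    elif mode == "chemical":
        y = two_state_chemical(x, p["a_n"], p["b_n"], p["a_d"], p["b_d"],
                               p["m_kj"] * 1e3, p["c_m"],
                               p.get("temperature", 298.15))
    else:
        raise ValueError(f"unknown denaturation mode {mode!r}")
    rng = np.random.default_rng(seed)
    noisy = y + rng.normal(0.0, noise_sd, size=y.shape)
    se = np.full_like(noisy, noise_sd) if noise_sd > 0 else None
    return CDCurve(x, noisy, mode=mode, se=se,
                   meta={"true_params": p, "noise_sd": noise_sd, "seed": seed})


# ---------------------------------------------------------------------------
# nsFCS correlograms
# ---------------------------------------------------------------------------

def make_nsfcs_curves(params: dict, lag, noise_sd: float, seed: int,
                      model: str = "short"):
    """Synthetic AA/DD/AD correlograms from known nsFCS parameters.

    ``params`` maps each channel to its full parameter dict (shared
    values like tau_cd repeated). Returns (curves, se) dicts.
    """
    from .fret import CHANNELS, nsfcs_curve

    rng = np.random.default_rng(seed)
    lag = np.asarray(lag, dtype=float)
    curves, se = {}, {}
    for ch in CHANNELS:
        clean = nsfcs_curve(lag, params[ch], model)
        curves[ch] = clean + rng.normal(0.0, noise_sd, size=lag.shape)
        se[ch] = np.full_like(lag, noise_sd if noise_sd > 0 else 1e-6)
    return curves, se
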