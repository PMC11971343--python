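# dynacomplex

Quantitative analysis of dynamic, charge-driven complexes between an
intrinsically disordered polyelectrolyte chain and a folded, oppositely
charged protein domain — the regime exemplified by prothymosin α (net
charge ≈ −44, fully disordered) binding the globular domain of linker
histone H1.0 (net charge +9) while remaining disordered in the complex.

The package is aimed at researchers combining single-molecule FRET, NMR,
and molecular simulation to characterize such complexes. It implements
the full analysis chain as a library of scikit-learn-style estimators and
functions, with a synthetic-data module so every stage can be validated
by parameter recovery without any measured data.

## What it computes

**Binding (smFRET titrations).** Burst transfer efficiencies
E = n_A/(n_A + n_D) with configurable background/crosstalk/γ corrections
and stoichiometry-window selection (0.2 < S < 0.75); Gaussian
decomposition of efficiency histograms; the 1:1 binding model

    <E> = ΔE_sat · ([G]t + K_D + [P]t − √(([G]t + K_D + [P]t)² − 4[G]t[P]t)) / (2[P]t) + <E>_0

and the sequential 1:N model with populations p_i from the coupled
equilibria K_Di = p_(i−1)[G]/p_i plus mass balance, weighted by a fixed
α-profile of per-stoichiometry efficiency increments (default
(0, 0.80, 0.91, 0.98, 1), from coarse-grained simulations of multivalent
binding). Salt dependence is analysed in the Lohman–Record form: the
slope of log₁₀ K_D vs log₁₀ ionic strength counts the counterions
released on binding.

**Chain dimensions and dynamics (FRET + nsFCS).** The SAW-ν distance
distribution P(r) ∝ (r/√⟨R²⟩)^(2+(γ−1)/ν) exp[−α(r/√⟨R²⟩)^(1/(1−ν))] with
√⟨R²⟩ = bN^ν, b = 0.55 nm, γ ≈ 1.1615; the mean-efficiency integral
⟨E⟩ = ∫P(r)/(1+(r/R₀)⁶)dr and its numerical inversion for √⟨R²⟩; global
fitting of nanosecond FCS auto-/cross-correlograms with a shared chain
dynamics time τ_cd; and the conversion of τ_cd into the chain
reconfiguration time τ_rec by modelling chain motion as diffusion in the
potential of mean force −kT ln P(r) (spectral Smoluchowski solver, with a
Brownian-dynamics cross-check).

**NMR.** Amide chemical-shift perturbations
Δδ_NH = √(ΔδH² + (0.154·ΔδN)²) and normalized CSP sums across variant
titrations; single-exponential relaxation-decay fits; and back-calculation
of ¹⁵N R₁, R₂, and heteronuclear NOE from amide N–H bond-vector
trajectories via the P₂ orientational correlation function, a
triple-exponential spectral density, and the dipolar (r_NH = 0.1041 nm) +
CSA (Δσ = −170 ppm) expressions at 600/750 MHz, with block-averaged
(N = 10) uncertainties.

**Trajectory kinetics.** Dual-cutoff (0.38 nm form / 0.8 nm break)
residue–residue contact events and lifetime distributions, per-residue
contact profiles, bound-ligand counting (1.3 nm minimum-distance
criterion evaluated every 100 ps), and the integrated autocorrelation
time of radius-of-gyration fluctuations.

**Stability (CD).** Mean-residue-weight conversion and two-state
chemical/thermal unfolding fits with linear baselines; variant stability
changes from ΔΔG ≈ −ΔH̄(Tm)·T·ΔTm/(Tm_WT·Tm_mut).

**Free energies (coarse-grained umbrella sampling).** WHAM
reconstruction of the PMF along the center-of-mass separation, K_D from
the Boltzmann-weighted volume integral of the bound region
(1/K_D = N_A ∫ 4πr² e^(−W/kT) dr vs the 1 M standard state), and van't
Hoff decomposition of K_D(T) into ΔH and ΔS.

## Worked example

```python
import numpy as np
from dynacomplex.synth import make_titration, make_salt_series
from dynacomplex.binding import fit_titration, fit_salt_dependence
from dynacomplex.fret import infer_rms_end_to_end

# an excess titration: picomolar labeled chain, ligand up to 100 uM
g = np.geomspace(1e-7, 1e-4, 12)
series = make_titration(kd=17e-6, e0=0.334, de_sat=0.25, g_tot=g,
                        p_tot=1e-10, noise_sd=0.005, seed=1)
fit = fit_titration(series)
print(f"K_D,app = {fit.kd_*1e6:.1f} +/- {fit.kd_se_*1e6:.1f} uM")
print(f"<E>_0   = {fit.e0_:.3f} +/- {fit.e0_se_:.3f}")

salt = make_salt_series(kd_ref=17e-6, n_ions=4.6,
                        ionic_strengths=np.geomspace(0.06, 0.3, 6),
                        noise_sd_log=0.05, seed=2)
sfit = fit_salt_dependence(salt)
print(f"ions released = {sfit.n_ions_:.1f} "
      f"(90% CI {sfit.ci90_[0]:.1f}-{sfit.ci90_[1]:.1f})")

rms = infer_rms_end_to_end(0.334, nu=0.598, n_residues=54, r0=5.4)
print(f"sqrt(<R^2>) = {rms:.2f} nm")
```

prints

```
K_D,app = 17.2 +/- 1.6 uM
<E>_0   = 0.335 +/- 0.002
ions released = 4.7 (90% CI 4.4-5.0)
sqrt(<R^2>) = 7.43 nm
```

The fitted K_D,app of 17 µM is the apparent 1:1 affinity at 165 mM ionic
strength; a slope of ~4.6 in the salt fit means about five counterions
are released on binding, the signature of an electrostatically driven
complex; and a mean transfer efficiency of 0.334 with ν ≈ 0.6 maps to a
root-mean-squared end-to-end distance of ~7.4 nm for the 54-residue
inter-dye segment of the expanded free chain.

A CLI mirrors the library (`dynacomplex fit-titration`, `fit-salt`,
`bursts`, `csp`, `relax-fit`, `relax-backcalc`, `contacts`, `rg-time`,
`nsfcs`, `saw-nu`, `melt-fit`, `wham`, `kd-pmf`, `vanthoff`,
`simulate`); every subcommand reads and writes delimited-text tables.

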