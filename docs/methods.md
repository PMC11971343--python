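# Methods

This note documents the models, numerical choices, and validation
strategy behind each analysis stage, and what the synthetic-data
generators do and do not emulate.

## Binding models

The 1:1 model treats the mean transfer efficiency of the labeled chain as
a population-weighted average of the free and bound states, with the
bound fraction given by the exact root of the binding quadratic. We
evaluate it in the subtraction-free form 2[G]t/(s + √(s² − 4[G]t[P]t)),
s = [G]t + K_D + [P]t, which stays accurate in the excess-titration limit
[P]t → 0 (picomolar labeled chain) where the naive root differences two
nearly equal numbers.

The sequential 1:N model assigns one macroscopic dissociation constant
K_Di per binding step. Populations follow from p_i ∝ ∏_(j≤i) [G]/K_Dj
(computed in log space to avoid overflow for extreme constants) and the
free-ligand concentration from the mass balance
[G]t = [G] + Σ i·p_i·[P]t, solved by Brent's method on [0, [G]t] at
1e-15 relative tolerance — the residual is monotone in [G], so the
bracket is guaranteed. Mean efficiencies combine the populations with a
fixed α-profile (fraction of the saturation efficiency change reached at
stoichiometry i). The default profile (0, 0.80, 0.91, 0.98, 1) encodes
the coarse-grained result that the first bound domain produces ~80% of
the total chain compaction and later ones ~11% and ~7% more; the fit
holds α fixed because it is not identifiable from a single titration. The
fitter flags any K_Di whose standard error exceeds the estimate — the
expected signature of an overparameterized multisite fit, where only the
first constant and the saturation efficiency carry meaning.

Titration fits are weighted least squares (scipy `curve_fit`,
`absolute_sigma` when per-point errors are provided). Initial K_D is the
ligand concentration at the half-change of the observed efficiency.

**Burst corrections.** Transfer efficiencies are computed from
background-, crosstalk-, direct-excitation- and γ-corrected photon
counts. All factors default to identity; the full detector calibration
chain is instrument-specific and out of scope, so the factors are plain
configuration. Bursts left with no photons after correction are dropped
and counted. The histogram default is 0.02 efficiency units over
[−0.1, 1.1] (corrected E can leave [0, 1] slightly).

**Gaussian peak decomposition.** Mixtures are fitted to binned counts
with Poisson weights (1/√counts), initialized from k-means on the burst
values. An overfit guard removes components whose three parameters do
not buy a likelihood-ratio-significant χ² reduction (Δχ² < 11.3,
p ≈ 0.01 for 3 dof); removed components are reported with zero area so
the requested number of peaks is always returned, flagged degenerate
below area 1e-3. Peaks are sorted by mean; areas normalized to 1.

**Salt dependence.** log₁₀ K_D is regressed on log₁₀ ionic strength with
weights from per-point K_D errors propagated symmetrically into log space
(se/K_D/ln 10). The slope (counterion count) is base-invariant; the 90%
confidence interval is a t-interval on the regression slope — profile
likelihood would differ only in strongly nonlinear settings. Ionic
strengths are totals including the buffer contribution (e.g. the 8 mM of
a 10 mM Tris buffer).

## Chain dimensions and dynamics

**SAW-ν distribution.** The two defining conditions (unit normalization
and second moment = ⟨R²⟩) reduce analytically to gamma-function
identities, so the constants A and α are evaluated in closed form (via
`gammaln` for stability) rather than by a numeric 2-D root solve; tests
verify both integrals by independent quadrature. ⟨E⟩ integrals use
adaptive quadrature to 1e-10 with the distribution scale supplied as a
quadrature breakpoint; the inversion for √⟨R²⟩ uses Brent bisection on
[0.1 nm, 3bN], unique by monotonicity of ⟨E⟩ in the chain dimension.
Segment length b = 0.55 nm and γ = 1.1615 are polypeptide standards. The
ν used when inverting ⟨E⟩ for a bound chain is a required argument — no
default is defensible there, whereas ν ≈ 0.6 suits expanded free chains.
Mapping simulation Cα distances to inter-dye distances uses
r = d((N+9)/N)^ν with ν = 0.6: dyes and linkers are approximated by nine
effective residues.

**nsFCS.** Correlograms g_ij(τ) for the acceptor/donor auto- and
cross-correlations are fitted globally: the overall amplitude c and the
chain-dynamics time τ_cd are shared across the three curves (plus the
diffusion time τ_D and aspect ratio s in the full model that includes the
translational-diffusion denominator and a second triplet component);
antibunching, chain-dynamics amplitude, and triplet terms are per curve.
Timescales are fitted in log space. The short model is restricted to
|τ| ≤ 1 µs. Chain dynamics must appear with positive amplitude in the
autocorrelations and negative in the cross-correlation; the fit recovers
this sign pattern from data generated that way but does not constrain it.

**Reconfiguration time.** τ_cd (the correlation time of E(r(t))
fluctuations) is converted to τ_rec (the correlation time of r(t)) by
modelling chain dynamics as diffusion on U(r) = −kT ln P(r) — P(r)
already contains the radial measure, so no extra Jacobian — with
reflecting boundaries. The Smoluchowski operator is discretized as a
birth–death chain with jump rates (D/h²)√(π_j/π_i), which satisfies
detailed balance by construction and symmetrizes to a constant-offdiagonal
tridiagonal eigenproblem; integrated correlation times are then exact
spectral sums Σ aₖ/|λₖ|. Because both correlation times scale exactly as
1/D, a single solve at D = 1 nm²/ns determines D from τ_cd and τ_rec
simultaneously. We made the deterministic spectral solver primary and
kept a seeded Brownian-dynamics propagator as an independent cross-check
(tests require agreement within a few percent; the harmonic case is
checked against the Ornstein–Uhlenbeck closed form τ = σ²/D).

**Correlation-time definition** (used for τ_rec cross-checks and Rg
relaxation): the normalized autocorrelation is integrated (trapezoid) up
to its first drop below 0.01, plus an exponential tail correction
C(t_c)·τ_loc with τ_loc from a log-linear fit over 0.01 < C < 0.1. Block
errors use 10 non-overlapping windows; the reported value comes from the
full series (short blocks bias integrated times upward). Constant series
are rejected as undefined.

## NMR

CSPs use the standard 0.154 nitrogen weighting; residues missing in
either state are reported, never imputed. The normalized CSP sum is the
ratio of variant to wild-type CSP sums over the shared residue set; its
error is the ratio times the relative standard error of the mean of the
replicate wild-type sums (SD/√n over n = 3 titrations, matched against a
bootstrap oracle in tests).

Back-calculation computes C_i(t) = ⟨P₂(μ(t′+t)·μ(t′))⟩ over all time
origins via FFT correlations of the six independent μ_aμ_b products. A
triple exponential is fitted to C(t) (amplitudes ≥ 0, Σaₖ bounded by the
first-lag value to absorb sub-resolution librational decay, timescales in
log space) and transformed analytically to
J(ω) = 2Σ aₖτₖ/(1+(ωτₖ)²). Component timescales are capped at the fitted
lag span (`tau_max_factor = 1`): slower components are not identifiable
from a window of that length, and an unbounded slow component fitted to
correlated tail noise inflates J(0) — and hence R₂ — without limit. The
fit window and the cap are configurable for systems with genuine C(t)
plateaus (e.g. bound complexes). Non-converging triple fits fall back to
bi-exponential, flagged. Rates use the dipolar + CSA expressions with
CODATA constants, γ_N negative, r_NH = 0.1041 nm, Δσ = −170 ppm, and
600/750 MHz presets; in extreme narrowing the NOE limit
1 + γ_H/(2γ_N) ≈ −3.93 is reproduced. Uncertainties are block averages
over N = 10 equal non-overlapping windows,
σ_M = √((⟨O²⟩−⟨O⟩²)/N).

## Contact kinetics

Contacts form when any two heavy atoms of a residue pair come within
0.38 nm and break only above 0.8 nm; excursions through the band in
between neither form nor break anything. The state machine sees only the
per-pair minimum heavy-atom distance per frame, making it deterministic
and atom-order independent. The sequence-separation exclusion (< 4
residues) applies only to intra-chain pairs — inter-chain pairs have no
sequence separation. Events open at either trajectory end are censored
and excluded from lifetime statistics by default (configurable); means
carry block errors over 10 temporal windows by formation time. Lifetimes
shorter than one frame interval are not representable. Minimum-image
distances are used when box dimensions are present (orthorhombic).

Bound-ligand counting uses a 1.3 nm minimum-distance criterion evaluated
every 100 ps by default.

## Stability

Chemical and thermal two-state fits use linear baselines; R = 8.314
J/mol/K, enthalpies in kJ/mol. ΔΔG from Tm shifts assumes a
temperature-independent ΔCp whose change between variants is negligible,
evaluated at 298 K; errors propagate to first order from the Tm and ΔH
standard errors. Reversibility of melts is metadata only.

## Umbrella sampling and thermodynamics

WHAM iterates the window free energies to < 1e-8 relative change; the
PMF is zeroed on the mean over the outer 20% of the grid and per-bin
uncertainties use the Poisson estimate 1/√counts (verified to scale as
1/√samples). K_D integrates 4πr²e^(−W/kT) from 0 to the bound cutoff —
the spherical volume element reflecting an isotropic unbound state —
against the 1 M standard state, with the integration interval closed
exactly at the cutoff by interpolation. The default cutoff is the first
r where the PMF returns within 0.5 kT of the plateau; it is logged per
run because the bound/unbound partition is a genuine modelling choice.
Uncertainty comes from Gaussian resampling of the per-bin PMF errors.
Van't Hoff fits regress ln K_D on 1/T (ΔH = R·slope, ΔS = −R·intercept,
K_D in 1 M units) with no extrapolation beyond the input range.

## Synthetic data: what it does and does not show

The generators draw from the exact statistical models the fitters assume:
titrations with i.i.d. Gaussian efficiency noise; log-linear salt series;
isotropic rotational diffusion by small random rotations (per-axis
angular variance 2·D_rot·dt, with dt ≤ τ_c/50 enforced so discretization
error stays below statistical error; D_rot = 1/(6τ_c) so the P₂
correlation decays as exp(−t/τ_c)); exact-discretization
Ornstein–Uhlenbeck traces (no Euler error, so analytic checks are exact
in distribution); scripted two-chain contact episodes whose approach
ramps through the hysteresis band; Metropolis-sampled umbrella windows;
and two-state denaturation curves. Every generator records its truth and
seed in the output metadata, and every fitter recovers noiseless truth to
high precision.

Passing these tests therefore demonstrates correctness of the estimators
under their own assumptions — it does not demonstrate robustness to what
real data add: correlated and heteroscedastic noise, shot-noise-limited
burst statistics, force-field error, anisotropic tumbling, exchange
broadening, or baseline drifts. The trajectory generators are statistical
stand-ins, not molecular models: no force field is emulated.

## Problem sizes

The validation runs use sizes chosen to keep statistical error a few
times tighter than each test's tolerance: 12–14-point titrations at
0.005 efficiency noise (50-seed recovery study), 6-point salt series,
500k-step tumbling trajectories at dt = τ_c/50 (10,000 τ_c; blocks of
1,000 τ_c), 500k-step Ornstein–Uhlenbeck traces for the 35 ns relaxation
check, 12 umbrella windows × 4,000 samples, and ~160 scripted contact
episodes. The acceptance script completes in well under a minute on one
CPU.

## Known limitations

- The multisite α-profile is an input, not something the package can
  infer from a single titration; joint fitting across conditions is not
  implemented (each titration is fitted independently).
- Raw photon time-tag processing (burst search, detector calibration) is
  out of scope; burst tables and correlograms are consumed pre-computed.
- J(0) from trajectory back-calculation is sensitive to the fit-window
  and timescale-cap choices whenever the trajectory is short relative to
  the slowest real motion; the defaults are logged and configurable.
- WHAM per-bin errors are Poisson approximations that ignore sample
  autocorrelation within windows; for strongly correlated samplers the
  K_D uncertainty is an underestimate.
- No three-state or ΔCp-explicit stability models; no clustering of
  contact interfaces; no free energies from contact occupancies.
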