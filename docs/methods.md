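# Methods

This note documents the models implemented in hvkit, the conventions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## The allosteric gating model

The gating scheme has eight states: {closed, open} × {unliganded,
externally protonated, internally protonated, doubly protonated}. Each
state's statistical weight is taken relative to the unliganded closed
state. Protonation of a single site contributes a titration weight
`x = 10^(pK − pH)` (bound:unbound ratio of a one-proton site; 1 at
pH = pK, tenfold per pH unit of acidification). The closed→open
transition carries the whole voltage dependence,
`K(V) = Kv(0)·exp(q_g·V/V_T)` with `V_T = k_B·T/e₀` (25.434 mV at the
default 295.15 K).

Coupling constants enter multiplicatively, once per realized pairwise
interaction: `C` for open∧externally-bound, `D` for open∧internally-bound,
and `E` for externally-bound∧internally-bound in **both** conformations.
This is the canonical MWC/Horrigan–Aldrich bookkeeping; the weights are
state functions, so detailed balance around every loop of the state graph
holds identically (a property test enumerates all four-cycles). An
alternative convention would apply `E` in only one conformation; with the
coral parameter set that choice rescales the closed tier at extreme acidic
internal pH but leaves the qualitative behavior (monotone decreasing
V_½(ΔpH) with two plateaus) unchanged. The both-conformations form was
chosen because it keeps `E` a pure site–site interaction energy,
independent of the gate.

Consequences used throughout:

* `P(V)` is an exact Boltzmann in V with slope charge `q_g`; pH moves only
  the midpoint. The closed form
  `V_½ = (V_T/q_g)·ln[Z_closed/(Kv(0)·Z'_open)]` is used directly and is
  cross-checked against a numeric root of `P(V) − ½` to 10⁻⁶ mV.
* `V_½(ΔpH)` saturates at both extremes because both sites titrate fully.
  With the coral preset (`D = 10⁵`, `pK_i = 7`) the alkaline-side plateau
  only appears when `D·x_i ≪ 1`, i.e. internal pH beyond ~13; sweeps and
  tests therefore cover a wide, partly unphysiological pH range to expose
  both plateaus. The plateau levels match the closed-form asymptotes with
  one site empty or saturated.
* The model's V_½ is defined against the saturating open probability
  (limit 1), matching the experimental G/G_max convention; the threshold
  voltage is the numeric solution of `P(V) = fraction` (default 0.1),
  bracketed around V_½ with interval doubling.

Numerics: all tier sums are computed in log space (`logsumexp`), so open
probabilities are well behaved at arbitrary voltages and extreme pH;
`state_weights` returns linear weights and may overflow to `inf` for
|V| far beyond the physiological range, which is documented behavior.

A scale discrepancy is worth stating plainly: with the coral parameter
set the model predicts V_½ ≈ 82 mV at pH_o 7/pH_i 6, far above the ~8 mV
midpoint measured for the real channel under the same gradient. The
parameter set reproduces the shape and steepness of the V_½–ΔpH relation,
not its absolute offset; fitting the model to G–V data is out of scope
here, and no parameter tuning is attempted.

## Electrophysiological fitting

**Conductance.** Chord conductance `G = I/(V − V_rev)` assumes ohmic
instantaneous currents. Voltages within a guard band of `V_rev` (1 mV in
the low-level routine; 5 mV in the pipeline, where noisy data make the
division ill-conditioned over a wider band) are rejected or dropped.
Normalization divides by the `G_max` of an unnormalized Boltzmann fit
rather than the largest observed point, which avoids bias when saturation
is incomplete.

**Boltzmann G–V.** `G/G_max = 1/(1 + exp(−q(V − V_½)/V_T))`, rising with
depolarization (q > 0). Unweighted least squares by default; per-point
sem weighting when the curve carries uncertainties. Note the sign: a form
with a positive exponent would fall with depolarization, contradicting
every proton-channel G–V, so the rising convention is used.

**Threshold.** The sub-maximal foot (default `G/G_max ≤ 0.3`) is fitted
log-linearly to `G = G′·exp(qV/V_T)`; the apparent threshold is
`V_Thr = (V_T/q)·ln(fraction·G_max/G′)` with fraction 0.1 by convention.

**Activation kinetics.** `I(t) = I_ss·(1 − exp(−(t − δ)/τ))`, fitted by
bounded least squares (I_ss, τ > 0, δ ≥ 0). The default window is the
second half of the pulse, the usual convention; the window is an explicit
parameter and is recorded in the fit, because a delay estimated from a
late window is an extrapolation. The convention degrades predictably: on
a fully plateaued window only I_ss is identifiable, and at voltages where
τ is tens of ms the analysis scripts instead open the window at the
detected onset of the rise. Steady-state currents for G–V work are
extracted sign-aware, so inward currents below the reversal potential are
handled; traces that fail the fit (flat or tiny) fall back to the
late-pulse mean.

**Rate–voltage.** `k(V) = k(0)·exp(−V·q_k/V_T)` for τ and δ. Default is a
linear regression on ln k — robust when k spans decades and exact on
noise-free data; a direct exponential fit is available
(`method="direct"`).

**Reversal.** The Nernst potential is `ln(10)·V_T·(pH_i − pH_o)`
(−58.6 mV per ΔpH unit at 22 °C). Tail-current reversal is the linear
interpolation of the instantaneous tail I–V between the sign-change
bracket.

**P/4 subtraction.** Each test step of amplitude ΔV carries N = 4
subsweeps of amplitude ΔV/4 from a sub-threshold level; the corrected
trace is `raw − N·mean(subsweeps)`. All traces are holding-baseline
referenced, so a purely ohmic cell cancels identically. A single
full-amplitude subsweep would subtract channel current too; that misuse
triggers a warning.

## Zinc block

Woodhull: `F_B(V) = 1/(1 + exp(−δz(V − V_½)/V_T))` with the valence fixed
at z = 2 (Zn²⁺) during fitting — δ and z are perfectly correlated, so
freeing z (available behind a flag) only determines their product. Hill:
`F_B = 1/(1 + (K_D/c)^n)`, fitted on linear F_B with no weighting.
Blocked fractions outside [0, 1] are retained during fitting to avoid
truncation bias; clipping happens only in reports, with a warning.

## FRET stoichiometry

Under random (binomial) assembly of donor- and acceptor-tagged subunits
into dimers, a donor's partner is an acceptor with probability
`f_A = 1/(1 + ρ·r)` where `r = I_d/I_a` and ρ is the acceptor-to-donor
brightness ratio; the population-average apparent efficiency is
`E_app = E_max·f_A`. Cells are binned in ratio windows (default width
0.1); each bin's abscissa is the mean ratio of its cells, not the bin
center, which removes the leading-order binning bias on a convex curve
(the residual second-order bias is bounded by `E″·w²/24`, well below the
fit tolerance). ρ is fitted jointly with E_max since no brightness
calibration is assumed. The Förster radius R₀ is a configuration
parameter — never fitted, always echoed in reports; the analysis scripts
use 54 Å, a typical CFP/YFP-class value, for which a pairwise efficiency
near 0.35 corresponds to a ~60 Å fluorophore separation. The module
consumes already-computed (I_d, I_a, E_app) triplets; spectral unmixing
is out of scope.

## Synthetic recordings

The generator composes the forward physics the analyses invert:
`I_ss(V) = G_max·P(V)·(V − V_rev)` with an ohmic driving force (no
Goldman rectification — the conductance analysis itself assumes ohmic
instantaneous currents), Nernstian reversal from the configured pH pair,
the exponential-with-delay time course with channel current exactly zero
before δ(V) (the delay parameterizes the sigmoidal onset), linear leak
referenced to holding, white Gaussian noise, optional P/4 subsweeps, and
multiplicative Woodhull/Hill block factors. Tails are instantaneous jumps
followed by mono-exponential decay with a configurable deactivation τ.

Default conditions describe the coral channel at 22 °C under ΔpH 1:
Boltzmann midpoint 7.85 mV with charge 2.09 e₀ (or the `amhv1` allosteric
preset), τ(0) = 212 ms/q_τ = 0.37 e₀, δ(0) = 98.2 ms/q_δ = 0.47 e₀,
G_max 5 nS, 500 ms pulses sampled at 1 kHz, and noise of a few pA —
values representative of whole-cell proton-current recordings. The FRET
population uses 134 cells with lognormal expression ratios (log-sd 0.75,
spanning acceptor- to donor-dominated cells) and 0.02 efficiency noise.

Every generator is a deterministic function of (config, seed). What the
generator does *not* emulate — capacitive transients, series-resistance
error, proton depletion during large currents, 1/f noise, stochastic
single-channel gating — bounds what passing tests show: they validate the
estimators against the stated model, not robustness to instrumentation
artifacts in real recordings.

## Study sizes and tolerances

Noise-free round trips are asserted at relative error 10⁻⁴ or tighter;
partition-function equivalence against brute-force enumeration at 10⁻¹²
over 1000 random draws; closed-form vs numeric V_½ at 10⁻⁶ mV. Noisy
simulation studies use 100–200 seeded replicates (bias bounds of 2–5 %
chosen from the estimators' expected behavior at the configured noise).
The end-to-end study runs four ΔpH conditions (−1…2, pH_o fixed at 7)
with 21-step protocols, 2 pA noise, and accepts each fitted V_½ within
four standard errors of the generating model value. These sizes keep the
whole suite and the reproduction script fast while leaving the Monte
Carlo assertions well-powered.

## Limitations

* Equilibrium only: no kinetic (rate-constant) simulation of the gating
  scheme, and no dimer cooperativity — the model is a single subunit.
* The allosteric parameter set is taken as given; no fitting of the model
  to G–V data.
* Block kinetics (onset/washout) and state-dependent block are not
  modelled; deactivation in the generator is a phenomenological
  mono-exponential.
* The FRET model is the minimal binomial-pairing form without
  direct-excitation corrections; monomer populations are representable
  (E_app ≈ 0) but higher-order oligomer models are not included.
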