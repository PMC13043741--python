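# Methods

## Gating model

A channel is a finite continuous-time Markov chain with states labelled
OPEN or CLOSED and generator Q (off-diagonal entries = transition rates in
s⁻¹, rows summing to zero). Equilibrium occupancy π solves πQ = 0,
Σπ = 1, computed by least squares on the normalisation-augmented linear
system (residual tolerance 1e-10); the open probability Po is the summed
occupancy of the open states. Schemes must be strongly connected;
reducible schemes are rejected with the unreachable states named.

The wild-type-like preset is a linear chain

    Cdeep <-> Cinter <-> O <-> Cflick

with mean lifetimes 1 s, 50 ms, 1.5 ms and 0.3 ms respectively and
equilibrium Po ≈ 0.018. This is the simplest topology that reproduces the
burst phenotype of a TASK-like leak channel in a cell-attached patch at
−100 mV: openings interrupted by brief flickers (intra-burst closures),
bursts separated by ~50 ms gaps, and a small population of ~1 s closures
(the chain visits Cdeep from Cinter about once per ten inter-burst
closures). Rate values are the package's own choice — chosen once to sit
in the stated lifetime/Po regime — since only those regimes, not rates,
are experimentally constrained. A gain-of-function preset (`n133s_like`)
shortens and de-populates the inter-burst state to give Po ≈ 0.23, the
regime in which single-channel inhibition experiments are practical. The
number of open states is an open modelling question; the presets use one,
and arbitrary user schemes are accepted (plain-text `[states]`/`[rates]`
files).

## Ligand modifiers

Ligand action is mean-field: rates are rescaled, no explicit bound states
(the analyses concern rate destabilisation, not binding kinetics).

* OPEN_DESTABILIZE: every rate leaving an open state × f_eff.
* CLOSED_STABILIZE: every closed→open rate ÷ f_eff.
* INDEPENDENT: rates untouched; pore block reported as the current scale
  1/(1 + X/K_d).

f_eff(X) = 1 + (max_factor − 1)·X/(X + K_d) ∈ [1, max_factor], monotone in
dose. For a two-state channel both state-dependent mechanisms give
Po′ = β/(f·α + β), hence identical macroscopic inhibition
I = 1 − Po′/Po — the degeneracy that motivates single-channel analysis.
I depends on the channel only through its baseline Po
(I = 1 − 1/(f(1−Po) + Po)), which is why the model predicts the inverse
Po–inhibition correlation across variants: I falls from ≈ 1 − 1/f at
Po → 0 to 0 at Po → 1. Note the decline is gentle below Po ≈ 0.7 at
f = 10 (0.90 → 0.73); the curve steepens only near Po → 1.

## Synthetic data generator

Dwell sequences are sampled by the standard CTMC construction
(exponential holding times at rate −q_ii, embedded-chain jumps, initial
state from equilibrium), seeded and reproducible. Rendering follows the
acquisition protocol of a high-bandwidth patch recording: 200 kHz
sampling, Gaussian FIR low-pass at 2 kHz (the standard analysis
approximation to a 4-pole Bessel filter; σ_t = 0.1325/f_c, 10–90% rise
time 0.3321/f_c), unitary current step 1.5 pA (a placeholder amplitude,
not a measured value), and white Gaussian noise added after filtering the
ideal signal (default sd 0.15 pA, i.e. SNR 10). Multi-channel patches are
independent identical channels with summed currents.

What the generator does **not** emulate: band-limited (filtered) noise,
capacitance transients, baseline drift, line interference, flicker noise,
and any voltage or PIP₂ dependence of the rates. Passing tests therefore
demonstrate correctness of the estimators under idealised recording
statistics, not robustness to every artefact of real patches.

## Idealization

Half-amplitude threshold: a sample is open when its signed deviation from
baseline (in the direction of the unitary amplitude) exceeds half the
amplitude; runs of equal class become events with boundaries at sample
boundaries. The imposed resolution (dead time, default 50 µs) is applied
by a left-to-right scan: an event shorter than the dead time is absorbed
into the preceding retained event, and same-class neighbours created by
the absorption are concatenated; the first event is exempt. Commercial
idealizers do not document their exact sub-resolution semantics, so this
leftward-absorption rule is declared as the package's convention and
pinned by a property test against an independent repeated-deletion
reference implementation. (Leftward absorption and shortest-first deletion
differ only when two sub-resolution events are adjacent; the convention
makes the choice explicit.) Po = summed open durations / record length.
Baseline and open level, when not known, are estimated from a two-Gaussian
fit of the all-points amplitude histogram; records with appreciable
occupancy beyond ~1.6× the unitary level are flagged as multi-channel and
not idealized automatically.

Consequence of the dead time worth knowing: when a ligand shortens
openings below the resolution, vanished openings merge their flanking
closures. This depresses the apparent number of short closures and
inflates the long-closure population — which is exactly the direction of
the intra-/inter-burst redistribution the mechanism analyses look for, so
the effect is part of the signature rather than a nuisance (the generator
and the estimators see the same dead time).

## Dwell-time mixtures

Histograms are log₁₀-binned (10 bins/decade) with the square-root-count
display ordinate, in which each exponential component peaks at its mean
lifetime. Fitting maximises the dead-time-censored log-likelihood
Σ log[pdf(t)/S(t_d)] with pdf(t) = Σ aᵢ/tᵢ·e^(−t/tᵢ), S the mixture
survival and Σaᵢ = 1. Maximum likelihood (not histogram least squares) is
the criterion because it admits exact oracles: for k = 1 the closed form
t̂ = mean(t) − t_d is used directly. For k ≥ 2, optimisation runs on
unconstrained parameters (log lifetimes; areas through a softmax) with
10 seeded restarts from quantile-spaced initials (L-BFGS-B); components
are returned sorted by lifetime. Component count is selected by BIC
(deterministic, no user-chosen significance level), capped at 5.

## Bursts

The critical time t_c separating intra- from inter-burst closures solves
a_short·e^(−t_c/τ_short) = a_long·(1 − e^(−t_c/τ_long)) — the
equal-*numbers* form of the misclassification criterion, with the fitted
areas read as relative event numbers; the root is bracketed in
(τ_short, τ_long) and found by Brent's method. The two largest-area
closed components supply (a, τ) pairs — the rare very-long component is
excluded. Alternative equal-proportion criteria are deliberately not
implemented. Bursts group openings separated by closures < t_c; burst
duration runs from first-opening start to last-opening end. Treated vs
control burst durations are summarised by their mean ratio with a seeded
1000-resample percentile bootstrap CI. t_c is computed per record (not
pooled across records).

## Dose–response

The Hill relation is the four-parameter logistic
Y(X) = base + (max − base)/(1 + (X/X_half)^H), matching the conventional
definitions of base (fully inhibited current), max (control current),
X_half (IC50) and H. Initialisation is deterministic (X_half at the dose
nearest half-response, H = 1); any of base/max/H may be fixed. With
responses normalised to the pre-drug current per patch, max ≈ 1.
Note the 4-parameter X_half estimate has an intrinsic sampling SD of
~6–7% at the 8-dose × 5-replicate, 5%-noise design — aggregate (RMS)
recovery is the meaningful accuracy statement at that problem size.
`ic50_from_model` closes the loop with the gating model: fractional
current Po(X)/Po(0) over a log dose grid, Hill-fitted; under open-state
destabilisation the apparent IC50 rises monotonically with baseline Po
(the model's account of inhibitor insensitivity of gain-of-function
channels), and for a state-independent blocker it equals K_d.

## State-dependence analyses

**Variant screen regression.** The per-variant table holds mean Po and
mean fractional inhibition with SEs and n (percent inputs auto-detected
when magnitudes exceed 1.5 and normalised). The regression of inhibition
on Po is ordinary least squares on the means — unweighted by default,
matching how such screens are usually plotted; inverse-variance weighting
is available as a flag. The 95% confidence band comes from the standard
regression variance formula. The synthetic screen generator draws, for
each of 12 variants with Po spanning 0.01–0.7, n = 8 replicate
measurements (a typical per-variant cell count in such screens) with
Gaussian measurement noise sd 0.05 on the model-predicted inhibition, and
tabulates means and SEs — the quantities a screen regresses. With a
single noisy draw per variant instead, the signal span (≈ 0.17 at
f_eff = 10 over this Po range) is comparable to the noise and the
correlation degrades to r ≈ −0.65; regressing per-variant means is both
what real screens do and what makes the inverse correlation reproducible.

**Mechanism verdict.** For a control/treated pair of idealized records
(≥ 200 events each), open- and closed-dwell mixtures are fitted (BIC,
k ≤ 2 open / k ≤ 3 closed) and two statistics computed: the log-ratio of
area-weighted mean open lifetime, and the log-ratio of the inter-burst
closed lifetime (the longer-lived of the two major closed components).
Decision rule with fold threshold 1.5 (configurable, chosen for ≥ 90%
simulated accuracy on 5-minute records at the wild-type-like preset):
open-lifetime ratio < 1/1.5 with inter-burst ratio inside [1/1.5, 1.5] →
OPEN_DESTABILIZE; the mirrored pattern → CLOSED_STABILIZE; anything else →
INDETERMINATE. The evidence object carries both mixture fits, the
rank-matched component shifts, and the intra-burst area change.

## Problem sizes and numerical choices

Simulated records used throughout the tests and the acceptance script are
300 s (5 min) at the wild-type-like preset — long enough for ~3–8×10³
events per record, the regime in which the mixture fits are stable; the
accuracy sweeps use 20 independent pairs per mechanism at the idealized
event level, while rendered 200 kHz traces (60×10⁶ samples per record)
are exercised on representative pairs and on the dedicated idealization
fidelity checks. Tolerances: generator row sums 1e-12, stationary solve
1e-10, mixture area normalisation 1e-9, critical-time root 1e-14
relative. Ties in BIC resolve toward fewer components; equal-lifetime
mixture components are forbidden (strictly increasing lifetimes).

## Known limitations

* No missed-event-corrected full-scheme likelihood (MIL/HJCFIT class);
  the censored mixture likelihood corrects the dwell distributions for
  the dead time but not for event concatenation, which is instead treated
  as part of the observable signature.
* No hidden-Markov/Viterbi idealization, stacked-opening resolution,
  drift correction, or voltage-dependent rates.
* The ligand model has no binding kinetics; concentration enters only
  through the saturable f_eff.
* Pearson r is reported alongside R²; for a simple regression R² = r²
  and the sign information lives in r (figure legends sometimes print a
  signed "R²", which is r).
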