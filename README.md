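# gatekin

Single-channel gating kinetics for burst-gating K2P (TASK) channels, and a
state-dependent model of their inhibition by diacylglycerol (DAG).

TASK-1/TASK-3 leak potassium channels are shut down by Gq-coupled receptor
signalling: receptor activation produces DAG, which directly inhibits the
channel. Whether that inhibition works by *stabilising the closed states*
or by *destabilising the open state* cannot be decided from whole-cell
currents — at equilibrium both mechanisms depress the open probability
P<sub>o</sub> identically. Single-channel dwell-time kinetics break the
tie: an open-state destabiliser shortens openings and bursts while leaving
the inter-burst closed lifetime alone; a closed-state stabiliser does the
mirror image. The open-state mechanism also predicts that any channel
variant or agonist that raises baseline P<sub>o</sub> loses inhibitor
sensitivity, producing a steep inverse correlation between P<sub>o</sub>
and fractional inhibition across variants.

`gatekin` implements this whole analysis as a tested pipeline, together
with a continuous-time Markov gating simulator so every stage can be
verified against ground truth without lab data:

* **`gatekin.scheme`** — gating schemes as labelled continuous-time Markov
  models; stationary occupancy and P<sub>o</sub>; mechanistic ligand
  modifiers (`OPEN_DESTABILIZE`, `CLOSED_STABILIZE`, `INDEPENDENT`) with
  saturable concentration coupling
  f<sub>eff</sub>(X) = 1 + (f<sub>max</sub> − 1)·X/(X + K<sub>d</sub>).
* **`gatekin.simulate`** — dwell-sequence sampling and rendering as noisy
  traces at patch-clamp settings (200 kHz sampling, 2 kHz Gaussian
  low-pass, unitary current step, additive noise).
* **`gatekin.idealize`** — half-amplitude threshold idealization with an
  imposed 50 µs resolution; P<sub>o</sub> from summed dwell times.
* **`gatekin.dwell`** — log-binned (square-root ordinate) dwell histograms
  and exponential-mixture fits pdf(t) = Σ aᵢ/tᵢ·exp(−t/tᵢ) by
  dead-time-censored maximum likelihood, with BIC model selection.
* **`gatekin.bursts`** — Magleby–Pallotta burst critical time (equal
  numbers of misclassified short and long closures) and burst
  segmentation/statistics.
* **`gatekin.hill`** — Hill dose–response fits
  Y = base + (max − base)/(1 + (X/X<sub>half</sub>)<sup>H</sup>) and
  model-predicted IC50s.
* **`gatekin.statedep`** — the headline analyses: the inverse
  P<sub>o</sub>–inhibition regression across variants and the
  single-channel mechanism verdict for a control/treated record pair.
* **`gatekin.pipeline` / `gatekin.cli`** — end-to-end runs and the
  `gatekin` command-line tool (`simulate`, `idealize`, `dwell-fit`,
  `bursts`, `hill`, `correlate`, `discriminate`, `demo`).

## Worked example

Simulate five minutes of wild-type-like gating, apply a saturating
open-state destabiliser (f<sub>eff</sub> = 10), idealize both records and
ask which mechanism produced the inhibition:

```sh
gatekin demo --outdir demo_out --seed 7 --duration 120
```

prints

```
verdict: OPEN_DESTABILIZE
log-ratio mean open lifetime (treated/control): -2.345
log-ratio inter-burst closed lifetime: +0.161
threshold: +/-0.405 (1.5-fold)
intra-burst closed area change: -0.067
open lifetimes control: 1.62 ms
open lifetimes treated: 0.156 ms
closed lifetimes control: 0.293 ms, 48.3 ms, 1.28e+03 ms
closed lifetimes treated: 0.382 ms, 56.8 ms, 1.07e+03 ms
```

Reading the numbers: the fitted mean open lifetime fell e^2.345 ≈ 10-fold
(1.62 ms → 0.156 ms) while the inter-burst closed lifetime moved less than
1.5-fold (48.3 ms → 56.8 ms) — the signature of open-state destabilisation,
so the verdict names that mechanism. The three fitted closed components are
the intra-burst flickers (~0.3 ms), the inter-burst gaps (~50 ms) and the
rare long-closed state (~1 s). The report file adds P<sub>o</sub>
(0.0153 → 0.0016) and the burst-duration ratio (0.18, 95% CI 0.16–0.20).

The same from Python:

```python
import gatekin as gk

scheme = gk.task_like()                       # WT-like preset, Po ~ 0.018
mod = gk.ModifierSpec("OPEN_DESTABILIZE", max_factor=10, k_d_um=1.0,
                      concentration_um=1e9)   # saturating dose
treated_scheme = gk.apply_modifier(scheme, mod)

ctrl = gk.record_from_dwells(gk.sample_dwell_sequence(scheme, 300, seed=1), scheme)
trt = gk.record_from_dwells(gk.sample_dwell_sequence(treated_scheme, 300, seed=2),
                            treated_scheme)
print(gk.discriminate_mechanism(ctrl, trt).verdict)   # Verdict.OPEN_DESTABILIZE

# population-level counterpart: the inverse Po-inhibition correlation
panel = gk.simulate_variant_panel(seed=0)
fit = gk.fit_inverse_correlation(panel)
print(round(fit.slope, 3), round(fit.pearson_r, 3))   # -0.23 -0.93
```

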