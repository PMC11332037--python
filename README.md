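# dyadsynch

Dyadic psychophysiology pipeline for studying the **social transmission of
nocebo hyperalgesia** — how treatment-related pain expectations spread from
person to person along a chain of demonstrator/observer dyads.

In the underlying design, dyads rotate through a transmission chain: a
first-generation demonstrator (G1) receives genuinely different thermal
stimuli under a sham-treatment cue (54 °C on "treatment" Tx trials, 45 °C on
"no treatment" NT trials) while a G2 observer watches. G2 then demonstrates
for G3 — but now every stimulus is 45 °C, so any Tx−NT difference in G2's or
G3's pain is *socially acquired* nocebo hyperalgesia. The package implements
the full analysis behind that design, plus a synthetic session generator so
every stage runs and is testable without the original recordings:

* **Phasic scoring** — EDA band-pass (0.0159–5 Hz), epoching ([−2, +6] s),
  100 Hz downsampling, 4.89 SD jack-knife outlier exclusion, peak-to-peak
  amplitude `max_{[t₀+3, t₀+6]} − min_{[t₀, τ_max]}` floored at 0.02 µS and
  ln(1+x)-transformed; PSPI-style facial pain expression
  `AU04 + max(AU06,AU07) + max(AU09,AU10) + AU12 + max(AU25,AU26)` scored as
  the 3-s post-onset maximum.
* **Physiological synchrony (CRQA)** — from-scratch cross-recurrence
  quantification of the dyad's EDA (0.05–1 Hz, 8 Hz, z-scored): time-delay
  embedding (delay from the first AMI minimum, dimension from false nearest
  neighbours), radius fitted so the recurrence rate RR lands in 2–4%, and the
  determinism (DET) and laminarity (LAM) line measures, exp-transformed and
  z-scored across dyads.
* **Psychological synchrony** — per-dyad correlation between demonstrator and
  observer trial-level pain-expectancy ratings.
* **Responder classification** — Monte-Carlo permutation test (10,000
  relabellings, or the exact 924-subset enumeration) on each subject's mean
  Tx−NT pain difference; upper-tail subjects are responders, lower-tail
  reverse-responders; responder proportions compared with Pearson χ² and
  Cramér's V.
* **Inference** — mixed ANCOVA (Cue × Trial within, Generation between, dyad
  gender match as covariate; Type-III, sphericity-uncorrected, partial η²
  with noncentral-F CIs, covariate-adjusted marginal means) and hierarchical
  moderation regressions (synchrony → + generation → + interaction) with
  simple slopes.
* **Synthetic data** — chain sessions with constraint-satisfying
  pseudorandom cue sequences, coupled Ornstein–Uhlenbeck + spontaneous-SCR
  arousal with tunable dyadic coupling κ, Bateman-kernel stimulus SCRs,
  delta-rule observer expectancy learning gated by the 50% rating-display
  schedule, responder-type mixtures, and 8.2% missing expectancy ratings.

## Worked example

Simulate a small study and run the inference stages end to end
(`examples/05_inference.py`):

```bash
python examples/05_inference.py
```

```
Cue main effect on pain: F(1, 21) = 4.25, p = 0.0518, eta_p2 = 0.17
  adjusted mean Tx: 38.91 (SE 1.17)
  adjusted mean NT: 36.01 (SE 0.74)
```

Twelve sessions give 24 socially conditioned demonstrators; although every
stimulus they received was 45 °C, the adjusted marginal means show ~3 VAS
points more pain on Tx than NT trials — the socially transmitted nocebo
effect, here just short of the 0.05 threshold at this small n. The same run
prints the final hierarchical-regression stage for psychological synchrony
and its simple slopes per generation, and writes every stage table
(`scores.csv`, `synchrony.csv`, `psync.csv`, `responders.csv`,
`regressions.csv`, ...) to a results directory.

The other example scripts each demonstrate one capability: session
simulation (`01`), phasic scoring (`02`), CRQA synchrony for a single dyad
(`03`), and responder classification with the χ² proportions test (`04`).

A thin command line mirrors the stages:

```bash
dyadsynch simulate --config cfg.yaml
dyadsynch run-all  --config cfg.yaml --seed 1
```

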