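# ictalpipe

Analysis toolkit for preclinical epilepsy gene-therapy studies that monitor
seizures with chronic single-channel ECoG. It covers the three computational
stages such a trial needs, plus synthetic-data generators that make every
stage testable without animal or cell recordings:

1. **Semiautomated seizure detection.** Recordings (512 samples/s,
   0.3–160 Hz passband) are divided into 5 s epochs; each epoch is
   summarized by band powers and line length and classified
   baseline/seizure by a random forest. Consecutive predictions are treated
   as observations of a two-state hidden Markov model whose hidden states
   are the manual annotations — the transition matrix comes from
   annotation transition counts, the emission matrix from the confusion
   table of out-of-fold predictions — and smoothed with the
   forward–backward algorithm. High-posterior runs become seizure events.

2. **Trial statistics for seizure counts.** Inclusion filtering (fewer than
   five baseline-week seizures excludes an animal), per-animal baseline
   normalization, seizure burden with an exact Mann–Whitney U test, the
   Fano factor (variance/mean of daily counts) as a clustering index, a
   permutation test for the treatment × week interaction, and the modified
   Lehr sample-size rule for Poisson rates

       n = 4 / (√λ₁ − √λ₂)²

   per group (λ₁, λ₂ = mean weekly seizure counts before/after treatment;
   80% power at two-sided α = 0.05 via the square-root variance-stabilizing
   transform), with a Monte-Carlo power check of the √-transform z-test.

3. **Voltage-clamp biophysics.** Series-resistance QC (> 10 MΩ excluded),
   steady-state current density over the last 40 ms of each 200 ms step,
   driving-force-corrected conductance G(V) = J(V)/(V − E_K) with
   E_K = −91.34 mV from the Nernst equation, per-cell Boltzmann fits

       G(V) = A₁ + (A₂ − A₁) / (1 + exp((V₀.₅ − V)/k))

   normalized to each cell's own A₁/A₂, a pooled group fit, and a
   Henderson-equation estimate of the liquid junction potential.

## Worked example

`examples/` holds one narrative script per capability. For instance:

```
$ python examples/voltage_clamp.py
K+ Nernst reversal potential: -91.34 mV
Henderson liquid junction potential (bath - pipette): +4.1 mV

QC: 5/12 cells pass (excluded Rs > 10 MOhm: [...])

per-cell V0.5: -28.2 +/- 0.0 mV (mean +/- SEM)
per-cell slope factor k: 8.0 mV

group Boltzmann on pooled normalized conductance: V0.5 = -28.2 mV, k = 8.0 mV
```

The reversal potential is the K⁺ Nernst potential for 4 mM external /
140 mM internal K⁺ at 25 °C; V₀.₅ is the half-activation voltage of the
simulated Kv1.1-like conductance, recovered by the fitting chain from noisy
synthetic traces. `examples/detect_seizures.py` trains the detector on one
synthetic recording and reports event-wise sensitivity and false positives
on an independent one; `examples/trial_statistics.py` runs the full count
analysis on a simulated 8 + 8 trial, ending with the Lehr sample size
(7.87 → 8 animals per group for a 10 → 6 seizures/week reduction) and its
simulated power (≈ 0.81).

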