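# smfret

Single-pair FRET (spFRET) TIRF trace analysis for surface-immobilized
protein–DNA complexes, built around the measurements used to characterize
how the ATPase Mot1 remodels and dissociates TBP–DNA complexes: two-channel
intensity traces are extracted and corrected, FRET-efficiency histograms
are decomposed into Gaussian state mixtures, conformational dynamics are
segmented with per-molecule hidden Markov models and summarized in
transition density plots, and TBP dissociation rates are measured by
photobleaching-corrected survival analysis.  A synthetic-data generator
reproduces the statistical structure of the raw measurements, so the whole
chain is testable against known ground truth without any external data.

## What it computes

* **Corrected FRET efficiency.** Per frame,
  `E = (I_A − αI_D − bg_A) / ((I_A − αI_D − bg_A) + γ(I_D − bg_D))`, with
  crosstalk `α` and detection-efficiency ratio `γ` estimated per molecule
  from single-step acceptor-first photobleaching events.
* **State mixtures.** Molecule-wise and frame-wise histograms fitted with
  sums of Gaussians `A_i exp(−(E−μ_i)²/2σ_i²)`, including a global
  amplitude-only mode with a fixed shared state set and bounded peak
  shifts.
* **Dynamics.** Per-molecule 3-state Gaussian-emission HMMs (Baum–Welch to
  |ΔlogL| < 1e-9, Viterbi decoding), transition density plots from
  fixed-width 2D kernels, gate-based subpopulation assignment, and
  dwell-time exit rates `k = −ln(p_stay)/Δt`.
* **Dissociation kinetics.** Paired survival curves fitted with
  `f(t) = e^{−kt}`; the dissociation rate is the excess decay `k₂ − k₁` of
  a treatment arm over its own photobleaching-only control.

See `docs/methods.md` for the full model and the numerical choices.

## Worked example

Simulate a ternary-complex population at the published static fraction,
correct it, classify traces, and fit the molecule-wise histogram:

```sh
smfret run --seed 0 --out runs/demo
```

```
run complete: {'simulate': 200, 'correct': 200,
 'classify': {'static': 101, 'dynamic': 93, 'unassigned': 6},
 'histfit': 3}
```

This run's binomial draw of the 60% static fraction planted 103 static
molecules; the classifier labels 101 of them static and none of the
dynamic ones wrongly (the 6 unassigned traces bleached before reaching
the 30-frame analysis minimum).  `runs/demo/mixture_fit.tsv` holds the
three-component fit of the molecule-wise histogram in the conventional
layout (area % / mean % / width %).  The numbered drivers under
`analysis/` run the full study-style
analyses and print their recovered quantities, e.g. `python
analysis/04_survival_kinetics.py`:

```
ATP only:          k2-k1 = -0.0064 +/- 0.0066 /s
ADP + Mot1:        k2-k1 = -0.0017 +/- 0.0064 /s
ATP + 1 nM Mot1:   k2-k1 = +0.0164 +/- 0.0072 /s
ATP + 3.4 nM Mot1: k2-k1 = +0.0637 +/- 0.0083 /s
ATP + 12 nM Mot1:  k2-k1 = +0.2126 +/- 0.0151 /s
```

The nucleotide-only and ADP controls are consistent with zero (no
dissociation without ATP hydrolysis plus free Mot1 in solution), while the
Mot1 series recovers the planted 0.02, 0.05 and 0.2 s⁻¹ rates within two
standard errors, rising monotonically with concentration (Spearman ρ = 1).

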