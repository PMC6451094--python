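# Methods

This package reimplements, as a tested pipeline, the trace-level analysis
of a single-pair FRET (spFRET) TIRF study of TBP–DNA complexes and their
remodeling by the ATPase Mot1: per-molecule intensity extraction and
correction, FRET-histogram mixture fitting, per-molecule hidden Markov
segmentation with transition-density kinetics, and photobleaching-corrected
survival analysis. Because no raw data are deposited for this kind of
measurement, a synthetic-data generator reproduces the statistical
structure of the recordings, and every analysis stage is validated by
recovering the generator's ground truth — parameterized throughout by the
published population tables and rates.

## Synthetic measurement model

A molecule occupies one of a small set of conformational FRET states.  Per
frame the apparent efficiency is drawn i.i.d. from the occupied state's
Gaussian `(μ, σ)`; state switching follows a row-stochastic per-frame
transition matrix (a discrete Markov chain started from its stationary
distribution).  The published frame-wise state tables supply `(μ, σ)` per
condition and subpopulation; the default chain is linear (nearest-neighbour
switching only), with per-frame switch probabilities of 0.05–0.1 giving
mean dwells of ~10 frames at the 15 ms default frame time — in the regime
where one draw per frame is an adequate approximation of frame integration.

Intensities follow the forward model

    I_D = T (1 − E),   I_A = γ T E,
    acceptor channel = I_A + α I_D + bg_A (+ noise),
    donor channel    = I_D + bg_D (+ noise),

with photon budget `T` (default 500 counts/frame), crosstalk `α` (default
0.05), detection-efficiency ratio `γ` (default 0.9) and per-channel
background (default 50 counts/frame).  These photometric defaults are not
printed in the source study; they were chosen once to give traces with
signal-to-noise comparable to the published example traces and are fully
configurable.  Noise is Poisson shot noise plus Gaussian read noise
(σ = 10 counts) by default; an EMCCD excess-noise variant doubles the shot
variance (Gaussian approximation of the √2 excess-noise factor).  The
camera's gain register is not modelled photon-by-photon.

Both fluorophores photobleach independently in single steps with
exponential waiting times.  After acceptor bleaching the donor jumps to the
full budget `T` in one step; after donor bleaching both channels fall to
background.  Static molecules occupy one state with no transitions.  Two
static variants exist: by default frames are drawn from the state Gaussian
directly (appropriate for frame-wise statistics), while
`static_frame_sd` enables molecule-to-molecule heterogeneity — the
molecule draws one personal mean from the state Gaussian and its frames
scatter narrowly around it.  The second variant is what makes simulated
*molecule-wise* histograms carry the published inter-molecule state
widths; without it, trace averaging collapses each state to a spike.

Per-molecule randomness uses `SeedSequence` spawn keys, so outputs are
bit-reproducible and adding molecules never reshuffles existing ones.
Survival experiments draw exponential disappearance times — control arm at
the photobleaching rate `k₁`, treatment arm at `k₁ + k_diss` — discretized
to the 30 ms dissociation-measurement frame time and right-censored at the
end of the recording.

What the generator does *not* emulate: blinking and triplet photophysics,
polarization, focal drift, non-uniform illumination, and diffusing
background molecules.  Passing recovery tests therefore demonstrate the
correctness of the estimators under the stated statistical model, not
robustness to every artifact of real recordings.

## Imaging and extraction

Dual-view detection places both spectral channels side by side on one
chip.  The channel map is estimated from matched bead centroids — closed
form for translation, `skimage.transform.estimate_transform` for affine
(default) and polynomial — with the RMS control-point residual reported.
Detection operates on the time-average of the first 10 frames of *both*
channel halves (a high-FRET molecule is dim in the donor channel);
acceptor-half detections are mapped back through the inverse transform and
merged with non-maximum suppression at the minimum separation (default
4 px).  Intensities are extracted by aperture photometry: aperture radius
3 px minus the annulus (5–7 px) median background, per frame and channel.
Spots whose aperture leaves either channel are dropped and logged.  With
the default 1 px PSF σ the 3 px aperture captures ≈99% of the flux, which
bounds the noiseless extraction error well under the 2% round-trip
tolerance.

## Corrections and FRET

Bleach steps are found by a two-segment least-squares change point per
channel, significant when the CUSUM statistic exceeds 5 local-noise SDs.
An acceptor bleach must additionally (a) stay at the low level for the
remainder of the trace and (b) leave a post-step proximity ratio below
0.15 — the crosstalk-level signature that separates a true acceptor bleach
from a transition into a low-FRET state (a FRET transition is also an
anti-correlated step; without these guards dynamic traces generate false
bleach calls).  A concurrent two-channel drop is classified as donor/total
loss.

For molecules whose acceptor bleaches first, `α` is the background-
corrected acceptor/donor ratio after the step and `γ` the crosstalk-
corrected acceptor drop over the donor rise across it, both averaged over
≥5-frame windows with a 2-frame guard around the detected step.  Molecules
without a usable acceptor-first event inherit the population medians, and
a run with no qualifying molecule falls back to config constants; each
molecule's provenance is recorded.  Efficiency is the standard corrected
ratiometric form

    E = (I_A − α I_D − bg_A) / ((I_A − α I_D − bg_A) + γ (I_D − bg_D)),

computed per frame, truncated at the first bleach, left unclamped for
fitting, with zero-denominator frames flagged invalid.  In the noise-free
limit this chain inverts the generator exactly (tested to 1e-6).  For
three-color experiments the 488-excitation green series is corrected by
subtracting a fraction of the adjacent donor-excitation signal (direct
excitation), and cofactor presence is called when the corrected signal
exceeds background + 3 SD for ≥3 consecutive frames.

## Histogram mixture fits

Histograms use 0.02-FRET bins on [−0.1, 1.1] — wide enough bins to keep
per-bin counts meaningful, narrow enough to resolve the σ = 0.04
component.  Molecule-wise histograms take one mean efficiency per static
molecule (dynamic molecules are excluded by default, configurable);
frame-wise histograms take every usable frame.  Fits are nonlinear least
squares on bin centers with Poisson weights (`1/√max(count,1)`), run from
a multistart library (histogram peaks, distribution quantiles and their
combinations) because overlapping mixtures have rugged least-squares
landscapes; the lowest-cost solution is kept.  Areas are reported in
percent of the fitted total (they sum to 100 by construction), means and
widths in FRET percent, matching the published table conventions.
Components closer than one width trigger a degeneracy warning.

The constrained "global amplitude-only" mode fixes a shared state set
(means and widths); only amplitudes vary per histogram, plus a small
bounded per-histogram peak shift (default ≤0.01, the allowance for
condition-to-condition background differences — the published tables show
such shifts are condition-specific, e.g. an intermediate peak at 0.32
rather than 0.34 after ATP addition, so the bound is per histogram rather
than shared).  This constrained fit exists because the free decomposition
of strongly overlapped minor components is not identifiable: at n = 2000
even an exact EM fit shows ~0.1 bias on the ternary condition's
intermediate mean.  Scikit-learn's `GaussianMixture` serves as an
independent EM cross-check in the tests, never as the fitting path.

## Hidden Markov segmentation

Each dynamic molecule gets its own Gaussian-emission HMM, trained by
Baum–Welch on the corrected efficiency series (not the raw channels) with
scaled forward/backward recursions (numba kernels).  Convergence is an
absolute likelihood change below 1e-9; training restarts from 5 seeded
quantile-spread initializations and keeps the best likelihood.  Emission
SDs are floored at 1e-3 to avoid variance collapse; models with an
unoccupied state or adjacent means closer than half the pooled width are
flagged degenerate.  Model order is the smallest state count whose BIC
matches the best among 1–4 states (tolerance 0).  Viterbi decoding
tabulates transitions as (time, from-state mean, to-state mean).

Static/dynamic classification — manual in the original analysis — is
automated: a trace is dynamic iff the 3-state HMM improves BIC over a
one-state Gaussian (margin 0 by default) *and* the decoded path contains a
transition with both flanking dwells ≥2 frames.  On populations simulated
at the published static fractions this classifier recovers 60%-static
populations within a few points and calls >90% static after ATP.

The transition density plot superimposes a unit-mass 2D Gaussian (fixed
σ = 0.03 FRET, 101×101 grid on [0,1]²) per transition; kernels are
normalized on the discrete grid so the integral equals the transition
count exactly even at the border.  Subpopulation gates are rectangles at
the allowed state pairs — auto-seeded by k-means on transition coordinates
or supplied explicitly from known state means — and each molecule is
assigned to the subpopulation whose gate set captures the plurality of its
transitions (ties and zero-capture molecules stay unassigned; labels are
per-run constants).  Dwell times are decoded-path run lengths in seconds
with first/last dwells censored; state exit rates come from a
mono-exponential fit to the frame-resolved dwell histogram, which for
geometric (frame-discretized) dwells returns the discretization-corrected
rate `k = −ln(p_stay)/Δt` directly.  The censored-geometric MLE is the
in-test cross-check.

Known limitation: with the published emission widths (σ ≈ 0.08–0.09 at
state separations of ~0.2), Viterbi decoding mislabels ~1% of one-frame
intermediate-state passages as direct outer-state jumps, so the TDP of
*decoded* transitions shows ~1–2% of maximal density in the forbidden
S₁↔S₃ gates of a linear chain; on the generator's true transition set, and
on decoded data at σ ≤ 0.05, the forbidden-gate density is <1%.

## Survival analysis

Survival curves count still-fluorescent molecules on a 101-point grid
(censored molecules survive through the horizon).  Each arm is fitted with
the one-parameter mono-exponential `f(t) = exp(−kt)` — amplitude pinned at
1 — and the dissociation rate is `k₂ − k₁` of the treatment over its own
same-experiment control (photobleaching is alignment-dependent, so
controls are never pooled).  Negative differences are reported and
flagged, never clipped, so "no dissociation" conditions are reproduced
honestly.  Because the points of an empirical survival curve are strongly
correlated, the naive fit covariance underestimates the rate SE by an
order of magnitude; the reported SE instead propagates the binomial
covariance `Cov(S_i, S_j) = S(t_max)(1 − S(t_min))/n₀` through the normal
equations (delta method), which matches the seed-to-seed spread within a
few percent at n = 500.  The difference SE is the quadrature sum.
Concentration series are sorted tables with a Spearman rank-correlation
check; no functional form is imposed.  The right-censored exponential MLE
(`k = events/Σt`) is the independent oracle in the tests.

## Problem sizes

The test suite and acceptance script run on one CPU with deliberately
scaled problem sizes: 2000 molecule-wise values per histogram fit, 500
molecules per survival arm, 300 traces per classification or
subpopulation run, and 100 molecules × 2000 frames for the HMM ensemble —
large enough that binomial/fit noise sits well inside the stated
tolerances, small enough to rerun casually.
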