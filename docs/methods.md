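# Methods

## Signal model of the synthetic cohort

Task epochs are generated from coupled stochastic phase oscillators. Each
channel i carries a phase θ_i integrated by Euler–Maruyama at the sampling
rate:

    dθ_i = [ ω_i + g Σ_j K_ij sin(θ_j + φ_ij − θ_i) ] dt + η dW_i

with natural frequency ω_i drawn uniformly from the carrier band (default
4–8 Hz, the theta range), symmetric coupling K ∈ [0,1]^{N×N}, antisymmetric
target lags φ, coupling gain g, and phase-diffusion noise η. The observed
signal is `mixing @ (A cos θ)` plus white measurement noise: the mixing
matrix models volume conduction as instantaneous linear leakage — precisely
the confound wPLI is designed to reject, which gives the pipeline its key
negative control. With symmetric coupling, a pair (i, j) locks at the
stable phase difference φ_ij, so the generator's lags are exactly the
quantity the wPLI stage estimates.

### Default operating point

| parameter | default | rationale |
|---|---|---|
| sample rate | 1000 Hz | native acquisition rate of the emulated protocol |
| epoch duration | 60 s | one task trial |
| rest duration | 120 s | eyes-closed rest blocks |
| amplitude | 50 (µV-like) | scalp-EEG oscillation scale |
| measurement noise SD | 10 | ~0.2 of oscillation amplitude |
| coupling gain g | 6 rad/s | see below |
| phase noise η | 2.5 rad/√s | see below |
| carrier band | 4–8 Hz | theta |
| coupling strength (effect map) | 0.8 | strong but sub-locking per pair |

g and η jointly set the synchrony regime. They are chosen so the network
sits in *partial* synchrony: coupled pairs reach wPLI ≈ 0.4–0.5 while
uncoupled pairs stay near the estimator's null floor (≈ 0.1–0.2 at trial
length) — the regime in which sensor-level wPLI contrasts are actually
observable. Raising g well above the worst-case frequency detuning
(2π × bandwidth ≈ 25 rad/s) instead drives the whole network into a single
phase-locked cluster in which even uncoupled pairs show wPLI ≈ 1 and
condition contrasts vanish; tests that need the fully locked two-channel
limit pass a high gain explicitly.

Rest epochs are synthesized in the frequency domain: amplitude
√(P_bg + P_α) with random phases, where P_bg ∝ 1/f within 0.5–48 Hz
(slope 1.0) and P_α is a Gaussian bump (width 1.5 Hz) centered at the
subject's alpha peak with height 4× the local background — a prominent
eyes-closed alpha. Over the 7.5–12.5 Hz COG window the 1/f background alone
has centroid ≈ 9.8 Hz, so its bias on a 10 Hz peak is small; the recovery
tests bound the total COG error at ±0.5 Hz.

### Study designs

The default design is 4 test sessions × 4 scenarios × 4 trials (16 task
trials per session) with pre/post rest per session. An `effect_map` assigns
each (test, scenario) cell a coupling density and strength; each
(subject, test, scenario) cell draws one random coupling topology at that
density (lag magnitudes uniform in [π/4, 3π/4], random sign — away from 0
and π so imaginary cross-spectral mass is substantial), shared by the
cell's trials. All randomness descends from one top-level seed through
`SeedSequence(entropy=seed, spawn_key=(subject, test, scenario, trial))`,
so any single recording is regenerable in isolation. The default effect
map encodes the qualitative study pattern: density rising with difficulty
in T1, flat in T2, falling (0.50/0.35/0.25/0.20) in T3 and T4.

### What the generator does *not* emulate

No biophysical head model or realistic artifacts (blinks, EMG, electrode
drift), no 1/f background *during task epochs* (task channels are
narrowband oscillations plus white noise), no cross-frequency structure,
and the coupling topology is an unstructured random graph at prescribed
density rather than anything anatomically organized. Passing tests
therefore demonstrate that the estimator chain recovers known phase-lag
structure and rejects zero-lag leakage under controlled conditions; they
do not certify performance against real artifacts or realistic source
geometry.

## Preprocessing

Broadband filtering is a zero-phase Butterworth bandpass (sosfiltfilt),
default order 8 per edge, which keeps a 60 Hz mains tone below 5% of its
input RMS in steady state — comparable to the steep FIR filters standard
EEG toolboxes apply — while remaining phase-neutral for the downstream
phase metrics. Decimation requires an integer factor and relies on the
48 Hz upper edge as the anti-alias bound for the 250 Hz target. ICA-based
artifact removal is inherently manual (visual component selection) and is
deliberately *not* reimplemented; cleaned data can enter the pipeline
directly at the `Recording` level.

iAPF uses Welch PSD (2 s Hann, 50% overlap → 0.5 Hz resolution) averaged
over all channels, COG over a configurable 7.5–12.5 Hz window; the session
iAPF is the mean of the pre- and post-session rest estimates, and the
individual theta band is (4, 0.8 × iAPF), defined only for iAPF > 5 Hz.
Averaging over all channels (rather than a posterior subset) is a
documented default, configurable at call level.

## Connectivity

Analytic signals come from a zero-phase bandpass to the individual theta
band followed by the Hilbert transform, with 1 s trimmed per side to bound
filter/Hilbert edge transients. Cross-spectra are formed per sample,
matching the sum over t in the wPLI definition. Multiple segments of one
condition are aggregated by pooling numerator and denominator terms before
the ratio (equivalent to concatenation, robust to unequal segment
lengths); per-segment averaging is available via `aggregate="mean"`.

Two numerical conventions: (i) when the total imaginary cross-spectral
mass is zero the wPLI is defined as 0 — zero-lag coupling is what the
index exists to discount; the comparison uses a relative floor
(denominator ≤ 1e-12 × Σ|S|) because exactly-real cross-spectra retain
~1e-16 imaginary rounding residue in floating point. (ii) matrices are
explicitly symmetrized (0.5(W + Wᵀ)) to remove float asymmetry before
validation.

## Graph metrics

Binarization is strictly-greater-than the median of all upper-triangle
values pooled across the scenarios of each (subject, test) group — the
default scope keeps densities comparable exactly where scenarios are
compared; a single global threshold is available by config. Ties at the
median are non-edges.

Distances are BFS hop counts. L averages finite ordered-pair distances
only, with the unreachable-pair count carried in the results and logged
(an infinite L would poison λ; at ~50% density on 24 nodes disconnection
is rare). E_global gives unreachable pairs efficiency 0. E_local(i) is the
global efficiency of the subgraph induced by i's neighbors (i excluded);
nodes of degree < 2 score 0, as does their clustering term. Surrogates are
Maslov–Sneppen degree-preserving edge swaps (10 × |E| attempted swaps per
surrogate, default ensemble 100); graphs that cannot be rewired at all
(e.g. stars) fall back to density-matched G(n, m) random graphs with a
warning. σ = γ/λ is exact by construction; σ is undefined (error) if a
normalizer is 0.

γ is implemented as C/C_random — normalized clustering — per its defining
formula, even though some texts loosely label both γ and λ "normalized
path length".

## Statistics

The two-way fully-within ANOVA partitions SS into A, B, A×B, subjects, and
the three subject-crossed error strata; F uses the matching stratum.
Greenhouse–Geisser ε is computed per effect from the covariance of
orthonormal contrast scores (Kronecker contrasts for the interaction) and
applied *unconditionally* — conservative, and independent of an arbitrary
Mauchly threshold. ε is clipped to [1/(k−1), 1]. Generalized η² uses
SS_effect / (SS_effect + SS_subjects + all error SS), the fully-within
formulation. Implementation checks: main effects agree with pingouin to
6 decimals; all three effects, including the interaction ε, agree with R
`car::Anova` (type III, multivariate model) to 7 decimals on a frozen
fixture; the SS partition is conserved to 1e-8 relative; null calibration
of each effect's type-I error at α = 0.05 lies in [0.03, 0.07] over 1000
simulated 3×4, n=20 null datasets.

Degenerate strata (zero error variance) are flagged rather than producing
infinite F: F = 0 when the effect is also null, +inf otherwise, and
mass-univariate runs skip such units with a logged reason. Bonferroni
divisors equal the number of units tested: 276 channel pairs or 24
channels for this montage. Post hoc paired t-tests report raw and
Bonferroni-corrected p; zero-variance differences are flagged degenerate.

## Pipeline and problem sizes

`run_all` executes all stages from a single `RunConfig` (YAML-loadable,
unknown keys rejected), writes a manifest (config + package version)
sufficient to regenerate every output bit-identically, and logs the
silent filters — segments discarded, unreachable pairs, degenerate units.
Scenario exclusion (L3 by default) and the surrogate count (default 100)
are config. The test suite and the analysis drivers run scaled-down
cohorts — typically 3–10 subjects, 1–2 sessions, 2 trials of 40 s at
250 Hz generation rate — sizes chosen so the full chain, including the
pattern-recovery analysis, completes in minutes on a single core while
leaving the estimator operating in the same regime as the full protocol
(the pooled per-condition data length, which controls the wPLI null
floor, is kept comparable).

## Known limitations

* The generator's task epochs are stationary; no within-trial workload
  dynamics.
* Kuramoto phase pulling plus measurement noise is a caricature of neural
  mass dynamics; it provides ground-truth lags, not biophysics.
* Only G-G correction is implemented (no Huynh–Feldt), and sphericity is
  never tested — the correction is always applied.
* Weighted-graph variants of the metrics, other synchronization indices
  (PLV, coherence, PLI), and cluster-based family-wise control are out of
  scope.
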