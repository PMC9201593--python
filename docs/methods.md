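# Methods

This note documents the models and estimators implemented in `pmconn`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical corner cases. Problem sizes quoted here are
the package's validation choices.

## Signal model and preprocessing

A `Recording` is a channels × samples matrix (µV) with a sampling rate and
per-channel (area, layer) labels. All IIR filters (Butterworth band limits,
mains notches) are applied forward–backward: zero phase costs a doubled
effective order but keeps lag structure intact, which matters because every
directed-connectivity statistic downstream is a function of lags. Notch
filters default to quality factor 25, giving ≥ 20 dB rejection at the notch
and < 1 dB ripple 5 Hz away after the two passes. Epoching is non-overlapping
and contiguous from the recording start; an epoch intersecting any
caller-flagged artifact sample is dropped whole. Resampling is polyphase with
a built-in anti-alias FIR (content above the new Nyquist attenuated ≥ 20 dB,
passband below 0.8 × Nyquist preserved within 5 %).

## Spectral power

Power spectral density uses DPSS (Slepian) multitapers with time–bandwidth
product NW = 2 (three tapers) on short segments cut from the epochs, default
50 ms, averaged over tapers, segments and epochs. The 0.25-Hz output grid is
obtained by zero-padding (NFFT = fs / 0.25); one-sided scaling preserves
Parseval (integrated PSD = variance, verified to < 5 % on white and 1/f
noise). Be aware that 50-ms segments have a ± 40-Hz half-bandwidth: fine
structure below ~40 Hz is smeared, which preserves the ordering of band
means on monotone spectra (delta still dominates on 1/f input) but hides
narrow lines; quantities that need sharp resolution (e.g. the 1/f slope, a
50-Hz line falling between the gamma bands) are measured with 2–4-s segments
instead. Band tables interpret printed integer edges half-open —
[low, high + 1 Hz) — so adjacent printed bands tile without overlap and
50 Hz falls in the gap between low and medium gamma. The mouse delta preset
starts at 0.1 Hz, the high-pass edge of the standard pipeline.

## Coherence and its surrogate null

Coherence is Welch-estimated with 2-s Hann segments and 50 % overlap (native
0.5-Hz grid), reported on 0.5–100 Hz. The null distribution is built by
shuffling the order of 500-ms blocks of **one** channel (shuffling both can
preserve alignment classes) and recomputing the spectrum, 100 permutations by
default; block permutation preserves the surrogate channel's marginal mean,
variance and histogram while destroying cross-channel temporal structure. A
frequency or band is significant when the observed value exceeds the
(1 − α) surrogate quantile, α = 0.05 by default (α ≥ 1 degenerates to
everything significant). Calibration on independent signals gives an
empirical type-I error within ± 0.03 of nominal, and power ≈ 1 against the
band-coupled generator at unit gain. The estimator floor for K segments is
≈ 1/K; with few segments "significant" and "non-trivial" are different
claims.

## Time-resolved partial directed coherence

The time-varying VAR is fit by ordinary least squares in sliding windows
(default 2 s, stepped 0.5 s, on 200-Hz data). Windowed OLS was chosen over
adaptive (Kalman/RLS) estimators because it is deterministic, testable and
adequate for quasi-stationary resting-state data. The model order is chosen
once on the full series by minimum AIC over p = 1…30 and held fixed across
windows; ties go to the smaller order. The grid extends to 30 because a
band-limited delayed coupling carries the filter's group delay on top of its
nominal lag — nominal lags of 20 samples put most of the influence at lags
20–30, and an under-ordered VAR both misses the influence and corrupts the
time-reversal behaviour of the fit.

PDC at frequency f from coefficients A₁…A_p is
`PDC(i←j, f) = |Ā_ij(f)| / sqrt(Σ_k |Ā_kj(f)|²)` with
`Ā(f) = I − Σ_r A_r e^{−i2πfr/fs}`; columns are normalized exactly
(Σ_i PDC² = 1). TPDC evaluates PDC per window on a 0.5-Hz grid to 100 Hz,
averages over windows, then over band bins, giving one scalar per ordered
pair and band. Window-averaged PDC has a noise floor at true-zero entries
(E|noise| of the per-window coefficient error), so oracle comparisons against
analytic PDC use windows long enough (10–30 s) that the floor sits below the
comparison tolerance.

### Time-reversal significance

A directed edge source → target is significant in a band iff the forward
asymmetry Δ = TPDC(source→target) − TPDC(target→source)

1. exceeds the (1 − α) quantile of |Δ| over block-shuffle surrogates
   (independent 500-ms block permutations per channel, n = 20 by default);
2. is significantly positive by a one-sided t-test on the per-window
   asymmetries, with the effective window count reduced by the overlap
   factor window/step; and
3. is significantly **negative** by the same t-test on the time-reversed
   series.

The rationale for the three parts: the shuffle null alone underestimates the
sampling variability of Δ when channels share an instantaneous (volume-
conducted) component, because shuffling destroys that component — the
across-window dispersion measures Δ's variability under whatever covariance
the data actually has. And requiring the reversed asymmetry to be
significantly negative (not merely negative) removes the coin-flip behaviour
of a bare sign check when the reversed asymmetry is near zero. A genuine
time-lagged interaction reverses fully under time reversal; instantaneous
mixing produces near-zero reversed asymmetries and fails part 3. Measured on
the generators: ground-truth direction recovered and flagged in 20/20 seeds
across nominal lags 1–20 samples, the call reverses with the coupling, and
under pure instantaneous mixing the false-call rate is 0/50 seeds (bound
α + 0.03).

Channel selection for TPDC follows the pipeline convention: one channel per
(area, layer) group, the one with the highest theta-band (4–7 Hz) power, ties
to the lowest channel id.

## Spike sorting

Detection operates on the 0.3–3-kHz band-passed trace. The noise SD is
estimated as median(|x|)/0.6745 by default — the raw SD is inflated by the
spikes themselves; `noise_estimator="raw"` restores the literal reading.
Local minima below −5 SD are events (1-ms dead time); any deflection beyond
30 SD is discarded as an artifact, a hard guarantee on retained events.
Waveforms span −0.5…+3 ms around the negative peak and are aligned on a 4×
upsampled grid: at sharp peaks, ± 1 sample of alignment jitter otherwise
dominates waveform variability and splits units.

Features are Haar wavelet coefficients (4 levels), ranked by the
Kolmogorov–Smirnov deviation of their z-scored distribution from a standard
normal; the 10 most non-Gaussian coefficients are kept (a constant
coefficient scores 0 and is never selected). Clustering is super-paramagnetic:
a q = 20 Potts model on the K = 11 nearest-neighbour graph with couplings
J = (1/K)·exp(−d²/2a²), Swendsen–Wang sampled at temperatures 0…0.2 (step
0.01, 80 sweeps after 20 burn-in); edges with pair correlation > ½ define
clusters. The working temperature maximizes the number of clusters with at
least `min_cluster` (= 20) members, ties toward the most assigned events and
then the colder temperature — the hottest temperature at which *some*
cluster still exceeds the minimum systematically lands past the
super-paramagnetic plateau, where clusters are eroded fragments. Two
post-steps mirror standard sorting practice: clusters whose centroids are
closer than the larger of their rms radii are merged (SPC can carve one
cloud in two at a sparse graph bottleneck), and, in the full pipeline,
leftover unassigned events join the nearest centroid if within 3 rms radii
(`spc_cluster` itself leaves them unassigned, so
assigned + unassigned = detected always holds). The quality screen drops
units with > 2 % inter-spike intervals under 1 ms or > 30 % mean-amplitude
drift between recording halves. On labeled traces (3 templates at SNR 8) the
pipeline recovers the unit count in 10/10 seeds with ≈ 98 % correct
assignments.

## Path (SEM) modelling

Observed-variable recursive path models only — all modelled quantities
(TPDC, coherence, power, unit rate) are measured, not latent. Parameters are
the free path coefficients B and the diagonal disturbance covariance Ψ
(mediator residual covariance can be freed by flag); the implied covariance
is Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ and estimation minimizes the ML discrepancy
F = log|Σ| + tr(SΣ⁻¹) − log|S| − k. Optimization runs on the correlation
scale and maps estimates back — an exact reparameterization that keeps the
problem conditioned when variables differ by orders of magnitude (band power
vs firing rate). χ² = (n−1)·F_min, df = k(k+1)/2 − free parameters,
RMSEA = sqrt(max(0, (χ²−df)/(df(n−1)))) with the df = 0 case defined as 0,
AIC = χ² + 2q (the −2lnL + 2q variant is reported alongside). Standard
errors come from the numerical Hessian of F (acov = 2/(n−1) · H⁻¹);
standardized coefficients use model-implied variances and are invariant to
positive column rescaling (verified to 1e−8). The "invariance under constant
scaling" diagnostic is implemented as the maximum change of any standardized
coefficient under random positive column rescalings — a substitute
definition, since no standard formula exists for the published criterion.
Calibration: under a true two-mediator model at n = 500 the χ² rejection
rate at the 0.05 critical value is within ± 0.03 of nominal. Note that for
df = 1 the true-model probability of a sample RMSEA below 0.05 at n = 500 is
P(χ²₁ < 2.2475) ≈ 0.87 — a "good fit" threshold, not a 95 % criterion.

## Group statistics

Welch (unequal-variance) two-sample t-tests per factor level with Bonferroni
adjustment p_adj = min(1, m·p); m defaults to the number of comparisons made
in the call and can be pinned to a predefined family size (7 bands, 9 layer
pairs).

## Synthetic generators: what they emulate and what they do not

- **VAR processes** — exact, stable (companion spectral radius < 1 enforced)
  linear systems; the oracle substrate for PDC/TPDC.
- **Band-coupled LFP** — 1/f^α backgrounds made by FFT amplitude shaping
  (exact slope control; α = 1 default), plus directed coupling injected as a
  causally band-passed (4th-order Butterworth), delayed, scaled copy of the
  source background, and optional full-rank instantaneous mixing for volume
  conduction. Defaults: unit-variance channels, gain 1, beta band.
- **Spiking traces** — Gaussian noise plus biphasic negative-dominant
  templates (default 1.5-ms width, lobes scaled to the width) at stated
  times; ≥ 20-kHz rates enforced.
- **Mediation tables** — linear structural equations with independent
  Gaussian disturbances; by default disturbance variances are chosen so all
  variables have unit population variance, making the path coefficients the
  population standardized coefficients. The validation truth
  (0.8/0.75/0.5/0.3/0.25) spans the coefficient range typical of strong
  observed mediations.

Not emulated: conductance-based neurons, forward head models and sensor-level
mixing geometry, non-Gaussian or nonstationary noise, electrode drift,
overlapping-spike decomposition, correlated disturbances. Passing tests
therefore demonstrate correctness and calibration of the estimators under
the stated generative assumptions — linear coupling, Gaussian noise,
quasi-stationarity — not performance on tissue data.

## Validation problem sizes

PDC oracle: random stable VARs (k = 2, 3; p ≤ 3) at machine precision; TPDC
vs analytic bands on 5 min of simulated 200-Hz data from a constant VAR(2),
30-s windows. Direction recovery: 20 seeds × 120-s two-channel recordings,
nominal lags 1–20 samples (plus 10 reversed-coupling seeds). Volume
conduction: 50 seeds × 60 s under symmetric mixing. Surrogate calibration:
50 null runs and 20 coupled runs of 40 s at 500 Hz, 100 permutations each.
Spikes: 10 seeds × 40-s traces at 20 kHz, three units at ~3 Hz. SEM: 20
recovery fits and 200 calibration fits at n = 500. Determinism: the full
10-subject pipeline run twice and compared by manifest hash. The pipeline
demo config (10 subjects, 15–30-s recordings, reduced surrogate counts)
completes in a few minutes on one CPU.
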