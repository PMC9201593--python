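# pmconn — premotor–motor cortical connectivity analysis

`pmconn` implements a laminar electrophysiology connectivity pipeline for the
premotor–motor system: human premotor cortex (PMC) → primary motor cortex
(M1), and their proposed mouse homologs, the rostral (RFA) and caudal (CFA)
forelimb areas. From multichannel field-potential recordings it computes

- **band-resolved spectral power** — DPSS multitaper estimates on 50-ms
  segments, 0.25-Hz grid, aggregated over a configurable band table
  (mouse preset: delta 0–3, theta 4–7, alpha 8–15, beta 16–31, low gamma
  32–49, medium gamma 51–75, high gamma 76–100 Hz);
- **functional connectivity** — magnitude-squared coherence
  |S<sub>xy</sub>|² / (S<sub>xx</sub>S<sub>yy</sub>) on a 0.5-Hz grid with a
  Monte-Carlo surrogate test (100 shuffles of 500-ms blocks);
- **effective (directed) connectivity** — time-resolved partial directed
  coherence (TPDC): sliding-window VAR fits, PDC
  `|Ā_ij(f)| / sqrt(Σ_k |Ā_kj(f)|²)` with `Ā(f) = I − Σ_r A_r e^{−i2πfr/fs}`,
  screened for significance by the time-reversal technique (TRT) so that
  volume conduction does not masquerade as directed influence;
- **single units** — negative 5-SD threshold detection with a 30-SD artifact
  guard, −0.5…+3-ms waveforms, KS-ranked Haar wavelet features,
  super-paramagnetic (Potts Monte-Carlo) clustering and a quality screen;
- **path (mediation) modelling** — maximum-likelihood SEM over observed
  variables (directed influence → coherence & power mediators → unit
  activity) with standardized coefficients, χ², RMSEA and AIC;
- **group statistics** — Bonferroni-corrected Welch t-tests per band.

Because the recordings behind these methods are not publicly deposited, the
package ships a first-class synthetic-data module that generates every input
with known ground truth — stable VAR processes, 1/f-background LFP with
strictly causal band-limited coupling and optional instantaneous mixing,
wide-band traces with embedded spike waveforms, and mediation feature
tables — so every stage is validated end-to-end against the truth that
generated its input.

## Worked example

`analysis/` contains numbered drivers that run the whole study on synthetic
data (later scripts read what `01` writes to `results/`):

```bash
python analysis/01_simulate_recordings.py
python analysis/02_band_power.py
python analysis/03_coherence.py
python analysis/04_directed_influence.py
python analysis/05_spike_sorting.py
python analysis/06_mediation_model.py
python analysis/07_group_statistics.py
```

`01` simulates a 4-channel laminar recording (RFA L5/L2-3, CFA L2/3/L5,
60 s at 1 kHz) whose only asymmetry is a beta-band (16–31 Hz) coupling from
RFA L5 into CFA L2/3 with 25 ms lag. The downstream scripts then print,
among other output:

```
largest band per channel: ['delta', 'delta', 'delta', 'delta']
highest coherence in the beta band (significant: True)
beta TPDC RFA->CFA = 0.668 (delta +0.479, TRT significant: True)
detected 338 events (noise SD 0.500), 3 units kept at T=0.01
chi2 = 0.919 (df=1), RMSEA = 0.0000, AIC = 18.92
```

Reading these numbers: delta carries the most power (1/f background), the
coherence spectrum peaks exactly in the imposed coupling band, the directed
beta influence is recovered in the true direction (TPDC 0.668 RFA→CFA vs
0.189 CFA→RFA) and survives the time-reversal screen, all three embedded
units are isolated with clean refractory statistics, and the two-mediator
path model reproduces its generating standardized coefficients with a
non-significant χ² (the model is true).

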