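# Methods

`seqssvep` implements the analysis chain for asking whether *spatially
organized sequential visual flicker* enhances high-frequency (100–190 Hz)
LFP power in visual cortex, together with a synthetic recording generator
that provides ground truth for every stage. This note documents the models,
the parameters that matter, the numerical choices, and the limits of what the
synthetic validation shows.

## Stimulus model

A sequential stimulus splits the screen into `N` checkerboard sections
(wedges or bars; `N ∈ {6, 7, 14}` canonically) and exposes exactly one
section per screen refresh cycle, cycling `0, 1, …, N−1, 0, …`. Two derived
quantities drive everything downstream:

- **repeat frequency** `f_rep = refresh_hz / N` — the rate at which any one
  section is re-exposed (10.29–40 Hz over the 4 kinds × 3 refresh rates
  battery; 9 distinct values among the 12 conditions, since the two wedge
  kinds share `N = 6`);
- **section phase shift** `1000 / refresh_hz` ms — the delay between
  neighbouring sections (6.94 ms at 144 Hz).

Reported frequencies are rounded half-up to one decimal; exact rationals are
kept internally. A 2 s trial need not hold an integer number of section
cycles (288 frames / 14 sections leaves a partial cycle); the partial cycle
is presented and the next trial restarts at section 0, which makes all trials
identical and is what trial averaging assumes. Schedules are abstract
(section index per frame); rendering, screen warping and gamma are out of
scope. Trials are 2 s stimulus alternated with 2 s gray, 50 trials per
condition, with one leading gray period so the first trial has a defined
baseline.

The full-field chirp used as a comparison stimulus is a piecewise trace:
luminance steps (2.2 s black, 3.3 s white, 3.3 s black, 2.2 s gray), an
8.75 s full-contrast frequency sweep 0.5→11 Hz, an 8.75 s contrast sweep
0→100 % at 0.4 Hz, and 2.2 s gray.

## Synthetic recordings

The generator emulates a 384-channel Neuropixels LFP at 2.5 kHz (10 µm per
sorted channel) just closely enough to exercise the pipeline with known
answers. It is *not* a biophysical simulation; it injects phenomena, it does
not arbitrate their mechanism.

- **Background**: per-channel Gaussian noise with power ∝ 1/f^α (default
  α = 1), synthesized in the frequency domain with random phases and
  normalised to 25 µV RMS. Channels are independent — real LFP is spatially
  correlated, so spatial-smoothness claims are untestable here.
- **SSVEP**: during stimulus windows, a harmonic series at `f_rep`
  (fundamental 40 µV, amplitudes 1/h, 3 harmonics by default), anchored at
  trial onset so it survives trial averaging, with a linear phase progression
  across channels mimicking retinotopy.
- **High-frequency injection**: on a contiguous channel span, band-limited
  Gaussian noise (Butterworth order-4 bandpass of white noise, 100–190 Hz by
  default) added during stimulus windows with 10 ms cosine ramps, scaled so
  the band power rises by the factor `hf_gain`. The injected noise is
  independent across trials — like genuine induced (non-phase-locked)
  activity, its trial average retains the power ratio even as the absolute
  level drops.
- **Spikes**: an inhomogeneous Poisson process with rate
  `r0 · exp(κ cos(φ(t) − μ)) / I0(κ)` inside stimulus windows (`φ` the phase
  of the repeat-frequency sinusoid), simulated by thinning. Spike phases are
  then exactly von Mises(μ, κ) and the mean rate stays `r0`; κ = 0 is
  homogeneous Poisson, κ = ∞ places one spike per cycle exactly at μ.
- **Waveforms**: biphasic templates (negative trough, delayed positive peak)
  at 30 kHz in two classes with trough-to-peak durations kept ≥ 0.02 ms away
  from the 0.43 ms class boundary.
- **Sparse-noise responses**: Poisson counts per 100 ms frame with rate
  `base + peak · Σ_targets exp(−d²/2σ²)` around a ground-truth centre
  (σ = 10° by default) on a 36 × 22 grid, 2 targets per frame. Grid positions
  are spaced one 15° square apart; only relative distances matter in the
  validation, and the spacing is configurable.

Everything is deterministic given `rng_seed` (sub-streams are spawned per
component). Defaults — trial structure, channel counts, band, rates — are
fixed once as the emulated study conditions and are not tuned per test.

## LFP spectral chain

1. **Preprocess**: Butterworth order-3 band-pass 0.1–400 Hz applied
   forward-backward (zero phase, so evoked latencies are unbiased; the filter
   family and order are fixed, zero-phase application is our choice), then
   downsampling to 1250 Hz by averaging neighbouring samples (the decimation
   factor must be an integer).
2. **Evoked response**: per-channel mean and SEM across the 50 repeats of a
   condition, aligned to stimulus onset.
3. **Stockwell transform**: the S-transform
   `S(t, f) = ∫ x(τ) (|f|/√2π) e^{−(t−τ)²f²/2} e^{−2πifτ} dτ`
   computed by the frequency-domain algorithm: per voice `n`, the FFT of the
   signal is shifted by `n` bins, multiplied by the periodised Gaussian
   `Σ_q exp(−2π²(m+qN)²/n²)`, and inverse-transformed. The `f = 0` voice is
   the signal mean. The Gaussian window scales with frequency, so time
   resolution is ~one period at every voice. An independent brute-force
   oracle (direct time-domain sum with the periodised window) pins the
   implementation to 1e−8 relative error in the tests.
4. **Evoked Z-spectrum**: per (frequency, channel),
   `z = (A − B)/(A + B)` with `A` the time-mean S magnitude over the stimulus
   window [0, 2000] ms and `B` over the baseline [−500, −5] ms. `z` is
   bounded in (−1, 1] for non-negative spectra, 0 where both vanish (counted
   and warned). The stimulus-window term is time-averaged like the baseline
   so the result is one value per frequency and channel.
5. **High-frequency metrics** on a fixed 1 Hz grid (so the absolute-unit
   threshold is comparable across runs regardless of native voice spacing):
   - *amplitude* = trapezoidal area of `|Σ_ch z(f, ch)|` over the band;
   - *size* = number of channels with `|Σ_f z(f, ch)| > 15 a.u.`, converted
     to µm via the 10 µm channel pitch, with a flag when the extent exceeds
     500 µm.
   The default band is 100–190 Hz; both band edges, the threshold and the
   channel range are configuration, never hard-coded (for synthetic data the
   channel range is the known visually driven span).

**Edge handling.** The discrete S-transform treats its input circularly, so
the wrap discontinuity between epoch end and epoch start splashes broadband
energy into the first and last few milliseconds of the epoch. With an epoch
cut exactly at [−0.5, 2.0] s that splash lands at the very start of the
baseline window and inflates `B` (the short baseline is ~5× more sensitive to
it than the 2 s stimulus window), biasing `z` negative everywhere. Analysis
epochs are therefore padded to [−1.0, 2.5] s while the z windows themselves
stay at the definitions above.

## Unit analysis

- **MUA**: common median across channels subtracted per sample, Butterworth
  order-2 band-pass 0.3–3 kHz (zero-phase), events where |signal| exceeds
  4 per-channel SDs, 1 ms dead time per channel.
- **Waveform classes**: trough-to-peak duration of the template; narrow
  (putative fast-spiking) below 0.43 ms, broad otherwise — the boundary value
  itself is assigned to broad; monotone templates are rejected.
- **ISI quality**: fraction of inter-spike intervals below the 2 ms
  refractory period; units pass QC below 0.05 %.
- **Responsiveness**: PSTH evoked peak (500–2000 ms) must reach baseline
  mean + 7.5 baseline SD (the SNR gate is read as mean + 7.5·SD across
  baseline bins). A zero-variance baseline degenerates to strict exceedance
  of the baseline level, warned explicitly.
- **Receptive fields**: STA over the sparse-noise grid, normalised by
  presentation counts, upsampled by 2-D cubic splines; centre = interpolated
  peak, size = mean width at half the peak amplitude along azimuth and
  elevation, SNR = peak deviation from the map mean over the SD of the
  outermost ring of grid squares (the estimator behind the 15 a.u. gate is
  our choice). Coverage = maximal pairwise distance between gated centres.
- **Phase locking**: spike phases are stored in cycles,
  `frac((t − t0)·f_rep)`, restricted to stimulus windows, and converted to
  radians before trigonometry. PPC is the mean over spike pairs of
  `cos(θ_j − θ_k)`, evaluated through the resultant identity
  `(|Σe^{iθ}|² − N)/(N(N−1))` and checked against the O(N²) double loop in
  the tests; it is undefined below 2 spikes. Aggregation is per unit, then
  across units within a recording, then across recordings. For von Mises
  phases the expected PPC is `(I1(κ)/I0(κ))²`.

**Partial-cycle caveat.** When a trial does not hold an integer number of
repeat cycles (e.g. 20.57 cycles at 10.29 Hz), even a homogeneous Poisson
process has slightly non-uniform phases — the truncated final cycle
over-represents early phases — giving a true PPC of ~2×10⁻⁴ at κ = 0 under
the default trial structure. This is a property of the definition, not an
estimator bias; the analytic recovery test therefore uses a condition with an
integer cycle count (24 Hz wedge, 48 cycles per trial).

## Statistics

Mice are the unit of inference: unit- or channel-level values are pooled
within mouse before testing. Paired condition contrasts use the exact
two-sided Wilcoxon signed-rank test (exact null for n ≤ 25, zero differences
dropped per Wilcoxon's prescription); with 6 subjects the attainable floor is
2/2⁶ = 0.03125. Factorial designs (waveform class × repeat frequency) use
two-way repeated measures ANOVA with Bonferroni-corrected pairwise
post-hocs, delegated to pingouin behind this module's interface; the
degenerate all-cells-equal design is reported as F = 0, p = 1. No sphericity
correction is applied by default (uncorrected p is reported alongside
pingouin's Greenhouse–Geisser column).

## Workflow and problem sizes

`run_pipeline` executes simulate → LFP chain → unit chain per condition with
per-condition seeds spawned from the run seed, and writes a report (JSON,
validated against a schema shipped with the package) carrying config hash,
seeds, versions and every threshold applied. Runs are bit-identical under a
fixed config.

Desk-scale defaults keep the full validation tractable: the end-to-end
high-frequency recovery runs at 120 channels (50-channel injected span) with
the full 50-trial structure; the demo battery runs all 12 sequential
conditions plus a checker at 16 channels × 6 trials; PPC recovery uses
20 replicates of ~10,000 spikes. These sizes are the package's validation
conditions, chosen to exercise every code path with tight statistics.

## Limitations

- The generator's channels are spatially independent and its SSVEP is a
  fixed harmonic series; passing tests demonstrate correct *recovery of
  injected structure*, not that real cortex behaves this way (travelling
  waves, laminar structure and spike-sorting artefacts are all absent).
- Welch PSDs and the Stockwell chain operate on the trial-averaged evoked
  response; induced activity that is weak relative to the averaged background
  would need per-trial spectra, which the package does not compute.
- Whether the amplitude AUC should span the full frequency axis or only the
  high-frequency band is exposed as a parameter (band-limited by default).
- The spatial-size threshold (15 a.u.) is only meaningful on the fixed 1 Hz
  grid; changing the grid rescales cumulative profiles and the threshold with
  it.
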