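# Methods

`eegemo` implements subject-independent emotion recognition from multichannel
EEG with a region-to-global hierarchy: the scalp is partitioned into nine
anatomical regions, each region's band-power dynamics are encoded by a
dual-stream recurrent/attention encoder, a global encoder combines the nine
regional summaries, and a softmax layer predicts the emotion class.  This
note records the model, the numerical choices, what the synthetic generator
does and does not emulate, and the package's known limitations.

## Electrode regions

The bundled `deap32` layout divides the standard 32-electrode 10–20 montage
into prefrontal (R1: Fp1, Fp2, AF3, AF4), frontal (R2: F7, F3, Fz, F4, F8),
left/right temporal (R3: FC5, T7, CP5; R4: FC6, T8, CP6), central (R5: FC1,
C3, Cz, C4, FC2), left parietal (R6: P3, P7, PO3), parietal (R7: CP1, Pz,
CP2), right parietal (R8: P8, P4, PO4) and occipital (R9: O1, Oz, O2)
groups.  Regions are data, not code: custom layouts (e.g. a 62-channel cap,
for which no canonical nine-way division is bundled) are JSON/YAML files
mapping `R1`..`R9` to label lists.  Label matching is case-insensitive and
whitespace-stripped because EDF headers vary; channels a montage does not
name (EOG, GSR, …) are ignored with a warning.

## Preprocessing

Per channel, in order:

1. **Baseline drop.** The pre-trial baseline (e.g. 3 s in DEAP-style trials)
   is removed, not subtracted — the pipeline treats it as non-trial signal.
2. **Bandpass 4–47 Hz.** 4th-order Butterworth applied forward-and-backward
   (`sosfiltfilt`), so the passband is zero-phase and segment boundaries stay
   aligned with the raw recording.  The band keeps theta–gamma and discards
   drift, delta and mains.
3. **Downsample to 128 Hz** by polyphase rational resampling (exact ratios
   512→128, 256→128) with built-in anti-aliasing.  Upsampling is refused.
4. **Blink handling.** Blinks are detected on prefrontal channels only (they
   are frontally dominant); concealment is applied per channel where a
   section was found.  The default detector computes a 200 ms moving RMS and
   thresholds it at `median + 12·MAD` of the channel's own RMS trace, merges
   candidates closer than 100 ms, discards candidates shorter than 100 ms,
   and snaps boundaries outward to zero crossings.  The 12-MAD threshold is
   set from the separation between background EEG (RMS excursions up to
   ~10 MADs) and blinks a few times the background RMS (>15 MADs).  The
   detector is a pluggable strategy — any
   `detector(signal, fs) -> [ArtifactInterval]` can replace it, e.g. a
   spectral-domain estimator.
5. **Concealment.** For an artifact section of length `n`, the `n` samples
   before and after it are crossfaded with complementary linear ramps,
   `(1−w)·pre + w·post`, `w` rising 0→1; the result replaces the section.
   The weights sum to one pointwise, so a constant signal passes through
   unchanged (exact to float precision), and the signal outside the section
   is untouched.  Context that would run off the signal is mirror-padded.
6. **Segmentation** into 1 s windows with 50% overlap;
   `T = floor((L−W)/H)+1` windows with hop `H = W/2`; trailing samples that
   do not fill a window are dropped.

## Band-power features

Each 1 s segment yields a 4-vector of average power in theta (4–7 Hz), alpha
(8–12), beta (13–30) and gamma (31–47); delta is excluded as a deep-sleep
band.  The estimate is Welch-style: a 0.25 s Hann window (32 samples at
128 Hz) slides with 80% overlap — the nominal 6.4-sample hop is rounded to
6 samples since hops must be integer — per-frame periodograms are normalised
by window energy, averaged, and each band value is the linear mean over the
band's FFT bins (a `log10` variant sits behind a flag).  At the 4 Hz bin
resolution, a bin belongs to a band if it lies within the printed edges;
bins in the printed gaps (7–8, 12–13, 30–31 Hz) go to the lower band, a
deterministic convention.

Per region r this gives the tensor `S[r]` (4 × N_r × T).  The two encoder
views collapse it by arithmetic mean: the channel sequence
`H[r] = mean_T S[r]` (4 × N_r) and the time sequence `U[r] = mean_{N_r} S[r]`
(4 × T).  The mean is this package's aggregation choice; `S` is retained so
alternatives can be derived.

## Model

Each region has two stream encoders (spatial over `H[r]`, temporal over
`U[r]`), each a **2BGRUA**: two stacked bidirectional GRU layers, then
single-head scaled dot-product self-attention, then mean pooling over
sequence positions.

GRU convention (pinned for reproducibility): update gate
`z = σ(xW_z + hU_z + b_z)`, reset gate `r = σ(xW_r + hU_r + b_r)`, candidate
`h̃ = tanh(xW_h + (r⊙h)U_h + b_h)`, state `h' = (1−z)⊙h + z⊙h̃`, initial
state zero.  A BGRU runs one GRU forward and one backward and concatenates
the states, so hidden size `d` yields outputs of size `2d` per position.
Attention uses one Q/K/V triple of square projections,
`softmax(QKᵀ/√d_K)V`, with row-max subtraction inside the softmax.

Attention outputs are sequences while the downstream fusion needs one
fixed-length vector per stream; mean pooling over positions provides it,
keeping the interface independent of N_r (3–5 channels) and T.  The region
vector `L_r` concatenates (spatial, temporal) pooled outputs (length
`2·d_gc + 2·d_gs`); the nine `L_r` form a 9-token sequence which a
single-layer BGRU (hidden `d_g`) turns into nine `2·d_g` states, re-weighted
by one more self-attention block, mean-pooled into the global feature `G`,
and classified by `softmax(W_z G + b_z)`.  Argmax ties break to the lowest
class index.

Each region has its own encoder parameters by default (`shared_regions=True`
shares one set).  Weights are Glorot-uniform, biases zero, all seeded.
Reference hidden sizes are `d_hc = d_hs = 64`, `d_gc = d_gs = 32`,
`d_g = 64`; the desk-scale experiments use 8 throughout (see below).

### Autodiff and training

No deep-learning framework is used: the network runs on a minimal tape-based
reverse-mode autodiff engine over float64 numpy arrays
(`eegemo.autodiff`), providing exactly the operations the model needs.
Gradient correctness is verified against central finite differences
(relative error < 1e-4 at randomly sampled parameters; in practice ~1e-7).

The loss is L2-regularised cross-entropy,
`−(1/Z) Σ log p(y) + (λ/2)‖θ‖²`, minimised by Adam (β₁ 0.9, β₂ 0.999,
ε 1e-8).  Library defaults: learning rate 1e-3, λ 1e-4, batch 32, up to 100
epochs, early stopping with patience 10 on a 10% seeded validation split
(training-loss monitoring when the set is too small for a split or
`val_fraction = 0`), best parameters restored; an optional `stop_loss` floor
ends training at convergence.  Feature standardisation is z-scoring per
feature, fit on training trials only — never on the held-out subject.

## Labels and evaluation

Self-assessment ratings on the 1–9 scale map to classes by the printed
integer ranges: two-level 1–5 → Low, 6–9 → High; three-level 1–3 / 4–6 /
7–9; four-level from the cross of two-level valence × arousal (HVHA, LVHA,
LVLA, HVLA, class indices in that order); SEED-style categorical −1/0/1 maps
to 0/1/2.  Continuous ratings are floored into the integer ranges (5.5 →
5 → Low), a documented convention for the unspecified boundary behaviour.

Evaluation is leave-one-subject-out: one fold per subject, the model freshly
initialised per fold, trained on all other subjects and scored on the
held-out one; one prediction per trial (no segment-level voting).  Accuracy
is the fraction of correctly classified trials; folds aggregate by
unweighted mean and standard deviation.  Method comparisons use a two-sided
paired t-test over per-subject accuracies (scipy); identical nonzero
differences report p = 0 with a warning since the statistic diverges, and
identical vectors raise.

## Synthetic data

`eegemo.synthetic` generates labelled EEG with exactly the structure the
pipeline assumes: per channel, one oscillator per band (frequency uniform
within the band per trial, random phase; base amplitudes 4/5/3/2 µV for
theta/alpha/beta/gamma) plus 1/f noise (5 µV RMS, exponent 1); classes
amplify their signature (region, band) amplitude by a multiplier; subjects
carry a log-normal global gain (sd 0.2); blinks are 300 ms raised-cosine
deflections on prefrontal channels (default 8× background RMS, 6/min) with
ground-truth positions recorded; ratings are written at class-prototypical
integer values so label mapping round-trips exactly.

What it does *not* emulate: volume conduction and channel correlation from a
head model, non-stationarity within trials, real artifact diversity (muscle,
line noise, electrode pops), or realistic class overlap.  Passing the
end-to-end tests therefore shows the pipeline recovers the kind of
region/band structure it is designed for — not that it reaches any
particular accuracy on real corpora, which require the licensed datasets.

## Desk-scale experiments

`eegemo.experiments` fixes the package's self-contained study conditions:
6 subjects × 12 trials of 6 s at 128 Hz, four classes with distinct
signatures ((R2, theta), (R9, alpha), (R5, beta), (R7, gamma)).  The **easy**
scenario uses multiplier 3 (9× band power) and should reach LOSO accuracy
≥ 0.9; the **null** scenario uses multiplier 1 and should sit at chance
(0.25), a leakage control.  The reduced model (hidden sizes 8, ~57k
parameters) trains with Adam at 1e-2 for up to 60 epochs, no validation
split (72 trials are too few), patience 15 and a convergence stop at epoch
loss 0.02.  Trial length and model width are the package's desk-scale
choices for a single-CPU pure-python trainer; the structure of the data and
protocol is unchanged by them.

## Limitations

- The OM-LSA-style spectral blink detector used in the original processing
  chain is not reimplemented; the amplitude detector is contract-equivalent
  (same intervals-out interface) and pluggable, not algorithm-equivalent.
- The per-frame STFT hop rounds 80% overlap to 6 samples (81.25%).
- Mean pooling of attention outputs and mean aggregation of `S[r]` into
  `H[r]`/`U[r]` are this package's choices where the design space was open.
- No ICA, re-referencing, muscle/line-noise handling beyond the bandpass;
  no multi-head attention; no GPU path.
- DEAP/MAHNOB-HCI/SEED on-disk adapters are not bundled (access-restricted
  datasets); EDF and the HDF5 array container are the supported inputs.
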