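# Methods

murmurkit detects heart murmurs from four-channel phonocardiograms
(PCG): one recording per auscultation point (aortic, pulmonic,
tricuspid, mitral valve) per patient, with one binary label per patient
("present" if a murmur is audible at any valve). This note describes
the model and procedure, the choices made where the design was open,
and what the synthetic-data experiments do and do not demonstrate.

## Pipeline

1. **Filtering.** Only patients with recordings from all four valves
   are kept, so every classification unit is a complete 4-channel set
   (retained files = 4 x retained patients).
2. **Synchronization.** The four channels are recorded independently,
   so their heartbeats are out of phase. Heartbeat peaks are detected
   on an energy envelope (squared signal, 50 ms moving average;
   adaptive threshold = max(half the envelope's 95th percentile, a
   tenth of its maximum); minimum peak separation 0.35 s, i.e. a
   ~170 bpm ceiling). Each channel is circularly rotated so all first
   beats land on the latest first-beat time — rotation rather than
   zero-padding, so no silence is injected and the sample multiset is
   preserved. Channels are then looped (tiled and truncated) to a
   common duration. The default target is 58 s; in practice the target
   should be the longest recording of the dataset, and `target_len_s:
   null` selects that automatically. "First heartbeat" means the first
   envelope peak, not specifically S1; with the detector's minimum
   separation the distinction does not affect alignment by more than
   one beat interval.
3. **Audio augmentation.** Each patient's channel set spawns 3
   augmented copies (so 4x the audio), each produced by a stack of 10
   transforms drawn uniformly with replacement from {Gaussian noise,
   pitch shift, circular time shift, time warp}. Structural parameters
   are shared across the four channels to preserve their correlation;
   the Gaussian noise *realization* is drawn per channel (four sensors
   never record one identical noise trace) while its scale is shared.
   Pitch shift and time warp run through an STFT phase vocoder
   (Hann 1024, hop 256): warp resamples frames along time at constant
   pitch; pitch shift is a time-stretch by alpha followed by reading
   the stretched signal back at speed alpha, so duration is exactly
   preserved while every spectral component moves to alpha times its
   frequency. Ranges are deliberately modest — noise factor 0.1-1% of
   full scale, alpha in [0.8, 1.25], warp rate in [0.85, 1.18], shift
   uniform over the full length — because aggressive pitch/tempo
   changes can leave the physiologically plausible regime. Time warp
   changes duration, so each stack's output is re-looped/truncated to
   the common length. Per-copy seeds derive from (master seed, patient
   id, copy index), so adding patients never perturbs existing copies.
4. **Mel spectrograms and masking.** Power STFT (Hann 1024, hop 256,
   no padding: frames = 1 + floor((N-1024)/256)) through 64 triangular
   Mel-spaced filters between 10 and 1000 Hz — the band that carries
   S1/S2 and murmur energy at the 4 kHz sampling rate. Each
   spectrogram is min-max normalized to [0, 1] individually (constant
   matrices map to zeros), so every variant is self-contained. Each
   audio file yields 1 original + 3 masked spectrograms: a mask zeroes
   either a contiguous run of time frames or of Mel bins, with the
   duration drawn uniformly in [0, 20] ms. A frequency band has no
   millisecond unit, so the same uniform draw is mapped proportionally
   onto [0, 8] bins for frequency masks. One mask is shared by the
   four channels of a variant, mirroring the audio coherence rule.
   The grouping arithmetic is: patients x 4 audio variants x 4
   spectrogram variants = labeled groups, and spectrograms = 4 x
   labeled groups (232 patients -> 928 files -> 3712 files -> 3712
   groups -> 14,848 spectrograms).
5. **Embedding.** Each normalized spectrogram is bilinearly resized to
   a 224x224 3-channel image and mapped to 1000 raw class scores
   ("logits" — never softmaxed) by a pluggable embedder. The default
   `FixtureEmbedder` is a deterministic transformer stand-in: 16x16
   patches get fixed seeded positional encodings added, are projected
   by a fixed Gaussian matrix through tanh, pooled along the *time*
   axis of the patch grid only, and the frequency-resolved row codes
   are projected to 1000 dimensions. Two design points matter. First,
   positional encoding: without it, pooling makes the embedding blind
   to *where* energy sits in the image, and the vertical position is
   the frequency axis — exactly the murmur signature. In development,
   a position-blind embedder capped end-to-end accuracy near 0.85;
   the positional, frequency-resolved design recovers ~1.0 under the
   same conditions. Second, pooling along time only reflects that a
   murmur is a quasi-stationary texture: its time position is
   uninformative, its spectral profile is the signal. A real
   pretrained 16x16-patch ViT (1000-class head, logits taken before
   softmax) can be plugged in via the optional `vit` extra; no test
   depends on it, and downstream code sees only the embedder contract
   (callable, fixed `dim`, deterministic).
6. **MiniROCKET features.** The (groups x 4 x 1000) logit tensor is
   treated as 4-channel sequences of length 1000. All C(9,3) = 84
   kernels of length 9 with weights in {-1, +2} (three +2, six -1,
   zero sum) are convolved at powers-of-two dilations d with span
   8d+1 <= 1000 (d = 1..64), valid mode. Each feature is the
   proportion of positive values (PPV) of one bias-shifted trace. The
   10,000-feature target is realized as the largest feasible multiple
   of 84: 84 kernels x 119 (dilation, bias) slots = 9,996 features,
   recorded on the bank. Biases are quantiles of training traces at
   golden-ratio low-discrepancy levels, computed on a seeded sample of
   at most 32 training groups (all of them when fewer) — the
   deterministic variant of random shifting; a literal uniform-random
   bias mode exists behind `mr_bias_mode`. Quantiles use the
   inverted-CDF definition, which returns an order statistic and is
   exactly invariant under duplicating every training group (the
   interpolating definitions are not). Biases are fitted on training
   data only, to avoid leakage. Multivariate handling defaults to
   `per_channel`: each feature reads one of the four channels, with
   features spread evenly across channels (the literal
   "each channel individually, then concatenate" reading); a
   `subset_sum` mode that sums seeded channel subsets before pooling
   is available. Numerics: the transform computes each kernel trace as
   3*(sum of the three +2 shifts) - (sum of all nine shifts); float32
   inputs stay float32 (the pipeline path), anything else promotes to
   float64 so exactness tests are meaningful.
7. **Ridge classification.** Labels are encoded present = +1,
   absent = -1; features standardized by training statistics
   (zero-variance columns get unit scale); the L2 penalty is selected
   by efficient leave-one-out error over 10 log-spaced alphas in
   [1e-3, 1e3]. Decision rule: "present" iff the decision value is
   strictly positive; exactly zero predicts "absent" (the boundary is
   open in the zero-threshold rule, and resolving it toward "absent"
   favors specificity). No class reweighting by default; a "balanced"
   option exists. Feature importance is |coefficient| ranking (ties by
   feature index): near-zero coefficients nullify their features'
   contribution.
8. **Splitting.** Seeded shuffle, train side = floor(0.8 n) groups.
   The default mode is *patient-level*: all 16 variants of a patient
   land on one side, so a model is always tested on unseen patients.
   A *group-level* mode shuffles variants independently — it matches
   the protocol where original and augmented data mix across both
   sides, and is retained precisely so the leakage effect of that
   protocol is measurable. Both mode's split sizes follow the same
   arithmetic (3712 groups -> 2969 train / 743 test at group level;
   patient level matches the target count up to one patient's block).
9. **Metrics.** Sensitivity, specificity, PPV, NPV, accuracy,
   F-Score = 2*PPV*Sens/(PPV+Sens), and the screening-weighted
   accuracy WAcc = (5 TP + TN) / (5 TP + FN + FP + TN), which
   penalizes a missed murmur five-fold. Metrics with a zero
   denominator are flagged `undefined` and reported as null, never
   silently zeroed — silent zeros would corrupt means over repeated
   runs. Repeated evaluation (`evaluate_repeats`) re-runs
   split/fit/predict with derived seeds and aggregates mean-of-metrics.

## Synthetic data

The generator emulates the structure the pipeline assumes, not
clinical waveforms: periodic beats (default 100 bpm with +-3% beat
jitter) of damped-sinusoid S1 (60 Hz) and S2 (90 Hz, 0.7 amplitude,
offset by a systolic interval of 0.35 periods); an optional murmur as
100-400 Hz band-passed Gaussian noise confined to systole with a Hann
taper (default amplitude 0.35 of full scale — a loud murmur — against
a 0.01 white-noise floor); per-valve gains (1.0/0.9/0.8/0.85) making
channels correlated but not identical; and independent per-channel
onset delays up to 0.5 s, so synchronization has real work. A quiet
tail of one maximum onset delay is reserved at the end of each
recording so circular delays and alignment rotations never wrap a beat
past the boundary. Default recording duration is 20 s; the pipeline
tests and the acceptance script use 4-6 s recordings (and `target_len_s:
null`) to keep runs at desk scale — stage counts are
duration-invariant, and the murmur/no-murmur contrast is present from
the first beat.

What passing these experiments shows: the pipeline preserves and
recovers a label <-> systolic-band-energy association end to end,
through augmentation, masking, embedding, and the PPV transform, with
patient-level generalization. What it does not show: performance on
real pediatric PCG, where murmurs are fainter, noise is structured
(stethoscope handling, crying), segmentation is harder, and labels are
noisy. The generator has no diastolic or continuous murmurs and no
pathological S1/S2 morphology.

## Problem sizes and runtime

Defaults are chosen so the complete test suite and the acceptance
script each run in minutes on one CPU: the bookkeeping cohort is 232
patients x 4 s recordings (the full 928 -> 3712 -> 14,848 expansion,
~4.5 min), the recovery cohort 60 patients x 6 s with 5 evaluation
repeats (~2.5 min), and unit tests use 2-8 patient fixtures. Mel
spectrograms can be cached on disk (`cache_dir`), keyed by content and
parameters.

## Known limitations

- The phase vocoder introduces mild transient smearing; identity
  checks (alpha = 1, rate = 1) are held to 5% relative RMS rather than
  exactness.
- Min-max normalization discards absolute loudness; a dataset whose
  labels correlate with loudness alone would lose that cue.
- The fixture embedder is a stand-in satisfying the ViT contract, not
  an approximation of any particular pretrained network's logits;
  conclusions about real-ViT performance require the optional plug-in.
- With patient-level splits the realized train fraction can deviate
  from 80% by up to one patient's block of variants.
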