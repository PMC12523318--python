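# murmurkit

Heart-murmur detection from four-valve phonocardiograms (PCG).

Cardiac auscultation — listening to the heart at the four classic
chest positions over the aortic (AV), pulmonic (PV), tricuspid (TV)
and mitral (MV) valves — is often the first test that flags a murmur,
the audible signature of turbulent blood flow. murmurkit implements a
complete, reproducible detection pipeline for patients with recordings
at all four points, treating the four recordings as correlated
channels of one multivariate time series:

1. **Synchronize** — detect heartbeat peaks on an energy envelope,
   circularly rotate every channel so first beats coincide, loop all
   channels to one common duration;
2. **Augment audio** — per patient, 3 extra copies from stacks of 10
   random transforms (Gaussian noise, pitch shift `X'(t, ω) = X(t, αω)`,
   circular time shift, phase-vocoder time warp), parameters shared
   across channels;
3. **Mel spectrograms + masking** — 64 triangular Mel filters
   (10-1000 Hz), per-spectrogram min-max normalization, then per file
   1 original + 3 masked variants (random time or frequency mask,
   0-20 ms);
4. **Embed** — each spectrogram becomes a 224×224 image and a
   1000-dimensional logit vector through a pluggable embedder (a
   deterministic patch-projection fixture by default; a pretrained
   16×16-patch Vision Transformer optionally);
5. **MiniROCKET** — all 84 kernels of length 9 with weights in
   {−1, +2} (three +2, zero sum) convolved at powers-of-two dilations
   over each channel's logit sequence; each of ~10,000 features is the
   proportion of positive values (PPV) of a bias-shifted trace,
   `PPV = #{i : (w ∗_d x)[i] > b} / (L − 8d)`, with biases fitted as
   training-trace quantiles;
6. **Ridge classification** — leave-one-out-selected L2 penalty on
   standardized features, decision threshold 0 ("present" iff the
   decision value is positive), plus |coefficient| feature ranking;
7. **Metrics** — sensitivity, specificity, PPV, NPV, accuracy,
   F-Score = 2·PPV·Sens/(PPV+Sens), and the screening-weighted
   accuracy WAcc = (5·TP + TN)/(5·TP + FN + FP + TN).

Everything runs on synthetic four-valve PCG (periodic S1/S2
transients, optional systolic band-noise murmur), so the whole
pipeline is testable without downloading any dataset. Real data in
the package's TSV/WAV dialect (see `murmurkit.io`) works identically,
and a best-effort converter for CirCor-style patient headers is
included.

## Worked example

Synthesize a 12-patient cohort (half with murmurs), run the pipeline,
and report:

```bash
murmurkit synth --n 12 --prevalence 0.5 --duration 6 --seed 7 --out data
printf 'target_len_s: null\naug_n_copies: 3\n' > cfg.yaml
murmurkit run --data data/patients.tsv --config cfg.yaml --seed 7 --out out
```

which prints the stage counts and the held-out metrics:

```json
{
  "patients": 12,
  "audio_files_original": 48,
  "audio_files_augmented_total": 192,
  "spectrograms": 768,
  "labeled_groups": 192,
  "train_groups": 160,
  "test_groups": 32
}
{
  "sensitivity": 1.0,
  "specificity": 1.0,
  "ppv": 1.0,
  "npv": 1.0,
  "accuracy": 1.0,
  "f_score": 1.0,
  "weighted_accuracy": 1.0,
  "undefined": []
}
```

The counts follow the pipeline's conservation laws: 12 patients × 4
valves = 48 recordings; ×(1 original + 3 augmented copies) = 192 audio
files; each file yields 4 spectrogram variants = 768 spectrograms in
192 labeled groups (one group = the four same-variant channel
spectrograms sharing the patient's label). The split is patient-level
by default, so all 16 variants of a patient stay on one side and the
metrics describe unseen patients; here the synthetic murmur (band
noise at 0.35 full scale) is loud enough that every held-out group is
classified correctly. `out/` additionally contains the fitted model,
the confusion matrix, and the 30 most important PPV features by
coefficient magnitude.

The same flow is available as library calls
(`murmurkit.synth_dataset`, `murmurkit.run_pipeline`,
`murmurkit.evaluate_repeats`); see `docs/methods.md` for the model
details and design rationale.

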