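# ecgtf — ECG arrhythmia diagnosis by time–frequency fusion

`ecgtf` classifies individual heartbeats of a single-lead 360 Hz ECG
into five classes — normal (N), atrial premature (A), premature
ventricular (V), left bundle branch block (L), right bundle branch
block (R) — for researchers and engineers working on automated
arrhythmia screening with MIT-BIH-style recordings.

The pipeline has four stages:

1. **Denoising.** Nine-scale db5 wavelet decomposition; the two finest
   detail bands (45–180 Hz) are zeroed and the rest soft-thresholded
   with `λ = median|D| / (0.6745·√(2 ln C))` before reconstruction.
2. **R-wave localization.** The signal's third-scale db3 detail band
   `fd3` (≈22–45 Hz, where QRS energy concentrates) is scanned with a
   sliding window (J=80, step 30, range threshold 0.15 mV); candidates
   are refined on the ECG to the sample maximizing `|f − mean(f)|`
   within ±20 samples — the absolute deviation also catches inverted R
   waves — and peaks closer than 50 samples are merged.
3. **Feature fusion.** Each beat window (99 samples before the R apex,
   the apex, 200 after; 300 total) is zero-padded to 360 points and
   FFT-transformed; the 180 magnitude bins (0–179 Hz, 1 Hz spacing) are
   appended to the time samples, giving a fused 480-vector.
4. **Classification.** A shallow 1D CNN — four wide-kernel SAME
   convolutions (4×21, 16×23, 32×25, 64×27) with three stride-2 pools,
   flatten to 3840, dense 128 (ReLU), softmax over 5 classes — trained
   30 epochs with Adam on cross-entropy, 70/30 stratified split.

A fully parametric synthetic ECG generator (sum-of-Gaussians PQRST
morphologies per class, baseline wander, myoelectric and powerline
noise, exact R-apex/label ground truth) makes every stage testable
without external data.  See `docs/methods.md` for the model details and
assumptions.

## Worked example

Simulate a small annotated record, denoise it, detect R peaks and score
them against the ground truth:

```
$ ecgtf simulate --beats "N:30,A:10,V:10,L:10,R:10" --noise default --seed 7 --out sig.csv
wrote 19494 samples, 70 beats
$ ecgtf denoise --input sig.csv --output den.csv
denoised 19494 samples -> den.csv
$ ecgtf detect-rpeaks --input den.csv --output peaks.csv
detected 70 peaks -> peaks.csv
$ ecgtf evaluate-rpeaks --detected peaks.csv --truth sig.ann.csv --tolerance 3
{"match_accuracy": 1.0, "n_truth": 70, "n_detected": 70}
```

All 70 simulated beats (54 s of signal at 360 Hz under the default
noise model) are recovered within the ±3-sample tolerance; `n_detected`
equal to `n_truth` means no spurious detections.  The same stages are
available as library calls:

```python
from ecgtf import (NoiseConfig, make_record, denoise, locate_rpeaks,
                   match_accuracy, PipelineConfig, run_pipeline)

rec = make_record(["N"] * 50 + ["V"] * 10, noise=NoiseConfig(), seed=7)
peaks = locate_rpeaks(denoise(rec))
print(match_accuracy(peaks, rec.ann_indices, tolerance=3))  # 1.0

result = run_pipeline(PipelineConfig(), [rec], mode="annotated", seed=7)
```

`run_pipeline` returns held-out metrics (accuracy, per-class
precision/recall, 5×5 confusion matrix) plus the training history, and
with `outdir=` writes features, the model, metrics and a manifest.
The full end-to-end commands are `ecgtf run`, `ecgtf extract-features`,
`ecgtf train` and `ecgtf evaluate`.

## Computational cost

Denoising and detection are `O(C)` in the signal length (wavelet
transforms and one sliding scan); per-beat feature extraction is
dominated by the 360-point FFT, `O(F log F)`.  One classifier forward
pass costs `Σ_i M_i·K_i·C_{i-1}·C_i` multiply–accumulates over the four
convolution layers (≈5·10⁶ for the 480-input geometry) plus the
3840×128 and 128×5 dense products; the whole 30-epoch desk-scale
training finishes in about a minute on one core.
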