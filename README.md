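# mmfd

Multimodal stress detection from intermittently collected wearable
physiological signals (EDA, heart rate, skin temperature, tri-axial
accelerometer), implemented as a fully testable pipeline:

1. **synthgen** — synthetic multirate recordings with a designed 3-class
   structure (one class pair separable only in the time domain, one only in
   the frequency domain), so every downstream stage is testable without any
   external download.
2. **signals_io** — wide/long CSV I/O at native per-channel rates, per-channel
   min-max scaling, resampling utilities.
3. **preprocess** — session segmentation by time gaps (Δt > 900 s) and 60 s /
   50 %-overlap windowing with a per-channel completeness rule.
4. **augment** — sliding-window and Gaussian-jitter augmentation, training
   split only, with provenance flags.
5. **features** — dual-domain extraction: per-sub-frame statistics (time
   branch) and binned log-magnitude spectra with the DC bin excluded
   (frequency branch); per-feature z-scoring fitted on training rows.
6. **balance** — from-scratch SMOTE (k-NN + segment interpolation) on the
   training split.
7. **model** — a pure-NumPy two-branch 1D-CNN
   (conv → batch-norm → ReLU → max-pool → dropout, global average pooling,
   concat fusion, MLP head with softmax), trained with Adam on cross-entropy
   + L2 and early stopping; ablation variants `no_freq` / `no_time`.
8. **evaluate** — confusion matrices and per-class/macro/weighted
   precision/recall/F1 reports.
9. **tune** — exhaustive 27-cell grid search, Expected-Improvement
   acquisition, and a Gaussian-process Bayesian search; sensitivity views.

Everything is seeded and reproducible bit-for-bit on one device.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion, including
the end-to-end fusion property: on the designed synthetic set (600 windows,
200 per class, stratified 80/20, 30 epochs, fixed seed) the full fusion model
reaches ≥ 0.90 test accuracy while each single-branch variant stays ≤ 0.75
(their ceiling is ≈ 2/3 by construction).

## CLI

```sh
mmfd simulate --out data/ --n-per-class 2 --seed 0
mmfd preprocess data/S0_000.csv windows.npz --delta 900 --window 60 --overlap 0.5
mmfd augment windows.npz windows_aug.npz --sigma 0.02 --copies 1
mmfd features windows_aug.npz feats.npz
mmfd balance feats.npz feats_bal.npz -k 5
mmfd run --config configs/example.yaml           # full pipeline end-to-end
mmfd train --config configs/example.yaml --variant no_freq
mmfd evaluate runs/example/checkpoint.npz feats.npz
mmfd ablate --n-per-class 200 --epochs 30 --seed 0
mmfd tune --mode grid --config configs/example.yaml --out results.csv
```

Exit codes: 0 ok, 1 user error, 2 internal error. A pipeline run writes
`manifest.json` (config + seed + hash), `checkpoint.npz`, `report.json`,
`report.txt` and `summary.json` into the run directory; the manifest alone
reproduces the run.

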