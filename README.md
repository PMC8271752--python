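# annispec

NIR chemometrics toolkit built around a multi-task 1-D convolutional
network for predicting constituent concentrations from near-infrared
absorbance spectra, together with classical baselines (PLSR, RBF-kernel
least-squares SVR), spectral preprocessing and augmentation, robustness
evaluation protocols, and masking-based attribution maps. Everything is
exercisable offline through a built-in Beer–Lambert spectra simulator.

## Components

| Module | Contents |
| --- | --- |
| `annispec.spectra_core` | dataset types (`WavelengthGrid`, `SpectralDataset`, …), validation, CSV I/O, wavelength cropping |
| `annispec.synthetic_data` | Gaussian-band Beer–Lambert simulator with temperature-dependent band shapes, virtual instruments, and three presets (`corn_like`, `mixture_like`, `grape_like`) |
| `annispec.preprocessing` | SNV, Savitzky–Golay smoothing/derivatives, wavelength-shift and baseline augmentation, the one-channel evaluation shift |
| `annispec.annin_model` | the network: convolution/max-pool encoder, up-sampling decoder, SELU→softplus dense regression head with optional temperature prior, multi-task training loop (pure numpy, hand-derived gradients) |
| `annispec.baselines` | PLSR (scikit-learn PLS2 behind the module interface) and an exact LS-SVM dual solver with RBF kernel, plus CV hyperparameter selection |
| `annispec.evaluation` | RMSE/R², train/test splits, instrument-transfer / shift-robustness / temperature protocols, attribution maps, tidy reports |

## CLI

```bash
annispec simulate --preset corn_like --seed 7 --out data/
annispec train --spectra data/mixture_like_spectra.csv \
    --targets data/mixture_like_targets.csv --epochs 150 --seed 0 --out model/
annispec predict --model model/ --spectra new_spectra.csv --out pred.csv
annispec baseline --method plsr --spectra s.csv --targets t.csv --out plsr/
annispec evaluate --experiment shift --preset mixture_like \
    --models annin,plsr --seed 0 --out report/
annispec attribute --model model/ --spectra s.csv --targets t.csv \
    --window 8 --out attribution.csv
```

Spectra files are CSV with a `sample_id` column followed by wavelength
headers in nm; target files are CSV with `sample_id`, one column per
constituent, and optional `temperature_C` / `instrument_id` columns.

## Notable model behaviors

- Raw absorbance spectra go in directly; no SNV/derivative preprocessing
  is required for the network (it is for the baselines).
- Training minimizes the sum of mean per-sample reconstruction RMSE and
  regression RMSE; the recorded history exposes both terms per epoch.
- Training-time augmentation (random sub-channel wavelength shifts plus
  polynomial baselines) combined with max-pooling gives the network its
  robustness to one-channel wavelength shifts, which the evaluation
  protocols measure explicitly.
- Fixed seeds reproduce simulated datasets, splits, and training
  histories exactly on a fixed platform.
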