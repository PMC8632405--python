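# dspline

Discriminant spatial-pattern (DSP) feature extraction and classification
for event-related EEG epochs, with a synthetic ERP generator so the whole
pipeline is testable without any recordings.

The package implements:

- **Epoch data model + canonical I/O** — labeled trial matrices
  (channels × samples, µV) stored as a JSON manifest plus one plain CSV
  per trial; adapter for epoched EEGLAB `.set` files
  (`dspline.io.import_eeglab_set`).
- **Preprocessing** — segmentation of continuous recordings, zero-phase
  Butterworth band-pass filtering (delta/theta/alpha/beta/1–30 Hz whole
  band), inclusive ±75 µV amplitude artifact rejection, baseline
  correction, and ERP component window extraction (N70, P120,
  N170–P200, P300, P400–700) recombined into a reduced trial matrix
  (`dspline.preprocess`).
- **DSP core** (`dspline.dsp`) — within/between-class scatter matrices
  on vectorized trials, the determinant-ratio Fisher criterion, a
  *classic* backend that solves the generalized eigenproblem by
  symmetric whitening (real spectrum guaranteed; used as oracle), and
  the *improved* backend computing closed-form per-class directions
  `w_j = (S_W + r·I)⁻¹ n_j (M_j − M)` with no eigendecomposition. The
  ridge solve has a matrix-free Woodbury route for high dimensionality
  (D ≈ 10⁴ with tens of trials) that never materializes D×D.
- **Selection & classification** (`dspline.selection`) — Euclidean KNN
  with nearest-neighbor tie-breaking, repeated stratified k-fold CV
  (ACC/SD across repeats, pooled sensitivity/specificity), univariate
  Fisher-score feature ordering, forward prefix selection, and
  feature-level fusion of per-band tables.
- **Synthetic data** (`dspline.simulate`) — three-condition ERP epochs:
  1/f background noise plus class-dependent Gaussian-windowed component
  effects with known topographies, optional latency jitter, oscillatory
  carriers, and planted supra-threshold artifacts. Emits ground truth
  (analytic noise-whitened discriminant directions, artifact ids) for
  recovery testing.
- **Pipeline + CLI** (`dspline.pipeline`, `dspline.cli`) — the chain
  filter → reject → baseline → extract → per-band DSP fit/transform →
  fusion → selection → repeated CV, with honest fold-nested fitting by
  default and a paper-style whole-set mode for comparison.

## CLI

```bash
# generate a synthetic epoch set (canonical manifest + CSVs + ground truth)
dspline simulate --preset small --seed 7 --out data/

# preprocess / extract components / fit a model
dspline preprocess --in data/manifest.json --out data_clean/
dspline extract --in data_clean/manifest.json --out data_comp/
dspline fit --in data_comp/manifest.json --pair Ug,Sc --out model.json

# end-to-end evaluation report (per task × band metric grid)
dspline evaluate --preset small --task Ug-vs-Sc,Tg-vs-Sc \
    --bands delta,theta,alpha,beta,whole,fusion \
    --k 3 --folds 5 --repeats 10 --seed 7 --report report.json

# or from a stored config document
dspline run --config config.json --report report.json
```

`--fit-scope all` reproduces the optimistic convention of fitting the
projection and feature selection on the full trial set; the default
(`fold`) refits everything inside each training fold.

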