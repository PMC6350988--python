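# qpmcell

Label-free classification of single cells from quantitative phase
microscopy (QPM) images.

QPM measures the optical path length (OPL) of a transparent cell — the
product of its refractive-index contrast and thickness — without any
stain or label. `qpmcell` implements a complete analysis pipeline that
distinguishes white blood cells (WBCs) from cancer cell-line cells (CLs)
by their *subcellular* structure rather than by their size:

1. **Field preprocessing** — conversion of reflection-geometry phase to
   OPL (Δϕ = 4π·OPL/λ), removal of the curved background by a two-pass
   paraboloid fit, and rule-based segmentation of single cells with the
   triangle threshold.
2. **Size-invariant normalization** — each cell crop is divided by its
   predicted diameter D (OPL/D) or, modelling a floating cell as a
   sphere, by the chord length PL(x, y) = 2·√((D/2)² − x² − y²)
   (OPL/PL), then resampled to 49×49 pixels with the spatial gradients
   compensated by the mean resize factor m = (m_x + m_y)/2.
3. **Feature extraction** — a from-scratch histogram-of-oriented-
   gradients (HOG) descriptor (49×49 window, 7-px cells, 14-px blocks,
   7-px stride, 9 unsigned orientation bins → 1296 elements, L2-Hys
   block normalization) and a 5-statistic descriptor (mean, std, max,
   skewness, excess kurtosis) of the dimensionless ratio map.
4. **Classification** — a linear soft-margin SVM (C-SVC). The decision
   value d = (w·x + b)/‖w‖ is the signed distance to the hyperplane;
   d > 0 classifies a cell as a WBC. The cost C is grid-searched over
   2⁻¹…2⁸ maximizing the mean 5-fold cross-validated AUC, and
   performance is reported as ROC/DET curves with sensitivity,
   specificity and accuracy at the d = 0 threshold.
5. **Phantom simulation** — synthetic cells (smooth hemispheroids vs.
   bumpy, organelle-bearing ones), bump-height sweeps and rotation
   sweeps that probe *what* the classifier responds to, plus full-field
   generators with curved, noisy backgrounds for end-to-end testing.

No real image data ship with the package: the phantom module generates
all inputs, emulating the imaging conditions (σ ≈ 5 nm OPL background
noise, ~0.27 µm pixel pitch, WBCs ~10 µm, CLs ~18 µm).

## Worked example

Train on a synthetic population and sweep a phantom's bump height
(`examples/04_interpret_phantoms.py`):

```text
bump height -> decision value (positive = WBC-like):
    0.0 %   +0.482   -> WBC
    3.5 %   -0.138   -> CL
    7.1 %   -0.477   -> CL
   11.0 %   -0.656   -> CL
   14.0 %   -0.734   -> CL
rotation sweep (36 angles, 10 deg steps):
  WBC phantom: decision value in [+0.842, +1.282]
  CL  phantom: decision value in [-0.656, -0.516]
```

The smooth phantom (0 % bumps) sits on the WBC side of the hyperplane;
as organelle-like bumps grow the decision value falls monotonically and
crosses zero below 3.5 % — the classifier is reading intracellular
heterogeneity, not cell size. Rotating either phantom never flips its
classification.

Cross-validated evaluation on a reduced population of 60 cells per
class (`examples/03_train_and_evaluate.py`) prints

```text
features: 120 cells x 1296 HOG elements
cross-validated: AUC 1.0000, sensitivity 100.0%, specificity 98.3%, accuracy 99.2%
```

The other examples cover field simulation + segmentation
(`examples/01_simulate_and_segment.py`) and normalization + feature
extraction (`examples/02_normalize_and_featurize.py`). A thin CLI
(`qpmcell flatten|segment|normalize|run|train|evaluate|predict|phantom|simulate|interpret|learn-curve`)
wraps the same library functions for shell use.

## Layout

```
src/qpmcell/
  phase_field.py     phase→OPL, paraboloid flattening, segmentation
  normalization.py   OPL/PL and OPL/D, 49×49 resampling, m compensation
  features.py        HOG (from first principles) and 5-statistic features
  classify.py        linear SVM, CV, grid search, ROC/DET, learning curve
  phantoms.py        phantom/population/field generators
  io.py, pipeline.py, cli.py
docs/methods.md      model assumptions, parameter choices, limitations
examples/            narrative scripts, one per capability
```
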