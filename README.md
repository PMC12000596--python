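# maizeyield

County-level maize yield estimation from satellite vegetation indices,
climate composites, soil properties and agricultural-modernization
covariates, built around an attention-based CNN–BiGRU regressor.

The package is aimed at agroecological modellers who work with county-year
panels: it provides the full pipeline — feature engineering from raw inputs,
a sequence model over the growing season, temporally honest validation,
and per-feature attribution — plus a synthetic-data module that generates
structurally realistic panels with known ground truth, so every stage is
testable without any satellite downloads.

## The model

Each county-year record is a 5 × 24 sequence: growth stages S1–S5 (May–
September) on the time axis, 15 dynamic variables (NDVI, EVI, GCVI, GNDVI,
WDRVI, OSAVI, SIF, LST, Tmin, Tmax, Pre, Pdsi, Pet, Vap, Vpd) as channels,
and 9 periodic variables (soil texture and fractions, SOC, normalized
planting-density-center coordinates, fertilizer degree DFC, mechanization
degree DCM) broadcast to every timestep.

The regressor stacks

1. three 1D convolutions (64/32/16 filters, kernel 2, ReLU; first layer
   length-preserving, the rest valid),
2. a 16-unit dense bottleneck per timestep,
3. two bidirectional GRU layers (64 units/direction), with per-timestep
   gates z_t = σ(W_z x_t + U_z h_{t−1} + b_z), r_t = σ(W_r x_t + U_r h_{t−1}
   + b_r), h̃_t = tanh(W_h x_t + r_t ⊙ U_h h_{t−1} + b_h), h_t = (1 − z_t) ⊙
   h_{t−1} + z_t ⊙ h̃_t, and forward/backward states combined as
   α ⊙ h⃗_t + β ⊙ h⃖_t + b,
4. softmax attention pooling a = softmax(tanh(W_d h + b) · u_w),
   context = Σ a_t h_t, and
5. a linear head predicting yield in t/ha.

Training is Adam on MAE loss (batch 32, 95 epochs, initial learning rate
0.01 with 0.93/epoch exponential decay, global gradient-norm clip 1.0),
implemented on the package's own compact reverse-mode autodiff engine; runs
are bit-reproducible for a fixed seed.  An independent loop-based
transcription of the layer equations (`maizeyield.oracle`) cross-checks the
forward pass.

Validation regimes: held-out calendar year (remaining years split 80/20),
forward/backward expanding windows, and in-season prediction (stages after a
cutoff masked, model retrained per cutoff).  Interpretation: permutation
importance (RMSE increase) and a permutation-sampling Shapley estimator with
exact local accuracy.  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from maizeyield import (NetworkConfig, SplitSpec, SyntheticConfig,
                        fit_evaluate, generate_panel)

panel, truth = generate_panel(
    SyntheticConfig(n_counties=60, year_start=2001, year_end=2012, seed=7))
result = fit_evaluate(panel,
                      SplitSpec(strategy="holdout_year", test_year=2012, seed=0),
                      NetworkConfig(seed=0))
r = result.report
print(f"test-year R2   {r.r2:.3f}")
print(f"RMSE           {r.rmse:.3f} t/ha")
print(f"MAE            {r.mae:.3f} t/ha")
print(f"bias classes   {r.bias_counts}")
```

prints (about two minutes on one CPU)

```
test-year R2   0.734
RMSE           0.820 t/ha
MAE            0.640 t/ha
bias classes   {'over': 7, 'under': 8, 'within': 45}
```

The generator planted a yield signal on the stage-3/4 canopy amplitude,
July precipitation, mechanization degree, soil organic carbon and latitude
(`truth["coefficients"]`), with 0.5 t/ha observation noise: the model
recovers ~73% of held-out-year variance on this 60-county panel, and 45 of
60 test counties land within the ±0.9 t/ha bias band.  (At the full study
scale of 150 counties x 21 years the same recipe reaches R2 ≈ 0.81–0.83;
see the acceptance script below.)

The same flow drives the command line:

```bash
maizeyield simulate --seed 7 --n-counties 60 --years 2001:2012 --out panel.csv
maizeyield train --panel panel.csv --seed 0 --out model.npz
maizeyield evaluate --panel panel.csv --seed 0
maizeyield explain --panel panel.csv --seed 0 --out importance.csv
```

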