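# Methods

This note documents the models, procedures and numerical choices behind
`maizeyield`: a package for county-level maize yield estimation from
vegetation-index time series, climate composites, soil properties and
agricultural-modernization covariates, using an attention-based CNN–BiGRU
regressor with temporal validation and feature attribution.

## The county-year feature panel

One record is a (county, year) pair carrying

- a **dynamic cube** of 15 variables × 5 growth stages.  Stages S1–S5 are the
  calendar months May–September of the maize season.  The variables are seven
  canopy indices (NDVI, EVI, GCVI, GNDVI, WDRVI, OSAVI, SIF), land-surface
  temperature (LST), and seven climate covariates (Tmin, Tmax, Pre, Pdsi,
  Pet, Vap, Vpd).  Satellite variables and Pet/Vap/Vpd are composited per
  stage by the monthly **mean**; Tmin/Tmax/Pre/Pdsi by the monthly **sum**
  (the convention is unusual for temperatures but is applied as declared in
  the variable registry);
- a **periodic vector** of 9 variables: soil texture class, clay/silt/sand
  percentages, soil organic carbon (five-year cadence); normalized
  longitude/latitude of the county's planting-density center and the
  fertilizer-consumption (DFC) and comprehensive-mechanization (DCM) degrees
  (yearly cadence);
- the yield label in t/ha (absent in prediction mode).

Panels serialize to CSV with a fixed, documented column order
(`county_id, year, NDVI_S1..Vpd_S5, texture_class..DCM, yield_t_ha`; 87
columns).  Coordinates are stored already min-max normalized to [0, 1] over
the study bounding box.  Yield quality screening is a configurable
mean ± k·sd exclusion hook (default k = 4); the criterion used for the real
yearbook data is not public, so the hook is deliberately simple and
replaceable.

Normalization is a per-feature z-score fitted **only on the training
subset**; the fitted statistics are returned and applied unchanged to
validation and test data, so held-out records can never influence them.
Coordinates, already on [0, 1], are passed through.

## Feature engineering

- **Vegetation indices** are exact Table-style formula evaluations, e.g.
  NDVI = (NIR − R)/(NIR + R), EVI = 2.5(NIR − R)/(NIR + 6R + 7.5B + 1),
  WDRVI = (0.2 NIR − R)/(0.2 NIR + R), GCVI = NIR/G − 1,
  GNDVI = (NIR − G)/(NIR + G), OSAVI = (NIR − R)/(NIR + R + 0.16).
- **Harmonic compositing**: an 8-day (or arbitrary) within-year series is fit
  by least squares with an intercept plus `n_harmonics` sine/cosine pairs on
  an annual fundamental period (default 2 harmonics — annual plus
  semi-annual, the usual choice for single-season vegetation curves; the
  order is configurable).  The fitted curve is evaluated daily (non-leap
  calendar) and averaged per month.  Any series lying in the fitted basis is
  reproduced exactly.
- **Mechanization rates**: R_p = A_p/(A_s − A_n), R_s = A_s/A_t,
  R_h = A_h/(A_h − A_l), composite R_c = 0.4 R_p + 0.3 R_s + 0.3 R_h.  The
  harvest-rate denominator is implemented exactly as published even though it
  yields rates above 100% whenever crop-loss area is positive; such results
  carry a `suspect` flag, and a plausible alternative denominator
  (A_t − A_l) is available behind a switch but off by default.  DCM is
  spatialized by an ordinary least-squares regression of R_c on county GDP.
- **Mask aggregation**: binary 30 m maize masks are aggregated to a coarse
  grid in blocks of 17 × 17 fine pixels; the maize count is capped at the
  theoretical maximum of ⌊(500/30)²⌋ = 277 pixels per 500 m cell and the
  maize fraction uses that fixed denominator.  A cell is classified maize iff
  its fraction reaches the threshold (default 80%).  The 17-pixel block makes
  the toy geometry exact while reproducing the published maximum; 500/30 is
  not an integer, so any real tiling is approximate.
- **Fertilizer disaggregation (DFC)**: the county maize-specific total
  (county total × maize area share) is distributed over cells proportionally
  to their scores on the **second principal component** of the cell ×
  timepoint NDVI matrix.  Since a signed score vector is not a proportion,
  the sign is first chosen so the scores correlate nonnegatively with mean
  cell NDVI, then scores are shifted by their minimum and renormalized to sum
  to one.  If the NDVI matrix is identically zero after centering there is no
  component at all and the operation fails loudly; if only the *second*
  component is degenerate (rank-one variation) the allocation falls back to
  uniform shares.  Allocation conserves the county total to machine
  precision.
- **Planting-density centers**: the maximal-density cell (ties broken at the
  smallest row-major index), min-max normalized over the grid of cell
  centers, so the minimum-corner cell maps to (0, 0).

## The regressor

Input layout: the 5 growth stages form the sequence axis; the 15 dynamic
variables are channels and the 9 periodic variables are broadcast to every
timestep, giving a 5 × 24 input per record.  How static covariates enter a sequence model has no single standard answer;
broadcasting keeps a single unified input and lets every layer see the
static context.

The full graph is:

1. **1D convolution stack** with ReLU, kernels of size 2 and 64/32/16
   filters.  Convolutions are valid (no padding) except the first layer,
   which is length-preserving: three valid kernel-2 layers would leave only
   2 of 5 positions, too short for the recurrent stack to exploit order;
   padding the first layer (5→5→4→3) keeps a usable sequence and is exposed
   in config.
2. **Dense bottleneck** of 16 units with ReLU, applied per timestep.
3. **Two stacked bidirectional GRU layers**, 64 units per direction.  Each
   GRU cell: z_t = σ(W_z x_t + U_z h_{t−1} + b_z), r_t = σ(W_r x_t +
   U_r h_{t−1} + b_r), h̃_t = tanh(W_h x_t + r_t ⊙ (U_h h_{t−1}) + b_h),
   h_t = (1 − z_t) ⊙ h_{t−1} + z_t ⊙ h̃_t.  Forward and backward states are
   combined per timestep as α ⊙ h⃗_t + β ⊙ h⃖_t + b with learnable
   per-feature vectors initialized at α = β = 0.5, b = 0 (a concatenation
   mode is available behind config).  The combination weights could in principle be
   time-varying; shared per-feature weights are used here.
4. **Attention pooling**: μ_t = tanh(W_d h_t + b), scores s_t = μ_t · u_w,
   weights a = softmax(s), context = Σ_t a_t h_t.  The projection is applied
   per timestep (standard additive attention); flattening the sequence into
   one vector would collapse the per-step weights the softmax requires.
5. **Linear head** mapping the context to yield in t/ha.

Ablation variants: `no_cnn` feeds the 24-channel sequence directly into the
BiGRU; `drop_one_gru_layer` keeps one bidirectional layer;
`no_attention` replaces the attentive context with the last combined hidden
state.

### Training

Adam (β₁ = 0.9, β₂ = 0.999) with mean-absolute-error loss, batch size 32,
95 epochs, initial learning rate 0.01.  Because MAE gradients are
sign-valued, the per-parameter Adam step stays near the learning rate no
matter how close the fit is, so a constant 0.01 never settles: the loss
reaches its minimum early and then jitters upward.  The initial rate is
therefore decayed exponentially by 0.93 per epoch, and gradients are clipped
to a global norm of 1.0 to protect the recurrent stack from occasional
exploding updates.  Both are config fields.  Weights use uniform
Glorot-style fan-based initialization from a seeded generator; biases start
at zero.  No early stopping or checkpointing: the final-epoch weights are
returned.  All computation is double precision and single threaded, so runs
with the same seed are bit-identical.

The forward pass is implemented twice: a vectorized autodiff graph
(`maizeyield.network`) used for training and prediction, and an independent
pure-Python loop transcription of the layer equations
(`maizeyield.oracle`) kept solely as a cross-check; the two agree to
< 1e-8 on random tiny networks of every variant.

The package carries its own compact reverse-mode autodiff engine
(`maizeyield.autodiff`) — a float64 tape over numpy arrays with exactly the
op set the graph needs — validated against finite differences in the test
suite.

## Validation regimes

- **Held-out year**: all records of the test year are excluded; remaining
  years are shuffled with a fixed seed and split 80/20 into train/validation.
- **Forward / backward expanding windows**: train/validation come only from
  years strictly before (resp. after) the test year, so window size grows as
  the test year moves away from the panel edge.
- **In-season**: a held-out-year split in which dynamic values at stages
  after the cutoff m are masked with a zero sentinel *after* normalization,
  in train, validation and test alike; the model is retrained per cutoff.
  Masking (rather than variable-length input) keeps one architecture for all
  cutoffs; zero is the training-data feature mean on the normalized scale.

Metrics: R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², RMSE = √MSE, MSE, MAE.  Signed errors
ŷ − y are classified over/under/within against a ±0.9 t/ha threshold, read
strictly (an error of exactly 0.9 is "within").  Constant actuals make R²
undefined; the error raised carries the remaining metrics.

The benchmark harness trains each model factory on identical seeded splits
for r repeats (default 3, configurable) and reports mean ± sd of R²/RMSE per year.  Baseline
adapters (LASSO, LightGBM) flatten the panel to an 84-vector.  The ablation
harness runs the module variants, or the full graph with one temporal
feature group zeroed (monthly dynamics / yearly lon-lat-DFC-DCM / five-year
soil), under identical splits and seeds.

## Interpretation

- **Permutation importance**: mean increase in test RMSE over seeded repeats
  (default 10) when one feature column is shuffled across test records.  Shares are
  percentages of summed importances after flooring negative raw means at
  zero (raw values are reported unfloored).
- **Shapley attribution**: permutation-sampling estimator against a
  background set.  Each sample pairs a random feature permutation with a
  background row; rows are cycled so each appears equally often, which makes
  the base value (mean background prediction) and the local-accuracy
  identity base + Σ attributions = prediction hold exactly by telescoping.
  For a linear model the estimator reproduces w_j(x_j − mean background x_j)
  exactly in expectation.  Positive attribution pushes predicted yield up.

## The synthetic study

The generator emulates the structure of the real inputs, not their joint
distribution.  Defaults define the study: 150 counties × 2001–2021, drought
year 2014, observation noise 0.5 t/ha.

- **Canopy curves**: each index is a county-specific Gaussian bump over day
  of year (width 26 d) on an index-specific base/scale, whose amplitude
  carries a latent county-year *vigor*.  The peak day (≈ 200) shifts ±18
  days across the south–north extent — a latitude-driven phenology gradient,
  so the informative growth stage varies by county within S3–S4.  This is
  what makes the temporal modules earn their keep: a content-based attention
  readout can localize each county's peak stage, while a fixed readout
  cannot.
- **Climate**: stage-wise precipitation draws (mean 140 mm in July); LST and
  Tmin/Tmax follow a seasonal shape peaking at S3; Pet/Vpd mildly seasonal.
  **Pdsi and Vap are pure noise by construction** — known-null features for
  importance checks.
- **Drought years**: precipitation halved, LST +2 °C, vigor −1.2 sd.
- **Statics**: soil texture/fractions (Dirichlet), SOC, uniform coordinates,
  DFC, and DCM = 150 + 40·latent (≈ 70–280 range).
- **Yield** (t/ha): 8.0 + 1.2·vigor + 0.6·Pre_S3(z) + 0.5·DCM(z) +
  0.3·SOC(z) + 0.8·(2·lat−1) + 0.25·vigor·Pre_S3(z) + county residual
  (sd 0.3) + year effect (sd 0.15) + N(0, 0.5), truncated at zero.  The mild
  vigor × precipitation interaction gives nonlinear models an edge over
  linear baselines.  All coefficients and the causal/noise feature lists are
  returned as ground truth, including the expected drought gap computed from
  the noiseless signal.

What the generator does **not** emulate: spatial autocorrelation between
counties, measurement error structure of satellite retrievals, reporting
artifacts in yearbook statistics, or trends in mechanization over time.
Passing tests therefore demonstrate that the pipeline recovers planted
structure under realistic scales and noise — not that the real-data skill
figures transfer.

## Problem sizes used by the test suite and acceptance script

Full-scale checks (parameter recovery, drought gap, importance ranking) use
the default 150 × 21 panel with three seeds.  The ablation-ordering and
in-season checks use a 60 county × 12 year panel (three seeds), and the
feature-group ablation check a 40 × 10 panel with the soil effect planted at
zero — sizes chosen so a complete desktop run of the suite stays within tens
of minutes while keeping test-year sample sizes (40–150 records) large
enough for stable R² estimates.

## Known limitations

- The harvest-mechanization formula is reproduced as published; its rates
  above 100% are flagged, not corrected.
- DFC and DCM are treated as unitless covariates; their native units are
  reported inconsistently across sources.
- In-season masking assumes the zero sentinel (training feature mean) is a
  neutral fill; models that extrapolate poorly off-manifold may react to it.
- The Shapley estimator is a sampling approximation; with few samples the
  per-feature values are noisy even though their sum is exact.
- Training is CPU-only and overhead-bound; panels beyond ~10⁴ records per
  epoch-budget call for a compiled deep-learning backend.
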