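# Methods

## Fermentation model

Yeast alcoholic fermentation is represented by four phases with fuzzy
temporal memberships (hours):

| phase        | membership            |
|--------------|-----------------------|
| lag          | tri(0, 0, 20)         |
| exponential  | trap(15, 20, 70, 80)  |
| stationary   | trap(70, 80, 150, 170)|
| death        | S(150, 336)           |

Each phase carries a closed-form rule per attribute; for example
biomass is X₀(1 − e^{−t/τ}) in lag, a logistic
X₀ + X_max/(1 + e^{−r(t−t_m)}) in the exponential phase, a linear
decline X_max − α(t − 100) in the stationary phase and an exponential
decay (X_max − 0.5)·e^{−β(t−200)} in death. CO₂ and alcohol rules are
functions of the concurrent biomass. Where memberships overlap, the
attribute is the normalized membership-weighted average of the phase
expressions — a Takagi–Sugeno reading of the rule chain; the rules
themselves do not specify a combination scheme, and weighted averaging
is the only choice that reduces exactly to the phase expression
wherever a single phase is active (which the fidelity tests pin to
1e-9).

Consequences of taking the rule-chain anchors literally:

* the stationary sugar expression 30 + 50e^{−0.02(t−100)} exceeds the
  exponential-phase value inside the 70–80 h overlap, producing a small
  rising hump there; sugar is non-increasing within each phase window
  but not across that blend,
* the death-phase biomass amplitude is parametrised as X_max − 0.5 so
  it equals the reference constant 3.0 at the nominal X_max = 3.5 and
  tracks drawn values elsewhere.

Kinetic defaults describe a temperature-controlled (15 °C) white-wine
fermentation: S₀ ~ U(200, 220) g/L falling to a 20 g/L residual,
X_max ~ U(3, 4) g/L, r ~ U(0.25, 0.35) h⁻¹, k_e ~ U(0.01, 0.02) h⁻¹.
Noise is sampled per time point, independent across points and
attributes (nothing in the model constrains its autocorrelation), with
per-phase Gaussian standard deviations per attribute; CO₂ release is
bursty and strictly positive, so its noise is exponential. The printed
exponential-noise parameters are read as the distribution's **mean**
(scale), not its rate: a rate reading would put ~10 units of noise on a
lag-phase CO₂ level of ~0.05, which is physically implausible for a
"very low" phase. A `noise_scale` multiplier scales every amplitude at
once (used by the robustness tests).

The growth-rate balance dX/dt = μX, dS/dt = −μX/Y is implemented as a
*diagnostic only* (`ode_consistency_check`): generation uses the closed
forms, since no integration scheme, initial-value protocol or
maintenance coefficient is specified for the rate equations. The
maintenance term is set to zero in the residual.

### What the generator does and does not emulate

It reproduces the phase structure, magnitudes, noise character and
fermentation-to-fermentation variability of temperature-controlled
white-wine fermentations. It does **not** model temperature-dependent
kinetics, stuck fermentations, nutrient effects, autocorrelated sensor
drift, or inter-attribute noise correlation. Tests passing on this
generator therefore demonstrate the correctness and calibration
behavior of the algorithms, not their accuracy on real tank data.

## Alcohol soft sensor

Partitions: per attribute, three Gaussian classes with centers
(min + C_low, mean + C_med, max + k_d·δ), bandwidth w = σ/k (defaults
C_low = C_med = 0, k_d = 1, k = 3) and universe bounds
(min − 2·min, max + 0.2·max). δ = (mean − median)/κ is dimensionless
yet added to a center in attribute units; this is implemented literally
as calibrated. An alternative convention (centers (min, median,
max − δ), bandwidth κ) is selectable, as the two appear in different
places of the source material; the calibrated-table convention is the
default because it is the one tied to a minimum-RMSE calibration.

Rules: Wang–Mendel grid induction — per training sample take the
winning class of each attribute, weight the candidate rule by the
product of winning memberships, and per distinct antecedent
combination keep the consequent with the largest accumulated weight
(stored weight = that consequent's share of the combination's total,
in [0, 1]). Inference: firing strength = min over antecedent
memberships × rule weight; per consequent class, max over rules;
centroid of the max-aggregated clipped consequent memberships on a
501-point universe grid. If no rule fires above 1e-6 the
consequent-universe midpoint is returned with a warning. The inferred
series is smoothed with a truncated (|lag| ≤ 4σ), unit-sum Gaussian
kernel, σ = 2 samples, nearest-value boundary padding.

**Attainable skill.** With three output classes the defuzzified output
is effectively a smooth staircase between class centroids. On real
monotone alcohol ramps a three-level quantizer explains most of the
variance, which is consistent with high reported R² on real tank data;
on the synthetic alcohol channel, which rises and then declines with
biomass, held-out R² is modest (≈0.2–0.4 across seeds). The
calibration tests therefore pin a floor of 0.2 at the fixture seed and
assert that inflating all noise amplitudes ×10 degrades R² — a
sanity property of the calibration pipeline, not a claim about real
fermentations.

## Forecaster

Architecture: `l` stacked LSTM layers of `nc` units (all but the last
return sequences; the final hidden state feeds the head), dense
nc → k·nc, dense → pl·k, reshape to (pl, k), batch normalization over
the attribute axis. Loss is RMSE on min-max-normalized labels. The
backend is a from-scratch numpy implementation (Glorot/orthogonal
initialization, forget-gate bias 1, full BPTT, Adam, float32),
verified against numerical differentiation in the test suite.

**Output batch normalization** is part of the literal layer stack and
is kept (default on in `build_model`), but it is disabled in the
reduced-scale replication protocol and recommended off for short
training budgets: normalizing the output discards the scale the
regression must reproduce, and with only a few hundred optimizer steps
the learnable affine cannot re-learn it (measured: validation RMSE
0.13 vs 0.02 on an independent sinusoid fixture; 0.33 vs 0.07 on
fermentation windows at the protocol learning rate). At inference it
uses running statistics (momentum 0.99, ε = 1e-3).

Windowing: per curve, inputs rows [i, i+nt) paired with labels
[i+nt, i+nt+pl) at offsets 0, stride, 2·stride, …; count
⌊(T − nt − pl)/stride⌋ + 1. Min-max bounds are fitted per attribute on
training curves; constant attributes are widened by 1e-9; values
outside the fitted range extrapolate linearly (no clipping), which the
tests document.

Auto-tuning: stage 1 samples 10 unique cell candidates ≥ 32 apart in
[32, 512] (range configurable down to 8), trains a 1-layer model
briefly and keeps the minimum validation RMSE, ties to fewer cells;
stage 2 scans depths 1–10 at the chosen width, reports the layer-count
penalty for every candidate and selects the minimum-RMSE depth
(minimum-penalty selection available). Tuning RMSE can optionally be
computed on raw (denormalized) units — tuning losses are sometimes
quoted on the raw scale while final evaluation uses the normalized
one; the ``raw_scale`` flag records which is in use.

Training protocol: Adam at 1e-4, ×0.25 on a 1-epoch validation
plateau down to 1e-10 ("25 % reduction factor" is read as
new = 0.25·old), early stopping with patience 5 and min_delta 1e-5
restoring best weights, batch 32, ≤100 epochs, 20 % validation split.
Chunked training iterates over ordered chunks **without**
reinitializing weights (the decreasing per-chunk epoch counts of the
full-scale protocol indicate continual learning); the miniature test
asserts that trend on 3 chunks.

### Reduced-scale replication protocol

The full-scale study (1200 fermentations, 12 chunks) is not
reproducible at desk scale; the package's replication
(`forecaster.scaled_down_replication`, used by `scripts/acceptance.py`)
fixes: 10 seeded 21-day fermentations at 5-minute steps, nt = pl = 288,
stride 48 (1150 windows), 20 % held-out windows, a 64-cell × 2-layer
model without output batch normalization, Adam 1e-4, batch 32, early
stopping, ≤15 epochs. Observed held-out normalized RMSE is ≈0.07,
below the full-scale reference mean of 0.1599, and well below the
mean-predictor baseline (≈0.18).

## Numerical choices

* Sample statistics use ddof = 1; the dispersion κ is floored at 0.01.
* Partition centers that an extreme skew offset would disorder fall
  back to the raw data anchors (with a warning); degenerate data
  ranges are widened by κ.
* The S-shaped membership is the standard C¹ quadratic-spline
  S-function (0.5 at the midpoint).
* Gaussian smoothing delegates to `scipy.ndimage.gaussian_filter1d`
  with `mode="nearest"`, `truncate=4.0`, which matches the kernel
  definition exactly.
* Ties in both architecture searches resolve to the smaller
  architecture.
* Dataset child seeds are spawned from a `SeedSequence` of the master
  seed and reduced mod 2³¹; all randomness flows through explicit
  `numpy.random.Generator`s, so every pipeline is bit-reproducible
  under a fixed seed.
* The gas-phase CO₂ factor 1.964e-6 g/L per ppm is stored as a
  constant (it corresponds to a 22.414 L/mol molar volume); the
  dissolved factor is *computed* from k_H = 1.65e-2 mol/(L·atm) and
  M = 44.01 g/mol, and a test pins agreement with the reference
  7.262e-7 to 4 significant figures.
* The ethanol gas→liquid conversion divides by the partition
  coefficient α = 2.5e-4 literally. Note that with this default,
  100–1000 ppm of gas-phase ethanol maps to liquid-equivalent values
  orders of magnitude above the 0.5–5 mg/L range expected in a tank
  headspace during active fermentation; the formula is implemented
  as defined and α is exposed as a setting rather than silently
  corrected.
* The simulator's CO₂ channel carries the rule-chain's native model
  units (values of order 1–40), which do not reconcile with either the
  g/L or the ppm scales of the gas conversions; unit conversions are
  applied only explicitly via the conversions module, never inside the
  generator.

## Known limitations

* The soft sensor's three-class output bounds its resolution; more
  classes per partition would lift the staircase ceiling but are outside
  the calibrated design.
* The forecaster backend is CPU numpy: adequate for the reduced-scale
  protocol and tests, not for the full 1200-fermentation corpus.
* Telemetry support is payload encode/decode only; no transport.
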