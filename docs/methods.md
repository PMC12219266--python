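# Methods

## Signal model

The DTNB assay reports CoA released by acetyltransfer: one TNB chromophore
per CoA thiol (1:1 stoichiometry), so [TNB] = [CoA] = [product]. Conversion
between A412 and concentration is plain Beer–Lambert,
conc = (A412 − blank)/(ε·ℓ), with ε = 13 800 M⁻¹cm⁻¹ for continuous
kinetic reads and ε = 13 700 M⁻¹cm⁻¹ for endpoint screens — two
conventions from different calibration literatures; both are kept, selected
by assay type, with explicit override (`OpticalCalibration.for_assay`).
The per-well pathlength comes from the water near-IR band:
ℓ = (A975 − A900)/0.18 cm. A non-positive band difference flags the well
(`InvalidOpticalRead`) rather than passing through. When a blank noise SD
is configured, negative concentrations within 3σ of the blank are clamped
to zero with a warning counter; more negative values raise as
miscalibration. Reagent depletion, instrument drift and the temperature
dependence of ε are not modelled.

## Synthetic plate generator

Progress curves integrate d[P]/dt = v(S₀ − P, A₀ − P), i.e. the sequential
rate law with both substrates depleted 1:1 by product, using LSODA at
rtol 1e-8 / atol 1e-10; integrator failure raises. Optional co-substrate
inhibition multiplies the rate by 1/(1 + A/Ki_si) — the mechanism behind
the high-Ac-CoA rate decline is not established, and this uncompetitive-
style factor is the simplest form producing it; it is a single pluggable
hook, not a claim about mechanism. Concentrations map to A412 through the
forward Beer–Lambert model; Gaussian noise is added in absorbance space
(instrument-realistic), and per-well pathlengths are drawn around a 0.55 cm
mean (a 50 µl well). Controls contain no enzyme and sit flat at the blank.

Default study conditions: 20 nM enzyme; histidine grid
{0, 20, 50, 120, 300, 720, 1800, 4500} µM (the extended
{0, 50, …, 10 000} µM set is provided for high-Ac-CoA series); fixed
Ac-CoA levels {5, 10, 25, 50, 125, 500} µM — the source protocol states
only the 5–500 µM range, so this log-spread grid is a declared stand-in.
Ground-truth constants default to the wild-type values kcat 36.5 s⁻¹,
KM^AcCoA 19.8 µM, KM^His 215 µM. Ki^His is not a reported constant;
scenarios take an explicit value (default 200 µM, the same order as
KM^His), and the tests verify that all three recovered constants are
independent of it. The continuous read defaults to 240 s at 3 s intervals,
chosen so even the fastest wells (low Ac-CoA, saturating His) are well
sampled before depletion. The endpoint screen models each substrate by a
pseudo-first-order activity k, endpoint product A₀(1 − e^(−kt)), which
caps naturally at the 300 µM Ac-CoA pool; layout is 4 reaction + 2
no-enzyme control wells per substrate at 500 nM enzyme, 30 min.

The generator emulates absorbance noise, pathlength variation and
substrate depletion but not enzyme inactivation over time, pipetting
(concentration) errors, well-to-well temperature gradients or mixing lags.
Passing tests therefore demonstrate correctness of the analysis chain
under a well-specified noise model, not robustness to every artifact of
real plates.

## Initial rates

The linear estimator is the OLS slope over an early window — points below
10% conversion of the limiting substrate pool, or the first 10 points,
whichever is larger; fewer than 3 usable samples is an error. The
logarithmic estimator fits P(t) = (v₀/k)·ln(1 + kt) (k ≥ 0) to the curve
and reports the analytic t = 0 slope v₀; as k → 0 the model degenerates to
the straight line P = v₀t, so it is exact on linear data. Because the
post-depletion plateau carries no rate information and distorts the log
model, the fit is restricted to samples below 50% conversion of the
limiting pool (at least 5 samples). Under these choices the estimator
recovers the true t = 0 derivative within 5% on every noise-free well of
the study grids, and within ~3% at 50% conversion. Non-convergence falls
back to the linear estimator with a recorded flag. Rates are always fitted
in concentration space (µM/s) after optical conversion. Lag phases, burst
kinetics and enzyme inactivation are out of scope.

## Constant extraction

Michaelis–Menten fits at each fixed Ac-CoA are unweighted nonlinear least
squares (S = 0 rows validate the blank and are excluded; ≥ 4 distinct
positive substrate levels required; non-convergent or non-positive fits are
rejected). A reciprocal-variance weighting option exists but is off by
default: the study-style analysis used plain least squares, and weighting
reciprocal-transformed data distorts the error structure.

Mechanism discrimination exploits the common-point property: if all Hanes
lines pass through (x₀, y₀) then interceptᵢ = y₀ − x₀·slopeᵢ, so x₀ is
estimated by OLS of intercepts on slopes, which is far more stable under
noise than pairwise intersections (those are still computed and reported
as a dispersion). The verdict is ternary_complex when x₀ < −threshold,
substituted_enzyme within ±threshold, indeterminate otherwise, with
threshold = max(tol, 2·SE(x₀)) and tol defaulting to 5% of the median
apparent KM. A sequential mechanism with Ki^His below this tolerance is
genuinely indistinguishable from ping-pong on primary plots — the verdict
is then substituted_enzyme by construction, which the tests acknowledge.

Substrate-inhibition exclusion supports a fixed Ac-CoA cutoff and an
automatic mode flagging fits whose Vmax^app falls more than 2% (relative)
below the running maximum over increasing A; when both are configured the
union is excluded, and excluding every fit is an error. Secondary plots
are OLS on the accepted apparent values as described in the README; the
KM^app/Vmax^app slope additionally yields a Ki^His estimate
(slope·Vmax/KM^AcCoA), reported but not headline. kcat = Vmax/[E]; with
several independent series the report carries per-series values,
across-series mean and SD, and both ratio aggregations (mean of per-series
kcat/KM ratios, and ratio of the mean constants — these differ once series
vary, so both are shown).

The global four-parameter fit is initialized from the secondary-plot
estimates; designs with a single Ac-CoA level are rejected as
rank-deficient (Ki^His unidentifiable). Route agreement is assessed by a
chi-square test of the 3-vector of headline-constant differences under the
combined covariance — the global fit's covariance plus the secondary
route's across-series standard errors — against the 95% quantile at 3 df
(`compare_routes`). This is a practical joint-region test; it treats the
two routes as independent, which they are not exactly (same data), making
the test mildly conservative.

## Statistics

Welch's t is the default for all group comparisons (conservative under
unequal variances; the Student's option exists for the metabolite tables
where the flavor is a config switch). The 95% CI of the mean difference
uses the t quantile at the Welch–Satterthwaite df. BH adjustment is the
standard step-up with enforced monotonicity (statsmodels backend; a
brute-force step-up implementation serves as the test oracle). The
rate-ratio prediction assumes equal Vmax between variants, so
v_ref/v_var = (KM_var + S)/(KM_ref + S); the fold is reported both as a
real number and rounded to the nearest integer. The wild-type/variant KM
pair used in the headline prediction is reconstructed from the published
3.6-fold elevation and 240 µM difference of means (KM_ref = 240/2.6 µM),
since per-replicate values are shown only graphically — a documented
assumption.

## Problem sizes and determinism

All simulations are seeded (`SimScenario.seed` fully determines output;
identical scenario + seed gives bit-identical tables). The stochastic
recovery study uses 100 runs of three independent series each at 5%
relative rate noise — the three-series design mirrors how the reported
constants were aggregated. The null-uniformity check uses 10 000 two-sample
tests at n = 10 per group; the BH oracle comparison uses 1000 random
p-vectors. The full test suite runs in a few seconds on one CPU.
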