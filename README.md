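# hisatkin

Steady-state bi-substrate enzyme kinetics for DTNB plate assays, built
around the histidine acetyltransferase HisAT (the human NAT16 protein).
HisAT transfers the acetyl group of acetyl-CoA (Ac-CoA) to the α-amino
group of free L-histidine, releasing CoA; Ellman's reagent (DTNB) converts
each CoA thiol into one TNB chromophore read at 412 nm, so a plate reader
can follow the reaction in real time. This package implements the complete
quantitative chain from raw absorbance to kinetic constants:

- **optics** — Beer–Lambert conversion between A412 and CoA concentration,
  with per-well pathlength correction from the water near-IR band
  ((A975 − A900)/0.18) and the two conventional TNB extinction coefficients
  (13 700 M⁻¹cm⁻¹ for endpoint screens, 13 800 M⁻¹cm⁻¹ for kinetics);
- **rates** — initial-rate (v₀) estimation from progress curves, by a
  linear low-conversion window or a logarithmic approximation
  P(t) = (v₀/k)·ln(1 + kt) fitted to the full curve;
- **kinetics** — the core inference (see below);
- **stats** — Welch's unequal-variances *t* test for variant comparisons,
  Benjamini–Hochberg-corrected *t* tests for metabolite tables, endpoint
  screen summaries, and the physiological rate-ratio prediction;
- **synth** — a seeded simulator of DTNB plates (progress curves with
  substrate depletion, optional Ac-CoA substrate inhibition, absorbance
  noise, pathlength variation, no-enzyme controls) so the whole chain is
  testable without instrument data.

## The model

The acetyltransfer is assumed sequential (ternary-complex): both substrates
bind before chemistry. With S = [His] and A = [Ac-CoA],

```
v0 = Vmax · S · A / (Ki^His · KM^AcCoA + KM^AcCoA · S + KM^His · A + S · A)
```

At each fixed A this collapses to a Michaelis–Menten curve in S with

```
Vmax^app(A) = Vmax · A / (KM^AcCoA + A)
KM^app(A)   = (Ki^His · KM^AcCoA + KM^His · A) / (KM^AcCoA + A)
```

Hanes primary plots (S/v₀ vs S; slope 1/Vmax^app, intercept
KM^app/Vmax^app) at different fixed A all pass through S = −Ki^His for a
sequential mechanism, but share their ordinate intercept (meeting at S = 0)
for a substituted-enzyme (ping-pong) mechanism — this is how the mechanism
is called. The true constants come from double-reciprocal secondary plots:
OLS of 1/Vmax^app on 1/A gives Vmax (inverse ordinate intercept) and
KM^AcCoA (negative inverse abscissa intercept); OLS of KM^app/Vmax^app on
1/A gives KM^His (ordinate intercept × Vmax). kcat = Vmax/[E]. Apparent
fits distorted by Ac-CoA substrate inhibition (a declining Vmax^app tail at
high A) are excluded before the secondary regressions. A direct nonlinear
fit of the four-parameter law over all points serves as a cross-check of
the plot-based route.

## Worked example

Simulate a noise-free kinetic plate under the wild-type ground truth
(kcat 36.5 s⁻¹, KM^AcCoA 19.8 µM, KM^His 215 µM, 20 nM enzyme) and run the
full pipeline:

```
$ hisatkin all --seed 1 --out results
          constant       mean  sd   series_1
              kcat  36.635701 0.0  36.635701
          km_accoa  19.225255 0.0  19.225255
kcat_over_km_accoa   1.905603 0.0   1.905603
            km_his 212.263048 0.0 212.263048
  kcat_over_km_his   0.172596 0.0   0.172596
```

The recovered constants agree with the generating truth to ~3% — the
residual bias comes from the initial-rate stage, since even the logarithmic
estimator sees finitely sampled, depleting curves. Fitting the analytic
rate grid instead recovers all constants to machine precision (see
`tests/test_acceptance.py`).

Comparing wild-type and variant apparent KM^His replicates, then
predicting the slowdown at physiological histidine:

```
$ hisatkin compare --group-a 92.3,88,95,94 --group-b 330,335,328,340 \
      --substrate-conc 159 --substrate-conc 20
t = -77.685, df = 4.79, p = 1.308e-08
difference of means -241 (95% CI -249 to -233), fold-change 3.61
predicted 1.96-fold (~2-fold) slower at 159 uM substrate
predicted 3.14-fold (~3-fold) slower at 20 uM substrate
```

A variant with a 3.6-fold elevated KM^His runs ~2-fold slower at 159 µM
histidine and ~3-fold slower at 20 µM — KM elevation matters most where
substrate is scarce.

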