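# Methods

## Scope

`doeopt` implements the two statistical stages of a
screen-then-optimize DOE campaign on coded factors, together with the
plumbing those stages need (design construction and auditing, level
coding, synthetic ground-truth data, reporting). Wet-lab matters — assay
chemistry, culture protocols, sequencing — are outside the package: the
bundled study data enter only as printed design matrices with run-aligned
responses, and laboratory-measured quantities that no model fit can
produce (the verification fermentation yield of 1610.22 μM/g and the
baseline isolate yield of 152.61 μM/g) are carried as metadata and
explicitly flagged as excluded from reproduction.

## Designs

Plackett–Burman arrays are built from the classical cyclic first-row
generators for n = 12, 20, 24 and from Hadamard matrices (dropping the
all-ones column) for n = 8, 16; supported run counts are {8, 12, 16, 20,
24}. Every generated column is balanced and every pair orthogonal, which
the test suite asserts for all supported sizes — this audit, not a
library cross-check, is the correctness oracle, since balance and
orthogonality are the defining properties of the array.

Box–Behnken designs place 4·C(k,2) runs at the edge midpoints of the
factor cube (two coordinates ±1, the rest 0) plus n_center center runs;
k ≥ 3. For k = 3 with one center run this is the 13-run design used by
the bundled study, which the generator reproduces as a set.

`validate_design` reports per-column means and balance, the k×k matrix of
raw column inner products, the offending non-orthogonal pairs, and the
condition number. It exists because transcribed matrices from the
literature are not always what they claim: the bundled 16-run screening
matrix is *not* an orthogonal PB array — 52 column pairs have nonzero
inner products (±4 typically; amino acids × temperature is −4) and the
ethanol and KCl columns are identical. The matrix is shipped verbatim and
never repaired; all analyses of the bundled data run on it as printed.

## Level coding

A factor's low/mid/high levels map to −1/0/+1. Default mode is
piecewise-linear: linear within [low, mid] and [mid, high] separately, so
non-uniformly spaced levels (amino acids 0.0125/0.025/0.05 %, urea
0.02/0.1/0.5 %) are hit exactly and the map remains strictly monotone and
exactly invertible. A log mode (linear in log of the natural value) is
offered because such level grids are roughly geometric. Piecewise-linear
is the default because it reproduces the bundled study's decoded optimum
arithmetic (coded +0.229 on the urea grid decodes to 0.1916 %, coded
+0.1255 on the amino-acid grid to 0.0281 %); a single linear rescale
cannot represent those spacings at all. How the study's own solver
decoded its fractional optimum is not stated anywhere; piecewise-linear
is this package's inference and is validated only by that arithmetic
agreement. Decoded levels are conventionally reported to 4 significant
figures, responses to 2 decimals.

Coding and decoding refuse values outside the factor range (or coded
values outside [−1, 1]) unless extrapolation is explicitly enabled; the
fitted surface is an interpolation over the design region and predictions
outside it are extrapolations of the model.

## Screening stage

`fit_first_order` is OLS of the response on intercept + coded columns
(via statsmodels; QR-based, so non-orthogonal matrices are handled by the
full normal equations). R² = 1 − SS_res/SS_tot with centered total sum of
squares. A rank-deficient column selection raises an error naming the
dependent columns; `allow_aliased=True` instead returns the minimum-norm
(pseudoinverse) solution and records which columns are aliased. That
option exists for matrices like the bundled one, where two identical
columns make the saturated fit singular while the intercept (= the grand
mean, 537.3125, whenever all columns are balanced) and the fitted values
remain perfectly well defined. On that fit R² = 0.8353.

Main effects are mean(+1) − mean(−1) per column, defined only for pure
two-level designs; on orthogonal arrays the half-effects equal the
saturated OLS slopes (asserted to 1e−9). Selection methods:

- `lenth_pse` (default, α = 0.05): PSE = 1.5·median of |effects| below
  2.5·(1.5·median|effects|); margin = t(α/2, k/3)·PSE. Standard for
  unreplicated screens; simulated power to detect all of three 5σ effects
  among 11 columns of a 12-run array is ≈0.99 over 500 seeded replicates.
- `top_m`: the m largest |effects| — the mode used when reproducing the
  bundled study, whose authors selected three factors narratively rather
  than by a stated test (Lenth at α = 0.05 selects none of the 14 on
  those data, whose effects are spread without a clean null group).

Model reduction is always by refitting on the reduced column set, never
by zeroing coefficients, because on a non-orthogonal matrix the
coefficients change under reduction.

The bundled study's printed first-order slopes (169.65…, 310.85…,
254.80…) match neither the half-effects nor any OLS solution on the
printed matrix; their provenance (third-party reduction software) cannot
be reconstructed. The package therefore computes and reports both honest
estimates, flags the discrepancy in the reproduction report, and treats
only the grand-mean intercept — and, as it turns out, the printed R² —
as recomputable screening quantities.

## Response-surface stage

`fit_quadratic` fits the full 10-term (for k = 3) second-order polynomial
by OLS on coded columns and reports coefficients, fitted values,
residuals, leverages (QR hat diagonal), and R². Requirements: at least as
many runs as parameters and a design of full model rank, otherwise the
unidentifiable terms are named in the error.

Structural facts asserted on the bundled 13-run fit: every edge run of a
k = 3 BBD satisfies x₁²+x₂²+x₃² = 2, so with a single center run the
center has leverage exactly 1 and is fitted exactly (observed = fitted =
1599.06); leverages sum to 10; the twelve edge residuals occur in
antisymmetric pairs. All 13 printed predicted values are reproduced
within ±0.05 (printing precision).

`stationary_point` solves xₛ = −½B⁻¹b and classifies the critical point
by the eigenvalues of B (all negative → maximum, all positive → minimum,
mixed → saddle); a quadratic form with |det B| below 1e−10 at the
coefficient scale is treated as a ridge system and the caller is directed
to the constrained search. `constrained_optimum` sweeps a deterministic
per-axis grid (default step 0.01) over the coded box, breaks value ties
by the smallest Euclidean norm, then polishes with bounded L-BFGS-B,
never accepting a polish that worsens the grid value. The grid stage is
kept because a saddle surface puts the constrained maximum on the
boundary, where purely local ascent from a bad start can stall; at k = 3
desk scale the sweep is exhaustive and cheap. The solver is validated
against an independent pure-grid oracle (coarse-to-fine sweeps, no
closed-form step) on 100 random concave surfaces and on the bundled fit.

On the bundled data the fitted surface has an interior maximum at coded
(0.1255, −0.0050, 0.0230), predicting 1605.70 μM/g — above the printed
predicted optimum of 1599.06, which equals the center fit and is
therefore a lower bound of the constrained maximum of the same surface.
Decoded piecewise-linearly, the optimum is 0.02814 % amino acids, 39.98 °C
and 0.1092 % urea: amino acids and temperature agree with the study's
reported optimum (0.0281 %, 40 °C); the study's urea level (0.1916 %,
coded ≈ +0.229) does not lie at the refit surface's stationary point, and
whether that reflects rounding or a solver artifact in the original
analysis is unknowable — the report presents both side by side.

## Synthetic data

`simulate_response` evaluates a known quadratic surface at each run's
coded point and adds i.i.d. Gaussian noise (PCG64, explicit seed);
`recovery_experiment` spawns per-replicate streams from one seed,
refits each dataset, and summarizes per-coefficient bias, RMSE and
empirical coverage of the nominal 95 % t-intervals. The generator
emulates exactly what the OLS analyses assume — a quadratic mean surface
with homoscedastic additive noise and no run-order or block effects. Real
fermentation data can violate all of these (heteroscedastic yields,
drift, model bias), so passing recovery tests demonstrate the estimators
and intervals work when the model holds, not that the model holds for any
particular dataset.

Default validation conditions (chosen once, as plausible analogues of the
bundled experiment's scale): a k = 3 BBD with 3 center runs (15 runs,
5 residual df — one center run leaves the intercept interval undefined
at leverage 1), noise of a few percent of the surface's span, 500
replicates. Under these, σ = 0 reproduces the true coefficients to
1e−9, doubling σ exactly doubles every RMSE (OLS error is linear in the
noise), coverage falls in [0.92, 0.98] for every coefficient, and the
estimator is unbiased within Monte-Carlo error.

## Numerical choices

- OLS through statsmodels (pinv/QR); hat diagonals from the thin QR of
  the model matrix.
- Balance/orthogonality tolerances 1e−9 on raw inner products; ±1/0
  levels are stored as exact floats so the audits are effectively exact.
- Stationary-point singularity threshold: |det B| ≤ 1e−10 × (max|B|)^k.
- Grid/polish optimum: step 0.01 per axis, tie-break by smallest coded
  norm, L-BFGS-B polish clipped to bounds.
- Monte-Carlo experiment sizes (500 replicates; 100 random surfaces for
  the oracle comparison) keep the full suite under ~2 minutes while
  leaving binomial error on coverage estimates near 1 %.

## Known limitations

- Plackett–Burman sizes other than {8, 12, 16, 20, 24} (e.g. 28) are not
  constructed; BBDs are the standard edge-midpoint family without
  blocking or incomplete variants.
- No lack-of-fit ANOVA against pure error (impossible with a single
  center point: zero pure-error df) and no confidence regions on the
  stationary point.
- Screening estimates interactions not at all (first-order model); on
  non-orthogonal matrices the main-effect contrasts and OLS slopes
  legitimately disagree, and neither recovers what unknown third-party
  software once printed.
- Single response only; multi-response desirability optimization is out
  of scope.
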