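# doeopt

Two-stage statistical optimization of a fermentation medium (or any
process with many candidate variables): **Plackett–Burman screening** of a
large set of two-level factors, followed by **Box–Behnken response-surface
optimization** of the few that matter.

The package is aimed at microbiologists and bioprocess engineers who run
design-of-experiments (DOE) campaigns — e.g. maximizing the intracellular
yield of reduced glutathione (GSH, μM/g) by a *Lactobacillus plantarum*
isolate over 14 culture variables — and at anyone who wants to audit such
an analysis: the complete dataset of a published GSH-optimization
experiment ships as a fixture, and a one-line command refits every number
in it that is refittable.

## The models

**Stage 1 (screening).** Each of k factors is coded to ±1 (low/high) and a
first-order model is fit by ordinary least squares:

    Y = β₀ + Σᵢ βᵢXᵢ

The per-factor *main effect* is the mean response at +1 minus the mean at
−1; on an orthogonal array its half equals the OLS slope. Active factors
are picked either by Lenth's pseudo-standard-error test (the standard
significance test when there are no replicates) or by taking the m
largest effects.

**Stage 2 (response surface).** The selected factors (three, here) are
studied at three levels each in a Box–Behnken design and a full
second-order polynomial is fit:

    Y = β₀ + Σ βᵢXᵢ + Σ βᵢⱼXᵢXⱼ + Σ βᵢᵢXᵢ²

Canonical analysis solves ∇Y = 0 (xₛ = −½B⁻¹b, with B the symmetric
quadratic-form matrix) and classifies the stationary point by the
eigenvalues of B; the constrained maximum over the coded cube [−1,1]³ is
found by a dense grid sweep plus local polish, then decoded back to
natural units. Because the factor levels need not be evenly spaced
(0.02 / 0.1 / 0.5 % urea), decoding uses a piecewise-linear (or log) map
that sends −1/0/+1 exactly onto the chosen levels.

## Worked example

```python
import doeopt as dp

bbd = dp.load_fixture("gsh_bbd13")            # 13-run Box-Behnken + GSH responses
fit = dp.fit_quadratic(bbd, bbd.responses)
print(round(fit.r_squared, 4))                 # 0.9978

sp = dp.stationary_point(fit)
print(sp.nature)                               # 'maximum'

opt = dp.constrained_optimum(fit, sense="max")
print(round(opt.predicted_response, 2))        # 1605.7
factors = dp.load_fixture("gsh_factors_bbd")
print(dp.decode_point(factors, opt.coded_point))
# {'amino_acids': 0.02814..., 'temperature': 39.975, 'urea': 0.1092}
```

The fitted surface explains 99.8 % of the variance of the 13 runs; its
stationary point is a true maximum just off the center of the design, and
the constrained optimum predicts ≈1606 μM/g GSH at 0.0281 % precursor
amino acids, 40 °C and 0.11 % urea. The center run of a single-center
Box–Behnken design has leverage 1, so its fitted value (1599.06) equals
its observed value exactly — a structural property the tests assert.

The same workflow from a shell:

```
doeopt design pb --runs 16 --factors 14 --out pb.csv
doeopt design validate pb.csv
doeopt screen --design pb.csv --responses y.csv --method lenth --report screen.json
doeopt rsm fit --design bbd.csv --responses gsh.csv --out fit.json
doeopt rsm optimize --fit fit.json --factors factors.yaml --report optimum.json
doeopt pipeline reproduce-study --out report/
```

`pipeline reproduce-study` reruns both stages on the bundled tables and
writes a printed-vs-recomputed comparison, including the audit findings:
the published 16-run screening matrix is not an orthogonal
Plackett–Burman array (several column pairs have inner product ±4, and
two columns are outright identical), so its printed first-order slopes
cannot be recovered by least squares — the report shows the honest
estimates next to the printed ones and flags the discrepancy rather than
emulating it.

## Layout

- `doeopt.designs` — Plackett–Burman / Box–Behnken construction, balance
  and orthogonality audits, CSV I/O, bundled study fixtures
- `doeopt.coding` — coded-level ↔ natural-unit maps (piecewise-linear, log)
- `doeopt.screening` — first-order fits, main effects, Lenth / top-m selection
- `doeopt.rsm` — quadratic fits, prediction, canonical analysis, constrained optimum
- `doeopt.synthetic` — seeded ground-truth surface simulator and recovery experiments
- `doeopt.pipeline` — two-stage orchestration, study reproduction, reports
- `doeopt.cli` — `doeopt` command-line entry point

See `docs/methods.md` for the statistical details and design choices.
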