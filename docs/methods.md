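# Methods

## Structural model and units

Disposition is a linear two-compartment model with zero-order infusion
input and first-order elimination from the central compartment,
parameterised by clearances and volumes: central volume `V` (L),
peripheral volume `Vp` (L), elimination clearance `CL` (L/h) and
inter-compartmental clearance `CLp` (L/h). The micro rates are
`k10 = CL/V`, `k12 = CLp/V`, `k21 = CLp/Vp`; the disposition exponents
`alpha >= beta > 0` satisfy `alpha + beta = k10 + k12 + k21` and
`alpha·beta = k10·k21`.

Each dose event is solved in closed form (a during-infusion and a
post-infusion branch, implemented as the difference of two "infinite
infusion" responses) and events combine by superposition. The closed form
is verified in the test suite against stiff ODE integration to a relative
error below 1e-6 over random parameter/regimen draws.

Units are fixed package-wide: time h, volume L, clearance L/h. Doses are
entered in mg and converted internally to µg, so concentrations are µg/L,
numerically identical to the ng/mL reported by the assay. A one-compartment
variant (`V`, `CL`) exists for the base-model comparison.

Numerical guards: the eigenvalue discriminant is floored at 1e-10 of the
rate sum (repeated-root protection) and `beta` at 1e-14 of the rate sum
(the `CLp -> 0` limit); both are far outside the parameter region the data
support and exist purely so that intermediate optimizer iterates cannot
produce NaNs.

## Exposure metrics

`AUC(0-t)` is integrated exactly from the piecewise-analytic
antiderivative; a linear-trapezoid alternative on an explicit sampling
schedule is provided because non-compartmental practice varies.
`AUC(0-inf)` for a single dose is `dose/CL` (linear kinetics). `Cmax` is
located from analytic candidates (each infusion end) plus a refined local
grid, because multi-dose accumulation can move the global peak to a later
infusion.

The covariate-effect simulation (single 20 mg, 0.75-h infusion; reference
subject healthy male, 60.6 kg) defaults to an *hourly output grid*
(0, 1, ..., 24 h) with grid-maximum Cmax and trapezoid AUC. On an hourly
grid the first post-infusion sample is the 1-h point, which systematically
reads the peak low — but it is the convention under which the published
covariate-effect percentages are reproduced (sex +4.8% Cmax / +24.8% AUC;
disease −16.7% / −27.0%; |ΔCmax| < 25% at 40 and 120 kg), and the
high-accuracy alternative (`grid="fine"`, exact AUC) is one keyword away.
The sex effect on `AUC(0-inf)` is analytically `exp(0.213) − 1 = +23.7%`
independent of any grid; the test suite asserts this identity exactly.

## Mixed-effects model and estimation

Inter-individual variability is exponential, `P_i = P_typ·exp(eta_i)` with
`eta ~ N(0, diag(ω²))` — parameters are log-normal across subjects and
stay positive. The residual model is multiplicative,
`y = f·(1 + ε), ε ~ N(0, σ²)`, so `σ = 0.184` is a proportional SD
(≈18.4% CV); additive, combined and exponential (`y = f·exp(ε)`) variants
are selectable. Observations below the 1 ng/mL quantification limit
(including all pre-dose samples) are flagged and excluded from the
likelihood rather than imputed, matching the source analysis' handling.
`CLp` carries no random effect: its variance is fixed to zero (the
published model fixed it after 84% eta-shrinkage); the constraint is a
model-spec flag, not a removed code path.

The marginal likelihood is approximated FOCE-ELS style: for each subject a
damped Gauss–Newton search (batched across subjects, central-difference
sensitivities, Newton-decrement stopping at 1e-10) finds the conditional
mode `eta_hat` of the joint density; the Laplace/FOCE-with-interaction
objective is

    OFV_i = g_i(eta_hat) − q·ln 2π + ln det(Ω⁻¹ + Σ_j G_j G_j' / v_j)

with `g_i` the −2 log joint density, `G` the sensitivity of the prediction
to `eta` and `v` the residual variance at the conditional prediction
(the "interaction": `v` depends on `eta` through `f`). All 2π constants are
kept, so for a model linear in `eta` with additive error the OFV equals
the exact Gaussian −2 log-likelihood (asserted to 1e-4 in the tests, and
to 0.3 against adaptive quadrature on a tiny nonlinear instance). OFV
values are therefore comparable within this implementation, but not
bit-identical to other engines whose constant conventions differ; ΔOFV
decisions are unaffected.

The outer problem optimises `(log tv, θ_cov, log ω², log σ)` with
L-BFGS-B and finite-difference gradients (step 1e-5); the log transform
enforces positivity and makes a uniform step well-scaled. Conditional
modes are warm-started across objective evaluations. Two presets exist:
`default` (ftol 2e-9, up to 400 iterations, used for reported fits) and
`fast` (ftol 1e-8, up to 120 iterations) for replicate-heavy work
(bootstrap replicates, stepwise screens, recovery studies) where the extra
digits change no decision. Standard errors come from the
central-finite-difference Hessian of the OFV on the transformed scale
(step 2e-3, eigenvalue-clipped inverse, covariance `2H⁻¹`), mapped to the
natural scale by the delta method; RSE% is `100·SE/|estimate|`.
Empirical-Bayes etas are the final conditional modes;
shrinkage is `100·(1 − SD(eta_hat)/ω)` with the sample SD (ddof 1).

`AIC = OFV + 2p` and `BIC = OFV + p·ln(n_obs)` count all estimated
parameters; `n_obs` counts quantifiable observations.

## Covariate machinery and selection

Continuous covariates scale a parameter by `(value/reference)^θ` with the
reference fixed at the analysis-dataset median (recomputed at model build;
60.6 kg is the packaged default reference weight). Categorical (0/1)
covariates scale by `exp(θ·value)`. Body-mass index is `WT/(HT/100)²`;
creatinine clearance uses Cockcroft–Gault in mg/dL with the 0.85 female
factor (a 88.4 µmol/L-per-mg/dL conversion constant is provided because
clinical tables usually report µmol/L).

Selection is the standard three-stage procedure. The collinearity screen
computes pairwise Pearson r² among continuous covariates and, above 0.5,
keeps the higher-priority member (WT > HT > BMI; TP > ALB; AST > ALT —
the ordering that reproduces the published retained set); binary
covariates are exempt. Forward inclusion accepts the largest OFV drop when
it exceeds 6.635 (χ², p < 0.01, 1 df); backward elimination removes the
cheapest covariate while its removal costs at most 10.828 (p < 0.001) —
i.e. a covariate survives only if deleting it worsens OFV by *more* than
10.828. The published methods text states the backward rule inverted
relative to its own worked table (which removes a covariate whose deletion
costs 10.098); this implementation follows the table, which is also
standard practice. Ties break deterministically (larger ΔOFV, then fewer
parameters, then name). Screening fits use the fast preset warm-started
from the parent model; accepted models become the next parent, keeping
ΔOFV comparisons anchored to converged fits. The default candidate set is
the screened covariates crossed with {V, Vp, CL}, configurable.

## Diagnostics and validation

CWRES uses the FOCE-with-interaction linearisation: with `G` evaluated at
`eta_hat`, the subject's observations are treated as
`N(f(eta_hat) − G·eta_hat, G Ω G' + diag(v))` and the residual is whitened
by the Cholesky factor. For model-generated data ~95% of CWRES fall in
[−2, 2].

The VPC simulates replicate datasets on the original design (same doses,
nominal times, covariates), bins by nominal time after dose (sparse bins
merged leftward; nominal scheduling makes the bins exact), dose-normalises
by default because the pooled designs span 5–30 mg, and compares observed
5th/50th/95th percentiles with the across-replicate median and 90% CI of
the simulated percentiles. BLQ values are excluded on both sides,
mirroring the likelihood. 500 replicates are the test default; release
runs use 1,000. The band width estimates the sampling spread of a
percentile under the design and does not shrink with more replicates —
only the Monte-Carlo error of the band does.

The bootstrap resamples subjects with replacement, stratified by study so
the mix of designs (and the 10-patient ulcer arm) is preserved;
unstratified resampling is available. Each replicate refits warm-started
from the point estimates with the fast preset; failed replicates are
counted and reported, with a warning above 10% failures. 1,000 replicates
is the release default; calibration tests use 100.

## Synthetic data

The generator is the package's definition of the study conditions: five
arms (n = 16/10/10/12/10; the four-period crossover is emulated as three
ilaprazole occasions — 5, 10, 20 mg — a week apart in the same subjects),
0.75-h infusions, the printed per-day sampling schedules with
minute-denominated points converted exactly (0.25, 0.5, 0.75, 5/6 h;
the ulcer arm's distinct day-1 grid reproduced verbatim), parameter truth
at the published final-model estimates (ω²_V = 0.013, ω²_Vp = 0.032,
ω²_CL = 0.059, σ = 0.184), LLOQ censoring at 1 ng/mL, and an optional
random-dropout knob (default off).

Covariates are drawn from log-normal marginals matched to the published
per-population medians and IQRs, with a Gaussian copula coupling the
collinear pairs. The published collinearity report (0.810 for WT–HT, 0.636
TP–ALB, 0.767 AST–ALT, against an "R² > 0.5" rule) is read as squared
correlations, so the copula uses r = 0.90/0.80/0.876; the generated data
then reproduce the screening outcome. Sex is assigned by exact-count
shuffle (50% female in healthy arms, 40% in the ulcer arm → 48.3% of 58).
Sampled covariates are rounded to clinical precision (0.1 kg, 0.1 cm)
*before* simulation, so stored and generating covariates agree exactly.

What the emulation does not model: real assay error structure beyond the
multiplicative term, covariate–sex dependence (published tables give only
pooled marginals), body-weight differences between sexes, time-varying
covariates, and the exact observation count of the real pool (withdrawals
are a knob, not a target). Passing tests therefore demonstrate that the
machinery recovers known truth under the stated design — not that the
published clinical estimates are themselves reproducible, which they are
not without the raw data.

## Verification scales

The heavy verification suites are sized for a single CPU: parameter
recovery uses 20 replicates of the full 58-subject suite with the fast
preset; stepwise recovery uses 10 effect replicates and 10 null replicates
over a five-pair candidate set (the four true effects plus a bilirubin
decoy, mirroring the covariate that enters and falls in the published
trace); the bootstrap calibration uses 100 replicates and the VPC 200.
With 10 replicates, the null-selection rate check "about 15%" is
discretised to at most 2 of 10 replicates.

## Known limitations

* Diagonal Ω only; covariance blocks between etas are out of scope (the
  source analysis built none).
* BLQ handling is exclusion; likelihood-based (M3) censoring is not
  implemented.
* SEs are Hessian-based; no sandwich estimator.
* The FOCE approximation is least accurate for sparse designs with large
  ω²; the quadrature cross-check bounds the error only at the tested
  scale.
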