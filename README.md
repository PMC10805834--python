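# ilapop — population pharmacokinetics of intravenous ilaprazole

Ilaprazole is a substituted-benzimidazole proton pump inhibitor whose
intravenous formulation is used for peptic-ulcer bleeding. Its plasma
disposition shows marked between-subject variability — women and healthy
volunteers reach clearly higher exposures than men and duodenal-ulcer
patients. `ilapop` implements, end to end, the population-pharmacokinetic
analysis that quantifies those differences: a two-compartment model with
zero-order (infusion) input and first-order elimination, fitted as a
nonlinear mixed-effects model by FOCE-ELS, with stepwise covariate
selection, bootstrap and visual-predictive-check validation, and a
covariate-effect exposure simulation.

Because the underlying clinical datasets are not public, the package ships
a first-class synthetic-trial generator that emulates the five study
designs of the source analysis (5–30 mg infusions over 0.75 h, the printed
sampling schedules, 58 subjects of whom 10 are duodenal-ulcer patients),
the published baseline covariate distributions, and censoring at the
1 ng/mL lower limit of quantification. Everything the package claims is
demonstrated on data from that generator.

## The model

For subject *i*, concentration at time *t* follows the two-compartment
infusion model with parameters `V, Vp, CL, CLp` (central/peripheral volume,
elimination/inter-compartmental clearance). Individual parameters carry
log-normal inter-individual variability and covariate effects:

    V_i   = tv_V · exp(η_V,i)
    CL_i  = tv_CL · exp(θ_sex·SEX_i) · exp(θ_disCL·DIS_i) · exp(η_CL,i)
    Vp_i  = tv_Vp · (WT_i / 60.6)^θ_wt · exp(θ_disVp·DIS_i) · exp(η_Vp,i)
    CLp_i = tv_CLp                         (variability fixed to zero)

    y_ij  = f(t_ij; P_i) · (1 + ε_ij),   η ~ N(0, diag(ω²)),  ε ~ N(0, σ²)

Estimation maximises the FOCE-ELS approximate marginal likelihood (Laplace
expansion at each subject's conditional mode, with interaction: the
multiplicative residual variance is evaluated at the conditional
prediction). Covariates enter the search as power laws
`(value/median)^θ` (continuous) or `exp(θ·value)` (categorical) and are
screened by forward inclusion (ΔOFV > 6.635, p < 0.01) and backward
elimination (removal must worsen OFV by > 10.828, p < 0.001), after a
collinearity pre-screen that keeps one member of any covariate pair with
r² > 0.5.

## Worked example

```python
from ilapop import (PopPKModel, CovariateEffect, SimulationTruth,
                    build_study_suite)

dataset = build_study_suite(SimulationTruth(), seed=42)   # 58 subjects
model = PopPKModel(
    dataset,
    covariate_effects=[CovariateEffect("Vp", "WT", "continuous"),
                       CovariateEffect("CL", "SEX", "categorical"),
                       CovariateEffect("CL", "DIS", "categorical"),
                       CovariateEffect("Vp", "DIS", "categorical")])
result = model.fit()
print(result.summary())
```

prints (abridged; your machine's timing line will differ):

```
Population PK model fit (FOCE-ELS)
==========================================================
structural: two_compartment   residual: multiplicative
subjects: 58   observations: 1484
OFV: 16663.497   AIC: 16687.497   BIC: 16751.127
----------------------------------------------------------
parameter           estimate          SE      RSE%
tv_V                   6.828      0.2449       3.6
tv_Vp                  5.985      0.3049       5.1
tv_CL                  3.328      0.1574       4.7
tv_CLp                 13.73       1.247       9.1
WT_Vp                  1.868      0.3587      19.2
SEX_CL               -0.1237      0.0638      51.6
DIS_CL                0.2708     0.08552      31.6
DIS_Vp                0.1189     0.08972      75.5
omega2_V            0.005596    0.004014      71.7
omega2_Vp            0.04495     0.01171      26.0
omega2_CL              0.057     0.01101      19.3
sigma_mult            0.1875    0.003749       2.0
----------------------------------------------------------
eta-shrinkage  eta_V: 45.3%   eta_Vp: 14.6%   eta_CL: 0.6%
```

The generating truth for this dataset was `tv_V = 6.795 L,
tv_Vp = 5.544 L, tv_CL = 3.394 L/h, tv_CLp = 13.086 L/h,
σ = 0.184` — the typical values are recovered within a few percent; the
covariate effects on only 10 patients (DIS) are, as the standard errors
say, weakly identified at this sample size. Validation and simulation hang
off the results object:

```python
from ilapop import bootstrap, vpc, gof_table, run_scenarios, effects_frame

bs  = bootstrap(result, n=1000, seed=1)    # subject resampling, per-study
v   = vpc(result, n_replicates=1000, seed=1)
gof = gof_table(result)                    # PRED / IPRED / CWRES
print(effects_frame(run_scenarios()))      # covariate-effect exposure table
```

The exposure table for the typical subject (healthy male, 60.6 kg; single
20 mg infusion) reports, on the hourly output grid:

```
      scenario  Cmax_ng_per_mL  AUC0t_ug_h_per_L  pct_diff_Cmax  pct_diff_AUC
     reference         1370.70           5504.56           0.00          0.00
        female         1436.22           6869.66           4.78         24.80
duodenal_ulcer         1141.81           4020.87         -16.70        -26.95
   weight_40kg         1625.14           5528.15          18.56          0.43
  weight_120kg         1028.53           5270.12         -24.96         -4.26
```

i.e. female sex raises exposure (AUC +24.8%) through its clearance effect,
duodenal ulcer lowers it (AUC −27%), and body weight mainly reshapes the
peak (|ΔCmax| < 25%) with little effect on AUC.

A command-line pipeline wraps the same steps
(`ilapop run --config config.yaml`, plus per-stage subcommands
`simulate-data`, `fit`, `compare`, `stepwise`, `bootstrap`, `vpc`,
`simulate-exposure`).

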