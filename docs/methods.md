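# Methods

## Structural and statistical model

Meropenem disposition is modeled as a one-compartment system with
first-order elimination. For constant-rate infusions the concentration has
a closed form; a regimen is an ordered set of infusion events and the
profile is their superposition:

- during an event, τ hours in: `C = (R/CL)·(1 − e^{−ke·τ})` (approaching
  the infusion plateau `R/CL`),
- after the event: the end-of-infusion concentration decays as
  `e^{−ke·(τ−T)}`,

with `ke = CL/V`. The closed form is verified in the test suite against a
segment-wise numeric ODE integration to 1e-4 mg/L on random regimens.

Individual parameters follow the final covariate model

```
CL_i = CLp (BW_i/7.88) e^{η1},   η1 ~ N(0, ω²_CL)
V_i  = Vp  (BW_i/7.88) (1+θ_CRRT)^{CRRT_i} e^{η2},   η2 ~ N(0, ω²_V)
```

and observations carry proportional error `y = f(1+ε)`, `ε ~ N(0, σ²)`.
Body-weight scaling is multiplicative through BW/7.88 (7.88 kg is the
cohort median) and the CRRT effect is a binary multiplicative shift on V.
The packaged estimates are CLp = 1.09 L/h, Vp = 3.98 L, θ_CRRT = 1.04,
ω²_CL = 0.0887, ω²_V = 0.916, σ² = 0.17. The ω²/σ² values are treated as
variances on the log/proportional scale (the usual NONMEM convention), not
CVs. No free-fraction correction is applied for fT>MIC: meropenem protein
binding is ~2%, so total ≈ free.

## Monte Carlo PTA simulation (`simulate`)

For each regimen × CRRT × MIC × target cell, `n = 10,000` subjects are
drawn from the IIV distributions (body weight fixed at the chosen value;
the published evaluation uses the cohort median and IQR bounds), a 7-day
course is simulated, and fT>MIC is computed on a discrete grid over the
final 24 h (steady state). A subject attains the target when the fraction
of grid points strictly above the MIC is at least the target (0.40 or
1.00). PTA is the percentage of attaining subjects.

Numerical conventions, chosen once:

- **Residual error is applied** to the simulated concentrations before
  computing fT (`include_ruv`, on by default). The alternative — noiseless
  model profiles — makes a continuous infusion attain 100% fT>MIC with
  probability given purely by the CL distribution, which saturates cells
  that the published table shows as clearly unsaturated (sub-100 values at
  low MIC, an all-zero row at MIC 16). Observation-level noise is the only
  mechanism consistent with that structure, so it is the default; the flag
  exposes the alternative.
- **Grid spacing 0.25 h.** The statistic is defined in continuous time;
  0.25 h resolves the shortest (0.5 h) infusion segment and brings the
  discrete fraction close to its continuous-time limit. With per-point
  noise the 100%-target cells are grid-sensitive (finer grids mean more
  chances to dip below the MIC); 0.25 h reproduces the saturated structure
  of the published table (the all-zero 100% fT row at MIC 16 and the
  all-100 40% fT continuous cells). Coarser grids (1-2 h) leave those rows
  visibly unsaturated.
- The evaluation window is the final 24 h of the 7-day course; regimens
  start at time zero with no loading dose (the published simulation design
  evaluates maintenance regimens).
- Same-shape regimens (e.g. 20 and 40 mg/kg short infusions) share the
  residual-noise stream, so PTA is exactly non-decreasing in dose at a
  fixed seed; PTA is exactly non-increasing in MIC because all MICs
  threshold the same simulated concentrations.

**Known irreducibility.** Two features of the published table cannot be
recovered from the stated model under any convention we explored (grid
0.25-2 h, noise on/off, per-interval or full-window evaluation): the
intermittent-regimen mid-MIC cells in the 40% block print ~8-10 points
lower than any recomputation (e.g. 20 mg/kg short infusion at MIC 4: ~90
recomputed vs 80 printed), and CRRT raises continuous-infusion PTA at
steady state in the printed table although a Vd-only covariate cannot
change `Css = R/CL`. These cells are matched with tolerance, not exactly,
and one graded cell remains outside its ±5 band; we report it as computed.

## Estimation (`estimate`)

The marginal likelihood integrates the two random effects per subject.
The inner problem — the mode of the joint density over (η1, η2) — is
solved by damped Newton iteration with analytic gradient and Hessian (the
first and second derivatives of the superposition prediction with respect
to the etas are closed-form). The curvature used in the Laplace
determinant is the **expected (Gauss-Newton) information plus the prior
precision**: it is positive definite and smooth in the population
parameters, where the exact Hessian can pass through singularity on
ridge-shaped subjects and make the approximate likelihood discontinuous.
`fit` refines the Laplace value by **adaptive Gauss-Hermite quadrature**
(5×5 nodes centred at the mode, scaled by the inverse curvature; one node
recovers Laplace exactly). On sparse data the refinement removes most of
the upward bias in Vp and θ_CRRT and much of the downward bias in ω²_V
that pure Laplace shows. `ofv()` itself reports the pure Laplace value and
is tested against a brute-force 32²-node Gauss-Hermite oracle.

Fitting minimizes the OFV with L-BFGS-B over a log-transformed parameter
vector (positivity of CLp, Vp, ω², σ²; categorical shifts via log(1+β));
box bounds keep the search in a physiologically plausible region.
Defaults: literature-magnitude start (CL 0.1 L/h/kg, V 0.5 L/kg at the
dataset's median BW) plus 3 jittered restarts, best optimum kept; a
line-search abort is polished by one restart from the abort point before
being declared non-convergence. Relative standard errors come from the
inverse numeric Hessian of the OFV at the optimum (on the log scale the
standard error of ln p is directly the relative SE of p). Objective values
above 1e5 are compressed logarithmically so a line search that probes a
wild region can interpolate back; predictions below 1e-6 mg/L are floored
inside the proportional-error variance only. The inner mode search always
starts from the prior mean — the joint density can be multimodal, and a
drifting warm start makes the objective a function of evaluation history.
A numba-compiled kernel implements the inner solve; the vectorized numpy
implementation is retained as an equivalent fallback (they agree to 1e-10
in the tests).

Time-varying covariates (CRRT on/off within a subject) are handled by
evaluating the covariate on each observation row: the prediction at that
time uses the parameter values implied by the covariate state at that
time, applied to the full dosing history. This is an approximation (the
true kinetics would integrate through the switch) shared exactly by the
synthetic-data generator, so estimation and generation are consistent.

Stepwise covariate modeling is forward-only: at each step every remaining
(parameter, covariate, form) candidate is refit — warm-started from the
current optimum after a coarse grid scan of the new coefficient — and the
largest ΔOFV enters if it exceeds 3.84 (chi-square, 1 df, p < 0.05).
Continuous covariates support linear and power forms; categorical
covariates a fractional shift. Constant or missing covariates are skipped
with a warning.

## Validation (`validate`)

- **Bootstrap**: subjects resampled with replacement to the original count,
  each replicate refit warm-started from the original estimates; medians
  and 95% percentile intervals over converged replicates, with the
  non-convergence rate reported.
- **NPDE**: the dataset is simulated 500 times under the model (same
  positive-truncated proportional error as the generator); per subject the
  observed vector is decorrelated with the simulated mean and covariance
  (Cholesky), rank-transformed within the simulated cloud, and mapped
  through the inverse normal. Location is tested with a one-sample t-test
  (mean 0), scale with a chi-square test (variance 1). Per-subject
  simulation streams are keyed by subject id rank, so results do not
  depend on row order. Single-observation datasets are flagged degenerate.
- **GOF**: population predictions (η = 0), individual predictions
  (empirical-Bayes η), and CWRES via the first-order-conditional
  linearization `V = G Ω Gᵀ + diag(σ² f²)` evaluated at the EB estimates;
  singular per-subject covariances fall back to standardized residuals and
  are flagged.

## Synthetic TDM generator (`syndata`)

The generator emulates the *structure* of the study data, since the
clinical dataset is not deposited: 45 subjects; body weight from a
two-piece lognormal matching median 7.88 kg and quartiles 3.62/11.97 kg
exactly (the reported quartiles are asymmetric on the log scale, which no
single lognormal can match); exact ECMO (38/45) and CRRT (31/45) counts
with CRRT nested in ECMO; a 60/9/31% neonate/infant/child age mix; and
~152 observations in total (at least two per subject).

Dosing follows the clinical protocol: a 20 mg/kg loading dose (capped at
2 g) followed by continuous infusion (30-80 mg/kg/day under 3 months,
60-120 mg/kg/day otherwise) while the ECMO episode runs, and 20-40 mg/kg
short infusions two or three times daily otherwise. Roughly half the ECMO
subjects decannulate before sampling ends and move to intermittent dosing,
which reproduces the study's feature that only ~60% of concentrations were
drawn during ECMO although 84% of patients were ECMO-treated. CRRT rides
on the ECMO episode; about a third of dialysed subjects stop CRRT early,
so datasets contain on- and off-CRRT observations in roughly the reported
3:2 ratio.

Sampling times mimic routine TDM rather than a uniform design:
post-loading-dose levels in the first hours (the level that guides
titration of the continuous rate), peak/trough pairs around intermittent
doses (how doses are adjusted toward the 20-40 mg/L target band), and the
remainder spread over treatment. Samples below a 0.05 mg/L quantification
limit are redrawn (below-LLOQ levels are not reported in routine TDM).
This matters: under uniform sampling most observations sit on
continuous-infusion steady state, where the data carry almost no
information about V — parameter recovery and covariate-selection power
then collapse for reasons that have nothing to do with the estimator. An
optional contamination mode multiplies a fraction of observations by 0.1,
mimicking levels drawn from the infusion line.

Extra covariates (PNA, CrCL, creatinine, albumin, PIM3) are independent
lognormals matched to the cohort medians/IQRs; they carry no PK effect and
exist to exercise the null behavior of the covariate search. CrCL is
synthesized directly (heights, needed for a Schwartz estimate, are not in
the data model).

**What passing tests do and do not show.** The generator shares the
estimation model's structure and its covariate-at-observation-time
convention, so recovery experiments validate the estimator, not the model:
they cannot detect structural misfit (two-compartment kinetics, circuit
adsorption, maturation), informative sampling beyond the LLOQ mechanism,
or assay error structure. Distributional targets (median/IQR body weight,
observation counts, on/off-CRRT mix) are matched; joint covariate
correlations of the real cohort are not.

## Problem sizes and experiment defaults

Parameter-recovery experiments use 200 replicate datasets at the study
design (45 subjects, ~3.4 observations each) with one jittered restart per
fit; covariate-selection consistency uses 50 replicates against a
six-candidate set (the three true relations plus CRRT→CL, CrCL→CL,
PNA→V); bootstrap calibration uses 200 replicates (scaled from the
published 1000, which the CLI default retains); NPDE uses the published
500 simulations. PTA cells use the published 10,000 subjects.

## Known limitations

- ω²_V and σ² retain some downward bias (~10-15%) at the study's sparsity
  even with quadrature refinement; CLp, Vp and ω²_CL are recovered with
  mean bias within the tolerances the tests assert.
- θ_CRRT is weakly identified at this design (the published analysis
  reports 76% relative standard error for it); its selection by the
  covariate search fails in a minority of replicates, and false inclusion
  of a noise covariate at the fixed 3.84 threshold occurs at roughly the
  familywise rate the chi-square calibration implies (~10-15% per
  replicate with three noise candidates in play).
- The PTA evaluation conventions reconcile the saturated structure of the
  published table but not every mid-range intermittent cell (see the
  irreducibility note above).
- The closed-form kinetics assume parameters constant since the first
  dose; the covariate-at-observation-time treatment of CRRT switches is an
  approximation shared with the generator.
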