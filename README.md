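# neoperem

Population pharmacokinetics of **meropenem in critically ill neonates and
children on ECMO and CRRT**: the final covariate model, Monte Carlo
probability-of-target-attainment (PTA) dosing evaluation, nonlinear
mixed-effects estimation with stepwise covariate modeling, bootstrap and
NPDE model validation, and a synthetic sparse-TDM data generator.

## The problem

Meropenem is a time-dependent beta-lactam: efficacy tracks the fraction of
time the concentration stays above the pathogen's MIC (fT>MIC; 40% for
susceptible organisms, 100% in severe infection). In neonatal/pediatric
extracorporeal membrane oxygenation (ECMO), disposition is distorted by
critical illness and by continuous renal replacement therapy (CRRT)
superimposed on the circuit, so standard dosing may miss those targets.
This package encodes the final population model for that setting and turns
it into a simulation and estimation toolkit.

## The model

One-compartment disposition with first-order elimination and log-normal
inter-individual variability (IIV):

```
CL_i = CLp · (BW_i / 7.88) · exp(η_CL),          η_CL ~ N(0, ω²_CL)
V_i  = Vp  · (BW_i / 7.88) · (1 + θ_CRRT)^CRRT_i · exp(η_V)
y_ij = f(t_ij; CL_i, V_i) · (1 + ε_ij),          ε_ij ~ N(0, σ²)
```

Packaged final estimates (at the 7.88 kg reference body weight):
CLp = 1.09 L/h, Vp = 3.98 L, θ_CRRT = 1.04 (CRRT roughly doubles V),
ω²_CL = 0.0887, ω²_V = 0.916, σ² = 0.17 (proportional). Concentration-time
profiles use the closed-form constant-rate-infusion solution superposed
over dose events; estimation maximizes a Laplace/adaptive-Gauss-Hermite
approximation to the marginal likelihood (OFV = −2 log L; ΔOFV > 3.84 for
nested-model selection).

## Worked example

```python
from neoperem import load_final_model, SubjectCovariates, individual_params
from neoperem.simulate import SimulationConfig, build_regimen, pta

pop = load_final_model()
ind = individual_params(pop, SubjectCovariates(bw=7.88, crrt_on=1))
print(f"CL={ind.cl:.2f} L/h  V={ind.v:.2f} L")

cfg = SimulationConfig(n_subjects=10_000, crrt_on=1, seed=1)
reg = build_regimen("continuous", 120, 7.88, cfg.horizon)
res = pta(pop, [reg], mic_grid=[2.0, 8.0], targets=[0.40, 1.00], cfg=cfg)
print(res.table[["mic", "target", "pta"]].to_string(index=False))
```

prints

```
CL=1.09 L/h  V=8.12 L
 mic  target    pta
 2.0     0.4 100.00
 2.0     1.0  33.52
 8.0     0.4 100.00
 8.0     1.0   6.79
```

i.e. a typical 7.88 kg patient on CRRT under 120 mg/kg/day continuous
infusion attains 40% fT>MIC essentially always up to MIC 8 mg/L, while the
stringent 100% fT>MIC target — every grid point above the MIC, with
observation-level noise included — is missed by most subjects already at
MIC 2: the package-level restatement of why severe infections need
individualized dosing.

The same pipeline is scriptable from the shell:

```bash
neoperem generate --seed 1 --out tdm.csv        # synthetic 45-subject TDM set
neoperem fit --data tdm.csv --out fit.json      # NLME fit of the final model
neoperem scm --data tdm.csv --out steps.csv     # forward covariate search
neoperem bootstrap --data tdm.csv --n 1000 --out boot.csv
neoperem npde --data tdm.csv --nsim 500 --out npde.json
neoperem report --n 10000 --seed 1 --out-dir pta/   # full PTA table
```

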