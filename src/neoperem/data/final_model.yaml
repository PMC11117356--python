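# Final covariate model parameter estimates (fixed effects, variance
# components and the reference body weight).  omega2_* and sigma2_prop are
# variances on the log / proportional scale.
clp: 1.09         # L/h at 7.88 kg
vp: 3.98          # L at 7.88 kg, off CRRT
theta_crrt: 1.04  # fractional Vd increase on CRRT
omega2_cl: 0.0887
omega2_v: 0.916
sigma2_prop: 0.17
bw_ref: 7.88      # kg
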