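seed: 1
out_dir: results
k_saline: 0.006
k_serum: 0.025
c0_saline: 20000.0
c0_serum: 50.0
assay_cv: 0.05
replicates: 2
metabolite_yield: 0.8
stability_threshold: 0.9
run_serum_stage: true
v: 26.2
theta_cl_nongfr: 3.6
omega_cl: 0.149
sigma_prop: 0.135
n_patients: 6
gfr_range:
- 28.0
- 307.0
dose_range:
- 125.0
- 250.0
samples_per_patient: 4
estimation_method: laplace
n_starts: 5
ratio_basis: mass
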