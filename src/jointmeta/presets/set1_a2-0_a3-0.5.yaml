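K: 5
n_per_study: 500
meas_times:
- 0.0
- 0.25
- 0.5
- 1.0
- 1.5
- 2.0
- 2.5
- 3.0
- 3.5
- 4.0
beta10: 1.0
beta11: 3.0
beta12: 2.0
beta21: 3.0
D:
- - 1.0
  - 0.5
- - 0.5
  - 1.5
A:
- - 1.0
  - 0.5
- - 0.5
  - 1.5
alpha2: 0.0
alpha3: 0.5
sigma_e2: 0.01
mu0: 3.0
sigma0: 0.5
lambda_cens: 0.6531163421206756
cure_condition: full
name: set1_a2-0_a3-0.5
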