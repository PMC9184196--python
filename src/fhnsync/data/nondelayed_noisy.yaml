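b:
- 1.0
- 1.001
- 1.002
- 1.003
- 1.004
c:
- 0.001
- 0.002
- 0.003
- 0.004
- 0.005
controller_gain_columns:
- 1
- 2
controller_law: nondelayed
controller_t_on: 150.0
coupling:
- - -0.0010735
  - 0.00036412
  - 0.00040396
  - 2.064e-05
  - 0.00028481
- - 0.00036412
  - -0.001507
  - 0.00083269
  - 0.00016223
  - 0.00014797
- - 0.00040396
  - 0.00083269
  - -0.0022451
  - 0.00081832
  - 0.00019013
- - 2.064e-05
  - 0.00016223
  - 0.00081832
  - -0.0016371
  - 0.00063596
- - 0.00028481
  - 0.00014797
  - 0.00019013
  - 0.00063596
  - -0.0012589
disturbance_amplitude:
- 0.001
- 0.002
- 0.003
- 0.004
- 0.005
disturbance_rate:
- 0.2
- 0.2
- 0.2
- 0.2
- 0.2
drive_ic:
- 0.0
- 0.05
- 0.05
- 0.0
- 0.05
- 0.1
- 0.2
- 0.2
- 0.1
- 0.2
ees_A: 0.1
ees_f: 0.129
n: 5
noise_D: 0.01
noise_common: true
noise_seed: 0
r:
- 10.0
- 10.2
- 10.4
- 10.6
- 10.8
slave_ic:
- 0.0
- 0.05
- 0.05
- 0.0
- 0.05
- 0.1
- 0.2
- 0.2
- 0.1
- 0.2
slave_ic_perturbation: 0.001
tau1: 0.0
tau2: 0.0
variant: nondelayed_noisy
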