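name: table4_scenario1
rows: 2
cols: 4
tox_probs:
- [0.01, 0.1, 0.4, 0.5]
- [0.05, 0.15, 0.45, 0.55]
eff_means:
- [0.5, 0.0, -1.5, -2.5]
- [-1.5, -2.0, -3.5, -4.5]
eff_sd: 1.0
phi: 0.3
psi: 0.0
targets:
- [2, 2]
n: 60
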