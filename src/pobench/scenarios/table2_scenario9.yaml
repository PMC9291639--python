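name: table2_scenario9
rows: 3
cols: 5
tox_probs:
- [0.005, 0.01, 0.02, 0.04, 0.07]
- [0.02, 0.05, 0.08, 0.12, 0.15]
- [0.15, 0.3, 0.45, 0.55, 0.65]
gamma: 0.3
targets:
- [3, 2]
n: 60
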