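name: table2_scenario5
rows: 3
cols: 5
tox_probs:
- [0.01, 0.02, 0.08, 0.1, 0.11]
- [0.03, 0.05, 0.1, 0.13, 0.15]
- [0.07, 0.09, 0.12, 0.15, 0.3]
gamma: 0.3
targets:
- [3, 5]
n: 60
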