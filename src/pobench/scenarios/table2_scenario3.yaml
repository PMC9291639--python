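name: table2_scenario3
rows: 3
cols: 5
tox_probs:
- [0.02, 0.07, 0.1, 0.15, 0.3]
- [0.07, 0.1, 0.15, 0.3, 0.45]
- [0.1, 0.15, 0.3, 0.45, 0.55]
gamma: 0.3
targets:
- [1, 5]
- [2, 4]
- [3, 3]
n: 60
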