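name: table1_scenario2
rows: 3
cols: 3
tox_probs:
- [0.05, 0.15, 0.3]
- [0.15, 0.3, 0.45]
- [0.45, 0.55, 0.6]
gamma: 0.3
targets:
- [1, 3]
- [2, 2]
n: 36
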