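name: table2_scenario7
rows: 3
cols: 5
tox_probs:
- [0.07, 0.1, 0.12, 0.15, 0.3]
- [0.15, 0.3, 0.45, 0.52, 0.6]
- [0.3, 0.5, 0.6, 0.65, 0.75]
gamma: 0.3
targets:
- [1, 5]
- [2, 2]
- [3, 1]
n: 60
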