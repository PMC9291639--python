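name: table2_scenario2
rows: 3
cols: 5
tox_probs:
- [0.15, 0.3, 0.45, 0.5, 0.6]
- [0.3, 0.45, 0.5, 0.6, 0.75]
- [0.45, 0.55, 0.6, 0.6, 0.8]
gamma: 0.3
targets:
- [1, 2]
- [2, 1]
n: 60
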