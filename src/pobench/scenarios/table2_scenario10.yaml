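name: table2_scenario10
rows: 3
cols: 5
tox_probs:
- [0.05, 0.1, 0.15, 0.3, 0.45]
- [0.45, 0.5, 0.6, 0.65, 0.7]
- [0.7, 0.75, 0.8, 0.85, 0.9]
gamma: 0.3
targets:
- [1, 4]
n: 60
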