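name: table2_scenario4
rows: 3
cols: 5
tox_probs:
- [0.3, 0.45, 0.6, 0.7, 0.8]
- [0.45, 0.55, 0.65, 0.75, 0.85]
- [0.5, 0.6, 0.7, 0.8, 0.9]
gamma: 0.3
targets:
- [1, 1]
n: 60
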