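name: table2_scenario8
rows: 3
cols: 5
tox_probs:
- [0.02, 0.1, 0.15, 0.5, 0.6]
- [0.05, 0.12, 0.3, 0.55, 0.7]
- [0.08, 0.15, 0.45, 0.6, 0.8]
gamma: 0.3
targets:
- [2, 3]
n: 60
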